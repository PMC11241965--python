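"""Core data model for EV proteomics matrices, sample metadata and clinical scores.

An :class:`AbundanceTable` holds a proteins x samples intensity matrix with an
explicit missing marker (NaN).  Non-detections are *missing*, never zero:
label-free LC/MS non-quantification is censoring, and ``log10(0)`` is
undefined.  Raw-scale intensities are strictly positive where observed;
log10-scale values are finite where observed.

Sample metadata travels as a plain :class:`pandas.DataFrame` with a fixed
column contract (see :data:`SAMPLE_INFO_COLUMNS`); clinical ALSFRS-R score
series are small per-subject records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "ALSFRSSeries",
    "SAMPLE_INFO_COLUMNS",
    "read_abundance",
    "write_abundance",
    "read_sample_info",
    "write_sample_info",
    "read_alsfrs",
    "write_alsfrs",
    "to_log10",
    "from_log10",
    "detection_rate",
    "validate_sample_info",
]

#: Required columns of a sample-metadata table.
SAMPLE_INFO_COLUMNS = (
    "sample_id",
    "subject_id",
    "cohort",      # control | SALS
    "fluid",       # serum | CSF
    "week",        # integer >= 0; controls: single draw recorded as week 0
    "arm",         # ROPI | placebo | none
    "batch",       # 1 | 2
    "ropi_exposed",  # bool: subject had received drug by this draw
)


@dataclass
class AbundanceTable:
    """Proteins x samples intensity matrix with explicit missingness.

    Parameters
    ----------
    data
        DataFrame indexed by protein id, columns are sample ids, ``NaN``
        marks a missing (non-detected) measurement.
    scale
        ``"raw"`` (positive intensities, arbitrary units) or ``"log10"``.
    """

    data: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log10"):
            raise ValueError(f"scale must be 'raw' or 'log10', got {self.scale!r}")
        dup_p = self.data.index[self.data.index.duplicated()].unique()
        if len(dup_p):
            raise ValueError(f"duplicate protein id(s): {list(dup_p)[:5]}")
        dup_s = self.data.columns[self.data.columns.duplicated()].unique()
        if len(dup_s):
            raise ValueError(f"duplicate sample id(s): {list(dup_s)[:5]}")
        self.data.index.name = "protein_id"
        values = self.data.to_numpy(dtype=float)
        if self.scale == "raw":
            bad = np.asarray(values <= 0) & ~np.isnan(values)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    "raw-scale values must be > 0 or missing; offending cell "
                    f"protein={self.data.index[i]!r} sample={self.data.columns[j]!r} "
                    f"value={values[i, j]}"
                )
        else:
            bad = ~np.isfinite(values) & ~np.isnan(values)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    "log10-scale values must be finite or missing; offending cell "
                    f"protein={self.data.index[i]!r} sample={self.data.columns[j]!r}"
                )

    @property
    def protein_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def subset_samples(self, sample_ids: Iterable) -> "AbundanceTable":
        ids = list(sample_ids)
        missing = set(ids) - set(self.data.columns)
        if missing:
            raise KeyError(f"unknown sample id(s): {sorted(missing)[:5]}")
        return AbundanceTable(self.data[ids].copy(), scale=self.scale)

    def subset_proteins(self, protein_ids: Iterable) -> "AbundanceTable":
        ids = list(protein_ids)
        missing = set(ids) - set(self.data.index)
        if missing:
            raise KeyError(f"unknown protein id(s): {sorted(missing)[:5]}")
        return AbundanceTable(self.data.loc[ids].copy(), scale=self.scale)


@dataclass
class ALSFRSSeries:
    """Per-subject ALSFRS-R clinical score series.

    Weeks are strictly increasing; scores lie in [0, 48] (integers in real
    data, floats accepted so noiseless model curves can be fitted exactly).
    """

    subject_id: str
    weeks: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.weeks = np.asarray(self.weeks, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.weeks.shape != self.scores.shape:
            raise ValueError("weeks and scores must have equal length")
        if np.any(np.diff(self.weeks) <= 0):
            raise ValueError(f"weeks must be strictly increasing for {self.subject_id}")
        if np.any((self.scores < 0) | (self.scores > 48)):
            raise ValueError(f"scores must lie in [0, 48] for {self.subject_id}")


def _sep_for(path: Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_abundance(path, missing_token: str = "NA") -> AbundanceTable:
    """Read a raw-scale abundance matrix from delimited text.

    First column = protein ids, header row = sample ids.  Cells equal to
    ``missing_token`` or empty become missing.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=_sep_for(path),
        index_col=0,
        na_values=[missing_token, ""],
        keep_default_na=False,
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df = df.astype(float)
    return AbundanceTable(df, scale="raw")


def write_abundance(table: AbundanceTable, path, missing_token: str = "NA") -> None:
    path = Path(path)
    df = table.data.copy()
    df.index.name = "protein_id"
    df.to_csv(path, sep=_sep_for(path), na_rep=missing_token)


def validate_sample_info(info: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table against the column contract.

    Checks the trial-design invariants: controls have arm ``none`` and are
    never drug-exposed; ROPI-arm samples after week 0 are exposed; placebo-arm
    samples are exposed exactly after week 24 (the open-label extension).
    """
    missing = set(SAMPLE_INFO_COLUMNS) - set(info.columns)
    if missing:
        raise ValueError(f"sample info missing column(s): {sorted(missing)}")
    info = info.copy()
    info["week"] = info["week"].astype(int)
    info["batch"] = info["batch"].astype(int)
    if info["ropi_exposed"].dtype != bool:
        info["ropi_exposed"] = (
            info["ropi_exposed"].astype(str).str.lower().isin(("true", "1", "yes"))
        )
    dup = info["sample_id"][info["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample id(s) in metadata: {list(dup)[:5]}")
    ctrl = info[info["cohort"] == "control"]
    if ((ctrl["arm"] != "none") | ctrl["ropi_exposed"]).any():
        raise ValueError("controls must have arm='none' and ropi_exposed=False")
    ropi = info[(info["arm"] == "ROPI") & (info["week"] > 0)]
    if (~ropi["ropi_exposed"]).any():
        raise ValueError("ROPI-arm samples at week > 0 must be ropi_exposed")
    plc = info[info["arm"] == "placebo"]
    if (plc.loc[plc["week"] <= 24, "ropi_exposed"]).any():
        raise ValueError("placebo-arm samples at week <= 24 must not be ropi_exposed")
    if (~plc.loc[plc["week"] > 24, "ropi_exposed"]).any():
        raise ValueError("placebo-arm samples at week > 24 must be ropi_exposed")
    return info


def read_sample_info(path) -> pd.DataFrame:
    path = Path(path)
    info = pd.read_csv(path, sep=_sep_for(path))
    return validate_sample_info(info)


def write_sample_info(info: pd.DataFrame, path) -> None:
    path = Path(path)
    info.to_csv(path, sep=_sep_for(path), index=False)


def read_alsfrs(path) -> list:
    """Read ALSFRS-R series (columns subject_id, week, alsfrs_r), one per subject."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    out = []
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("week")
        out.append(
            ALSFRSSeries(
                subject_id=str(sid),
                weeks=grp["week"].to_numpy(),
                scores=grp["alsfrs_r"].to_numpy(),
            )
        )
    return out


def write_alsfrs(series: Iterable[ALSFRSSeries], path) -> None:
    path = Path(path)
    rows = []
    for s in series:
        for w, v in zip(s.weeks, s.scores):
            rows.append({"subject_id": s.subject_id, "week": int(w), "alsfrs_r": v})
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


def to_log10(table: AbundanceTable) -> AbundanceTable:
    """log10-transform a raw-scale table; missing cells stay missing.

    A zero raw value is an error: non-detections must be encoded as missing
    upstream, not as zero.
    """
    if table.scale != "raw":
        raise ValueError("to_log10 expects a raw-scale table")
    values = table.data.to_numpy(dtype=float)
    if np.any(np.asarray(values == 0)):
        i, j = np.argwhere(values == 0)[0]
        raise ValueError(
            f"zero intensity at protein={table.data.index[i]!r} "
            f"sample={table.data.columns[j]!r}; encode non-detections as missing"
        )
    out = pd.DataFrame(
        np.log10(values), index=table.data.index, columns=table.data.columns
    )
    return AbundanceTable(out, scale="log10")


def from_log10(table: AbundanceTable) -> AbundanceTable:
    """Pointwise 10**x back-transform of a log10-scale table."""
    if table.scale != "log10":
        raise ValueError("from_log10 expects a log10-scale table")
    out = pd.DataFrame(
        np.power(10.0, table.data.to_numpy(dtype=float)),
        index=table.data.index,
        columns=table.data.columns,
    )
    return AbundanceTable(out, scale="raw")


def detection_rate(table: AbundanceTable, sample_subset: Iterable) -> pd.Series:
    """Fraction of subset samples with a non-missing value, per protein."""
    ids = list(sample_subset)
    if not ids:
        raise ValueError("sample subset must be non-empty")
    sub = table.subset_samples(ids)
    return sub.data.notna().mean(axis=1)
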