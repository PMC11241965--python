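"""Drug-response scoring by effect size on per-patient fold changes.

Each patient's 0-to-24-week log2 fold change (on raw, batch-corrected
intensities) is compared between treatment arms with Cohen's d,

    d = (mean_ROPI - mean_placebo) / s_pooled,

banded negligible / small / medium / large at |d| cut-points 0.2 / 0.5 / 0.8.
Proteins with a medium-or-greater drug effect (|d| >= 0.5) are called
effect-size-based differentially abundant proteins (es-DAPs); with small
arms, plain significance testing is underpowered and the effect-size route
is the informative one.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AbundanceTable

__all__ = [
    "per_patient_log2fc",
    "cohen_d",
    "magnitude_band",
    "es_dap_table",
    "ES_DAP_THRESHOLD",
]

#: |Cohen's d| at and above which a protein is an es-DAP (medium or large).
ES_DAP_THRESHOLD = 0.5


def per_patient_log2fc(table: AbundanceTable, info: pd.DataFrame,
                       week: int, baseline_week: int = 0) -> pd.DataFrame:
    """Per-protein, per-patient log2(value_week / value_baseline).

    Operates on raw intensities.  Patients lacking a sample at either week
    are excluded; bridge re-measurements are ignored.  Returns proteins x
    subjects; a cell is missing if either endpoint is missing.
    """
    if table.scale != "raw":
        raise ValueError("fold changes are computed on raw intensities")
    ids = set(table.sample_ids)
    meta = info[(info["sample_id"].isin(ids)) & (info["cohort"] == "SALS")]
    if "bridge_of" in meta.columns:
        meta = meta[meta["bridge_of"].fillna("") == ""]
    at_base = meta[meta["week"] == baseline_week].set_index("subject_id")["sample_id"]
    at_week = meta[meta["week"] == week].set_index("subject_id")["sample_id"]
    subjects = sorted(set(at_base.index) & set(at_week.index))
    if not subjects:
        raise ValueError(f"no subject has samples at weeks {baseline_week} and {week}")
    base = table.data[[at_base[s] for s in subjects]].to_numpy()
    late = table.data[[at_week[s] for s in subjects]].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.log2(late / base)
    return pd.DataFrame(fc, index=table.data.index.copy(), columns=subjects)


def cohen_d(group_a: Sequence, group_b: Sequence) -> float:
    """Pooled-SD Cohen's d of group a minus group b on non-missing values.

    Zero pooled variance with equal means gives 0; with unequal means,
    signed infinity.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 non-missing values")
    diff = a.mean() - b.mean()
    s2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if s2 == 0:
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return float(diff / np.sqrt(s2))


def magnitude_band(d: float) -> str:
    """Band |d|: <0.2 negligible, <0.5 small, <0.8 medium, >=0.8 large."""
    ad = abs(d)
    if ad < 0.2:
        return "negligible"
    if ad < 0.5:
        return "small"
    if ad < 0.8:
        return "medium"
    return "large"


def es_dap_table(fc: pd.DataFrame, info: pd.DataFrame,
                 threshold: float = ES_DAP_THRESHOLD) -> pd.DataFrame:
    """Per-protein effect-size records comparing arms on fold changes.

    ``fc`` is a proteins x subjects fold-change frame; arm membership is read
    from the metadata.  d is ROPI minus placebo, so d > 0 means the protein
    is increased by the drug.  Proteins with fewer than two observed fold
    changes in either arm are flagged untestable.
    """
    arm = info.drop_duplicates("subject_id").set_index("subject_id")["arm"]
    ropi_subj = [s for s in fc.columns if arm.get(s) == "ROPI"]
    plc_subj = [s for s in fc.columns if arm.get(s) == "placebo"]
    if not ropi_subj or not plc_subj:
        raise ValueError("both arms must be represented among subjects")
    a = fc[ropi_subj].to_numpy()
    b = fc[plc_subj].to_numpy()
    na, nb = (~np.isnan(a)).sum(axis=1), (~np.isnan(b)).sum(axis=1)
    tested = (na >= 2) & (nb >= 2)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma, mb = np.nanmean(a, axis=1), np.nanmean(b, axis=1)
        va = np.nanvar(a, axis=1, ddof=1)
        vb = np.nanvar(b, axis=1, ddof=1)
    s2 = ((na - 1) * va + (nb - 1) * vb) / np.maximum(na + nb - 2, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (ma - mb) / np.sqrt(s2)
    d = np.where(s2 == 0, np.where(ma == mb, 0.0, np.sign(ma - mb) * np.inf), d)
    d = np.where(tested, d, np.nan)
    out = pd.DataFrame(
        {
            "cohen_d": d,
            "magnitude": [magnitude_band(x) if np.isfinite(x) or np.isinf(x)
                          else "untestable" for x in d],
            "is_es_dap": np.where(np.isnan(d), False, np.abs(d) >= threshold),
            "direction": np.where(d >= 0, "increased_by_ropi", "decreased_by_ropi"),
            "tested": tested,
            "n_ropi": na,
            "n_placebo": nb,
        },
        index=fc.index.copy(),
    )
    return out
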