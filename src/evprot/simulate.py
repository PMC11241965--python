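"""Synthetic trial-cohort generator with planted ground truth.

Emulates the sampling design of a two-arm longitudinal EV-proteomics trial:
10 healthy controls with one draw per fluid, 20 sporadic-ALS patients sampled
at weeks {0, 13, 24, 39, 48} (serum) and {0, 24, 48} (CSF), 13 assigned to the
drug (ROPI) arm and 7 to placebo with an open-label switch after week 24, two
measurement batches linked by bridge samples, left-censored missingness at a
detection limit, and exponential ALSFRS-R clinical decline.

Generative model (log10 scale), protein ``p``, subject ``s``, week ``t``::

    L(p,s,t) = mu_p + disease_p * 1[SALS] + slope_p * P_att(s,t)
               + batch_p * 1[batch 2] + eps(p,s,t)

where ``P(s,t) = exp(a_s t) - 1`` is the subject's modelled progression
burden (zero at baseline and for controls; equals ``(b_s - aALSFRS(s,t)) - 1``
under the clinical model ``-exp(a t) + b``) and drug exposure attenuates the
burden *increment* accrued after exposure starts::

    P_att(s,t) = P(s,t0) + (1 - ropi_attenuation) * (P(s,t) - P(s,t0)),
    t0 = min(t, exposure_start)   # 0 for ROPI arm, 24 for placebo, inf controls

Inflammation-class proteins carry ``disease_p = +disease_shift`` and
``slope_p > 0``; UPR-class proteins the negated signs; null proteins zero.
The noise draw ``eps`` belongs to the (protein, subject, week) sample, so the
two emissions of a bridge sample differ only by the batch factor — bridge
samples are aliquots of one physical sample.

The observed raw intensity is ``10**L`` when ``L`` exceeds the log10 limit of
detection, otherwise missing (left-censoring).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    AbundanceTable,
    ALSFRSSeries,
    validate_sample_info,
    write_abundance,
    write_alsfrs,
    write_sample_info,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "CohortData",
    "simulate_alsfrs",
    "simulate_cohort",
    "write_cohort",
    "bridge_pairs",
]

#: Weeks at which the clinical score is recorded.
ALSFRS_WEEKS = tuple(range(0, 61, 4))


@dataclass
class SimulationConfig:
    """Study-design and effect-size parameters of the synthetic cohort."""

    n_controls: int = 10
    n_sals: int = 20
    n_ropi: int = 13
    n_placebo: int = 7
    serum_weeks: tuple = (0, 13, 24, 39, 48)
    csf_weeks: tuple = (0, 24, 48)
    n_proteins: int = 1000
    frac_inflammation_up: float = 0.10
    frac_upr_down: float = 0.10
    disease_shift_log10: float = 0.3
    trend_scale: float = 1.0
    ropi_attenuation: float = 0.8    # fraction of post-exposure trend removed
    batch_sd_log10: float = 0.15
    noise_sd_log10: float = 0.1
    baseline_mean_log10: float = 6.5
    baseline_sd_log10: float = 0.8
    lod_log10: float = 5.0
    n_bridge: int = 3
    a_log_mean: float = math.log(0.02)
    a_log_sd: float = 0.5
    b_mean: float = 45.0
    b_sd: float = 2.0
    score_noise_sd: float = 1.0
    placebo_switch_week: int = 24    # open-label extension start
    seed: int = 0

    def validate(self) -> None:
        if self.frac_inflammation_up + self.frac_upr_down > 1:
            raise ValueError("planted class fractions must sum to <= 1")
        if self.n_ropi + self.n_placebo != self.n_sals:
            raise ValueError("n_ropi + n_placebo must equal n_sals")
        for name in ("batch_sd_log10", "noise_sd_log10", "score_noise_sd",
                     "a_log_sd", "b_sd", "baseline_sd_log10"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.ropi_attenuation <= 1:
            raise ValueError("ropi_attenuation must lie in [0, 1]")
        if self.n_bridge > self.n_sals:
            raise ValueError("n_bridge cannot exceed n_sals")


@dataclass
class SyntheticTruth:
    """Planted parameters the recovery tests score against.

    ``proteins``: per-protein class label, baseline, disease shift, trend
    slope, and per-fluid log10 batch factor.  ``subjects``: per-patient
    (a, b) of the clinical model and arm.  ``bridge_subjects``: patients whose
    week-0 samples were measured in both batches.
    """

    proteins: pd.DataFrame
    subjects: pd.DataFrame
    bridge_subjects: list
    config: SimulationConfig


@dataclass
class CohortData:
    """One simulated cohort: raw tables per fluid, metadata, scores, truth."""

    tables: dict
    info: pd.DataFrame
    alsfrs: list
    truth: SyntheticTruth


def simulate_alsfrs(config: SimulationConfig, a: float, b: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Noisy, rounded, clipped ALSFRS-R scores at :data:`ALSFRS_WEEKS`."""
    weeks = np.asarray(ALSFRS_WEEKS, dtype=float)
    eps = rng.normal(0.0, config.score_noise_sd, size=weeks.size) \
        if config.score_noise_sd > 0 else np.zeros(weeks.size)
    scores = -np.exp(a * weeks) + b + eps
    return np.clip(np.round(scores), 0, 48)


def _progression_burden(a: float, week: float) -> float:
    return math.exp(a * week) - 1.0


def _attenuated_burden(a: float, week: float, exposure_start: float,
                       attenuation: float) -> float:
    t0 = min(week, exposure_start)
    p0 = _progression_burden(a, t0)
    return p0 + (1.0 - attenuation) * (_progression_burden(a, week) - p0)


def _protein_truth(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_proteins
    width = len(str(n))
    ids = [f"PROT{i + 1:0{width}d}" for i in range(n)]
    n_inf = int(round(cfg.frac_inflammation_up * n))
    n_upr = int(round(cfg.frac_upr_down * n))
    classes = np.array(
        ["inflammation_up"] * n_inf + ["upr_down"] * n_upr
        + ["null"] * (n - n_inf - n_upr)
    )
    rng.shuffle(classes)
    sign = np.where(classes == "inflammation_up", 1.0,
                    np.where(classes == "upr_down", -1.0, 0.0))
    mu = rng.normal(cfg.baseline_mean_log10, cfg.baseline_sd_log10, size=n)
    disease = sign * cfg.disease_shift_log10
    # trend slope per unit progression burden; magnitude centred on the
    # disease shift so a median progressor's accrued longitudinal change over
    # the trial matches the cross-sectional disease contrast
    slope = sign * rng.uniform(0.2, 0.4, size=n) * cfg.trend_scale
    batch_serum = rng.normal(0.0, cfg.batch_sd_log10, size=n)
    batch_csf = rng.normal(0.0, cfg.batch_sd_log10, size=n)
    return pd.DataFrame(
        {
            "protein_class": classes,
            "mu_log10": mu,
            "disease_shift_log10": disease,
            "trend_slope_log10": slope,
            "batch_factor_serum_log10": batch_serum,
            "batch_factor_csf_log10": batch_csf,
        },
        index=pd.Index(ids, name="protein_id"),
    )


def simulate_cohort(config: SimulationConfig | None = None) -> CohortData:
    """Simulate one full cohort with ground truth.

    Same seed gives bit-identical output.  Patients are measured in batch 1,
    controls in batch 2; the week-0 samples of ``n_bridge`` patients are
    emitted a second time in batch 2 (suffix ``_b2``) as bridge samples.
    """
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    proteins = _protein_truth(cfg, rng)

    pat_ids = [f"P{i + 1:02d}" for i in range(cfg.n_sals)]
    ctl_ids = [f"C{i + 1:02d}" for i in range(cfg.n_controls)]
    arms = ["ROPI"] * cfg.n_ropi + ["placebo"] * cfg.n_placebo
    a_vals = rng.lognormal(cfg.a_log_mean, cfg.a_log_sd, size=cfg.n_sals)
    b_vals = rng.normal(cfg.b_mean, cfg.b_sd, size=cfg.n_sals)
    subjects = pd.DataFrame(
        {"arm": arms, "a": a_vals, "b": b_vals},
        index=pd.Index(pat_ids, name="subject_id"),
    )
    bridge_subjects = list(rng.choice(pat_ids, size=cfg.n_bridge, replace=False))

    alsfrs = [
        ALSFRSSeries(sid, np.asarray(ALSFRS_WEEKS, dtype=float),
                     simulate_alsfrs(cfg, subjects.at[sid, "a"],
                                     subjects.at[sid, "b"], rng))
        for sid in pat_ids
    ]

    tables: dict = {}
    info_rows: list = []
    fluid_weeks = {"serum": cfg.serum_weeks, "csf": cfg.csf_weeks}
    for fluid in ("serum", "csf"):
        weeks = fluid_weeks[fluid]
        batch_col = proteins[f"batch_factor_{fluid}_log10"].to_numpy()

        # core physical samples: (subject, week) for patients, week 0 for controls
        core: list = []          # (subject_id, cohort, arm, week)
        for sid in pat_ids:
            for w in weeks:
                core.append((sid, "SALS", subjects.at[sid, "arm"], w))
        for sid in ctl_ids:
            core.append((sid, "control", "none", 0))

        slope = proteins["trend_slope_log10"].to_numpy()
        disease = proteins["disease_shift_log10"].to_numpy()
        mu = proteins["mu_log10"].to_numpy()

        burden = np.zeros(len(core))
        is_sals = np.zeros(len(core))
        for j, (sid, cohort, arm, w) in enumerate(core):
            if cohort != "SALS":
                continue
            is_sals[j] = 1.0
            exposure_start = 0.0 if arm == "ROPI" else float(cfg.placebo_switch_week)
            burden[j] = _attenuated_burden(subjects.at[sid, "a"], float(w),
                                           exposure_start, cfg.ropi_attenuation)

        eps = rng.normal(0.0, cfg.noise_sd_log10,
                         size=(cfg.n_proteins, len(core))) \
            if cfg.noise_sd_log10 > 0 else np.zeros((cfg.n_proteins, len(core)))
        base = (mu[:, None] + disease[:, None] * is_sals[None, :]
                + slope[:, None] * burden[None, :] + eps)

        # emissions: every core sample once in its home batch, bridge week-0
        # samples a second time in batch 2
        col_ids: list = []
        col_core: list = []
        col_batch: list = []
        for j, (sid, cohort, arm, w) in enumerate(core):
            home_batch = 1 if cohort == "SALS" else 2
            sample_id = f"{sid}_{fluid}_w{w}"
            col_ids.append(sample_id)
            col_core.append(j)
            col_batch.append(home_batch)
            info_rows.append(
                dict(sample_id=sample_id, subject_id=sid, cohort=cohort,
                     fluid=fluid, week=w, arm=arm, batch=home_batch,
                     ropi_exposed=_exposed(arm, w, cfg), bridge_of="")
            )
            if cohort == "SALS" and w == 0 and sid in bridge_subjects:
                dup_id = f"{sample_id}_b2"
                col_ids.append(dup_id)
                col_core.append(j)
                col_batch.append(2)
                info_rows.append(
                    dict(sample_id=dup_id, subject_id=sid, cohort=cohort,
                         fluid=fluid, week=w, arm=arm, batch=2,
                         ropi_exposed=False, bridge_of=sample_id)
                )

        L = base[:, col_core] + batch_col[:, None] * (np.asarray(col_batch) == 2)
        raw = np.power(10.0, L)
        raw[L <= cfg.lod_log10] = np.nan
        tables[fluid] = AbundanceTable(
            pd.DataFrame(raw, index=proteins.index.copy(), columns=col_ids),
            scale="raw",
        )

    info = validate_sample_info(pd.DataFrame(info_rows))
    truth = SyntheticTruth(proteins=proteins, subjects=subjects,
                           bridge_subjects=bridge_subjects, config=cfg)
    return CohortData(tables=tables, info=info, alsfrs=alsfrs, truth=truth)


def _exposed(arm: str, week: float, cfg: SimulationConfig) -> bool:
    if arm == "ROPI":
        return week > 0
    if arm == "placebo":
        return week > cfg.placebo_switch_week
    return False


def bridge_pairs(info: pd.DataFrame, fluid: str) -> list:
    """(batch-1 id, batch-2 id) pairs of bridge samples for one fluid."""
    dup = info[(info["fluid"] == fluid)
               & (info["bridge_of"].fillna("") != "")]
    return [(row["bridge_of"], row["sample_id"]) for _, row in dup.iterrows()]


def write_cohort(cohort: CohortData, outdir) -> None:
    """Write the cohort as plain TSV artefacts plus truth tables and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for fluid, table in cohort.tables.items():
        write_abundance(table, outdir / f"abundance_{fluid}.tsv")
    write_sample_info(cohort.info, outdir / "sample_info.tsv")
    write_alsfrs(cohort.alsfrs, outdir / "alsfrs.tsv")
    cohort.truth.proteins.to_csv(outdir / "truth_proteins.tsv", sep="\t")
    cohort.truth.subjects.to_csv(outdir / "truth_subjects.tsv", sep="\t")
    manifest = {
        "config": asdict(cohort.truth.config),
        "bridge_subjects": cohort.truth.bridge_subjects,
        "n_samples": {f: t.shape[1] for f, t in cohort.tables.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
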