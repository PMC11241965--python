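"""Exponential disease-progression modelling and prognostic biomarker ranking.

Each patient's ALSFRS-R series is fitted with the two-parameter model

    score(week) = -exp(a * week) + b,        a > 0,

where ``a`` is the per-week decay-rate (larger a = faster progression) and
``b`` an intercept-like plateau.  Derived quantities: the model-approximated
score at a sampling week (aALSFRS-R), the fixed-point progression rate
``d score / d week = -a exp(a week)``, and the prognostic index adj-a, the
within-arm z-score of ``-log10(a)`` (higher adj-a = slower progression).

Biomarker ranking correlates baseline (week-0) log10 protein levels with a
progression target (adj-a, aALSFRS-R at a week, or the fixed-point rate)
across patients, by pairwise-complete Pearson correlation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .io import AbundanceTable, ALSFRSSeries

__all__ = [
    "ProgressionFit",
    "ProgressionCurveFitter",
    "fit_progression",
    "fit_all",
    "aalsfrs",
    "fixed_point_rate",
    "adj_a",
    "rank_biomarkers",
]

logger = logging.getLogger(__name__)

A_BOUNDS = (1e-6, 1.0)
A_STARTS = (0.001, 0.005, 0.02, 0.05, 0.1)


@dataclass
class ProgressionFit:
    subject_id: str
    a: float
    b: float
    rss: float
    converged: bool
    at_bound: bool = False
    adj_a: float | None = None


class ProgressionCurveFitter(BaseEstimator):
    """Multi-start bounded nonlinear least squares for ``-exp(a w) + b``.

    Starts from several decay rates spanning slow to fast progressors with
    ``b0 = max(score) + 1`` and keeps the best-RSS solution; ``a`` is bounded
    to [1e-6, 1] per week.

    Attributes: ``a_``, ``b_``, ``rss_``, ``converged_``, ``at_bound_``.
    """

    def __init__(self, a_starts: Sequence = A_STARTS,
                 a_bounds: tuple = A_BOUNDS, tol: float = 1e-12):
        self.a_starts = a_starts
        self.a_bounds = a_bounds
        self.tol = tol

    def fit(self, weeks: Sequence, scores: Sequence) -> "ProgressionCurveFitter":
        w = np.asarray(weeks, dtype=float)
        y = np.asarray(scores, dtype=float)
        ok = ~np.isnan(y)
        w, y = w[ok], y[ok]
        if w.size < 3 or np.unique(w).size < 2:
            raise ValueError("need >= 3 observations spanning >= 2 distinct weeks")

        def resid(theta):
            a, b = theta
            return -np.exp(a * w) + b - y

        best = None
        b0 = float(y.max()) + 1.0
        for a0 in self.a_starts:
            try:
                sol = least_squares(
                    resid, x0=[a0, b0],
                    bounds=([self.a_bounds[0], -np.inf],
                            [self.a_bounds[1], np.inf]),
                    xtol=self.tol, ftol=self.tol, gtol=self.tol,
                )
            except Exception:  # pragma: no cover - defensive
                continue
            rss = float(np.sum(sol.fun ** 2))
            if best is None or rss < best[0] - 0.0:
                best = (rss, sol)
        if best is None:
            self.converged_ = False
            self.a_ = self.b_ = self.rss_ = math.nan
            self.at_bound_ = False
            return self
        rss, sol = best
        self.a_, self.b_ = float(sol.x[0]), float(sol.x[1])
        self.rss_ = rss
        self.converged_ = bool(sol.success)
        self.at_bound_ = bool(
            self.a_ <= self.a_bounds[0] * (1 + 1e-6)
            or self.a_ >= self.a_bounds[1] * (1 - 1e-6)
        )
        return self

    def predict(self, weeks: Sequence) -> np.ndarray:
        w = np.asarray(weeks, dtype=float)
        return -np.exp(self.a_ * w) + self.b_


def fit_progression(series: ALSFRSSeries) -> ProgressionFit:
    """Fit one patient's series; unconverged fits are flagged for exclusion."""
    fitter = ProgressionCurveFitter().fit(series.weeks, series.scores)
    if not fitter.converged_:
        logger.warning("progression fit failed to converge for %s",
                       series.subject_id)
    if fitter.at_bound_:
        logger.warning("decay rate pinned at bound for %s (a=%.3g)",
                       series.subject_id, fitter.a_)
    return ProgressionFit(
        subject_id=series.subject_id, a=fitter.a_, b=fitter.b_,
        rss=fitter.rss_, converged=fitter.converged_,
        at_bound=fitter.at_bound_,
    )


def fit_all(series_list: Iterable[ALSFRSSeries]) -> list:
    return [fit_progression(s) for s in series_list]


def aalsfrs(fit: ProgressionFit, week: float) -> float:
    """Model-approximated ALSFRS-R at a sampling week."""
    return -math.exp(fit.a * week) + fit.b


def fixed_point_rate(fit: ProgressionFit, week: float) -> float:
    """Fixed-point progression rate, the model derivative at a week."""
    return -fit.a * math.exp(fit.a * week)


def adj_a(fits: Sequence[ProgressionFit], arms: Mapping) -> list:
    """Within-arm z-score of -log10(a) (sample sd); higher = slower decline.

    Arms with fewer than two converged fits, or zero spread, leave adj_a
    undefined for their members.
    """
    by_arm: dict = {}
    for f in fits:
        if f.converged:
            by_arm.setdefault(arms[f.subject_id], []).append(f)
    for arm, group in by_arm.items():
        vals = np.array([-math.log10(f.a) for f in group])
        if vals.size < 2:
            logger.warning("arm %s has < 2 converged fits; adj_a undefined", arm)
            continue
        sd = vals.std(ddof=1)
        if sd == 0:
            logger.warning("arm %s has zero spread in a; adj_a undefined", arm)
            continue
        mean = vals.mean()
        for f, v in zip(group, vals):
            f.adj_a = float((v - mean) / sd)
    return list(fits)


def rank_biomarkers(table: AbundanceTable, info: pd.DataFrame,
                    targets: Mapping, week: int = 0,
                    min_n: int = 3, report_cutoff: float = 0.5) -> pd.DataFrame:
    """Correlate week-``week`` protein levels with a progression target.

    ``targets`` maps subject id -> target value (e.g. adj-a).  Pairwise-
    complete Pearson r per protein with two-sided p; proteins with fewer
    than ``min_n`` complete pairs are skipped.  The result is ranked by r
    (descending) and flags |r| >= ``report_cutoff``; top-5 tails are stored
    in ``result.attrs``.
    """
    if table.scale != "log10":
        raise ValueError("biomarker ranking expects log10 intensities")
    meta = info[(info["sample_id"].isin(table.sample_ids))
                & (info["cohort"] == "SALS") & (info["week"] == week)]
    if "bridge_of" in meta.columns:
        meta = meta[meta["bridge_of"].fillna("") == ""]
    meta = meta.drop_duplicates("subject_id")
    subj = [s for s in meta["subject_id"] if s in targets
            and targets[s] is not None and np.isfinite(targets[s])]
    if len(subj) < min_n:
        raise ValueError(f"need >= {min_n} subjects with target values")
    sample_of = meta.set_index("subject_id")["sample_id"]
    X = table.data[[sample_of[s] for s in subj]].to_numpy()
    y = np.array([float(targets[s]) for s in subj])

    rows = []
    for i, pid in enumerate(table.data.index):
        x = X[i]
        ok = ~np.isnan(x)
        if ok.sum() < min_n:
            continue
        yy = y[ok]
        if np.std(x[ok]) == 0 or np.std(yy) == 0:
            continue
        res = stats.pearsonr(x[ok], yy)
        rows.append({"protein_id": pid, "r": float(res.statistic),
                     "p_value": float(res.pvalue), "n": int(ok.sum())})
    out = pd.DataFrame(rows).set_index("protein_id")
    out = out.sort_values("r", ascending=False)
    out["rank"] = np.arange(1, len(out) + 1)
    out["above_cutoff"] = out["r"].abs() >= report_cutoff
    out.attrs["top5_positive"] = list(out.index[:5])
    out.attrs["top5_negative"] = list(out.index[::-1][:5])
    return out
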