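"""Control-vs-patient differential abundance on log10 intensities.

Per protein, a classical equal-variance (pooled) Student's t test compares
log10-transformed intensities between controls and drug-naive patients;
multiple testing is handled by Storey's q-value, which scales
Benjamini-Hochberg adjusted p-values by an estimate of the null proportion
pi0.  Proteins with q < 0.05 are called differentially abundant (DAPs), with
direction taken from the sign of the group-mean difference.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_smoothing_spline

from .io import AbundanceTable

__all__ = [
    "student_t",
    "estimate_pi0",
    "storey_qvalues",
    "differential_table",
    "compare_and_intersect",
    "DAP_Q_THRESHOLD",
]

#: q-value significance cut-off for DAP calls.
DAP_Q_THRESHOLD = 0.05

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.0, 0.96, 0.05), 2)


def student_t(group_a: Sequence, group_b: Sequence) -> tuple:
    """Two-sided pooled-variance Student's t on non-missing values.

    Returns ``(t, p)``.  Raises if either group has fewer than two
    non-missing values.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 non-missing values")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def estimate_pi0(p_values: Sequence,
                 lambda_grid: Sequence = DEFAULT_LAMBDA_GRID) -> float:
    """Smoothed estimate of the null proportion pi0.

    ``pi0_hat(lambda) = #{p > lambda} / (m (1 - lambda))`` over the grid, a
    cubic smoothing spline (GCV penalty) is fitted and evaluated at the
    largest lambda; the result is clipped to (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        raise ValueError("no p-values")
    lam = np.asarray(lambda_grid, dtype=float)
    if np.any((lam < 0) | (lam >= 1)):
        raise ValueError("lambda grid must lie in [0, 1)")
    lam = np.unique(lam)
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    if lam.size >= 4:
        spline = make_smoothing_spline(lam, pi0_lam)
        pi0 = float(spline(lam.max()))
    else:
        pi0 = float(pi0_lam[-1])
    return float(min(1.0, max(pi0, 1.0 / m)))


def storey_qvalues(p_values: Sequence,
                   lambda_grid: Sequence = DEFAULT_LAMBDA_GRID,
                   pi0: float | None = None) -> tuple:
    """Storey q-values for a vector of p-values.

    ``q_(i) = min_{j >= i} pi0 * m * p_(j) / j`` over sorted p-values; with
    ``pi0 = 1`` this is exactly the Benjamini-Hochberg adjustment.  Returns
    ``(q_values, pi0)`` with q-values in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        raise ValueError("no p-values")
    if pi0 is None:
        pi0 = estimate_pi0(p, lambda_grid)
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must lie in (0, 1]")
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, float(pi0)


def differential_table(table: AbundanceTable, info: pd.DataFrame,
                       protein_universe: Iterable | None = None,
                       week0_only: bool = True,
                       q_threshold: float = DAP_Q_THRESHOLD,
                       pi0: float | None = None) -> pd.DataFrame:
    """Control-vs-SALS differential abundance table for one fluid's samples.

    Cases are drug-naive SALS samples (week 0 only by default, one sample per
    subject, avoiding pseudo-replication); controls are all control samples
    present in the table.  Bridge re-measurements are excluded.  Proteins
    with fewer than two observed values in either group are flagged
    untestable and excluded from the FDR input.
    """
    if table.scale != "log10":
        raise ValueError("differential testing operates on log10 intensities")
    ids = set(table.sample_ids)
    meta = info[info["sample_id"].isin(ids)]
    if "bridge_of" in meta.columns:
        meta = meta[meta["bridge_of"].fillna("") == ""]
    ctrl_ids = meta.loc[meta["cohort"] == "control", "sample_id"].tolist()
    case_mask = (meta["cohort"] == "SALS") & (~meta["ropi_exposed"])
    if week0_only:
        case_mask &= meta["week"] == 0
    case_ids = meta.loc[case_mask, "sample_id"].tolist()
    if len(ctrl_ids) < 2 or len(case_ids) < 2:
        raise ValueError("need >= 2 control and >= 2 case samples")

    data = table.data
    if protein_universe is not None:
        data = data.loc[sorted(set(protein_universe) & set(data.index))]
    ctrl = data[ctrl_ids].to_numpy()
    case = data[case_ids].to_numpy()

    n_ctrl = (~np.isnan(ctrl)).sum(axis=1)
    n_case = (~np.isnan(case)).sum(axis=1)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")   # under-observed rows handled below
        res = stats.ttest_ind(case, ctrl, axis=1, equal_var=True,
                              nan_policy="omit")
    t_stat = np.asarray(res.statistic, dtype=float)
    p_val = np.asarray(res.pvalue, dtype=float)
    tested = (n_ctrl >= 2) & (n_case >= 2) & np.isfinite(t_stat) & np.isfinite(p_val)

    q_val = np.full(data.shape[0], np.nan)
    pi0_used = np.nan
    if tested.any():
        q_val[tested], pi0_used = storey_qvalues(p_val[tested], pi0=pi0)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)   # all-missing rows
        mean_ctrl = np.nanmean(ctrl, axis=1)
        mean_case = np.nanmean(case, axis=1)
    direction = np.where(mean_case >= mean_ctrl, "up_in_case", "down_in_case")

    out = pd.DataFrame(
        {
            "mean_log10_control": mean_ctrl,
            "mean_log10_case": mean_case,
            "t_statistic": np.where(tested, t_stat, np.nan),
            "p_value": np.where(tested, p_val, np.nan),
            "q_value": q_val,
            "direction": direction,
            "tested": tested,
            "is_dap": tested & (q_val < q_threshold),
        },
        index=data.index.copy(),
    )
    out.attrs["pi0"] = pi0_used
    out.attrs["n_control"] = len(ctrl_ids)
    out.attrs["n_case"] = len(case_ids)
    return out


def compare_and_intersect(dap_a: pd.DataFrame, dap_b: pd.DataFrame) -> dict:
    """Overlap of DAP calls between two tables (e.g. serum vs CSF).

    Returns sets: proteins up in both, down in both, DAP only in the first,
    DAP only in the second (keyed on protein id and direction).
    """
    def _sets(df):
        dap = df[df["is_dap"]]
        up = set(dap.index[dap["direction"] == "up_in_case"])
        down = set(dap.index[dap["direction"] == "down_in_case"])
        return up, down

    up_a, down_a = _sets(dap_a)
    up_b, down_b = _sets(dap_b)
    return {
        "up_both": up_a & up_b,
        "down_both": down_a & down_b,
        "first_only": (up_a | down_a) - (up_b | down_b),
        "second_only": (up_b | down_b) - (up_a | down_a),
    }
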