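"""Set-similarity comparisons, paired fluid-profile correlation, divergence plot.

Protein sets from the different analyses (disease DAPs, drug es-DAPs, time
clusters) are encoded as signed membership vectors over a common universe
(+1 up, -1 down, 0 absent) and compared by cosine similarity, so that a set
"increased in disease" and one "decreased by drug" over the same proteins
yields a negative cosine — the anti-disease directionality read-out.

Also provided: the per-subject, per-week Pearson correlation between a
subject's serum and CSF EV profiles with a Dunnett-style many-to-one
comparison of patient week groups against controls (max-|t| null estimated
by seeded Monte-Carlo), and the divergence-trajectory summary that places
every sample on a (down-set, up-set) deviation-from-baseline plane.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

__all__ = [
    "signed_vector",
    "cosine_similarity",
    "similarity_heatmap",
    "dunnett_many_to_one",
    "paired_profile_correlation",
    "divergence_trajectory",
]


def signed_vector(universe: Sequence, up: Iterable = (), down: Iterable = ()) -> pd.Series:
    """Signed membership vector over an ordered universe (+1 up, -1 down)."""
    up, down = set(up), set(down)
    overlap = up & down
    if overlap:
        raise ValueError(f"protein(s) in both up and down sets: {sorted(overlap)[:5]}")
    values = [1.0 if p in up else (-1.0 if p in down else 0.0) for p in universe]
    return pd.Series(values, index=list(universe))


def cosine_similarity(u: Sequence, v: Sequence) -> float:
    """Cosine of two vectors on the same universe; zero vectors are an error."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must share the same universe")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def similarity_heatmap(vectors: Mapping) -> tuple:
    """All pairwise cosines of named vectors plus a display ordering.

    Returns ``(matrix, order)`` where ``matrix`` is a symmetric DataFrame and
    ``order`` an average-linkage leaf ordering of the names (cosine distance).
    """
    names = list(vectors)
    if len(names) < 2:
        raise ValueError("need at least two vectors")
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            c = cosine_similarity(vectors[a], vectors[b])
            mat.loc[a, b] = mat.loc[b, a] = c
    X = np.vstack([np.asarray(vectors[n], dtype=float) for n in names])
    Z = linkage(pdist(X, metric="cosine"), method="average")
    order = [names[i] for i in leaves_list(Z)]
    return mat, order


def dunnett_many_to_one(groups: Mapping, control: Sequence,
                        n_draws: int = 100_000, seed: int = 0) -> pd.DataFrame:
    """Two-sided Dunnett-style comparison of several groups to one control.

    Pooled within-group variance; the family-wise null distribution of
    max |t| over the correlated contrasts (they share the control mean) is
    estimated by seeded Monte-Carlo rather than multivariate-t quadrature.
    """
    ctrl = np.asarray(control, dtype=float)
    ctrl = ctrl[~np.isnan(ctrl)]
    arrs = {k: np.asarray(v, dtype=float)[~np.isnan(np.asarray(v, dtype=float))]
            for k, v in groups.items()}
    if ctrl.size < 2 or any(a.size < 2 for a in arrs.values()):
        raise ValueError("each group needs >= 2 non-missing values")
    ns = {k: a.size for k, a in arrs.items()}
    n0 = ctrl.size
    ss = sum(((a - a.mean()) ** 2).sum() for a in arrs.values())
    ss += ((ctrl - ctrl.mean()) ** 2).sum()
    dof = n0 + sum(ns.values()) - (len(arrs) + 1)
    s2 = ss / dof
    t_obs = {
        k: (a.mean() - ctrl.mean()) / np.sqrt(s2 * (1 / ns[k] + 1 / n0))
        for k, a in arrs.items()
    }
    rng = np.random.default_rng(seed)
    z0 = rng.standard_normal(n_draws) / np.sqrt(n0)
    s_star = np.sqrt(rng.chisquare(dof, size=n_draws) / dof)
    T = np.empty((len(arrs), n_draws))
    for i, k in enumerate(arrs):
        zk = rng.standard_normal(n_draws) / np.sqrt(ns[k])
        T[i] = (zk - z0) / (s_star * np.sqrt(1 / ns[k] + 1 / n0))
    max_abs = np.abs(T).max(axis=0)
    rows = []
    for k, a in arrs.items():
        p_adj = float((max_abs >= abs(t_obs[k])).mean())
        rows.append({"group": k, "n": ns[k], "mean": a.mean(),
                     "mean_control": ctrl.mean(), "t": t_obs[k],
                     "p_adjusted": p_adj})
    return pd.DataFrame(rows).set_index("group")


def paired_profile_correlation(serum, csf, info: pd.DataFrame,
                               min_proteins: int = 3,
                               n_draws: int = 100_000,
                               seed: int = 0) -> dict:
    """Per-(subject, week) Pearson r between a subject's two fluid profiles.

    Both tables must be log10 scale.  The shared universe per subject-week is
    the proteins observed in both fluids for that draw (pairwise-complete).
    Patient week groups are then compared against controls with the
    Dunnett-style adjustment.
    """
    if serum.scale != "log10" or csf.scale != "log10":
        raise ValueError("paired profile correlation expects log10 tables")
    meta = info.copy()
    if "bridge_of" in meta.columns:
        meta = meta[meta["bridge_of"].fillna("") == ""]
    shared_prot = serum.data.index.intersection(csf.data.index)
    if shared_prot.empty:
        raise ValueError("no shared proteins between fluids")
    s_meta = meta[meta["fluid"] == "serum"].set_index(["subject_id", "week"])
    c_meta = meta[meta["fluid"] == "csf"].set_index(["subject_id", "week"])
    keys = s_meta.index.intersection(c_meta.index)
    rows = []
    for subj, week in keys:
        sid = s_meta.loc[(subj, week), "sample_id"]
        cid = c_meta.loc[(subj, week), "sample_id"]
        x = serum.data.loc[shared_prot, sid]
        y = csf.data.loc[shared_prot, cid]
        ok = x.notna() & y.notna()
        if ok.sum() < min_proteins:
            continue
        r = stats.pearsonr(x[ok], y[ok]).statistic
        rows.append({"subject_id": subj, "week": int(week),
                     "cohort": s_meta.loc[(subj, week), "cohort"],
                     "n_proteins": int(ok.sum()), "r": float(r)})
    per_draw = pd.DataFrame(rows)
    comparison = None
    if len(per_draw):
        ctrl_r = per_draw.loc[per_draw["cohort"] == "control", "r"].to_numpy()
        sals = per_draw[per_draw["cohort"] == "SALS"]
        groups = {f"week_{w}": g["r"].to_numpy()
                  for w, g in sals.groupby("week") if len(g) >= 2}
        if ctrl_r.size >= 2 and groups:
            comparison = dunnett_many_to_one(groups, ctrl_r,
                                             n_draws=n_draws, seed=seed)
    return {"per_draw": per_draw, "comparison": comparison}


def divergence_trajectory(table, info: pd.DataFrame,
                          up_set: Iterable, down_set: Iterable) -> pd.DataFrame:
    """(x, y) deviation-from-baseline coordinates per sample.

    x = mean log10 level over the down set minus baseline, y = same over the
    up set.  Patients are referenced to their own week-0 draw; controls to
    the control-group mean (so the control cloud is centred at the origin).
    """
    up_ids = sorted(set(up_set) & set(table.data.index))
    down_ids = sorted(set(down_set) & set(table.data.index))
    if not up_ids or not down_ids:
        raise ValueError("up and down sets must intersect the table universe")
    meta = info[info["sample_id"].isin(table.sample_ids)].copy()
    if "bridge_of" in meta.columns:
        meta = meta[meta["bridge_of"].fillna("") == ""]
    m_up = table.data.loc[up_ids].mean(axis=0, skipna=True)
    m_down = table.data.loc[down_ids].mean(axis=0, skipna=True)

    rows = []
    sals = meta[meta["cohort"] == "SALS"]
    base = sals[sals["week"] == 0].set_index("subject_id")["sample_id"]
    for _, r in sals.iterrows():
        if r["subject_id"] not in base.index:
            continue
        b = base[r["subject_id"]]
        rows.append({
            "sample_id": r["sample_id"], "subject_id": r["subject_id"],
            "cohort": "SALS", "arm": r["arm"], "week": int(r["week"]),
            "x": float(m_down[r["sample_id"]] - m_down[b]),
            "y": float(m_up[r["sample_id"]] - m_up[b]),
        })
    ctrl = meta[meta["cohort"] == "control"]
    if len(ctrl):
        cx = m_down[ctrl["sample_id"]].mean()
        cy = m_up[ctrl["sample_id"]].mean()
        for _, r in ctrl.iterrows():
            rows.append({
                "sample_id": r["sample_id"], "subject_id": r["subject_id"],
                "cohort": "control", "arm": "none", "week": int(r["week"]),
                "x": float(m_down[r["sample_id"]] - cx),
                "y": float(m_up[r["sample_id"]] - cy),
            })
    return pd.DataFrame(rows)
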