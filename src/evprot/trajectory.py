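"""Placebo-anchored trajectory clustering and arm-by-time ANOVA.

Protein trajectories (mean placebo-arm log2 fold change from baseline at each
post-baseline week) are clustered with Ward's minimum-variance method at
k = 3 and the clusters named increased / unchanged / decreased by the rank of
their centroid at the final week.  The partition is a function of placebo
data only; drug-arm trajectories of each cluster are then compared to the
placebo arm by two-way fixed-effects ANOVA (treatment x week, Type-III sums
of squares) with Bonferroni-adjusted estimated-marginal-mean contrasts, the
unit of observation being the per-protein arm mean at each week.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy import stats
from sklearn.base import BaseEstimator
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .io import AbundanceTable
from .effects import per_patient_log2fc

__all__ = [
    "fold_change_cube",
    "TrajectoryClusterer",
    "fit_trajectory_clusters",
    "transfer_and_test",
    "two_way_anova",
]

LABELS_BY_RANK = {0: "decreased", 1: "unchanged", 2: "increased"}


def fold_change_cube(table: AbundanceTable, info: pd.DataFrame,
                     weeks: Sequence) -> dict:
    """Per-week fold-change slices: {week: proteins x subjects log2FC frame}."""
    return {int(w): per_patient_log2fc(table, info, int(w)) for w in weeks}


def mean_trajectories(cube: Mapping, subjects: Iterable) -> pd.DataFrame:
    """Mean log2FC across the given subjects at each week (proteins x weeks).

    Rows with any missing week mean are dropped (complete vectors only).
    """
    subjects = list(subjects)
    cols = {}
    for week in sorted(cube):
        fc = cube[week]
        present = [s for s in subjects if s in fc.columns]
        if not present:
            raise ValueError(f"no requested subject has week-{week} fold changes")
        cols[week] = fc[present].mean(axis=1, skipna=True)
    traj = pd.DataFrame(cols)
    return traj.dropna()


class TrajectoryClusterer(BaseEstimator):
    """Ward hierarchical clustering of trajectory vectors, cut at k clusters.

    For k = 3 the clusters are named by the rank of their centroid at the
    final week: maximum -> ``increased``, minimum -> ``decreased``, middle ->
    ``unchanged``.  Proteins are sorted lexicographically before linkage so
    the result is deterministic in the input order.

    Attributes
    ----------
    labels_ : pandas.Series, protein id -> cluster label
    centroids_ : pandas.DataFrame, label x week centroid trajectories
    linkage_ : scipy linkage matrix (merge costs non-decreasing)
    """

    def __init__(self, k: int = 3):
        self.k = k

    def fit(self, trajectories: pd.DataFrame) -> "TrajectoryClusterer":
        X = trajectories.sort_index()
        if X.isna().any().any():
            raise ValueError("trajectories must be complete (no missing weeks)")
        if X.shape[0] < self.k:
            raise ValueError(
                f"need >= {self.k} complete trajectories, got {X.shape[0]}")
        Z = linkage(X.to_numpy(), method="ward")
        raw = fcluster(Z, t=self.k, criterion="maxclust")
        final_week = X.columns[-1]
        centroid_final = {c: X.loc[raw == c, final_week].mean()
                          for c in np.unique(raw)}
        if self.k == 3:
            order = sorted(centroid_final, key=centroid_final.get)
            name_of = {c: LABELS_BY_RANK[r] for r, c in enumerate(order)}
        else:
            order = sorted(centroid_final, key=centroid_final.get)
            name_of = {c: f"cluster_{r}" for r, c in enumerate(order)}
        labels = pd.Series([name_of[c] for c in raw], index=X.index,
                           name="label")
        self.linkage_ = Z
        self.labels_ = labels
        self.centroids_ = pd.DataFrame(
            {lab: X.loc[labels == lab].mean() for lab in labels.unique()}
        ).T
        self.feature_weeks_ = list(X.columns)
        return self

    def predict(self, trajectories: pd.DataFrame) -> pd.Series:
        """Assign new trajectory vectors to the nearest fitted centroid."""
        if not hasattr(self, "centroids_"):
            raise RuntimeError("clusterer is not fitted")
        C = self.centroids_[self.feature_weeks_].to_numpy()
        X = trajectories[self.feature_weeks_].to_numpy()
        d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
        idx = d2.argmin(axis=1)
        return pd.Series(self.centroids_.index.to_numpy()[idx],
                         index=trajectories.index, name="label")


def fit_trajectory_clusters(cube: Mapping, placebo_subjects: Iterable,
                            k: int = 3) -> TrajectoryClusterer:
    """Fit the placebo-arm trajectory partition.

    Proteins whose mean placebo trajectory is incomplete are excluded from
    clustering and labelled ``unchanged`` (the conservative default); their
    ids are recorded in ``model.incomplete_``.
    """
    subjects = list(placebo_subjects)
    all_ids = cube[sorted(cube)[0]].index
    traj = mean_trajectories(cube, subjects)
    model = TrajectoryClusterer(k=k).fit(traj)
    incomplete = all_ids.difference(traj.index)
    if len(incomplete):
        filler = pd.Series("unchanged", index=incomplete, name="label")
        model.labels_ = pd.concat([model.labels_, filler]).loc[all_ids]
    model.incomplete_ = list(incomplete)
    return model


def two_way_anova(long: pd.DataFrame) -> dict:
    """Two-factor fixed-effects ANOVA with Type-III SS and EMM contrasts.

    ``long`` needs columns ``value``, ``arm``, ``week``.  Returns the ANOVA
    table, per-cell estimated marginal means, and Bonferroni-adjusted
    between-arm contrasts at each week.
    """
    df = long.copy()
    df["week"] = df["week"].astype(int).astype(str)
    model = smf.ols("value ~ C(arm, Sum) * C(week, Sum)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=3)

    cells = df.groupby(["arm", "week"], observed=True)["value"].agg(["mean", "count"])
    mse = model.mse_resid
    dof = int(model.df_resid)
    arms = sorted(df["arm"].unique())
    weeks = sorted(df["week"].unique(), key=int)
    rows = []
    if len(arms) == 2:
        a1, a2 = arms
        for w in weeks:
            m1, n1 = cells.loc[(a1, w)]
            m2, n2 = cells.loc[(a2, w)]
            se = np.sqrt(mse * (1.0 / n1 + 1.0 / n2))
            t = (m1 - m2) / se if se > 0 else np.nan
            p = 2 * stats.t.sf(abs(t), dof) if np.isfinite(t) else np.nan
            rows.append({"week": int(w), "contrast": f"{a1} - {a2}",
                         "estimate": m1 - m2, "se": se, "t": t, "p": p})
    contrasts = pd.DataFrame(rows)
    if len(contrasts):
        contrasts["p_bonferroni"] = np.minimum(contrasts["p"] * len(contrasts), 1.0)
    emmeans = cells.rename(columns={"mean": "emmean", "count": "n"})
    return {"anova": anova, "emmeans": emmeans, "contrasts": contrasts,
            "residual_df": dof}


def transfer_and_test(model: TrajectoryClusterer, cube: Mapping,
                      ropi_subjects: Iterable,
                      placebo_subjects: Iterable) -> dict:
    """Arm-by-time ANOVA per trajectory cluster.

    Observations are per-protein arm means of log2FC at each week (what the
    cluster trajectory plots display).  Clusters with fewer than two
    clustered proteins are skipped.
    """
    reports: dict = {}
    arm_subjects = {"ROPI": list(ropi_subjects), "placebo": list(placebo_subjects)}
    clustered = model.labels_.drop(getattr(model, "incomplete_", []))
    for label in clustered.unique():
        ids = clustered.index[clustered == label]
        if len(ids) < 2:
            reports[label] = None
            continue
        frames = []
        for arm, subs in arm_subjects.items():
            traj = mean_trajectories(cube, subs)
            traj = traj.loc[traj.index.intersection(ids)]
            long = traj.reset_index(names="protein_id").melt(
                id_vars="protein_id", var_name="week", value_name="value")
            long["arm"] = arm
            frames.append(long)
        reports[label] = two_way_anova(pd.concat(frames, ignore_index=True))
    return reports
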