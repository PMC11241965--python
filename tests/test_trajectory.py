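import itertools

import numpy as np
import pandas as pd
import pytest

from evprot.trajectory import (
    TrajectoryClusterer,
    fit_trajectory_clusters,
    fold_change_cube,
    mean_trajectories,
    transfer_and_test,
    two_way_anova,
)


def brute_force_ward_merges(points):
    """Greedy minimum Ward-cost merge sequence by exhaustive pair search."""
    clusters = [frozenset([i]) for i in range(len(points))]
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            ca = points[list(a)].mean(axis=0)
            cb = points[list(b)].mean(axis=0)
            cost = len(a) * len(b) / (len(a) + len(b)) * np.sum((ca - cb) ** 2)
            if best is None or cost < best[0]:
                best = (cost, a, b)
        _, a, b = best
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(a | b)
        merges.append(frozenset((a, b)))
    return merges


def scipy_ward_merges(points):
    from scipy.cluster.hierarchy import linkage
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    Z = linkage(points, method="ward")
    members = [frozenset([i]) for i in range(len(points))]
    merges = []
    for row in Z:
        a, b = members[int(row[0])], members[int(row[1])]
        merges.append(frozenset((a, b)))
        members.append(a | b)
    return merges


class TestWardOracle:
    @pytest.mark.parametrize("seed", range(6))
    def test_merge_sequence_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        points = rng.normal(size=rng.integers(4, 9))
        assert scipy_ward_merges(points) == brute_force_ward_merges(points)

    def test_merge_costs_nondecreasing(self):
        rng = np.random.default_rng(3)
        traj = pd.DataFrame(rng.normal(size=(30, 4)),
                            index=[f"p{i}" for i in range(30)])
        model = TrajectoryClusterer(k=3).fit(traj)
        heights = model.linkage_[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)


class TestClusterLabels:
    def test_separable_singletons_named_by_final_week(self):
        traj = pd.DataFrame([[1.0, 2.0], [0.0, 0.0], [-1.0, -2.0]],
                            index=["a", "b", "c"], columns=[24, 48])
        model = TrajectoryClusterer(k=3).fit(traj)
        assert model.labels_["a"] == "increased"
        assert model.labels_["b"] == "unchanged"
        assert model.labels_["c"] == "decreased"

    def test_labels_invariant_to_input_order(self):
        rng = np.random.default_rng(0)
        traj = pd.DataFrame(rng.normal(size=(25, 3)),
                            index=[f"p{i:02d}" for i in range(25)])
        m1 = TrajectoryClusterer(k=3).fit(traj)
        m2 = TrajectoryClusterer(k=3).fit(traj.sample(frac=1, random_state=4))
        assert m1.labels_.sort_index().equals(m2.labels_.sort_index())

    def test_too_few_proteins_rejected(self):
        traj = pd.DataFrame([[1.0, 2.0]], index=["a"], columns=[24, 48])
        with pytest.raises(ValueError):
            TrajectoryClusterer(k=3).fit(traj)

    def test_placebo_only_partition_and_planted_recovery(self, cohort,
                                                          corrected_serum):
        cube = fold_change_cube(corrected_serum, cohort.info, [13, 24, 39, 48])
        arm = cohort.truth.subjects["arm"]
        placebo = list(arm.index[arm == "placebo"])
        model = fit_trajectory_clusters(cube, placebo)
        truth = cohort.truth.proteins.loc[model.labels_.index, "protein_class"]
        lab = model.labels_
        assert (lab[truth == "inflammation_up"] == "increased").mean() > 0.7
        assert (lab[truth == "upr_down"] == "decreased").mean() > 0.6
        assert (lab[truth == "null"] == "unchanged").mean() > 0.9
        # ROPI data never influence the partition
        model2 = fit_trajectory_clusters(
            {w: fc[placebo] for w, fc in cube.items()}, placebo)
        assert model.labels_.equals(model2.labels_)


class TestTwoWayAnova:
    def test_identical_arms_give_null_treatment_effect(self):
        rng = np.random.default_rng(5)
        base = pd.DataFrame({
            "value": rng.normal(size=40),
            "week": np.tile([24, 48], 20),
        })
        long = pd.concat([base.assign(arm="ROPI"), base.assign(arm="placebo")])
        rep = two_way_anova(long)
        arm_row = rep["anova"].loc["C(arm, Sum)"]
        assert arm_row["F"] == pytest.approx(0.0, abs=1e-20)

    def test_balanced_2x2_closed_form(self):
        # cells (arm x week) with 2 obs each; hand-computed sums of squares
        long = pd.DataFrame({
            "arm": ["a"] * 4 + ["b"] * 4,
            "week": [1, 1, 2, 2] * 2,
            "value": [1.0, 3.0, 5.0, 7.0, 2.0, 4.0, 10.0, 12.0],
        })
        rep = two_way_anova(long)
        an = rep["anova"]
        # grand mean 5.5; cell means 2,6,3,11; arm means 4,7; week means 2.5,8.5
        # SSA = 4*(1.5^2+1.5^2) = 18; SSB = 4*(3^2+3^2) = 72; SSint = 2*4*1 = 8
        # residual = (1-2)^2+(3-2)^2 per cell * 4 cells = 8, df = 4 -> MSE = 2
        assert an.loc["C(arm, Sum)", "sum_sq"] == pytest.approx(18.0)
        assert an.loc["C(week, Sum)", "sum_sq"] == pytest.approx(72.0)
        assert an.loc["C(arm, Sum):C(week, Sum)", "sum_sq"] == pytest.approx(8.0)
        assert an.loc["Residual", "sum_sq"] == pytest.approx(8.0)
        assert an.loc["C(arm, Sum)", "F"] == pytest.approx(18.0 / 2.0)

    def test_bonferroni_is_capped_multiple_of_raw(self):
        rng = np.random.default_rng(8)
        long = pd.DataFrame({
            "arm": np.repeat(["a", "b"], 30),
            "week": np.tile([13, 24, 48], 20),
            "value": rng.normal(size=60),
        })
        rep = two_way_anova(long)
        c = rep["contrasts"]
        assert np.allclose(c["p_bonferroni"],
                           np.minimum(c["p"] * len(c), 1.0))

    def test_drug_effect_detected_in_planted_clusters(self, cohort,
                                                      corrected_serum):
        cube = fold_change_cube(corrected_serum, cohort.info, [13, 24, 39, 48])
        arm = cohort.truth.subjects["arm"]
        placebo = list(arm.index[arm == "placebo"])
        ropi = list(arm.index[arm == "ROPI"])
        model = fit_trajectory_clusters(cube, placebo)
        reports = transfer_and_test(model, cube, ropi, placebo)
        for label in ("increased", "decreased"):
            p = reports[label]["anova"].loc["C(arm, Sum)", "PR(>F)"]
            assert p < 0.01
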