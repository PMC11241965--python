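import numpy as np
import pandas as pd
import pytest
from scipy import stats

from evprot.io import AbundanceTable, to_log10
from evprot.similarity import (
    cosine_similarity,
    divergence_trajectory,
    dunnett_many_to_one,
    paired_profile_correlation,
    signed_vector,
    similarity_heatmap,
)


class TestCosine:
    def test_basic_identities(self):
        u = np.array([1.0, 0.0, -1.0])
        assert cosine_similarity(u, u) == pytest.approx(1.0)
        assert cosine_similarity(u, -u) == pytest.approx(-1.0)
        assert cosine_similarity([1, 0], [0, 1]) == 0.0

    def test_scale_invariance_symmetry_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            u, v = rng.normal(size=8), rng.normal(size=8)
            c = cosine_similarity(u, v)
            assert -1 <= c <= 1
            assert cosine_similarity(v, u) == pytest.approx(c)
            assert cosine_similarity(3.7 * u, v) == pytest.approx(c)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 0])

    def test_signed_vector_encoding(self):
        v = signed_vector(["a", "b", "c"], up=["a"], down=["c"])
        assert v.tolist() == [1.0, 0.0, -1.0]
        with pytest.raises(ValueError):
            signed_vector(["a"], up=["a"], down=["a"])


class TestHeatmap:
    def test_identical_and_negated_sets(self):
        uni = list("abcd")
        u = signed_vector(uni, up=["a", "b"])
        vecs = {"x": u, "y": u.copy(), "z": -u}
        mat, order = similarity_heatmap(vecs)
        assert mat.loc["x", "y"] == pytest.approx(1.0)
        assert mat.loc["x", "z"] == pytest.approx(-1.0)
        assert set(order) == {"x", "y", "z"}

    def test_disjoint_sets_orthogonal(self):
        uni = list("abcd")
        mat, _ = similarity_heatmap({
            "x": signed_vector(uni, up=["a"]),
            "y": signed_vector(uni, up=["c"]),
        })
        assert mat.loc["x", "y"] == 0.0

    def test_disease_and_drug_sets_anticorrelated_on_cohort(
            self, cohort, corrected_serum, log_serum):
        from evprot.differential import differential_table
        from evprot.effects import es_dap_table, per_patient_log2fc

        d = differential_table(log_serum, cohort.info)
        e = es_dap_table(per_patient_log2fc(corrected_serum, cohort.info, 24),
                         cohort.info)
        uni = sorted(d.index)
        v_dis = signed_vector(
            uni,
            up=d.index[d["is_dap"] & (d["direction"] == "up_in_case")],
            down=d.index[d["is_dap"] & (d["direction"] == "down_in_case")])
        v_drug = signed_vector(
            uni,
            up=e.index[e["is_es_dap"] & (e["direction"] == "increased_by_ropi")],
            down=e.index[e["is_es_dap"] & (e["direction"] == "decreased_by_ropi")])
        assert cosine_similarity(v_dis, v_drug) < -0.5


class TestDunnett:
    def test_adjusted_p_bounded_by_raw_and_detects_shift(self):
        rng = np.random.default_rng(0)
        ctrl = rng.normal(0, 1, 10)
        groups = {"shifted": rng.normal(2.5, 1, 10),
                  "null": rng.normal(0, 1, 10)}
        res = dunnett_many_to_one(groups, ctrl, n_draws=50_000, seed=1)
        raw_p = 2 * stats.t.sf(abs(res.loc["shifted", "t"]), 27)
        assert res.loc["shifted", "p_adjusted"] >= raw_p - 1e-6
        assert res.loc["shifted", "p_adjusted"] < 0.01
        assert res.loc["null", "p_adjusted"] > 0.1

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        ctrl = rng.normal(size=8)
        groups = {"g": rng.normal(size=8)}
        a = dunnett_many_to_one(groups, ctrl, n_draws=20_000, seed=9)
        b = dunnett_many_to_one(groups, ctrl, n_draws=20_000, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestPairedProfiles:
    def _mini_tables(self):
        prot = [f"p{i}" for i in range(3)]
        serum = AbundanceTable(pd.DataFrame(
            {"A_serum_w0": [10.0, 100.0, 1000.0]}, index=prot))
        csf = AbundanceTable(pd.DataFrame(
            {"A_csf_w0": [100.0, 10000.0, 1000000.0]}, index=prot))
        info = pd.DataFrame([
            dict(sample_id="A_serum_w0", subject_id="A", cohort="SALS",
                 fluid="serum", week=0, arm="ROPI", batch=1, ropi_exposed=False),
            dict(sample_id="A_csf_w0", subject_id="A", cohort="SALS",
                 fluid="csf", week=0, arm="ROPI", batch=1, ropi_exposed=False),
        ])
        return to_log10(serum), to_log10(csf), info

    def test_perfect_linearity_gives_r_one(self):
        serum, csf, info = self._mini_tables()
        res = paired_profile_correlation(serum, csf, info)
        assert res["per_draw"]["r"].iloc[0] == pytest.approx(1.0)

    def test_cohort_run_produces_per_draw_rows_and_comparison(
            self, cohort):
        serum = to_log10(cohort.tables["serum"])
        csf = to_log10(cohort.tables["csf"])
        res = paired_profile_correlation(serum, csf, cohort.info,
                                         n_draws=20_000, seed=0)
        per = res["per_draw"]
        assert set(per["cohort"]) == {"control", "SALS"}
        assert per["r"].between(-1, 1).all()
        assert res["comparison"] is not None
        assert {"week_0", "week_24", "week_48"} <= set(res["comparison"].index)


class TestDivergence:
    def test_week0_samples_sit_at_origin(self, cohort, log_serum):
        prot = cohort.truth.proteins
        up = prot.index[prot["protein_class"] == "inflammation_up"]
        down = prot.index[prot["protein_class"] == "upr_down"]
        div = divergence_trajectory(log_serum, cohort.info, up, down)
        w0 = div[(div["cohort"] == "SALS") & (div["week"] == 0)]
        assert np.allclose(w0[["x", "y"]], 0.0)
        ctl = div[div["cohort"] == "control"]
        assert abs(ctl["x"].mean()) < 1e-12 and abs(ctl["y"].mean()) < 1e-12

    def test_placebo_diverges_more_than_drug_arm(self):
        # Monte-Carlo over seeds: mean week-48 up-set deviation larger under
        # placebo than under the drug
        from evprot.simulate import SimulationConfig, simulate_cohort
        gaps = []
        for seed in range(8):
            c = simulate_cohort(SimulationConfig(seed=seed, n_proteins=200))
            log = to_log10(c.tables["serum"])
            prot = c.truth.proteins
            up = prot.index[prot["protein_class"] == "inflammation_up"]
            down = prot.index[prot["protein_class"] == "upr_down"]
            div = divergence_trajectory(log, c.info, up, down)
            w48 = div[div["week"] == 48]
            gaps.append(w48.loc[w48["arm"] == "placebo", "y"].mean()
                        - w48.loc[w48["arm"] == "ROPI", "y"].mean())
        assert np.mean(gaps) > 0
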