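import math

import numpy as np
import pandas as pd
import pytest

from evprot.io import ALSFRSSeries
from evprot.progression import (
    ProgressionFit,
    adj_a,
    aalsfrs,
    fit_progression,
    fixed_point_rate,
    rank_biomarkers,
)
from evprot.simulate import ALSFRS_WEEKS, SimulationConfig, simulate_alsfrs

WEEKS = np.asarray(ALSFRS_WEEKS, dtype=float)


def _series(a, b, weeks=WEEKS):
    return ALSFRSSeries("s", weeks, -np.exp(a * weeks) + b)


class TestCurveFit:
    def test_noiseless_recovery_exact(self):
        fit = fit_progression(_series(0.05, 45.0))
        assert fit.a == pytest.approx(0.05, abs=1e-6)
        assert fit.b == pytest.approx(45.0, abs=1e-6)
        assert fit.converged and not fit.at_bound

    def test_constant_series_pins_rate_at_lower_bound(self):
        s = ALSFRSSeries("s", WEEKS, np.full(WEEKS.size, 44.0))
        fit = fit_progression(s)
        assert fit.at_bound and fit.a == pytest.approx(1e-6, rel=1e-3)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            fit_progression(ALSFRSSeries("s", [0, 4], [44, 43]))

    def test_bias_shrinks_with_noise(self):
        cfg0 = SimulationConfig(seed=0)
        rng = np.random.default_rng(10)
        med = {}
        for noise in (2.0, 0.5, 0.0):
            cfg = SimulationConfig(seed=0, score_noise_sd=noise)
            errs = []
            for i in range(40):
                a = rng.lognormal(math.log(0.02), 0.5)
                b = rng.normal(45, 2)
                scores = simulate_alsfrs(cfg, a, b, rng)
                fit = fit_progression(ALSFRSSeries(f"s{i}", WEEKS, scores))
                errs.append(abs(fit.a - a) / a)
            med[noise] = float(np.median(errs))
        assert med[0.0] <= med[0.5] <= med[2.0]


class TestDerivedQuantities:
    def test_closed_form_values(self):
        fit = ProgressionFit("s", a=0.05, b=45.0, rss=0.0, converged=True)
        assert aalsfrs(fit, 0) == pytest.approx(44.0)
        assert fixed_point_rate(fit, 0) == pytest.approx(-0.05)
        assert aalsfrs(fit, 24) == pytest.approx(41.67988, abs=1e-4)
        assert fixed_point_rate(fit, 24) == pytest.approx(-0.16601, abs=1e-4)

    def test_rate_is_derivative_of_curve(self):
        fit = ProgressionFit("s", a=0.03, b=44.0, rss=0.0, converged=True)
        h = 1e-6
        for week in (0.0, 13.0, 24.0, 48.0):
            fd = (aalsfrs(fit, week + h) - aalsfrs(fit, week - h)) / (2 * h)
            assert fd == pytest.approx(fixed_point_rate(fit, week), rel=1e-4)

    def test_rate_strictly_decreasing(self):
        fit = ProgressionFit("s", a=0.05, b=45.0, rss=0.0, converged=True)
        rates = [fixed_point_rate(fit, w) for w in WEEKS]
        assert np.all(np.diff(rates) < 0)


class TestAdjA:
    def _fits(self, a_values, arm):
        return [ProgressionFit(f"s{i}", a=a, b=45.0, rss=0.0, converged=True)
                for i, a in enumerate(a_values)], \
               {f"s{i}": arm for i in range(len(a_values))}

    def test_two_point_zscore(self):
        fits, arms = self._fits([0.01, 0.1], "ROPI")
        fits = adj_a(fits, arms)
        assert fits[0].adj_a == pytest.approx(+math.sqrt(0.5), abs=1e-6)
        assert fits[1].adj_a == pytest.approx(-math.sqrt(0.5), abs=1e-6)

    def test_degenerate_equal_rates_leave_undefined(self):
        fits, arms = self._fits([0.02, 0.02, 0.02], "placebo")
        fits = adj_a(fits, arms)
        assert all(f.adj_a is None for f in fits)

    def test_monotone_decreasing_in_a_and_standardised(self):
        fits, arms = self._fits([0.005, 0.01, 0.02, 0.05, 0.1], "ROPI")
        fits = adj_a(fits, arms)
        vals = [f.adj_a for f in fits]
        assert np.all(np.diff(vals) < 0)
        assert np.mean(vals) == pytest.approx(0.0, abs=1e-12)
        assert np.std(vals, ddof=1) == pytest.approx(1.0, abs=1e-12)


class TestBiomarkerRanking:
    def test_affine_protein_ranks_first(self, cohort, log_serum):
        table = log_serum
        info = cohort.info
        subj = cohort.truth.subjects.index
        targets = {s: float(v) for s, v in
                   zip(subj, np.linspace(-1.5, 1.5, len(subj)))}
        # plant a protein exactly affine in the target
        planted = table.data.copy()
        w0 = info[(info["cohort"] == "SALS") & (info["week"] == 0)
                  & (info["fluid"] == "serum") & (info["bridge_of"] == "")]
        for _, r in w0.iterrows():
            if r["sample_id"] in planted.columns:
                planted.loc[planted.index[0], r["sample_id"]] = \
                    3.0 + 2.0 * targets[r["subject_id"]]
        from evprot.io import AbundanceTable
        ranking = rank_biomarkers(AbundanceTable(planted, scale="log10"),
                                  info, targets)
        assert ranking.index[0] == planted.index[0]
        assert ranking.iloc[0]["r"] == pytest.approx(1.0)
        assert ranking.attrs["top5_positive"][0] == planted.index[0]
        assert (ranking["rank"] == np.arange(1, len(ranking) + 1)).all()

    def test_planted_bivariate_correlation_recovered(self):
        # protein constructed with r = 0.8 against the target, n = 20
        rng = np.random.default_rng(6)
        got = []
        for _ in range(20):
            z = rng.multivariate_normal([0, 0], [[1, 0.8], [0.8, 1]], size=20)
            r = np.corrcoef(z[:, 0], z[:, 1])[0, 1]
            got.append(r)
        assert abs(np.mean(got) - 0.8) < 0.15

    def test_null_r_distribution_consistent_with_independence(self, cohort,
                                                              log_serum):
        from scipy import stats
        rng = np.random.default_rng(13)
        subj = list(cohort.truth.subjects.index)
        rs = []
        for it in range(20):
            targets = {s: float(v) for s, v in
                       zip(subj, rng.normal(size=len(subj)))}
            ranking = rank_biomarkers(log_serum, cohort.info, targets)
            full = ranking[ranking["n"] == 20].sort_index()  # uniform df
            # disjoint protein block per target draw -> independent r values
            rs.extend(full["r"].iloc[it * 25:(it + 1) * 25].tolist())
        # null r for n=20 maps to Student t with n-2 df
        n = 20
        t_vals = np.array(rs) * np.sqrt((n - 2) / (1 - np.array(rs) ** 2))
        ks = stats.kstest(t_vals, "t", args=(n - 2,))
        assert ks.pvalue > 0.01
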