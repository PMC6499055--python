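"""Occupancy summaries and comparison statistics against brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from colonypulse.surveys import (
    BurrowRecord,
    BurrowStatus,
    PlotGeometry,
    SaturationModel,
    fit_saturation,
    occupancy_summary,
    ols_regress,
    rank_test,
    saturation_contingency,
)


def _recs(n_occ, n_unocc, n_unknown=0, plot="p", quadrat=None):
    out = [BurrowRecord(plot, BurrowStatus.OCCUPIED, quadrat) for _ in range(n_occ)]
    out += [BurrowRecord(plot, BurrowStatus.UNOCCUPIED, quadrat) for _ in range(n_unocc)]
    out += [BurrowRecord(plot, BurrowStatus.UNKNOWN, quadrat) for _ in range(n_unknown)]
    return out


class TestOccupancy:
    def test_census_density_14_burrows_two_circles(self):
        s = occupancy_summary(_recs(11, 3), [PlotGeometry.circle(), PlotGeometry.circle()])
        assert round(s.total_density, 3) == 0.045
        assert s.n_burrows == 14

    def test_zero_burrows_zero_density(self):
        s = occupancy_summary([], PlotGeometry.rectangle())
        assert s.total_density == 0.0

    def test_quadrat_mean_and_se(self):
        recs = (_recs(4, 0, quadrat="q1") + _recs(5, 0, quadrat="q2")
                + _recs(6, 0, quadrat="q3"))
        s = occupancy_summary(recs, PlotGeometry.rectangle(), mode="quadrat")
        assert s.total_density == pytest.approx(5.0)
        assert s.total_density_se == pytest.approx(0.577, abs=1e-3)

    def test_unknowns_excluded_everywhere(self):
        s = occupancy_summary(_recs(2, 2, n_unknown=10), PlotGeometry.rectangle())
        assert s.n_burrows == 4
        assert s.total_density == pytest.approx(4 / 250)

    def test_record_order_invariance(self, rng):
        recs = _recs(7, 5, 3)
        shuffled = [recs[i] for i in rng.permutation(len(recs))]
        a = occupancy_summary(recs, PlotGeometry.circle())
        b = occupancy_summary(shuffled, PlotGeometry.circle())
        assert a == b

    def test_occupied_never_exceeds_total(self):
        s = occupancy_summary(_recs(3, 9), PlotGeometry.circle())
        assert s.occupied_density <= s.total_density

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            occupancy_summary(_recs(1, 0), [])


class TestOlsRegress:
    def test_exact_linear_data(self):
        x = np.arange(8.0)
        res = ols_regress(x, 2 * x)
        assert res.slope == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.df_resid == 6

    def test_matches_anova_decomposition(self, rng):
        """Oracle: F and p recomputed from raw sums of squares."""
        x = rng.standard_normal(15)
        y = 1.5 * x + rng.standard_normal(15)
        res = ols_regress(x, y)
        b = np.cov(x, y, bias=True)[0, 1] / np.var(x)
        a = y.mean() - b * x.mean()
        ss_res = ((y - a - b * x) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1 - ss_res / ss_tot
        f = (r2 / 1) / ((1 - r2) / (len(x) - 2))
        p = stats.f.sf(f, 1, len(x) - 2)
        assert res.r_squared == pytest.approx(r2)
        assert res.f_stat == pytest.approx(f)
        assert res.p_value == pytest.approx(p)

    def test_zero_variance_x_undefined(self):
        with pytest.raises(ValueError):
            ols_regress([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ols_regress([1, 2], [3, 4])


class TestSaturationModel:
    def test_midpoint_identity(self):
        m = SaturationModel(asymptote=30.0, xmidpt=15.0, scale=2.0)
        assert m.predict(15.0) == pytest.approx(15.0)

    def test_asymptote_reached(self):
        m = SaturationModel(scale=0.5)
        assert m.predict(1e6) == pytest.approx(30.0)
        assert m.predict(-1e6) == pytest.approx(0.0, abs=1e-12)

    def test_scale_is_half_to_three_quarters_increment(self):
        m = SaturationModel(scale=2.0)
        # moving one "scale" above the midpoint takes the rate from 1/2 to
        # 1/(1+e^-1) of the asymptote; ln(3) scales reach exactly 3/4
        x_34 = 15.0 + 2.0 * math.log(3)
        assert m.predict(x_34) == pytest.approx(22.5)

    def test_scale_recovery_from_model_generated_data(self):
        rng = np.random.default_rng(0)
        true = 0.002
        errs = []
        for _ in range(20):
            x = 15 + rng.uniform(-4, 4, 60) * true
            y = np.clip(SaturationModel(scale=true).predict(x)
                        + rng.standard_normal(60), 0, 30)
            fit = fit_saturation(x, y)
            errs.append(abs(fit.model.scale - true) / true)
        assert np.median(errs) < 0.2

    def test_saturating_data_prefers_logistic_by_aic(self):
        rng = np.random.default_rng(1)
        x = np.linspace(10, 20, 60)
        y = np.clip(SaturationModel(scale=0.8).predict(x) + 0.5 * rng.standard_normal(60), 0, 30)
        fit = fit_saturation(x, y)
        assert fit.converged
        assert fit.delta_aic < 0

    def test_free_midpoint_variant(self):
        rng = np.random.default_rng(2)
        x = np.linspace(0.0, 0.01, 50)
        y = np.clip(SaturationModel(xmidpt=0.005, scale=0.001).predict(x)
                    + 0.5 * rng.standard_normal(50), 0, 30)
        fit = fit_saturation(x, y, xmidpt=None)
        assert fit.model.xmidpt == pytest.approx(0.005, rel=0.2)

    def test_out_of_range_rates_rejected(self):
        with pytest.raises(ValueError):
            fit_saturation([1, 2, 3, 4, 5], [0, 10, 20, 31, 5])

    def test_too_few_nights_rejected(self):
        with pytest.raises(ValueError):
            fit_saturation([1, 2, 3, 4], [1, 2, 3, 4])


class TestSaturationContingency:
    def test_identical_proportions_no_association(self):
        a = [25] * 50 + [5] * 50
        stat, p = saturation_contingency(a, a)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_chi_square(self):
        a = [25] * 61 + [5] * 39   # 61% saturated
        b = [25] * 23 + [5] * 77   # 23% saturated
        stat, _ = saturation_contingency(a, b)
        obs = np.array([[61, 39], [23, 77]])
        row = obs.sum(1, keepdims=True)
        col = obs.sum(0, keepdims=True)
        exp = row * col / obs.sum()
        assert stat == pytest.approx(((obs - exp) ** 2 / exp).sum())

    def test_extreme_separation_significant(self):
        stat, p = saturation_contingency([30] * 100, [0] * 100)
        assert p < 0.001

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            saturation_contingency([], [1, 2])


class TestRankTest:
    def test_identical_groups_p_one(self):
        assert rank_test([3, 3, 3], [3, 3, 3])[1] == 1.0

    def test_exact_one_sided_p_for_complete_separation(self):
        _, p = rank_test([1, 2, 3], [4, 5, 6], alternative="less")
        assert p == pytest.approx(1 / 20)  # U = 0; 1 of C(6,3) assignments

    def test_exact_p_matches_full_enumeration(self, rng):
        """Oracle: permutation distribution of U over all label assignments."""
        a = [1.3, 2.7, 0.2, 4.1, 3.3]
        b = [5.0, 0.9, 2.1, 6.2]
        u_obs, p = rank_test(a, b)
        pooled = np.array(a + b)
        n_a = len(a)
        us = []
        for idx in itertools.combinations(range(len(pooled)), n_a):
            ga = pooled[list(idx)]
            gb = np.delete(pooled, list(idx))
            u = sum((x > y) + 0.5 * (x == y) for x in ga for y in gb)
            us.append(u)
        us = np.array(us)
        mean_u = len(a) * len(b) / 2
        p_enum = np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12)
        assert p == pytest.approx(p_enum, abs=1e-12)

    def test_label_swap_symmetry(self, rng):
        a = rng.standard_normal(8)
        b = rng.standard_normal(6) + 0.5
        assert rank_test(a, b)[1] == pytest.approx(rank_test(b, a)[1])

    def test_large_samples_use_normal_approximation_with_ties(self, rng):
        a = rng.integers(0, 5, 50).astype(float)
        b = rng.integers(0, 5, 60).astype(float) + 1
        _, p = rank_test(a, b)
        assert 0 < p < 1
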