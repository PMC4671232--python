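"""Lognormal fitting, exposure categories, intervention and birth weighting."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from hgscreen.exposure import (
    InfeasibleFitError,
    LognormalParams,
    apply_intervention,
    birth_weights,
    category_masses,
    count_above_threshold,
    fit_lognormal,
    fitted_groups,
    group_weights,
    maternal_bounds,
    weighted_tail_probability,
)

Z75 = norm.ppf(0.75)
Z90 = norm.ppf(0.90)


class TestFit:
    def test_single_anchor_quantile_inversion(self):
        """sigma = (ln P75 - ln GM) / z75; the fitted quantile inverts exactly."""
        fit = fit_lognormal(0.66, [(75, 1.6)])
        assert fit.log_mu == pytest.approx(np.log(0.66), abs=1e-12)
        assert fit.log_sigma == pytest.approx((np.log(1.6) - np.log(0.66)) / Z75, abs=1e-12)
        assert fit.log_sigma == pytest.approx(1.313, abs=1e-3)
        # quantile-inversion oracle: the fitted distribution returns the anchor
        assert np.exp(fit.log_mu + Z75 * fit.log_sigma) == pytest.approx(1.6, abs=1e-9)

    def test_p90_anchor(self):
        fit = fit_lognormal(0.82, [(90, 2.9)])
        assert fit.log_mu == pytest.approx(-0.1985, abs=1e-4)
        assert fit.log_sigma == pytest.approx((np.log(2.9) - np.log(0.82)) / Z90, abs=1e-12)
        assert fit.log_sigma == pytest.approx(0.9857, abs=1e-4)

    def test_two_anchor_least_squares(self, ps):
        """With two anchors sigma is the weighted LS slope through the origin."""
        fit = fit_lognormal(0.82, [(75, 1.7), (90, 2.9)])
        z = np.array([Z75, Z90])
        d = np.array([np.log(1.7 / 0.82), np.log(2.9 / 0.82)])
        assert fit.log_sigma == pytest.approx(z @ d / (z @ z), abs=1e-12)
        # brute-force oracle: grid search of the LS objective
        grid = np.linspace(0.5, 1.5, 20001)
        obj = ((d[None, :] - grid[:, None] * z[None, :]) ** 2).sum(axis=1)
        assert fit.log_sigma == pytest.approx(grid[obj.argmin()], abs=1e-4)

    def test_median_anchor_degenerates(self):
        fit = fit_lognormal(1.0, [(50, 1.0 + 1e-9)])
        assert fit.degenerate

    def test_infeasible_anchor_raises(self):
        with pytest.raises(InfeasibleFitError):
            fit_lognormal(0.66, [(75, 0.5)])


class TestBounds:
    def test_printed_ratio(self):
        out = maternal_bounds((5.8, 7.3, 10.2, 13.0), 1.7)
        assert out == pytest.approx([3.41176, 4.29412, 6.0, 7.64706], abs=1e-5)

    def test_identity_and_scaling(self):
        bounds = np.array([1.0, 2.0, 3.0, 4.0])
        assert maternal_bounds(bounds, 1.0) == pytest.approx(bounds)
        assert maternal_bounds(bounds, 2.0) == pytest.approx(bounds / 2)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            maternal_bounds((1, 2, 3, 4), 0.0)


class TestCategoryMasses:
    def test_tail_above_screening_threshold(self, ps):
        """P(maternal Hg > 3.4) for women 20-39 is ~0.106 (population ~0.104)."""
        fit = fitted_groups(ps)[0]
        tail = 1 - norm.cdf((np.log(3.4) - fit.log_mu) / fit.log_sigma)
        assert tail == pytest.approx(0.106, abs=0.002)
        assert weighted_tail_probability(ps, 3.4) == pytest.approx(0.104, abs=0.002)

    def test_degenerate_bounds_collapse_to_first_category(self):
        ln = LognormalParams(0.0, 1.0)
        cm = category_masses(ln, (1e12, 2e12, 3e12, 4e12))
        assert cm.masses == pytest.approx([1, 0, 0, 0, 0], abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        mu=st.floats(-2, 2),
        sigma=st.floats(0.05, 3),
        start=st.floats(0.1, 5),
        steps=st.lists(st.floats(0.1, 5), min_size=3, max_size=3),
    )
    def test_masses_are_probability_vector(self, mu, sigma, start, steps):
        bounds = start + np.cumsum([0.0] + steps)
        cm = category_masses(LognormalParams(mu, sigma), bounds)
        assert np.all(cm.masses >= -1e-15)
        assert cm.masses.sum() == pytest.approx(1.0, abs=1e-12)

    def test_cdf_telescoping_against_scipy(self):
        ln = LognormalParams(-0.4, 1.3)
        bounds = np.array([2.0, 4.0, 6.0, 8.0])
        cm = category_masses(ln, bounds)
        ref = np.diff(np.concatenate((
            [0.0], norm.cdf((np.log(bounds) - ln.log_mu) / ln.log_sigma), [1.0])))
        assert cm.masses == pytest.approx(ref, abs=1e-14)


class TestIntervention:
    BOUNDS = (3.4118, 4.2941, 6.0, 7.6471)

    def test_null_intervention(self, ps):
        ln = fitted_groups(ps)[0]
        base = category_masses(ln, self.BOUNDS).masses
        for kwargs in ({"p_success": 0.0, "effectiveness": 0.5},
                       {"p_success": 0.9, "effectiveness": 0.0}):
            out = apply_intervention(ln, self.BOUNDS, 3.4, **kwargs)
            assert out.masses == pytest.approx(base, abs=1e-12)

    def test_total_effectiveness_moves_all_treated_below(self, ps):
        ln = fitted_groups(ps)[0]
        base = category_masses(ln, self.BOUNDS).masses
        threshold = 6.0
        p_above = 1 - norm.cdf((np.log(threshold) - ln.log_mu) / ln.log_sigma)
        out = apply_intervention(ln, self.BOUNDS, threshold, 1.0, 1 - 1e-12)
        assert out.masses[0] == pytest.approx(base[0] + p_above, abs=1e-6)
        assert out.masses[1:3] == pytest.approx(base[1:3], abs=1e-12)
        assert out.masses[3:] == pytest.approx([0.0, 0.0], abs=1e-6)

    def test_mass_conserved(self, ps):
        for ln in fitted_groups(ps):
            out = apply_intervention(ln, self.BOUNDS, 3.4, 6 / 7, 0.556)
            assert out.masses.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(out.masses >= 0)

    @pytest.mark.parametrize("threshold", [3.4, 4.7, 8.0])
    def test_matches_individual_level_monte_carlo(self, ps, threshold):
        """Closed-form masses agree with simulating 1e6 women within 3 SE."""
        ln = fitted_groups(ps)[0]
        out = apply_intervention(ln, self.BOUNDS, threshold, 6 / 7, 0.556)
        rng = np.random.default_rng(20240917)
        n = 1_000_000
        hg = rng.lognormal(ln.log_mu, ln.log_sigma, n)
        treated = (hg > threshold) & (rng.random(n) < 6 / 7)
        hg = np.where(treated, hg * (1 - 0.556), hg)
        counts = np.histogram(hg, bins=[0, *self.BOUNDS, np.inf])[0]
        freq = counts / n
        se = np.sqrt(freq * (1 - freq) / n)
        assert np.all(np.abs(freq - out.masses) < 3 * np.maximum(se, 1e-6))

    def test_raising_threshold_never_raises_low_mass(self, ps):
        ln = fitted_groups(ps)[0]
        below = [
            apply_intervention(ln, self.BOUNDS, thr, 6 / 7, 0.556).masses[0]
            for thr in (3.4, 4.0, 4.7, 6.0, 8.0, 12.0)
        ]
        assert np.all(np.diff(below) <= 1e-12)


class TestBirthWeights:
    def test_band_counts_and_screening(self, ps):
        bw = birth_weights(ps.births)
        assert bw.live_births[0] == pytest.approx(0.122 * 140_135)
        assert bw.planned_live_births == pytest.approx(bw.live_births * 0.5)
        assert bw.screened_pregnancies == pytest.approx(bw.planned_live_births / 0.9)
        assert list(bw.exposure_group) == [0, 0, 0, 0, 1, 1]

    def test_zero_planned_fraction(self, ps):
        bm = dataclasses.replace(ps.births, planned_fraction=0.0)
        assert birth_weights(bm).screened_pregnancies == pytest.approx(0.0)

    def test_group_weights_normalized(self, ps):
        w = group_weights(ps.births)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert w[0] == pytest.approx(0.928 / 0.970, abs=1e-9)


class TestCountAboveThreshold:
    def test_infinite_threshold_gives_zero(self, ps):
        ps_hi = dataclasses.replace(ps, intervention_threshold_maternal=1e12)
        births, planned = count_above_threshold(ps_hi)
        assert births == pytest.approx(0.0, abs=1e-6)
        assert planned == pytest.approx(0.0, abs=1e-6)

    def test_planned_is_half_of_births_over_point_nine(self, ps):
        births, planned = count_above_threshold(ps)
        assert planned == pytest.approx(births * 0.5 / 0.9, rel=1e-12)

    def test_base_case_magnitude(self, ps):
        births, _ = count_above_threshold(ps)
        # roughly 10% of the 140,135 Ontario live births
        assert 0.09 * 140_135 < births < 0.12 * 140_135
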