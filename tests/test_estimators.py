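"""Univariable MR estimators against closed-form, grid and limiting oracles."""

import numpy as np
import pytest
from scipy import stats

from mrmediate import (
    DegenerateInstrumentsError,
    InsufficientInstrumentsError,
    ParameterError,
    SimConfig,
    egger,
    harmonize,
    ivw,
    mode_based,
    raps,
    select_by_pvalue,
    simulate_mediation_gwas,
    weighted_median,
)
from mrmediate.estimators import RatioEstimates, _weighted_median

from conftest import make_harmonized, random_harmonized


def wls_oracle(x, y, w):
    """Weighted least squares via explicit normal equations (test-side)."""
    xw = x * np.sqrt(w)[:, None]
    yw = y * np.sqrt(w)
    coef, *_ = np.linalg.lstsq(xw, yw, rcond=None)
    return coef


class TestIVW:
    def test_single_snp_is_wald_ratio(self):
        h = make_harmonized([0.1], [0.01], [0.05], [0.01])
        with pytest.warns(UserWarning, match="single SNP"):
            est = ivw(h)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_zero_heterogeneity_floors_random_scale(self):
        bx = np.array([0.1, 0.2, 0.3])
        h = make_harmonized(bx, 0.01 * np.ones(3), 0.5 * bx, 0.01 * np.ones(3))
        est_r = ivw(h, model="multiplicative-random")
        est_f = ivw(h, model="fixed")
        assert est_r.beta == pytest.approx(0.5)
        assert est_r.extras["Q"] == pytest.approx(0.0, abs=1e-20)
        assert est_r.se == est_f.se

    def test_three_snp_closed_form(self):
        bx = np.array([0.1, 0.2, 0.15])
        by = np.array([0.06, 0.09, 0.08])
        sy = np.array([0.01, 0.01, 0.02])
        h = make_harmonized(bx, 0.01 * np.ones(3), by, sy)
        est = ivw(h, model="fixed")
        expected = wls_oracle(bx[:, None], by, 1 / sy**2)[0]
        assert est.beta == pytest.approx(expected, rel=1e-12)
        assert est.se == pytest.approx(np.sum(bx**2 / sy**2) ** -0.5, rel=1e-12)

    def test_degenerate_instruments_raise(self):
        h = make_harmonized([0.0, 0.0], [0.01, 0.01], [0.1, 0.1], [0.01, 0.01])
        with pytest.raises(DegenerateInstrumentsError):
            ivw(h)

    def test_ci_and_pvalue_conventions(self, rng):
        h = random_harmonized(rng, 8)
        est = ivw(h)
        assert est.ci_low == pytest.approx(est.beta - 1.96 * est.se)
        assert est.ci_high == pytest.approx(est.beta + 1.96 * est.se)
        assert est.pvalue == pytest.approx(2 * stats.norm.sf(abs(est.beta / est.se)))


class TestEgger:
    def test_exact_line_recovers_slope_and_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.01 + 0.5 * bx
        h = make_harmonized(bx, 0.01 * np.ones(4), by, 0.01 * np.ones(4))
        est = egger(h)
        assert est.beta == pytest.approx(0.5, rel=1e-10)
        assert est.extras["intercept"] == pytest.approx(0.01, rel=1e-9)
        assert est.extras["residual_q"] == pytest.approx(0.0, abs=1e-18)

    def test_origin_data_gives_zero_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_harmonized(bx, 0.01 * np.ones(4), 0.7 * bx, 0.01 * np.ones(4))
        assert egger(h).extras["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        h = random_harmonized(rng, 6, intercept=0.02)
        bx, _, by, sy = h.pair()
        sign = np.where(bx < 0, -1.0, 1.0)
        x = np.column_stack([np.ones(6), bx * sign])
        expected = wls_oracle(x, by * sign, 1 / sy**2)
        est = egger(h)
        assert est.extras["intercept"] == pytest.approx(expected[0], rel=1e-10)
        assert est.beta == pytest.approx(expected[1], rel=1e-10)

    def test_requires_three_snps(self):
        h = make_harmonized([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            egger(h)


class TestWeightedMedian:
    def test_identical_ratios(self):
        bx = np.array([0.1, 0.2, 0.3])
        h = make_harmonized(bx, 0.01 * np.ones(3), 0.5 * bx, 0.01 * np.ones(3))
        est = weighted_median(h, n_boot=100, seed=1)
        assert est.beta == pytest.approx(0.5)

    def test_equal_weight_crossing_by_hand(self):
        # ratios {0.1, 0.5, 0.9}, equal weights: cumulative (1/6, 3/6, 5/6)
        # crosses 0.5 exactly at the middle ratio
        bx = np.ones(3)
        by = np.array([0.1, 0.5, 0.9])
        est = _weighted_median(by / bx, np.ones(3))
        assert est == pytest.approx(0.5)

    def test_interpolation_between_brackets(self):
        # weights 1,2,1 on ratios 0,1,2: p = (.125, .5, .875) -> exactly 1
        assert _weighted_median(np.array([0.0, 1.0, 2.0]),
                                np.array([1.0, 2.0, 1.0])) == pytest.approx(1.0)

    def test_seed_determinism_and_boot_noise(self, rng):
        h = random_harmonized(rng, 10)
        a = weighted_median(h, n_boot=300, seed=7)
        b = weighted_median(h, n_boot=300, seed=7)
        c = weighted_median(h, n_boot=300, seed=8)
        assert a.beta == b.beta and a.se == b.se
        assert c.se == pytest.approx(a.se, rel=0.5)  # MC noise only

    def test_small_n_boot_rejected(self, rng):
        h = random_harmonized(rng, 5)
        with pytest.raises(ParameterError):
            weighted_median(h, n_boot=1, seed=0)


class TestModeBased:
    def test_majority_cluster_wins(self):
        bx = np.ones(4) * 0.2
        by = np.array([0.1, 0.1, 0.1, 0.4])  # ratios 0.5,0.5,0.5,2.0
        h = make_harmonized(bx, 0.01 * np.ones(4), by, 0.01 * np.ones(4))
        est = mode_based(h, "simple", n_boot=100, seed=1)
        assert est.beta == pytest.approx(0.5, abs=0.15)

    def test_single_snp_degenerates_to_ratio(self):
        h = make_harmonized([0.1], [0.01], [0.05], [0.01])
        with pytest.warns(UserWarning):
            est = mode_based(h, "simple", n_boot=100, seed=1)
        assert est.beta == pytest.approx(0.5)

    @pytest.mark.parametrize("variant", ["simple", "weighted"])
    def test_matches_dense_grid_oracle(self, rng, variant):
        h = random_harmonized(rng, 12, sy_scale=0.02)
        est = mode_based(h, variant, n_boot=100, seed=3)
        re = RatioEstimates.from_harmonized(h)
        w = np.ones(12) if variant == "simple" else re.weights
        bw = est.extras["bandwidth"]
        grid = np.linspace(re.ratios.min() - 3 * bw, re.ratios.max() + 3 * bw, 200_001)
        dens = np.zeros_like(grid)
        for r, wi in zip(re.ratios, w):  # independent density accumulation
            dens += wi * np.exp(-0.5 * ((grid - r) / bw) ** 2)
        oracle = grid[np.argmax(dens)]
        coarse_step = (grid[-1] - grid[0]) / 4095
        assert abs(est.beta - oracle) <= coarse_step

    def test_zero_bandwidth_factor_rejected(self, rng):
        h = random_harmonized(rng, 5)
        with pytest.raises(ParameterError):
            mode_based(h, "simple", bandwidth_factor=0.0)


class TestRAPS:
    def test_limits_to_fixed_ivw_when_exposure_error_vanishes(self):
        bx = np.array([0.1, 0.15, 0.2, 0.25, 0.3])
        by = 0.4 * bx + np.array([0.001, -0.002, 0.0, 0.002, -0.001])
        sy = 0.01 * np.ones(5)
        h = make_harmonized(bx, 1e-10 * np.ones(5), by, sy)
        est_ivw = ivw(h, model="fixed")
        assert raps(h).beta == pytest.approx(est_ivw.beta, abs=1e-6)

    def test_noise_free_ratios_recovered_exactly(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_harmonized(bx, 0.005 * np.ones(4), -0.8 * bx, 0.01 * np.ones(4))
        assert raps(h).beta == pytest.approx(-0.8, abs=1e-9)

    def test_root_matches_grid_search_oracle(self, rng):
        from mrmediate.estimators import _profile_score

        h = random_harmonized(rng, 8, sx_scale=0.02)
        bx, sx, by, sy = h.pair()
        root = raps(h).beta
        # the score may have spurious far-field crossings; verify the
        # returned root brackets a sign change on a fine local grid
        step = 1e-4
        s_lo = _profile_score(root - step, bx, sx, by, sy)
        s_hi = _profile_score(root + step, bx, sx, by, sy)
        assert np.sign(s_lo) != np.sign(s_hi)
        # and that it is the crossing nearest the IVW estimate
        center = ivw(h, model="fixed").beta
        grid = np.linspace(center - 0.2, center + 0.2, 4001)
        scores = np.array([_profile_score(b, bx, sx, by, sy) for b in grid])
        crossings = grid[np.flatnonzero(np.diff(np.sign(scores)))]
        assert len(crossings) >= 1
        assert min(abs(crossings - root)) <= (grid[1] - grid[0])

    def test_reserved_flags_rejected(self, rng):
        h = random_harmonized(rng, 5)
        with pytest.raises(ParameterError):
            raps(h, robust=True)


class TestEquivariance:
    """Shared symmetries every estimator must respect."""

    def _all(self, h, seed=5):
        return {
            "ivw": ivw(h),
            "egger": egger(h),
            "wm": weighted_median(h, n_boot=100, seed=seed),
            "mode": mode_based(h, "weighted", n_boot=100, seed=seed),
            "raps": raps(h),
        }

    def test_negating_outcome_negates_betas(self, rng):
        h = random_harmonized(rng, 8)
        neg = make_harmonized(h.beta[:, 0], h.se[:, 0], -h.beta[:, 1], h.se[:, 1])
        a, b = self._all(h), self._all(neg)
        for key in a:
            assert b[key].beta == pytest.approx(-a[key].beta, rel=1e-6), key
        # analytic SEs are exactly unchanged
        for key in ("ivw", "egger", "raps"):
            assert b[key].se == pytest.approx(a[key].se, rel=1e-9), key

    def test_scaling_exposure_scales_betas_inversely(self, rng):
        h = random_harmonized(rng, 8)
        c = 2.5
        scaled = make_harmonized(c * h.beta[:, 0], c * h.se[:, 0],
                                 h.beta[:, 1], h.se[:, 1])
        a, b = self._all(h), self._all(scaled)
        for key in ("ivw", "egger", "raps", "wm"):
            assert b[key].beta == pytest.approx(a[key].beta / c, rel=1e-7), key
        assert b["mode"].beta == pytest.approx(a["mode"].beta / c, rel=1e-3)

    def test_bit_reproducibility_on_same_seed(self, rng):
        h = random_harmonized(rng, 10)
        for fn in (
            lambda: weighted_median(h, n_boot=200, seed=42),
            lambda: mode_based(h, "simple", n_boot=200, seed=42),
        ):
            r1, r2 = fn(), fn()
            assert (r1.beta, r1.se) == (r2.beta, r2.se)


class TestMedianRobustness:
    def test_weighted_median_resists_directional_pleiotropy(self):
        """With 60% of weight on valid instruments and strong directional
        pleiotropy on the rest, the weighted median stays near the truth
        while IVW is pulled far off (200 simulated datasets)."""
        wm, iv = [], []
        for s in range(200):
            e, m, _, tr = simulate_mediation_gwas(SimConfig(
                n_mediator_snps=0, pleiotropy="directional",
                pleiotropy_magnitude=0.05, pleiotropy_frac=0.4, seed=70_000 + s,
            ))
            h = harmonize(select_by_pvalue(e), [m])
            iv.append(ivw(h).beta)
            re = RatioEstimates.from_harmonized(h)
            wm.append(_weighted_median(re.ratios, re.weights))
        mcse_iv = np.std(iv, ddof=1) / np.sqrt(len(iv))
        bias_wm = abs(np.mean(wm) - tr.alpha)
        bias_iv = abs(np.mean(iv) - tr.alpha)
        assert bias_iv > 10 * mcse_iv          # IVW demonstrably biased
        assert bias_wm < bias_iv / 3           # median largely resists it
        assert bias_wm < 0.05                  # and stays near the truth
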