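import numpy as np
import pandas as pd
import pytest

import hookqc as h
from hookqc.hook_core import HookCurve


class TestSigmaDelta:
    @pytest.mark.parametrize(
        "pm,mm,sigma,delta",
        [(100, 100, 2.0, 0.0), (1000, 100, 2.5, 1.0), (100, 1000, 2.5, -1.0)],
    )
    def test_worked_values(self, pm, mm, sigma, delta):
        s, d = h.sigma_delta(pm, mm)
        assert s == pytest.approx(sigma)
        assert d == pytest.approx(delta)

    def test_non_positive_raises(self):
        with pytest.raises(ValueError, match="probe"):
            h.sigma_delta([100.0, 0.0], [100.0, 100.0])


class TestProbesetHookPoints:
    def test_constant_set(self, flat_chip):
        pts = h.probeset_hook_points(flat_chip)
        assert np.allclose(pts["sigma"], 2.0)
        assert np.allclose(pts["delta"], 0.0)

    def test_matches_bruteforce_recomputation(self, small_chip):
        chip, _ = small_chip
        pts = h.probeset_hook_points(chip)
        df = chip.regular
        some = df["probeset_id"].unique()[:25]
        for pid in some:
            sub = df[df["probeset_id"] == pid]
            sig = np.mean(0.5 * (np.log10(sub["pm"]) + np.log10(sub["mm"])))
            dlt = np.mean(np.log10(sub["pm"]) - np.log10(sub["mm"]))
            assert pts.loc[pid, "sigma"] == pytest.approx(sig)
            assert pts.loc[pid, "delta"] == pytest.approx(dlt)


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        curve = h.moving_average(np.arange(50.0), np.full(50, 3.14), base_window=7)
        assert np.allclose(curve.delta, 3.14)

    def test_window3_interior(self):
        curve = h.moving_average(np.arange(5.0), np.array([1.0, 2, 3, 4, 5]), 3, shrink_tail=False)
        assert np.allclose(curve.delta[1:4], [2.0, 3.0, 4.0])

    def test_noise_reduction_follows_sqrt_n(self):
        rng = np.random.default_rng(0)
        n, w = 20000, 1000
        vals = rng.normal(0, 1, n)
        curve = h.moving_average(np.arange(float(n)), vals, w, shrink_tail=False)
        interior = curve.delta[w : n - w]
        ratio = interior.std() * np.sqrt(w + 1)
        assert 0.6 < ratio < 1.5

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            h.moving_average(np.array([]), np.array([]), 5)


class TestTheoreticalHook:
    FIT = dict(alpha=0.85, beta=2.5, sigma_start=1.5, delta_start=0.0)

    def test_origin(self):
        sig, dlt = h.theoretical_hook(0.0, **self.FIT)
        assert sig == pytest.approx(1.5, abs=2e-3)
        assert dlt == pytest.approx(0.0, abs=2e-3)

    def test_saturation_cancels_alpha(self):
        sig, dlt = h.theoretical_hook(1e12, **self.FIT)
        assert dlt == pytest.approx(0.0, abs=1e-6)
        assert sig == pytest.approx(1.5 + 2.5, abs=1e-3)

    def test_s_range_reaches_alpha_for_large_beta(self):
        _, dlt = h.theoretical_hook(1e4, alpha=0.85, beta=12.0, sigma_start=1.5)
        assert dlt == pytest.approx(0.85, abs=1e-3)

    def test_sigma_strictly_increasing_delta_nonnegative(self):
        r = 10.0 ** np.linspace(-4, 7, 500)
        sig, dlt = h.theoretical_hook(r, **self.FIT)
        assert np.all(np.diff(sig) > 0)
        assert np.all(dlt > -1e-12)


class TestFitHook:
    def test_noiseless_self_consistency(self):
        a, b, s0 = 0.85, 2.5, 1.5
        logr = np.linspace(-3, b + 3, 600)
        sig, dlt = h.theoretical_hook(10.0**logr, a, b, s0, 0.0)
        fit = h.fit_hook(HookCurve(sigma=sig, delta=dlt, window_sizes=np.ones_like(sig)))
        assert fit.alpha == pytest.approx(a, abs=0.01)
        assert fit.beta == pytest.approx(b, abs=0.01)
        assert fit.sigma_start == pytest.approx(s0, abs=0.01)
        assert fit.logM == pytest.approx(s0 + b, abs=0.01)

    def test_simulated_alpha_recovery(self, default_result):
        assert default_result.hook_fit.alpha == pytest.approx(0.85, abs=0.1)

    def test_flat_curve_has_no_specific_branch(self):
        sig = np.linspace(1, 3, 200)
        with pytest.raises(h.HookError, match="no specific branch"):
            h.fit_hook(HookCurve(sigma=sig, delta=np.zeros(200), window_sizes=np.ones(200)))

    def test_narrow_curve_rejected(self):
        sig = np.linspace(1, 1.05, 50)
        with pytest.raises(h.HookError, match="narrow"):
            h.fit_hook(HookCurve(sigma=sig, delta=np.full(50, 0.5), window_sizes=np.ones(50)))


class TestRegimes:
    def test_boundary_labels(self):
        fit = h.HookFit(alpha=0.85, beta=2.5, sigma_start=1.5)
        labels = h.classify_regimes(np.array([1.5, 4.0]), fit)
        assert labels[0] == "N"
        assert labels[1] == "as"

    def test_pct_absent_recovery(self, default_chip, default_result):
        _, truth = default_chip
        assert default_result.hook_fit.pct_absent == pytest.approx(
            truth.pct_absent_true, abs=0.05
        )

    def test_pct_absent_invariant_under_rescaling(self, small_chip):
        chip, _ = small_chip
        df = chip.probes.copy()
        df["pm"] *= 3.0
        df["mm"] *= 3.0
        res1 = h.analyze_chip(chip)
        res2 = h.analyze_chip(chip.with_probes(df))
        assert res2.hook_fit.pct_absent == pytest.approx(res1.hook_fit.pct_absent, abs=0.02)


class TestExpressionIndex:
    def test_all_sets_at_unity_ratio(self):
        fit = h.HookFit(alpha=0.85, beta=2.5, sigma_start=1.5)
        sig_at_r1, _ = h.theoretical_hook(1.0, 0.85, 2.5, 1.5)
        phi = h.expression_index(np.full(50, sig_at_r1), fit, labels=np.full(50, "mix"))
        assert phi == pytest.approx(1.5 - 4.0, abs=0.02)

    def test_doubling_concentrations_shifts_phi_by_log2(self):
        base = dict(n_psets=3000, fraction_absent=0.3, noise_sd=0.05)
        cfg1 = h.SimConfig(S_log10_range=(-3.0, 1.0), **base)
        cfg2 = h.SimConfig(S_log10_range=(-3.0 + np.log10(2), 1.0 + np.log10(2)), **base)
        phis = []
        for cfg in (cfg1, cfg2):
            chip, _ = h.simulate_chip(cfg, seed=5)
            res = h.analyze_chip(chip)
            phis.append(res.hook_fit.phi)
        assert phis[1] - phis[0] == pytest.approx(np.log10(2), abs=0.08)

    def test_pure_n_chip_flagged_undefined(self):
        fit = h.HookFit(alpha=0.85, beta=2.5, sigma_start=1.5)
        with pytest.warns(UserWarning, match="undefined"):
            phi = h.expression_index(np.full(10, 1.5), fit, labels=np.full(10, "N"))
        assert np.isnan(phi)
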