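import numpy as np
import pandas as pd
import pytest

import hookqc as h
from hookqc.degradation import DecayProfile, theoretical_tongs_ordinate
from hookqc.hook_core import HookFit
from tests.conftest import make_chip

LN10 = np.log(10.0)


def chip_with_sigma_profile(slope=0.05, n_sets=20, sigma0=3.0):
    """Sets whose per-probe Σ declines linearly with k (pm = mm)."""
    recs = []
    for i in range(n_sets):
        for k in range(1, 12):
            v = 10.0 ** (sigma0 - slope * (k - 1))
            recs.append((f"s{i}", k, 50 * (k - 1), v, v))
    return make_chip(recs)


class TestSubsetSigma:
    def test_identical_probes_all_subsets_equal(self, flat_chip):
        sub = h.subset_sigma(flat_chip)
        for col in ("sigma_3p", "sigma_m", "sigma_5p"):
            assert np.allclose(sub[col], 2.0)

    def test_linear_sigma_hand_value(self):
        # Σ_k = 3 − 0.05(k−1): 3' subset mean 2.95, 5' subset mean 2.55
        sub = h.subset_sigma(chip_with_sigma_profile())
        diff = sub["sigma_3p"] - sub["sigma_5p"]
        assert np.allclose(diff, 0.4)

    def test_size_three_set_has_zero_opening(self):
        recs = [("s1", k, 0, 10.0 * k, 10.0 * k) for k in range(1, 4)]
        sub = h.subset_sigma(make_chip(recs))
        assert sub["sigma_3p"].iloc[0] == pytest.approx(sub["sigma_5p"].iloc[0])


class TestTongsAndDeghook:
    def test_pure_n_chip_flat_branches(self):
        # branches stay within 3x their local noise (set-to-set affinity
        # scatter averaged over the smoothing window)
        cfg = h.SimConfig(n_psets=800, fraction_absent=1.0)
        chip, _ = h.simulate_chip(cfg, seed=3)
        sub = h.subset_sigma(chip)
        tongs, deghook = h.tongs_and_deghook(chip)
        for branch, raw in (
            (tongs.d3, sub["sigma_3p"] - sub["sigma"]),
            (tongs.dm, sub["sigma_m"] - sub["sigma"]),
            (tongs.d5, sub["sigma_5p"] - sub["sigma"]),
            (deghook.delta35, sub["sigma_3p"] - sub["sigma_5p"]),
        ):
            local_noise = raw.std() / np.sqrt(tongs.window_sizes)
            n_decile = len(branch) // 10
            assert np.all(np.abs(branch[:n_decile]) < 3.0 * local_noise[:n_decile])
            assert np.all(np.abs(branch) < 4.0 * local_noise)

    def test_degraded_chip_maximum_near_truth(self, default_chip):
        chip, truth = default_chip
        _, deghook = h.tongs_and_deghook(chip)
        assert np.max(deghook.delta35) == pytest.approx(truth.delta_gamma_true, rel=0.15)

    def test_branch_ordering_3p_above_5p(self, default_chip):
        chip, _ = default_chip
        sub = h.subset_sigma(chip)
        tongs, _ = h.tongs_and_deghook(chip)
        noise_3m = (sub["sigma_3p"] - sub["sigma_m"]).std() / np.sqrt(tongs.window_sizes)
        noise_m5 = (sub["sigma_m"] - sub["sigma_5p"]).std() / np.sqrt(tongs.window_sizes)
        assert np.all(tongs.d3 >= tongs.dm - 3.0 * noise_3m)
        assert np.all(tongs.dm >= tongs.d5 - 3.0 * noise_m5)

    def test_saturated_sets_reconverge(self, default_chip):
        # beyond the maximum the opening declines again (saturation)
        chip, _ = default_chip
        _, deghook = h.tongs_and_deghook(chip)
        i_max = int(np.argmax(deghook.delta35))
        tail = deghook.delta35[i_max:]
        assert tail[-1] < 0.6 * deghook.delta35[i_max]


class TestTongsOpeningFit:
    FIT = HookFit(alpha=0.85, beta=2.5, sigma_start=1.5)

    def test_self_consistency_on_generated_curve(self):
        logr = np.linspace(-3, 5, 400)
        R = 10.0**logr
        d35 = theoretical_tongs_ordinate(R, 0.3, -0.3, self.FIT)
        sig, _ = h.theoretical_hook(R, 0.85, 2.5, 1.5)
        curve = h.DegradationHookCurve(sigma=sig, delta35=d35)
        dg, _, converged = h.fit_tongs_opening(curve, self.FIT)
        assert converged
        assert dg == pytest.approx(0.6, abs=0.01)

    def test_flat_curve_gives_zero(self):
        sig = np.linspace(1.5, 4.0, 100)
        curve = h.DegradationHookCurve(sigma=sig, delta35=np.zeros(100))
        dg, _, _ = h.fit_tongs_opening(curve, self.FIT)
        assert dg == pytest.approx(0.0, abs=0.01)

    def test_simulated_recovery(self, default_chip, default_result):
        _, truth = default_chip
        assert default_result.summary.tongs_opening == pytest.approx(
            truth.delta_gamma_true, abs=0.05
        )

    def test_theoretical_limits_vanish(self):
        v0 = theoretical_tongs_ordinate(np.array([1e-12]), 0.3, -0.3, self.FIT)
        vinf = theoretical_tongs_ordinate(np.array([1e12]), 0.3, -0.3, self.FIT)
        assert abs(v0[0]) < 1e-6 and abs(vinf[0]) < 1e-6

    def test_maximum_approaches_opening_without_saturation(self):
        weak_sat = HookFit(alpha=0.85, beta=8.0, sigma_start=1.5)
        R = 10.0 ** np.linspace(-3, 6, 600)
        vals = theoretical_tongs_ordinate(R, 0.3, -0.3, weak_sat)
        assert np.max(vals) == pytest.approx(0.6, abs=0.01)


@pytest.mark.parametrize("dg,expected", [(0.57, 0.27), (0.29, 0.51), (0.0, 1.0)])
def test_d_from_tongs_worked_values(dg, expected):
    assert round(h.d_from_tongs(dg), 2) == expected


@pytest.mark.parametrize("dg,expected", [(0.57, -0.285), (0.0, 0.0), (0.47, -0.235)])
def test_mean_log_d(dg, expected):
    assert h.mean_log_d(dg) == pytest.approx(expected)


class TestDecayProfiles:
    def test_flat_chip_unit_decay(self, flat_chip):
        labels = pd.Series("S", index=flat_chip.regular["probeset_id"].unique())
        prof = h.decay_profile(flat_chip, labels, subset="S", scale="k")
        assert np.allclose(prof.d, 1.0)

    def test_nonspecific_profile_flat(self, default_chip):
        # truth-absent sets: the model applies no positional decay to the
        # non-specific signal, so their profile stays flat
        chip, truth = default_chip
        labels = pd.Series(
            np.where(truth.per_set["absent"], "N", "S"),
            index=truth.per_set["probeset_id"],
        )
        prof = h.decay_profile(chip, labels, subset="N", scale="k")
        assert np.all(np.abs(prof.d - 1.0) < 0.05)

    def test_empty_subset_errors(self, flat_chip):
        labels = pd.Series("S", index=flat_chip.regular["probeset_id"].unique())
        with pytest.raises(ValueError, match="no probe sets"):
            h.decay_profile(flat_chip, labels, subset="N", scale="k")

    def test_l_scale_recovers_truth_constant(self):
        cfg = h.SimConfig(
            n_psets=3000, fraction_absent=0.0, K_N_log10_mean=-4.0,
            S_log10_range=(-2.0, -0.5), noise_sd=0.05,
            decay=h.DecayTruth(scale="L", lambda_=150.0),
        )
        chip, _ = h.simulate_chip(cfg, seed=9)
        labels = pd.Series("S", index=chip.regular["probeset_id"].unique())
        prof = h.decay_profile(chip, labels, subset="S", scale="L")
        fit = h.fit_decay(prof, fix_d_inf=True)
        assert fit.lambda_ == pytest.approx(150.0, rel=0.1)


class TestFitDecay:
    def test_pure_exponential_exact(self):
        x = np.arange(11.0)
        prof = DecayProfile("k", "S", x, np.zeros(11), np.exp(-x / 4.0), np.ones(11))
        fit = h.fit_decay(prof)
        assert fit.lambda_ == pytest.approx(4.0, abs=1e-6)
        assert fit.x0 == pytest.approx(0.0, abs=1e-6)
        assert fit.d_inf == 0.0

    def test_shifted_exponential_plus_constant_recovered(self):
        lam, dinf, x0 = 150.0, 0.2, 150.0
        x = np.arange(112.5, 600.0, 25.0)
        d = (1 - dinf) * np.exp(-np.maximum(x - x0, 0) / lam) + dinf
        prof = DecayProfile("L", "S", x, np.zeros_like(x), d, np.ones_like(x))
        fit = h.fit_decay(prof)
        assert fit.lambda_ == pytest.approx(lam, rel=0.01)
        assert fit.d_inf == pytest.approx(dinf, rel=0.01)
        assert fit.x0 == pytest.approx(x0, rel=0.01)

    def test_too_few_bins_error(self):
        x = np.arange(3.0)
        prof = DecayProfile("k", "S", x, np.zeros(3), np.exp(-x / 4), np.ones(3))
        with pytest.raises(ValueError, match="bins"):
            h.fit_decay(prof)


class TestDegradationRatio:
    def test_exponential_oracle(self):
        # constant affinities, d(k) = exp(−(k−1)/4): the mean index gap
        # between {10,11} and {1,2} is 9, so log10 d^k = −9/(4 ln 10)
        recs = [
            (f"s{i}", k, 50 * (k - 1), 1000.0 * np.exp(-(k - 1) / 4.0), 50.0)
            for i in range(60)
            for k in range(1, 12)
        ]
        chip = make_chip(recs)
        labels = pd.Series("S", index=chip.regular["probeset_id"].unique())
        log_dk, low_conf = h.degradation_ratio_dk(chip, labels)
        assert not low_conf
        assert log_dk == pytest.approx(-9.0 / (4.0 * LN10), abs=1e-9)

    def test_flat_chip_zero(self, flat_chip):
        labels = pd.Series("S", index=flat_chip.regular["probeset_id"].unique())
        log_dk, low_conf = h.degradation_ratio_dk(flat_chip, labels)
        assert log_dk == pytest.approx(0.0, abs=1e-12)
        assert low_conf  # only 20 sets

    def test_noisy_simulation_close_to_noiseless(self):
        base = dict(n_psets=1500, fraction_absent=0.0, K_N_log10_mean=-4.0,
                    S_log10_range=(-2.0, -0.5))
        cfg0 = h.with_tongs_opening(h.SimConfig(noise_sd=0.0, **base), 0.5)
        cfg1 = h.with_tongs_opening(h.SimConfig(noise_sd=0.1, **base), 0.5)
        vals = []
        for cfg in (cfg0, cfg1):
            chip, _ = h.simulate_chip(cfg, seed=13)
            labels = pd.Series("S", index=chip.regular["probeset_id"].unique())
            vals.append(h.degradation_ratio_dk(chip, labels)[0])
        assert vals[1] == pytest.approx(vals[0], abs=0.05)


class TestLambdaFromDk:
    def test_closed_form(self):
        lam_k, lam_L = h.lambda_from_dk(np.log10(np.exp(-2.0)), 50.0)
        assert lam_k == pytest.approx(4.0)
        assert lam_L == pytest.approx(200.0)

    def test_non_negative_ratio_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            lam_k, lam_L = h.lambda_from_dk(0.0, 50.0)
        assert np.isnan(lam_k) and np.isnan(lam_L)


class TestAffyslope:
    def test_flat_chip_zero_slope(self, flat_chip):
        _, slope = h.affyslope(flat_chip)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_pure_s_chip_matches_s_profile(self):
        recs = [
            (f"s{i}", k, 50 * (k - 1), 1000.0 * np.exp(-(k - 1) / 4.0), 50.0)
            for i in range(60)
            for k in range(1, 12)
        ]
        chip = make_chip(recs)
        _, slope = h.affyslope(chip)
        assert slope == pytest.approx(-1.0 / (4.0 * LN10), abs=1e-9)

    def test_diluting_with_flat_sets_shrinks_slope(self):
        decayed = [
            (f"s{i}", k, 50 * (k - 1), 1000.0 * np.exp(-(k - 1) / 4.0), 50.0)
            for i in range(60)
            for k in range(1, 12)
        ]
        flat = [(f"n{i}", k, 50 * (k - 1), 80.0, 80.0) for i in range(60) for k in range(1, 12)]
        _, slope_pure = h.affyslope(make_chip(decayed))
        _, slope_mixed = h.affyslope(make_chip(decayed + flat))
        assert abs(slope_mixed) < abs(slope_pure)


class TestPositionalHistograms:
    @staticmethod
    def _chip_and_labels(n_low=60, n_high=60, same=False):
        recs, labels = [], {}
        for i in range(n_low):
            for k in range(1, 12):
                recs.append((f"low{i}", k, 30 * (k - 1) + 20, 100.0, 100.0))
            labels[f"low{i}"] = "S" if same else "N"
        for i in range(n_high):
            for k in range(1, 12):
                recs.append((f"high{i}", k, 50 * (k - 1) + 200, 100.0, 100.0))
            labels[f"high{i}"] = "S"
        return make_chip(recs), pd.Series(labels)

    def test_n_enrichment_at_short_sets(self):
        chip, labels = self._chip_and_labels()
        hist = h.sn_positional_histograms(chip, labels)
        short = hist[(hist["position"] == "L_max") & (hist["bin_right"] <= 500)]
        assert short["diff_N_minus_S"].sum() > 0.5

    def test_identical_distributions_zero_difference(self):
        recs, labels = [], {}
        for i in range(40):
            for k in range(1, 12):
                recs.append((f"s{i}", k, 40 * (k - 1) + 50, 100.0, 100.0))
            labels[f"s{i}"] = "N" if i % 2 else "S"
        hist = h.sn_positional_histograms(make_chip(recs), pd.Series(labels))
        assert np.allclose(hist["diff_N_minus_S"], 0.0)
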