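"""Positional intensity decays of specifically and non-specifically
hybridized probes, on the probe-index (k) and nucleotide (L) scales.

Only the specific signal decays with distance from the transcript 3'-end;
the non-specific background is flat. The two fitted decay lengths are
linked by the mean probe spacing: lambda_L ~ lambda_k * <dL>."""

import hookqc as h

config = h.with_tongs_opening(h.SimConfig(n_psets=5000), 0.5)
chip, truth = h.simulate_chip(config, seed=4)
result = h.analyze_chip(chip)

for subset in ("S", "N"):
    prof = h.decay_profile(chip, result.labels, subset=subset, scale="k")
    dvals = " ".join(f"{v:.2f}" for v in prof.d)
    print(f"{subset}-subset d(k): {dvals}")

fit_k = result.summary.decay_fits["k"]
fit_L = result.summary.decay_fits["L"]
_, spacing = h.mean_probe_spacing(chip)
print(f"fitted lambda_k = {fit_k.lambda_:.2f} probe indices "
      f"(truth {truth.lambda_k_true:.2f})")
print(f"fitted lambda_L = {fit_L.lambda_:.0f} nt, d_inf = {fit_L.d_inf:.2f}")
print(f"mean probe spacing <dL> = {spacing:.1f} nt/index; "
      f"lambda_k * <dL> = {fit_k.lambda_ * spacing:.0f} nt")
print("The S-profile decays to ~30% over the set while the N-profile stays "
      "flat: only specific binding reports RNA quality.")
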