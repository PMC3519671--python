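"""Remove the 3'/5' positional bias from a degraded chip and verify the
round trip: after correction the two-point degradation ratio and the tongs
opening should collapse to ~0."""

import hookqc as h

config = h.with_tongs_opening(h.SimConfig(n_psets=5000), 0.5)
chip, truth = h.simulate_chip(config, seed=2)

before = h.analyze_chip(chip)
corrected, factors, model = h.correct_chip(chip, scale="k", result=before)
after = h.analyze_chip(corrected)

print(f"before correction: log d^k = {before.summary.log_dk:+.3f}   "
      f"tongs opening = {before.summary.tongs_opening:.3f}")
print(f"after  correction: log d^k = {after.summary.log_dk:+.3f}   "
      f"tongs opening = {after.summary.tongs_opening:.3f}")
print(f"decay used: lambda_{model.scale} = {model.decay.lambda_:.2f} "
      f"(amplitude-calibrated exponent {model.theta:.2f})")
print(f"largest applied rescaling: x{1.0 / factors['C_pm'].min():.2f} "
      "(5'-most probes of fully specific sets)")
print("Values near zero mean the positional bias was removed; non-specific "
      "sets were left untouched.")
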