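"""Overlap artifact in a world of fixed S and R components — and its exact removal.

Simulates 500 trials whose ground truth is a stimulus-locked bump plus a
response-locked bump, identical on every trial (no RT effect anywhere).
Because the two components overlap more on fast trials, the uncorrected
response-locked averages show a spurious fast-vs-slow amplitude difference;
subtracting the jointly fitted stimulus-locked kernel removes it to
numerical precision, because this world satisfies the regression's
time-invariance assumption exactly.
"""

import rerpsim as rs

cfg = rs.default_sr_config(seed=1, n_trials=500)
report = rs.run_s_subtraction(cfg)

unc = report.measurements["uncorrected"]
cor = report.measurements["corrected"]
print(f"uncorrected fast-slow pre-response amplitude: {unc.amplitude_effect:+.4f}")
print(f"corrected   fast-slow pre-response amplitude: {cor.amplitude_effect:+.2e}")
print(f"residual variance fraction of the fit:        {report.scalars['residual_fraction']:.2e}")
print()
print("The uncorrected effect is pure overlap artifact (the ground truth has")
print("none); after S subtraction it vanishes to machine precision and the")
print("regression explains the recording essentially exactly.")
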