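"""How non-decision-time jitter decides where an accumulation signal lands.

Simulates a diffusion accumulator flanked by a pre-accumulation (encoding)
delay and a post-accumulation (motor) delay, and sweeps the ratio of their
jitter SDs while holding the delay means and the total jitter SD fixed.
The more the response jitters relative to the accumulation trace, the more
of the trace the stimulus-locked kernel absorbs — and at high ratios that
kernel inherits the accumulator's genuine RT effect (fast > slow peak under
a collapsing bound).
"""

import rerpsim as rs

cfg = rs.default_ddm_config(seed=1, n_trials=500)
rep = rs.run_jitter_experiment(cfg)

print("post/pre jitter SD ratio   S variance share   S-peak effect (fast-slow)")
for ratio, share, eff in zip(rep.ratios, rep.s_variance_share, rep.s_peak_effect):
    print(f"{ratio:>22.1f}   {share:>16.4f}   {eff:>+24.4f}")
print()
print(f"monotone non-decreasing S share: {rep.monotone_nondecreasing}")
print("The S-attribution grows with relative motor jitter; finding RT effects")
print("in a stimulus-locked component is expected, not anomalous, when the")
print("underlying signal is an accumulation process.")
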