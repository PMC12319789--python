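"""Two further diagnostics that fail to separate the two worlds.

1. Fit RT-split S and R kernels and compare the S kernels' pre-stimulus
   baselines: the accumulation world forces a spurious fast < slow baseline
   offset into the S estimates; the fixed-component world does not.
2. Fit RT-agnostic pooled S+R kernels and measure the residual variance
   fraction: it is small in BOTH worlds, so a small residual cannot certify
   that no accumulation signal was present.
"""

import rerpsim as rs

for name, cfg in (
    ("fixed S+R components", rs.default_sr_config(seed=1, n_trials=500)),
    ("accumulation ramp   ", rs.default_ramp_config(seed=1, n_trials=500)),
):
    rep = rs.run_split_component_fit(cfg)
    print(f"{name}:  S-kernel baseline difference (fast-slow) = "
          f"{rep.scalars['s_kernel_baseline_difference']:+.4f},  "
          f"RT-agnostic residual fraction = "
          f"{rep.scalars['rt_agnostic_residual_fraction']:.4f}")

print()
print("A negative baseline difference flags misattributed accumulation")
print("activity; near-zero residuals occur in both worlds and are therefore")
print("not diagnostic of whether a real ramp was removed.")
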