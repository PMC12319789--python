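"""Unit tests for the ground-truth signal generators."""

import numpy as np
import pytest
from scipy.stats import norm

import rerpsim as rs
from rerpsim.config import RTDistribution
from rerpsim.sim import DDMNonCrossingError


class TestDrawRTs:
    def test_degenerate_distribution_gives_identical_rts(self):
        dist = RTDistribution(shift=0.2, median=0.8, sigma_log=0.0)
        rts = rs.draw_rts(5, dist, seed=0)
        assert np.all(rts == 0.8)

    def test_quantiles_match_closed_form(self):
        dist = RTDistribution()
        rts = rs.draw_rts(10_000, dist, seed=42)
        for q in (0.1, 0.9):
            analytic = dist.shift + (dist.median - dist.shift) * np.exp(
                dist.sigma_log * norm.ppf(q)
            )
            assert np.quantile(rts, q) == pytest.approx(analytic, rel=0.02)
        assert np.all(rts > 0)

    def test_empty_request_rejected(self):
        with pytest.raises(ValueError):
            rs.draw_rts(0, RTDistribution(), seed=0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            RTDistribution(shift=0.5, median=0.4)

    def test_reproducible_given_seed(self):
        dist = RTDistribution()
        assert np.array_equal(rs.draw_rts(100, dist, 3), rs.draw_rts(100, dist, 3))


class TestSRTrial:
    fs = 100.0

    def kernels(self):
        s = rs.hann_bump_kernel(0.3, 0.6, 1.0, self.fs)
        r = rs.hann_bump_kernel(-0.1, 0.6, 1.5, self.fs)
        return s, r

    def test_zero_r_kernel_leaves_s_kernel(self):
        s, r = self.kernels()
        r = rs.WaveformKernel(r.lags, np.zeros_like(r.values))
        seg = rs.make_sr_trial(0.8, s, r, self.fs)
        i = round(s.lags[0] * self.fs) - seg.start
        assert np.array_equal(seg.values[i : i + s.values.size], s.values)

    def test_disjoint_supports_concatenate(self):
        s, r = self.kernels()
        seg = rs.make_sr_trial(2.0, s, r, self.fs)  # rt far beyond both supports
        assert seg.values.max() == pytest.approx(max(s.values.max(), r.values.max()))

    def test_overlapping_supports_sum_pointwise(self):
        # brute-force oracle: place each kernel on a common absolute grid and add
        s, r = self.kernels()
        rt = 0.5
        seg = rs.make_sr_trial(rt, s, r, self.fs)
        n = 400
        direct = np.zeros(n)
        off = 200
        s0 = off + round(s.lags[0] * self.fs)
        direct[s0 : s0 + s.values.size] += s.values
        r0 = off + round(rt * self.fs) + round(r.lags[0] * self.fs)
        direct[r0 : r0 + r.values.size] += r.values
        placed = np.zeros(n)
        placed[off + seg.start : off + seg.start + seg.values.size] = seg.values
        assert np.array_equal(placed, direct)

    def test_subsample_rt_rejected(self):
        s, r = self.kernels()
        with pytest.raises(ValueError):
            rs.make_sr_trial(0.001, s, r, self.fs)


class TestRampTrial:
    fs = 100.0

    def test_constant_bound_endpoint_and_slope(self):
        bound = rs.constant_bound(2.0)
        seg = rs.make_ramp_trial(0.5, 0.1, bound, 0.1, self.fs)
        assert seg.values[50] == pytest.approx(2.0)
        rise = seg.values[10:51]
        slopes = np.diff(rise) * self.fs
        assert np.allclose(slopes, 2.0 / 0.4)

    def test_collapsing_bound_monotone_in_rt(self):
        bound = rs.collapsing_bound(1.0, 0.3, 0.6)
        amp, slope = [], []
        for rt in (0.5, 0.8, 1.2):
            seg = rs.make_ramp_trial(rt, 0.1, bound, 0.1, self.fs)
            i_resp = round(rt * self.fs)
            amp.append(seg.values[i_resp])
            slope.append((seg.values[i_resp] - seg.values[i_resp - 1]) * self.fs)
        assert amp[0] > amp[1] > amp[2]
        assert slope[0] > slope[1] > slope[2]

    def test_endpoint_equals_bound_at_rt(self):
        bound = rs.collapsing_bound(1.0, 0.3, 0.6)
        rt = 0.73
        seg = rs.make_ramp_trial(rt, 0.1, bound, 0.1, self.fs)
        rt_q = round(rt * self.fs) / self.fs
        assert seg.values[round(rt * self.fs)] == pytest.approx(float(bound(rt_q)))

    def test_zero_before_onset_and_after_decay(self):
        seg = rs.make_ramp_trial(0.5, 0.1, rs.constant_bound(1.0), 0.1, self.fs)
        assert np.all(seg.values[:10] == 0)
        assert seg.values[-1] == pytest.approx(0.0)

    def test_rt_not_exceeding_onset_rejected(self):
        with pytest.raises(ValueError):
            rs.make_ramp_trial(0.1, 0.1, rs.constant_bound(1.0), 0.1, self.fs)


class TestDDMTrial:
    fs = 100.0

    def test_noiseless_decision_time_is_bound_over_drift(self):
        seg, rt = rs.simulate_ddm_trial(
            drift=2.0, noise_sd=0.0, bound=rs.constant_bound(1.0), dt=0.001,
            pre_ea_delay=0.0, post_ea_delay=0.0, seed=0, fs=self.fs,
        )
        # rt = pre + decision + post with both delays zero; decision = b/drift
        assert rt == pytest.approx(0.5, abs=0.0011)

    def test_noiseless_trajectory_is_linear_ramp(self):
        seg, rt = rs.simulate_ddm_trial(
            drift=1.0, noise_sd=0.0, bound=rs.constant_bound(1.0), dt=0.001,
            pre_ea_delay=0.2, post_ea_delay=0.0, seed=0, fs=self.fs,
        )
        ramp = rs.make_ramp_trial(rt, 0.2, rs.constant_bound(1.0), 0.1, self.fs)
        n = min(seg.values.size, ramp.values.size)
        assert np.allclose(seg.values[:n], ramp.values[:n], atol=0.015)

    def test_first_passage_mean_matches_wald(self):
        # single absorbing boundary from 0 with positive drift: E[T] = b/mu,
        # independent of the diffusion coefficient (Wald distribution)
        rng = np.random.default_rng(99)
        times = []
        for _ in range(4000):
            _, rt = rs.simulate_ddm_trial(
                drift=1.0, noise_sd=1.0, bound=rs.constant_bound(1.0), dt=0.0005,
                pre_ea_delay=0.0, post_ea_delay=0.0, seed=rng, fs=100.0,
                max_decision_time=30.0,
            )
            times.append(rt)
        assert np.mean(times) == pytest.approx(1.0, rel=0.05)

    def test_rt_includes_both_delays(self):
        _, rt = rs.simulate_ddm_trial(
            drift=1.0, noise_sd=0.0, bound=rs.constant_bound(1.0), dt=0.001,
            pre_ea_delay=0.25, post_ea_delay=0.15, seed=0, fs=self.fs,
        )
        assert rt == pytest.approx(0.25 + 1.0 + 0.15, abs=0.002)

    def test_non_crossing_raises_diagnostic(self):
        with pytest.raises(DDMNonCrossingError):
            rs.simulate_ddm_trial(
                drift=-1.0, noise_sd=0.0, bound=rs.constant_bound(1.0), dt=0.001,
                pre_ea_delay=0.0, post_ea_delay=0.0, seed=0, fs=self.fs,
                max_decision_time=0.5, max_resamples=2,
            )


class TestAssembleRecording:
    def test_single_trial_recording_equals_segment(self):
        cfg = rs.default_sr_config(seed=3, n_trials=1)
        recording, events, details = rs.assemble_recording(cfg, return_details=True)
        seg = details["segments"][0]
        si = recording.sample_index(events.stim_onset[0])
        window = recording.samples[si + seg.start : si + seg.start + seg.values.size]
        assert np.array_equal(window, seg.values)
        assert np.all(np.delete(recording.samples,
                                np.arange(si + seg.start,
                                          si + seg.start + seg.values.size)) == 0)

    def test_same_seed_bit_identical(self):
        for scenario in ("SR", "RAMP", "DDM"):
            cfg = rs.ScenarioConfig(scenario=scenario, seed=5, n_trials=20)
            r1, e1 = rs.assemble_recording(cfg)
            r2, e2 = rs.assemble_recording(cfg)
            assert np.array_equal(r1.samples, r2.samples)
            assert np.array_equal(e1.stim_onset, e2.stim_onset)
            assert np.array_equal(e1.resp_onset, e2.resp_onset)

    def test_noise_free_recording_is_exact_superposition(self, sr_world):
        # energy bookkeeping against the brute-force summation of segments
        cfg, recording, events, details = sr_world
        direct = np.zeros(recording.n_samples)
        for seg, onset in zip(details["segments"], events.stim_onset):
            si = recording.sample_index(onset)
            direct[si + seg.start : si + seg.start + seg.values.size] += seg.values
        assert np.array_equal(recording.samples, direct)
        assert np.sum(recording.samples**2) == pytest.approx(np.sum(direct**2))

    def test_component_bookkeeping_sums_to_recording(self, sr_world):
        cfg, recording, events, details = sr_world
        assert np.allclose(
            details["S"].samples + details["R"].samples, recording.samples,
            atol=1e-12,
        )

    def test_too_short_iti_rejected(self):
        cfg = rs.default_sr_config(
            seed=0, n_trials=3,
            iti_distribution=rs.ITIDistribution(low=0.2, high=0.3),
        )
        with pytest.raises(ValueError):
            rs.assemble_recording(cfg)

    def test_sensor_noise_changes_only_noise(self):
        base = rs.default_sr_config(seed=9, n_trials=10)
        noisy = base.replace(sensor_noise_sd=0.5)
        r0, _ = rs.assemble_recording(base)
        r1, _ = rs.assemble_recording(noisy)
        diff = r1.samples - r0.samples
        assert np.std(diff) == pytest.approx(0.5, rel=0.05)

    def test_events_match_placement(self, sr_world):
        cfg, recording, events, details = sr_world
        assert np.allclose(events.rt, details["rts"])
        assert np.all(events.rt > 0)
        assert np.all(np.diff(events.stim_onset) > 0)
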