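"""Time-expanded design construction and the joint least-squares fit."""

import numpy as np
import pytest

import rerpsim as rs
from rerpsim.deconv import BY_RT_CATEGORY, RankDeficientDesignError
from rerpsim.events import FAST, SLOW


def small_events(stims, rts, fs=100.0):
    stim = np.asarray(stims) / fs
    return rs.EventTable(stim_onset=stim, resp_onset=stim + np.asarray(rts) / fs)


def pooled_spec(s_window=(-0.2, 1.0), r_window=(-0.8, 0.2), fs=100.0):
    return rs.DesignSpec(
        stimulus=rs.PredictorSpec(window=s_window),
        response=rs.PredictorSpec(window=r_window),
        fs=fs,
    )


class TestBuildDesign:
    def test_single_event_indicator_structure(self):
        ev = small_events([100], [50])
        spec = pooled_spec(s_window=(0.0, 0.02), r_window=(0.0, 0.02))
        design = rs.build_design(ev, spec, 300)
        X = design.matrix.toarray()
        g = design.group("stimulus")
        assert g.n_cols == 3
        sub = X[:, g.start : g.stop]
        assert sub.sum() == 3
        assert sub[100, 0] == 1 and sub[101, 1] == 1 and sub[102, 2] == 1

    def test_close_events_overlap_in_rows(self):
        ev = small_events([100, 102], [300, 300])
        spec = pooled_spec(s_window=(0.0, 0.04), r_window=(0.0, 0.01))
        design = rs.build_design(ev, spec, 600)
        X = design.matrix.toarray()
        g = design.group("stimulus")
        row = X[102, g.start : g.stop]
        assert row.sum() == 2  # lag 2 of the first event, lag 0 of the second
        assert row[2] == 1 and row[0] == 1

    def test_window_beyond_recording_rejected(self):
        ev = small_events([5], [50])
        with pytest.raises(ValueError):
            rs.build_design(ev, pooled_spec(), 1000)

    def test_column_count(self):
        ev = small_events([200, 600], [60, 80])
        design = rs.build_design(ev, pooled_spec(), 1500)
        assert design.n_cols == 121 + 101

    def test_by_category_requires_assigned_categories(self):
        ev = small_events([200, 600], [60, 80])
        spec = rs.DesignSpec(
            stimulus=rs.PredictorSpec(window=(-0.1, 0.5), scheme=BY_RT_CATEGORY),
            response=rs.PredictorSpec(window=(-0.5, 0.1)),
            fs=100.0,
        )
        with pytest.raises(ValueError):
            rs.build_design(ev, spec, 1500)


class TestFit:
    def test_exact_recovery_of_known_betas(self, rng):
        ev = small_events([150, 450, 800], [55, 90, 70], fs=100.0)
        spec = pooled_spec(s_window=(-0.1, 0.4), r_window=(-0.3, 0.1))
        design = rs.build_design(ev, spec, 1200)
        beta = rng.standard_normal(design.n_cols)
        recording = rs.ContinuousRecording(design.matrix @ beta, 100.0)
        est = rs.fit(recording, design)
        assert np.allclose(est.betas, beta, atol=1e-10)

    def test_matches_dense_normal_equations(self, rng):
        ev = small_events([120, 300, 520, 780], [60, 95, 75, 110])
        spec = pooled_spec(s_window=(-0.05, 0.3), r_window=(-0.2, 0.05))
        design = rs.build_design(ev, spec, 1100)
        y = rng.standard_normal(1100)
        est = rs.fit(rs.ContinuousRecording(y, 100.0), design)
        dense, *_ = np.linalg.lstsq(design.matrix.toarray(), y, rcond=None)
        assert np.allclose(est.betas, dense, rtol=0, atol=1e-8 * max(1, np.abs(dense).max()))

    def test_rank_deficiency_detected_and_named(self):
        # identical RTs make stimulus and response columns exact time-shifted
        # copies of each other: no jitter, no identifiability
        ev = small_events([200, 500, 800], [50, 50, 50])
        spec = pooled_spec(s_window=(0.0, 0.8), r_window=(-0.5, 0.3))
        design = rs.build_design(ev, spec, 1400)
        rec = rs.ContinuousRecording(np.zeros(1400) + 0.0, 100.0)
        rec.samples[200] = 1.0
        with pytest.raises(RankDeficientDesignError, match="stimulus"):
            rs.fit(rec, design)

    def test_sr_world_kernels_recovered_exactly(self, sr_world):
        cfg, recording, events, details = sr_world
        design = rs.build_design(events, pooled_spec(), recording.n_samples)
        est = rs.fit(recording, design)
        s_true = rs.hann_bump_kernel(0.3, 0.6, 1.0, cfg.fs)
        r_true = rs.hann_bump_kernel(-0.1, 0.6, 1.5, cfg.fs)
        for name, true in (("stimulus", s_true), ("response", r_true)):
            k = est.kernel(name)
            est_on_support = np.array([true.value_at(l) for l in k.lags])
            assert np.max(np.abs(k.values - est_on_support)) <= 1e-6 * true.peak

    def test_permuted_trial_labels_leave_estimate_unchanged(self, sr_world):
        cfg, recording, events, _ = sr_world
        shuffled = rs.EventTable(
            stim_onset=events.stim_onset,
            resp_onset=events.resp_onset,
            rt_category=events.rt_category,
            trial_id=events.trial_id[::-1].copy(),
        )
        d1 = rs.build_design(events, pooled_spec(), recording.n_samples)
        d2 = rs.build_design(shuffled, pooled_spec(), recording.n_samples)
        assert np.array_equal(rs.fit(recording, d1).betas, rs.fit(recording, d2).betas)


@pytest.fixture(scope="module")
def sr_fit(sr_world):
    cfg, recording, events, details = sr_world
    design = rs.build_design(events, pooled_spec(), recording.n_samples)
    return recording, events, details, rs.fit(recording, design)


class TestComponents:

    def test_full_prediction_plus_residual_reconstructs(self, sr_fit):
        recording, events, details, est = sr_fit
        pred = rs.predict_component(est, which="all")
        assert np.allclose(pred.samples + est.residual, recording.samples, atol=1e-10)

    def test_empty_selection_is_zero(self, sr_fit):
        recording, *_ , est = sr_fit
        assert not np.any(rs.predict_component(est, which="none").samples)

    def test_unknown_predictor_rejected(self, sr_fit):
        *_, est = sr_fit
        with pytest.raises(KeyError):
            rs.predict_component(est, which="saccade")

    def test_s_prediction_matches_ground_truth_bookkeeping(self, sr_fit):
        recording, events, details, est = sr_fit
        s_pred = rs.predict_component(est, which="stimulus")
        assert np.max(np.abs(s_pred.samples - details["S"].samples)) <= 1e-6

    def test_subtract_zero_is_identity(self, sr_fit):
        recording, *_ , est = sr_fit
        zero = rs.ContinuousRecording(np.zeros(recording.n_samples), recording.fs)
        assert np.array_equal(
            rs.subtract_component(recording, zero).samples, recording.samples
        )

    def test_subtract_full_prediction_leaves_fit_residual(self, sr_fit):
        recording, *_ , est = sr_fit
        pred = rs.predict_component(est, which="all")
        resid = rs.subtract_component(recording, pred)
        assert np.var(resid.samples) == pytest.approx(est.residual_variance, abs=1e-12)

    def test_shape_mismatch_rejected(self, sr_fit):
        recording, *_ , est = sr_fit
        other = rs.ContinuousRecording(np.zeros(10), recording.fs)
        with pytest.raises(ValueError):
            rs.subtract_component(recording, other)


class TestResidualFraction:
    def test_noise_free_design_generated_recording_is_zero(self, rng):
        ev = small_events([150, 400, 700], [60, 85, 95])
        spec = pooled_spec(s_window=(-0.1, 0.4), r_window=(-0.3, 0.1))
        design = rs.build_design(ev, spec, 1100)
        rec = rs.ContinuousRecording(design.matrix @ rng.standard_normal(design.n_cols), 100.0)
        est = rs.fit(rec, design)
        assert rs.residual_fraction(rec, est) <= 1e-12

    def test_pure_noise_recording_close_to_one(self, rng):
        ev = small_events([300, 900, 1500], [60, 85, 95])
        spec = pooled_spec(s_window=(-0.1, 0.3), r_window=(-0.2, 0.1))
        design = rs.build_design(ev, spec, 2200)
        rec = rs.ContinuousRecording(rng.standard_normal(2200), 100.0)
        est = rs.fit(rec, design)
        frac = rs.residual_fraction(rec, est)
        assert 0.9 < frac <= 1.0

    def test_zero_variance_recording_rejected(self, rng):
        ev = small_events([300], [60])
        spec = pooled_spec(s_window=(0.0, 0.1), r_window=(0.0, 0.1))
        design = rs.build_design(ev, spec, 800)
        rec = rs.ContinuousRecording(np.ones(800), 100.0)
        est = rs.fit(rec, design)
        rec0 = rs.ContinuousRecording(np.zeros(800), 100.0)
        with pytest.raises(ValueError):
            rs.residual_fraction(rec0, est)
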