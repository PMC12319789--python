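"""Ground-truth signal generators and recording assembly.

Three ground-truth worlds are simulated (see :mod:`rerpsim.config`):

* ``SR`` — fixed stimulus-locked and response-locked component kernels whose
  only RT dependence is their temporal overlap;
* ``RAMP`` — a stimulus-to-response accumulation ramp terminating on a bound,
  with no separately locked components;
* ``DDM`` — a noisy single-bound diffusion accumulator flanked by jittered
  pre-accumulation (encoding) and post-accumulation (motor) delays, whose RT
  is the emergent first-passage time.

Per-trial signals are expressed as :class:`TrialSignal` segments (a sample
offset relative to the stimulus sample plus an amplitude array) and summed
linearly into a continuous recording, optionally with white Gaussian sensor
noise.  All randomness derives from the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bounds import BoundFunction
from .config import DelayDistribution, RTDistribution, ScenarioConfig
from .events import EventTable
from .recording import ContinuousRecording, WaveformKernel, hann_bump_kernel

__all__ = [
    "TrialSignal",
    "draw_rts",
    "draw_delays",
    "make_sr_trial",
    "make_ramp_trial",
    "simulate_ddm_trial",
    "assemble_recording",
    "DDMNonCrossingError",
]


class DDMNonCrossingError(RuntimeError):
    """Accumulator failed to reach the bound within the time/resample budget."""


@dataclass
class TrialSignal:
    """A per-trial signal segment anchored to the trial's stimulus sample.

    ``start`` is the offset, in samples, of ``values[0]`` relative to the
    stimulus sample (negative for pre-stimulus activity).
    """

    start: int
    values: np.ndarray

    def add_into(self, out: np.ndarray, stim_index: int) -> None:
        """Add this segment into ``out`` with the stimulus at ``stim_index``."""
        i0 = stim_index + self.start
        i1 = i0 + self.values.size
        if i0 < 0 or i1 > out.size:
            raise ValueError("trial segment falls outside the recording")
        out[i0:i1] += self.values


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def draw_rts(n: int, dist: RTDistribution, seed) -> np.ndarray:
    """Draw ``n`` reaction times (seconds) from a shifted lognormal.

    ``seed`` may be an integer or a ``numpy.random.Generator``.  With
    ``sigma_log = 0`` all draws equal the median (degenerate distribution).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    scale = dist.median - dist.shift
    rts = dist.shift + scale * np.exp(dist.sigma_log * rng.standard_normal(n))
    return rts


def draw_delays(n: int, dist: DelayDistribution, seed) -> np.ndarray:
    """Draw non-decision delays: normal(mean, sd) truncated below at ``lower``.

    Truncation is by redraw (exact truncated-normal sampling via scipy's
    inverse CDF would also do; redraw keeps the dependency surface small and
    is exact too).  ``sd = 0`` returns the constant mean.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    if dist.sd == 0:
        return np.full(n, dist.mean)
    out = dist.mean + dist.sd * rng.standard_normal(n)
    for _ in range(1000):
        bad = out < dist.lower
        if not np.any(bad):
            return out
        out[bad] = dist.mean + dist.sd * rng.standard_normal(int(bad.sum()))
    raise RuntimeError("delay truncation failed to converge; check parameters")


def _check_kernel_grid(kernel: WaveformKernel, fs: float) -> None:
    if abs(kernel.fs - fs) > 1e-6 * fs:
        raise ValueError("kernel lag grid does not match the recording rate")


def make_sr_trial(
    rt: float,
    s_kernel: WaveformKernel,
    r_kernel: WaveformKernel,
    fs: float,
) -> TrialSignal:
    """One trial of the SR world: S kernel at the stimulus plus R kernel at
    the response, summed linearly where their supports overlap.

    The RT is quantized to the sample grid; an RT shorter than one sample is
    rejected.
    """
    _check_kernel_grid(s_kernel, fs)
    _check_kernel_grid(r_kernel, fs)
    rt_idx = int(round(rt * fs))
    if rt_idx < 1:
        raise ValueError("rt shorter than one sample")
    s_start = int(round(s_kernel.lags[0] * fs))
    r_start = rt_idx + int(round(r_kernel.lags[0] * fs))
    start = min(s_start, r_start)
    end = max(s_start + s_kernel.values.size, r_start + r_kernel.values.size)
    values = np.zeros(end - start)
    values[s_start - start : s_start - start + s_kernel.values.size] += s_kernel.values
    values[r_start - start : r_start - start + r_kernel.values.size] += r_kernel.values
    return TrialSignal(start=start, values=values)


def make_ramp_trial(
    rt: float,
    onset_delay: float,
    bound: BoundFunction,
    post_response_decay: float,
    fs: float,
) -> TrialSignal:
    """One trial of the RAMP world: zero until ``onset_delay`` after the
    stimulus, then a linear rise reaching ``bound(rt)`` exactly at the
    response, then a linear return to zero over ``post_response_decay``.

    The terminal amplitude follows the bound evaluated at the trial's RT, so
    under a collapsing bound slower trials terminate lower and build more
    slowly (slope = bound(rt) / (rt - onset_delay)).
    """
    rt_idx = int(round(rt * fs))
    onset_idx = int(round(onset_delay * fs))
    if rt_idx <= onset_idx:
        raise ValueError("rt must exceed the ramp onset delay")
    rt_q = rt_idx / fs
    amp = float(bound(rt_q))
    if amp <= 0:
        raise ValueError("bound must be positive at the trial RT")
    decay_idx = max(int(round(post_response_decay * fs)), 1)
    n = rt_idx + decay_idx + 1
    values = np.zeros(n)
    rise = np.arange(onset_idx, rt_idx + 1) - onset_idx
    values[onset_idx : rt_idx + 1] = amp * rise / (rt_idx - onset_idx)
    values[rt_idx:] = amp * (1.0 - np.arange(decay_idx + 1) / decay_idx)
    return TrialSignal(start=0, values=values)


def simulate_ddm_trial(
    drift: float,
    noise_sd: float,
    bound: BoundFunction,
    dt: float,
    pre_ea_delay: float,
    post_ea_delay: float,
    seed,
    fs: float,
    post_response_decay: float = 0.1,
    max_decision_time: float = 4.0,
    max_resamples: int = 50,
) -> tuple[TrialSignal, float]:
    """Simulate one diffusion trial; return its signal (on the fs grid) and RT.

    The accumulator starts at zero ``pre_ea_delay`` seconds after the
    stimulus and integrates ``drift*dt + noise_sd*sqrt(dt)*N(0,1)`` until it
    first crosses ``bound(t)`` (t on the accumulation clock).  The trajectory
    is clipped to the bound at the crossing, held there through the
    post-accumulation (motor) delay, then decays linearly to zero.  The trial
    RT is ``pre_ea_delay + decision_time + post_ea_delay``.  Trials that fail
    to cross within ``max_decision_time`` are redrawn; persistent failure
    raises :class:`DDMNonCrossingError`.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    step = 1.0 / (fs * dt)
    k = int(round(step))
    if abs(step - k) > 1e-9 or k < 1:
        raise ValueError("1/(fs*dt) must be a positive integer for decimation")
    rng = _as_rng(seed)
    max_steps = int(round(max_decision_time / dt))
    t_grid = dt * np.arange(1, max_steps + 1)
    bound_grid = np.asarray(bound(t_grid))

    for _ in range(max_resamples + 1):
        incr = drift * dt + noise_sd * np.sqrt(dt) * rng.standard_normal(max_steps)
        x = np.cumsum(incr)
        crossed = x >= bound_grid
        if crossed.any():
            j = int(np.argmax(crossed))  # first crossing step (0-based)
            break
    else:
        raise DDMNonCrossingError(
            f"no bound crossing within {max_decision_time} s after "
            f"{max_resamples + 1} attempts (drift={drift}, noise_sd={noise_sd})"
        )

    decision_time = t_grid[j]
    ea_path = x[: j + 1].copy()
    ea_path[-1] = bound_grid[j]  # clip the overshooting final step to the bound

    n_pre = int(round(pre_ea_delay / dt))
    n_post = int(round(post_ea_delay / dt))
    n_decay = max(int(round(post_response_decay / dt)), 1)
    level = ea_path[-1]
    fine = np.concatenate(
        [
            np.zeros(n_pre + 1),  # sample at the stimulus itself is zero
            ea_path,
            np.full(n_post, level),
            level * (1.0 - np.arange(1, n_decay + 1) / n_decay),
        ]
    )
    coarse = fine[::k]
    rt = (n_pre + (j + 1) + n_post) * dt
    return TrialSignal(start=0, values=coarse), rt


def _build_kernels(config: ScenarioConfig) -> tuple[WaveformKernel, WaveformKernel]:
    s = config.s_kernel
    r = config.r_kernel
    return (
        hann_bump_kernel(s.peak_time, s.width, s.amplitude, config.fs),
        hann_bump_kernel(r.peak_time, r.width, r.amplitude, config.fs),
    )


def assemble_recording(
    config: ScenarioConfig,
    return_details: bool = False,
):
    """Assemble a continuous recording and its event table from a scenario.

    Trials are placed sequentially: each stimulus follows the previous
    response by a uniform inter-trial-interval draw.  Per-trial ground-truth
    segments are summed linearly into the recording; optional white Gaussian
    sensor noise is added last.  Every draw derives from ``config.seed``, so
    identical configs produce bit-identical outputs.

    With ``return_details=True`` a third element is returned: a dict with the
    per-trial segments and, for the SR world, separate noise-free ``S`` and
    ``R`` component recordings for ground-truth bookkeeping.
    """
    fs = config.fs
    ss = np.random.SeedSequence(config.seed)
    rng_trials, rng_iti, rng_noise, rng_delays = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]
    n = config.n_trials

    segments: list[TrialSignal] = []
    s_segments: list[TrialSignal] = []
    r_segments: list[TrialSignal] = []

    if config.scenario == "SR":
        s_kernel, r_kernel = _build_kernels(config)
        tail = max(s_kernel.lags[-1], r_kernel.lags[-1])
        if config.iti_distribution.low < tail:
            raise ValueError(
                "minimum ITI shorter than the longest kernel window tail"
            )
        rts = draw_rts(n, config.rt_distribution, rng_trials)
        rts = np.maximum(np.round(rts * fs), 1) / fs
        for rt in rts:
            segments.append(make_sr_trial(rt, s_kernel, r_kernel, fs))
            s_segments.append(TrialSignal(int(round(s_kernel.lags[0] * fs)),
                                          s_kernel.values.copy()))
            r_start = int(round(rt * fs)) + int(round(r_kernel.lags[0] * fs))
            r_segments.append(TrialSignal(r_start, r_kernel.values.copy()))
    elif config.scenario == "RAMP":
        if config.iti_distribution.low < config.post_response_decay:
            raise ValueError("minimum ITI shorter than the post-response decay")
        rts = draw_rts(n, config.rt_distribution, rng_trials)
        rts = np.maximum(np.round(rts * fs),
                         round(config.ramp_onset_delay * fs) + 1) / fs
        for rt in rts:
            segments.append(
                make_ramp_trial(rt, config.ramp_onset_delay, config.bound,
                                config.post_response_decay, fs)
            )
    else:  # DDM
        d = config.ddm
        pres = draw_delays(n, d.pre_ea_delay, rng_delays)
        posts = draw_delays(n, d.post_ea_delay, rng_delays)
        rts = np.empty(n)
        for i in range(n):
            seg, rt = simulate_ddm_trial(
                d.drift, d.noise_sd, config.bound, d.dt,
                pres[i], posts[i], rng_trials, fs,
                post_response_decay=config.post_response_decay,
                max_decision_time=d.max_decision_time,
                max_resamples=d.max_resamples,
            )
            segments.append(seg)
            rts[i] = rt
        rts = np.maximum(np.round(rts * fs), 1) / fs

    itis = rng_iti.uniform(config.iti_distribution.low,
                           config.iti_distribution.high, n)
    stim = np.empty(n)
    stim[0] = config.pad
    for i in range(1, n):
        stim[i] = stim[i - 1] + rts[i - 1] + itis[i - 1]
    stim = np.round(stim * fs) / fs
    resp = stim + rts

    n_samples = int(round((resp[-1] + config.pad) * fs)) + 1
    out = np.zeros(n_samples)
    stim_idx = np.round(stim * fs).astype(int)
    for seg, si in zip(segments, stim_idx):
        seg.add_into(out, si)

    details: dict = {"segments": segments, "rts": rts}
    if config.scenario == "SR":
        s_only = np.zeros(n_samples)
        r_only = np.zeros(n_samples)
        for seg, si in zip(s_segments, stim_idx):
            seg.add_into(s_only, si)
        for seg, si in zip(r_segments, stim_idx):
            seg.add_into(r_only, si)
        details["S"] = ContinuousRecording(s_only, fs)
        details["R"] = ContinuousRecording(r_only, fs)

    if config.sensor_noise_sd > 0:
        out = out + rng_noise.normal(0.0, config.sensor_noise_sd, n_samples)

    recording = ContinuousRecording(out, fs)
    events = EventTable(stim_onset=stim, resp_onset=resp)
    if return_details:
        return recording, events, details
    return recording, events
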