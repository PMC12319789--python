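"""Epoching, RT-split averaging, and waveform measurements.

Measurements follow a fixed sign convention: every reported "effect" is the
fast-RT value minus the slow-RT value.  No baseline correction is applied by
default anywhere (pre-stimulus levels are themselves a diagnostic here); an
explicit :func:`baseline_correct` is available for the variant analyses that
want it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .events import FAST, SLOW, EventTable
from .recording import ContinuousRecording, WaveformKernel

__all__ = [
    "EpochSet",
    "CategoryAverages",
    "MeasurementReport",
    "epoch",
    "average_by_category",
    "baseline_correct",
    "preresponse_amplitude",
    "buildup_slope",
    "baseline_difference",
    "measure_categories",
]

# default measurement windows (seconds relative to the locking event)
PRERESPONSE_WINDOW = (-0.05, 0.0)
SLOPE_WINDOW = (-0.30, -0.05)
BASELINE_WINDOW = (-0.2, 0.0)


@dataclass
class EpochSet:
    """Trials x time matrix aligned to stimulus or response.

    Row order matches the event table; the time axis runs from ``t_min`` to
    ``t_max`` inclusive on the recording's sample grid.
    """

    data: np.ndarray
    alignment: str  # "stimulus" | "response"
    window: tuple[float, float]
    fs: float
    rt: np.ndarray
    rt_category: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        i0 = int(round(self.window[0] * self.fs))
        return (i0 + np.arange(self.data.shape[1])) / self.fs

    def subset(self, mask: np.ndarray) -> "EpochSet":
        return EpochSet(
            self.data[mask], self.alignment, self.window, self.fs,
            self.rt[mask], self.rt_category[mask],
        )

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("epochs", data=self.data)
            f.create_dataset("rt", data=self.rt)
            f.create_dataset(
                "rt_category", data=np.asarray(self.rt_category, dtype="S12")
            )
            ds.attrs["alignment"] = self.alignment
            ds.attrs["t_min"] = self.window[0]
            ds.attrs["t_max"] = self.window[1]
            ds.attrs["fs"] = self.fs


def epoch(
    recording: ContinuousRecording,
    events: EventTable,
    alignment: str,
    window: tuple[float, float],
) -> EpochSet:
    """Cut the recording into per-trial segments around stimulus or response.

    No baseline correction is applied.  Raises if any trial's window falls
    outside the recording.
    """
    if alignment not in ("stimulus", "response"):
        raise ValueError("alignment must be 'stimulus' or 'response'")
    if events.n_trials == 0:
        raise ValueError("no events to epoch around")
    onsets = events.stim_onset if alignment == "stimulus" else events.resp_onset
    fs = recording.fs
    i_lo = int(round(window[0] * fs))
    i_hi = int(round(window[1] * fs))
    n_t = i_hi - i_lo + 1
    centers = np.round((onsets - recording.t0) * fs).astype(int)
    starts = centers + i_lo
    if starts.min() < 0 or (starts + n_t).max() > recording.n_samples:
        raise ValueError("epoch window extends beyond the recording")
    idx = starts[:, None] + np.arange(n_t)[None, :]
    return EpochSet(
        data=recording.samples[idx],
        alignment=alignment,
        window=window,
        fs=fs,
        rt=events.rt.copy(),
        rt_category=events.rt_category.copy(),
    )


@dataclass
class CategoryAverages:
    """Per-RT-category mean waveforms on a common time axis."""

    times: np.ndarray
    waveforms: dict[str, np.ndarray]
    counts: dict[str, int]
    alignment: str

    def effect(self) -> np.ndarray:
        """Pointwise fast - slow difference waveform."""
        return self.waveforms[FAST] - self.waveforms[SLOW]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for cat, wf in self.waveforms.items():
            for t, v in zip(self.times, wf):
                recs.append((cat, t, v, self.counts[cat]))
        return pd.DataFrame(
            recs, columns=["category", "time_s", "amplitude", "n_trials"]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")


def average_by_category(epochs: EpochSet) -> CategoryAverages:
    """Arithmetic mean across trials within each RT category."""
    waveforms: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for cat in (FAST, SLOW):
        mask = epochs.rt_category == cat
        if not np.any(mask):
            raise ValueError(f"category {cat!r} is empty")
        waveforms[cat] = epochs.data[mask].mean(axis=0)
        counts[cat] = int(mask.sum())
    return CategoryAverages(
        times=epochs.times, waveforms=waveforms, counts=counts,
        alignment=epochs.alignment,
    )


def baseline_correct(
    epochs: EpochSet, window: tuple[float, float] = BASELINE_WINDOW
) -> EpochSet:
    """Subtract each trial's mean over ``window`` from that trial (optional;
    never applied implicitly)."""
    mask = _window_mask(epochs.times, window)
    corrected = epochs.data - epochs.data[:, mask].mean(axis=1, keepdims=True)
    return EpochSet(
        corrected, epochs.alignment, epochs.window, epochs.fs,
        epochs.rt.copy(), epochs.rt_category.copy(),
    )


def _window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    eps = 1e-9
    mask = (times >= lo - eps) & (times <= hi + eps)
    if not np.any(mask):
        raise ValueError(f"window {window} lies outside the epoch time axis")
    if times[0] > lo + eps or times[-1] < hi - eps:
        raise ValueError(f"window {window} not fully covered by the epoch")
    return mask


def _coerce_waveform(waveform, times=None) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(waveform, WaveformKernel):
        return waveform.lags, waveform.values
    values = np.asarray(waveform, dtype=float)
    if times is None:
        raise ValueError("a bare array waveform needs an explicit time axis")
    return np.asarray(times, dtype=float), values


def preresponse_amplitude(
    waveform, times=None, window: tuple[float, float] = PRERESPONSE_WINDOW
) -> float:
    """Mean amplitude over the pre-response window (default [-50, 0] ms)."""
    t, v = _coerce_waveform(waveform, times)
    return float(v[_window_mask(t, window)].mean())


def buildup_slope(
    waveform, times=None, window: tuple[float, float] = SLOPE_WINDOW
) -> float:
    """Slope (amplitude/s) of the least-squares line over the buildup window
    (default [-300, -50] ms before the response)."""
    t, v = _coerce_waveform(waveform, times)
    mask = _window_mask(t, window)
    if mask.sum() < 3:
        raise ValueError("slope window must contain at least 3 samples")
    return float(np.polyfit(t[mask], v[mask], 1)[0])


def baseline_difference(
    fast_waveform,
    slow_waveform,
    times=None,
    window: tuple[float, float] = BASELINE_WINDOW,
) -> float:
    """Fast minus slow mean amplitude over the pre-stimulus baseline window
    (default [-200, 0] ms); negative values mean fast < slow."""
    tf, vf = _coerce_waveform(fast_waveform, times)
    ts, vs = _coerce_waveform(slow_waveform, times)
    return float(vf[_window_mask(tf, window)].mean() - vs[_window_mask(ts, window)].mean())


@dataclass
class MeasurementReport:
    """Pre-response amplitude, buildup slope and baseline level per RT
    category, with fast - slow effects, and the windows used."""

    amplitude: dict[str, float]
    slope: dict[str, float]
    amplitude_effect: float
    slope_effect: float
    windows: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "amplitude": dict(self.amplitude),
            "slope": dict(self.slope),
            "amplitude_effect": self.amplitude_effect,
            "slope_effect": self.slope_effect,
            "windows": {k: list(v) for k, v in self.windows.items()},
        }


def measure_categories(
    averages: CategoryAverages,
    amplitude_window: tuple[float, float] = PRERESPONSE_WINDOW,
    slope_window: tuple[float, float] = SLOPE_WINDOW,
) -> MeasurementReport:
    """Pre-response amplitude and buildup slope of the fast and slow average
    waveforms (response-locked), with fast - slow effects."""
    amp = {
        cat: preresponse_amplitude(wf, averages.times, amplitude_window)
        for cat, wf in averages.waveforms.items()
    }
    slope = {
        cat: buildup_slope(wf, averages.times, slope_window)
        for cat, wf in averages.waveforms.items()
    }
    return MeasurementReport(
        amplitude=amp,
        slope=slope,
        amplitude_effect=amp[FAST] - amp[SLOW],
        slope_effect=slope[FAST] - slope[SLOW],
        windows={"amplitude": amplitude_window, "slope": slope_window},
    )
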