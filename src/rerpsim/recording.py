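"""Continuous single-channel recordings and lag-indexed waveform kernels.

The recording is the un-epoched signal that both the simulators write into and
the deconvolution regressions read from.  A :class:`WaveformKernel` is a
waveform indexed by lag (seconds) relative to a locking event, on the same
uniform sample grid as the recording; it serves both as a ground-truth
component shape and as the container for fitted deconvolution betas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = ["ContinuousRecording", "WaveformKernel", "hann_bump_kernel"]


@dataclass
class ContinuousRecording:
    """Uniformly sampled single-channel signal.

    Parameters
    ----------
    samples
        Amplitude values (arbitrary units), one per sample.
    fs
        Sampling rate in Hz.
    t0
        Time of the first sample in seconds (default 0).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("recording must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def copy(self) -> "ContinuousRecording":
        return ContinuousRecording(self.samples.copy(), self.fs, self.t0)

    def sample_index(self, t: float) -> int:
        """Nearest sample index for time ``t`` (seconds)."""
        return int(round((t - self.t0) * self.fs))

    # ------------------------------------------------------------------ I/O
    def to_hdf5(self, path) -> None:
        """Write to HDF5: dataset ``/signal`` with attrs ``fs`` and ``t0``."""
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("signal", data=self.samples)
            ds.attrs["fs"] = self.fs
            ds.attrs["t0"] = self.t0

    @classmethod
    def from_hdf5(cls, path) -> "ContinuousRecording":
        with h5py.File(path, "r") as f:
            ds = f["signal"]
            return cls(ds[...], float(ds.attrs["fs"]), float(ds.attrs["t0"]))


@dataclass
class WaveformKernel:
    """Waveform indexed by lag relative to a locking event.

    ``lags`` must be a uniform grid whose spacing equals ``1/fs`` of the
    recording it will be placed into; ``lags[0]`` may be negative (activity
    preceding the locking event).
    """

    lags: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.shape != self.values.shape or self.lags.ndim != 1:
            raise ValueError("lags and values must be matching 1-d arrays")
        if self.lags.size >= 2:
            steps = np.diff(self.lags)
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
                raise ValueError("lag grid must be uniform")

    @property
    def fs(self) -> float:
        if self.lags.size < 2:
            raise ValueError("kernel with fewer than 2 samples has no rate")
        return 1.0 / (self.lags[1] - self.lags[0])

    @property
    def lag0_index(self) -> int:
        """Index of the sample at (or nearest to) lag zero."""
        return int(np.argmin(np.abs(self.lags)))

    @property
    def peak(self) -> float:
        return float(np.max(np.abs(self.values)))

    def value_at(self, lag: float) -> float:
        """Linearly interpolated value; zero outside the support."""
        return float(np.interp(lag, self.lags, self.values, left=0.0, right=0.0))


def hann_bump_kernel(
    peak_time: float,
    width: float,
    amplitude: float,
    fs: float,
) -> WaveformKernel:
    """Smooth unimodal bump: a raised-cosine (Hann) lobe.

    The bump is ``amplitude`` at ``peak_time`` and exactly zero outside
    ``[peak_time - width/2, peak_time + width/2]``, so its support is compact
    and can be placed wholly inside a deconvolution time-expansion window.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    half = width / 2.0
    # snap support edges onto the fs grid
    i0 = int(np.floor((peak_time - half) * fs))
    i1 = int(np.ceil((peak_time + half) * fs))
    lags = np.arange(i0, i1 + 1) / fs
    x = (lags - peak_time) / half  # in [-1, 1] over the support
    values = np.where(np.abs(x) <= 1.0, amplitude * 0.5 * (1.0 + np.cos(np.pi * x)), 0.0)
    return WaveformKernel(lags, values)
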