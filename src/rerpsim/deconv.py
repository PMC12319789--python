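"""Linear overlap correction (deconvolution) with time-expanded FIR designs.

The continuous recording is modelled as the superposition of event-locked
kernels: for every event type (stimulus, response) and every lag in its
time-expansion window there is one indicator column that is 1 at sample
``event + lag`` and 0 elsewhere (FIR / "stick" basis, one free coefficient
per lag sample, no smoothness assumption).  All kernels are estimated
jointly by ordinary least squares over the whole recording, which is what
disentangles overlapping stimulus- and response-locked activity — provided
the ground truth really is a sum of time-invariant event-locked components.

Predictors can be pooled across trials or split by RT category (separate
indicator columns per category, so each category's kernel is read directly
off the betas with no reference level).

The solver forms the compact Gram matrix ``X^T X`` (a few hundred columns at
most for these designs) and solves the normal equations by Cholesky
factorization; rank deficiency (e.g. insufficient RT jitter making stimulus
and response columns collinear) is detected from the Gram condition number
and reported with the most-implicated predictor pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp

from .events import FAST, SLOW, EventTable
from .recording import ContinuousRecording, WaveformKernel

__all__ = [
    "PredictorSpec",
    "DesignSpec",
    "ColumnGroup",
    "TimeExpandedDesign",
    "KernelEstimate",
    "RankDeficientDesignError",
    "build_design",
    "fit",
    "predict_component",
    "subtract_component",
    "residual_fraction",
]

POOLED = "pooled"
BY_RT_CATEGORY = "by_rt_category"


class RankDeficientDesignError(np.linalg.LinAlgError):
    pass


@dataclass(frozen=True)
class PredictorSpec:
    """Time-expansion window and coding scheme for one event type.

    ``window`` is (lag_min, lag_max) in seconds relative to the event;
    ``scheme`` is ``"pooled"`` (one kernel) or ``"by_rt_category"`` (one
    kernel per fast/slow RT category).
    """

    window: tuple[float, float]
    scheme: str = POOLED

    def __post_init__(self) -> None:
        lo, hi = self.window
        if hi <= lo:
            raise ValueError("time-expansion window must be non-empty")
        if self.scheme not in (POOLED, BY_RT_CATEGORY):
            raise ValueError(f"unknown predictor scheme {self.scheme!r}")


@dataclass(frozen=True)
class DesignSpec:
    """Full regression structure: one :class:`PredictorSpec` per event type."""

    stimulus: PredictorSpec = field(
        default_factory=lambda: PredictorSpec(window=(-0.2, 1.0))
    )
    response: PredictorSpec = field(
        default_factory=lambda: PredictorSpec(window=(-0.8, 0.2))
    )
    fs: float = 100.0
    add_intercept: bool = False


@dataclass
class ColumnGroup:
    """A contiguous block of design columns: one (event type, category) kernel."""

    name: str  # e.g. "stimulus", "response:fast", "intercept"
    event_type: str  # "stimulus" | "response" | "intercept"
    category: str | None
    lags: np.ndarray  # seconds, empty for intercept
    start: int  # first column index
    n_cols: int

    @property
    def stop(self) -> int:
        return self.start + self.n_cols


@dataclass
class TimeExpandedDesign:
    """Sparse indicator design: rows = recording samples, columns = (predictor,
    lag) pairs, with the map back to (event type, category, lag)."""

    matrix: sp.csc_matrix
    groups: list[ColumnGroup]
    spec: DesignSpec

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    def group(self, name: str) -> ColumnGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(f"no predictor named {name!r}")

    def column_names(self) -> list[str]:
        return [g.name for g in self.groups]


def _event_samples(events: EventTable, event_type: str, fs: float) -> np.ndarray:
    onsets = events.stim_onset if event_type == "stimulus" else events.resp_onset
    return np.round(onsets * fs).astype(int)


def _groups_for(spec: DesignSpec, events: EventTable) -> list[tuple[str, str, str | None]]:
    """Expand the spec into (name, event_type, category) triples."""
    out: list[tuple[str, str, str | None]] = []
    for event_type, pspec in (("stimulus", spec.stimulus), ("response", spec.response)):
        if pspec is None:
            continue
        if pspec.scheme == POOLED:
            out.append((event_type, event_type, None))
        else:
            if not events.has_categories:
                raise ValueError(
                    f"{event_type} uses by_rt_category but RT categories are unassigned"
                )
            for cat in (FAST, SLOW):
                out.append((f"{event_type}:{cat}", event_type, cat))
    return out


def build_design(
    events: EventTable, spec: DesignSpec, n_samples: int
) -> TimeExpandedDesign:
    """Construct the sparse time-expanded indicator matrix.

    Column (p, lag) is 1 at sample s iff an event of predictor p occurred at
    sample s - lag.  Raises if any event's window extends beyond the
    recording.
    """
    fs = spec.fs
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    groups: list[ColumnGroup] = []
    col0 = 0
    for name, event_type, category in _groups_for(spec, events):
        pspec = getattr(spec, event_type)
        lo = int(round(pspec.window[0] * fs))
        hi = int(round(pspec.window[1] * fs))
        lag_idx = np.arange(lo, hi + 1)
        ev = _event_samples(events, event_type, fs)
        if category is not None:
            ev = ev[events.trials_in(category)]
        r = (ev[:, None] + lag_idx[None, :]).ravel()
        if r.size and (r.min() < 0 or r.max() >= n_samples):
            raise ValueError(
                f"time-expansion window of {name!r} extends beyond the recording"
            )
        c = col0 + np.tile(np.arange(lag_idx.size), ev.size)
        rows.append(r)
        cols.append(c)
        groups.append(
            ColumnGroup(name, event_type, category, lag_idx / fs, col0, lag_idx.size)
        )
        col0 += lag_idx.size
    if spec.add_intercept:
        rows.append(np.arange(n_samples))
        cols.append(np.full(n_samples, col0))
        groups.append(
            ColumnGroup("intercept", "intercept", None, np.empty(0), col0, 1)
        )
        col0 += 1
    if col0 == 0:
        raise ValueError("design has no predictors")
    data = np.ones(sum(r.size for r in rows))
    matrix = sp.coo_matrix(
        (data, (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_samples, col0),
    ).tocsc()
    return TimeExpandedDesign(matrix=matrix, groups=groups, spec=spec)


@dataclass
class KernelEstimate:
    """Fitted deconvolution betas plus diagnostics.

    ``kernels`` maps predictor name to its estimated lag-indexed waveform.
    The full residual trace is stored so that the diagnostics are
    recomputable.
    """

    kernels: dict[str, WaveformKernel]
    betas: np.ndarray
    design: TimeExpandedDesign
    residual: np.ndarray
    gram_condition: float

    @property
    def residual_variance(self) -> float:
        return float(np.var(self.residual))

    @property
    def fraction_variance_explained(self) -> float:
        total = self.residual + self.design.matrix @ self.betas
        return 1.0 - self.residual_variance / float(np.var(total))

    def kernel(self, name: str) -> WaveformKernel:
        return self.kernels[name]

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: predictor, category, lag_s, beta."""
        recs = []
        for g in self.design.groups:
            if g.event_type == "intercept":
                continue
            k = self.kernels[g.name]
            for lag, beta in zip(k.lags, k.values):
                recs.append((g.event_type, g.category or POOLED, lag, beta))
        return pd.DataFrame(recs, columns=["predictor", "category", "lag_s", "beta"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            grp = f.create_group("kernels")
            for name, k in self.kernels.items():
                ds = grp.create_dataset(name.replace("/", "_"), data=k.values)
                ds.attrs["lag_min"] = k.lags[0] if k.lags.size else 0.0
                ds.attrs["lag_max"] = k.lags[-1] if k.lags.size else 0.0
                ds.attrs["fs"] = self.design.spec.fs


def _name_collinear_pair(G: np.ndarray, groups: list[ColumnGroup]) -> str:
    w, v = np.linalg.eigh(G)
    weights = np.abs(v[:, 0])  # eigenvector of the smallest eigenvalue
    per_group = [
        (float(weights[g.start : g.stop].sum()), g.name) for g in groups
    ]
    per_group.sort(reverse=True)
    names = [name for _, name in per_group[:2]]
    return " and ".join(names)


def fit(
    recording: ContinuousRecording,
    design: TimeExpandedDesign,
    cond_limit: float = 1e10,
) -> KernelEstimate:
    """Jointly estimate all kernels by ordinary least squares.

    Minimizes the summed squared residual over the entire recording; all
    predictors (stimulus- and response-locked, all categories) are solved
    simultaneously, never sequentially.  Raises
    :class:`RankDeficientDesignError` when the Gram matrix is (near-)singular
    — typically from too little RT jitter, which makes stimulus- and
    response-locked columns indistinguishable.
    """
    X = design.matrix
    if X.shape[0] != recording.n_samples:
        raise ValueError("design and recording lengths differ")
    y = recording.samples
    G = np.asarray((X.T @ X).todense())
    xty = X.T @ y
    cond = float(np.linalg.cond(G))
    if not np.isfinite(cond) or cond > cond_limit:
        raise RankDeficientDesignError(
            f"design is rank deficient or ill-conditioned (cond~{cond:.3g}); "
            f"most collinear predictors: {_name_collinear_pair(G, design.groups)}"
        )
    try:
        c, low = scipy.linalg.cho_factor(G)
        betas = scipy.linalg.cho_solve((c, low), xty)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - cond gate first
        raise RankDeficientDesignError(str(exc)) from exc
    residual = y - X @ betas
    kernels = {
        g.name: WaveformKernel(g.lags, betas[g.start : g.stop])
        for g in design.groups
        if g.event_type != "intercept"
    }
    return KernelEstimate(
        kernels=kernels,
        betas=betas,
        design=design,
        residual=residual,
        gram_condition=cond,
    )


def _select_columns(design: TimeExpandedDesign, which) -> np.ndarray:
    """Boolean mask over design columns for a predictor selection.

    ``which`` may be "all", "none", an event-type name ("stimulus",
    "response"), a full group name ("response:fast"), or an iterable of
    names.
    """
    mask = np.zeros(design.n_cols, dtype=bool)
    if which == "all":
        mask[:] = True
        return mask
    if which == "none" or which is None:
        return mask
    names = [which] if isinstance(which, str) else list(which)
    for name in names:
        hits = [
            g for g in design.groups if g.name == name or g.event_type == name
        ]
        if not hits:
            raise KeyError(f"unknown predictor {name!r}")
        for g in hits:
            mask[g.start : g.stop] = True
    return mask


def predict_component(
    estimate: KernelEstimate,
    events: EventTable | None = None,
    which="all",
) -> ContinuousRecording:
    """Continuous modelled contribution of a subset of predictors.

    With the fitting events (the default), this is simply the selected design
    columns times their betas; passing a different event table re-expands the
    design at the new event times (same windows and betas).
    """
    design = estimate.design
    if events is not None:
        design = build_design(events, design.spec, design.n_samples)
    mask = _select_columns(design, which)
    b = np.where(mask, estimate.betas, 0.0)
    return ContinuousRecording(design.matrix @ b, design.spec.fs)


def subtract_component(
    recording: ContinuousRecording, component: ContinuousRecording
) -> ContinuousRecording:
    """Pointwise removal of a modelled component from the recording."""
    if recording.n_samples != component.n_samples or recording.fs != component.fs:
        raise ValueError("recording and component shapes/rates differ")
    return ContinuousRecording(
        recording.samples - component.samples, recording.fs, recording.t0
    )


def residual_fraction(
    recording: ContinuousRecording, estimate: KernelEstimate
) -> float:
    """Residual variance as a fraction of the recording variance."""
    total = float(np.var(recording.samples))
    if total == 0:
        raise ValueError("recording has zero variance")
    return float(np.var(estimate.residual)) / total
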