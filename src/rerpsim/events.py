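"""Per-trial event tables: stimulus onsets, response onsets, RTs, RT split.

The event table is the temporal skeleton shared by simulation, deconvolution
design construction and epoching.  It round-trips through a BIDS-style
``events.tsv`` (columns: onset, duration, trial_type, response_time).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EventTable", "assign_rt_categories"]

UNASSIGNED = "unassigned"
FAST = "fast"
SLOW = "slow"


@dataclass
class EventTable:
    """Stimulus onset, response onset and RT per trial, in seconds.

    Invariants: ``resp_onset > stim_onset`` for every trial, and trials are
    sorted by (non-decreasing) stimulus onset.
    """

    stim_onset: np.ndarray
    resp_onset: np.ndarray
    rt_category: np.ndarray = field(default=None)  # type: ignore[assignment]
    trial_id: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.stim_onset = np.asarray(self.stim_onset, dtype=float)
        self.resp_onset = np.asarray(self.resp_onset, dtype=float)
        if self.stim_onset.shape != self.resp_onset.shape:
            raise ValueError("stim_onset and resp_onset must have equal length")
        if np.any(self.resp_onset <= self.stim_onset):
            raise ValueError("every response must follow its stimulus (rt > 0)")
        if np.any(np.diff(self.stim_onset) < 0):
            raise ValueError("trials must be sorted by stimulus onset")
        if self.trial_id is None:
            self.trial_id = np.arange(self.n_trials)
        else:
            self.trial_id = np.asarray(self.trial_id)
        if self.rt_category is None:
            self.rt_category = np.full(self.n_trials, UNASSIGNED, dtype=object)
        else:
            self.rt_category = np.asarray(self.rt_category, dtype=object)
            bad = set(self.rt_category) - {FAST, SLOW, UNASSIGNED}
            if bad:
                raise ValueError(f"unknown rt categories: {sorted(bad)}")

    @property
    def n_trials(self) -> int:
        return self.stim_onset.size

    @property
    def rt(self) -> np.ndarray:
        return self.resp_onset - self.stim_onset

    @property
    def has_categories(self) -> bool:
        return bool(np.all(self.rt_category != UNASSIGNED)) and self.n_trials > 0

    def trials_in(self, category: str) -> np.ndarray:
        """Boolean mask of trials in ``category``."""
        return self.rt_category == category

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        """BIDS-style events table: one row per trial, stimulus-onset keyed."""
        return pd.DataFrame(
            {
                "onset": self.stim_onset,
                "duration": np.zeros(self.n_trials),
                "trial_type": self.rt_category,
                "response_time": self.rt,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path) -> "EventTable":
        df = pd.read_csv(path, sep="\t")
        stim = df["onset"].to_numpy(dtype=float)
        rt = df["response_time"].to_numpy(dtype=float)
        cat = df["trial_type"].astype(str).to_numpy(dtype=object)
        cat = np.where(np.isin(cat, [FAST, SLOW]), cat, UNASSIGNED)
        return cls(stim_onset=stim, resp_onset=stim + rt, rt_category=cat)


def assign_rt_categories(events: EventTable) -> EventTable:
    """Median split of trials into fast/slow RT categories.

    Trials with RT below the median are ``fast``, above are ``slow``; a trial
    exactly at the median is assigned ``fast`` (fixed tie rule).  Raises if
    fewer than 2 trials or if the split would leave a category empty (all RTs
    identical).
    """
    if events.n_trials < 2:
        raise ValueError("median split needs at least 2 trials")
    rt = events.rt
    med = float(np.median(rt))
    cat = np.where(rt <= med, FAST, SLOW).astype(object)
    if not (np.any(cat == FAST) and np.any(cat == SLOW)):
        raise ValueError("degenerate RT distribution: one split category is empty")
    return EventTable(
        stim_onset=events.stim_onset.copy(),
        resp_onset=events.resp_onset.copy(),
        rt_category=cat,
        trial_id=events.trial_id.copy(),
    )
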