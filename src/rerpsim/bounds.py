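"""Decision-bound functions for the accumulation-to-bound simulators.

Two families: a constant bound, and an exponentially collapsing bound

    bound(t) = b_asym + (b0 - b_asym) * exp(-t / tau)

which is strictly decreasing in t and stays above ``b_asym > 0``, so later
responses terminate at lower accumulator values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BoundFunction", "constant_bound", "collapsing_bound"]


@dataclass(frozen=True)
class BoundFunction:
    """Decision bound as a function of time within the trial.

    kind
        ``"constant"`` or ``"collapsing"``.
    b0
        Bound value at t = 0.
    b_asym
        Asymptotic bound for the collapsing family (ignored for constant).
    tau
        Collapse time constant in seconds (collapsing only).
    """

    kind: str
    b0: float
    b_asym: float = 0.0
    tau: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "collapsing"):
            raise ValueError(f"unknown bound kind {self.kind!r}")
        if self.b0 <= 0:
            raise ValueError("b0 must be positive")
        if self.kind == "collapsing":
            if self.tau <= 0:
                raise ValueError("collapse time constant must be positive")
            if not 0 < self.b_asym < self.b0:
                raise ValueError("collapsing bound needs 0 < b_asym < b0")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.kind == "constant":
            out = np.full_like(t, self.b0)
        else:
            out = self.b_asym + (self.b0 - self.b_asym) * np.exp(-t / self.tau)
        return out if out.ndim else float(out)

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "b0": self.b0}
        if self.kind == "collapsing":
            d.update(b_asym=self.b_asym, tau=self.tau)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BoundFunction":
        return cls(**d)


def constant_bound(b0: float) -> BoundFunction:
    return BoundFunction(kind="constant", b0=b0)


def collapsing_bound(b0: float, b_asym: float, tau: float) -> BoundFunction:
    return BoundFunction(kind="collapsing", b0=b0, b_asym=b_asym, tau=tau)
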