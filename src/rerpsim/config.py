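"""Scenario configurations: the full parameterization of one ground-truth world.

A :class:`ScenarioConfig` pins down everything a simulation run needs —
scenario family, trial count, RT and inter-trial-interval distributions,
component kernels or accumulator parameters, sensor noise, sampling rate and
seed — and round-trips through YAML so every run can emit its resolved
configuration alongside its outputs.

Three scenario families:

``SR``
    Timescale-invariant stimulus-locked (S) and response-locked (R) component
    kernels, identical on every trial; all apparent RT effects in averaged
    waveforms arise from RT-dependent overlap.  This world satisfies the
    assumptions of linear overlap correction exactly.
``RAMP``
    No S or R components; a single accumulation-to-bound ramp interposed
    between stimulus and response, terminating on a (possibly collapsing)
    bound.  Its timescale stretches with RT, violating the time-invariance
    assumption.
``DDM``
    A diffusion-type accumulator (Euler–Maruyama) with separately jittered
    pre-accumulation (encoding) and post-accumulation (motor) delays; RT is an
    emergent first-passage time rather than a sampled quantity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .bounds import BoundFunction, collapsing_bound

__all__ = [
    "RTDistribution",
    "ITIDistribution",
    "DelayDistribution",
    "KernelSpec",
    "DDMParams",
    "ScenarioConfig",
    "default_sr_config",
    "default_ramp_config",
    "default_ddm_config",
]


@dataclass(frozen=True)
class RTDistribution:
    """Shifted lognormal RT distribution.

    RT = shift + LogNormal(log(median - shift), sigma_log); the shift plays
    the role of a minimal non-decision time and guarantees a positive support
    floor.  Defaults give a realistic right-skewed distribution with median
    0.8 s and well separated 10th/90th percentiles.
    """

    shift: float = 0.2
    median: float = 0.8
    sigma_log: float = 0.35

    def __post_init__(self) -> None:
        if self.shift < 0 or self.median <= self.shift:
            raise ValueError("need 0 <= shift < median (positive RT support)")
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be non-negative")

    def quantile(self, q):
        """Closed-form quantile of the shifted lognormal."""
        import numpy as np
        from scipy.stats import norm

        scale = self.median - self.shift
        return self.shift + scale * np.exp(self.sigma_log * norm.ppf(q))


@dataclass(frozen=True)
class ITIDistribution:
    """Uniform interval (seconds) between a response and the next stimulus."""

    low: float = 1.5
    high: float = 2.5

    def __post_init__(self) -> None:
        if not 0 < self.low <= self.high:
            raise ValueError("need 0 < low <= high")


@dataclass(frozen=True)
class DelayDistribution:
    """Non-decision delay: normal(mean, sd) truncated below at ``lower``.

    ``sd = 0`` degenerates to the constant ``mean``.
    """

    mean: float
    sd: float = 0.0
    lower: float = 0.0

    def __post_init__(self) -> None:
        if self.mean < self.lower:
            raise ValueError("mean must be >= lower truncation point")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class KernelSpec:
    """Parametric shape of a ground-truth component kernel (Hann bump)."""

    peak_time: float
    width: float
    amplitude: float


@dataclass(frozen=True)
class DDMParams:
    """Single-bound drift-diffusion parameters.

    Euler–Maruyama integration at step ``dt`` (seconds); a trial whose
    accumulator has not crossed the bound by ``max_decision_time`` is redrawn,
    up to ``max_resamples`` attempts.
    """

    drift: float = 1.0
    noise_sd: float = 0.3
    dt: float = 0.001
    pre_ea_delay: DelayDistribution = field(
        default_factory=lambda: DelayDistribution(mean=0.2, sd=0.035)
    )
    post_ea_delay: DelayDistribution = field(
        default_factory=lambda: DelayDistribution(mean=0.15, sd=0.035)
    )
    max_decision_time: float = 4.0
    max_resamples: int = 50

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


_SCENARIOS = ("SR", "RAMP", "DDM")


@dataclass(frozen=True)
class ScenarioConfig:
    scenario: str = "SR"
    n_trials: int = 500
    fs: float = 100.0
    seed: int = 0
    rt_distribution: RTDistribution = field(default_factory=RTDistribution)
    iti_distribution: ITIDistribution = field(default_factory=ITIDistribution)
    # SR world
    s_kernel: KernelSpec = field(
        default_factory=lambda: KernelSpec(peak_time=0.3, width=0.6, amplitude=1.0)
    )
    r_kernel: KernelSpec = field(
        default_factory=lambda: KernelSpec(peak_time=-0.1, width=0.6, amplitude=1.5)
    )
    # RAMP world
    ramp_onset_delay: float = 0.1
    post_response_decay: float = 0.1
    bound: BoundFunction = field(
        default_factory=lambda: collapsing_bound(b0=1.0, b_asym=0.3, tau=0.6)
    )
    # DDM world
    ddm: DDMParams = field(default_factory=DDMParams)
    sensor_noise_sd: float = 0.0
    # recording padding before the first stimulus / after the last response
    pad: float = 2.0

    def __post_init__(self) -> None:
        if self.scenario not in _SCENARIOS:
            raise ValueError(f"scenario must be one of {_SCENARIOS}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.sensor_noise_sd < 0:
            raise ValueError("sensor_noise_sd must be non-negative")
        if self.scenario == "RAMP" and self.ramp_onset_delay < 0:
            raise ValueError("ramp_onset_delay must be non-negative")
        if self.scenario == "DDM" and self.ddm.dt > 1.0 / self.fs + 1e-12:
            raise ValueError("DDM integration step must not exceed 1/fs")

    def replace(self, **kw) -> "ScenarioConfig":
        return dataclasses.replace(self, **kw)

    # ------------------------------------------------------------------ YAML
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bound"] = self.bound.to_dict()
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "bound" in d:
            d["bound"] = BoundFunction.from_dict(d["bound"])
        for key, sub in (
            ("rt_distribution", RTDistribution),
            ("iti_distribution", ITIDistribution),
            ("s_kernel", KernelSpec),
            ("r_kernel", KernelSpec),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "ddm" in d and isinstance(d["ddm"], dict):
            dd = dict(d["ddm"])
            for key in ("pre_ea_delay", "post_ea_delay"):
                if key in dd and isinstance(dd[key], dict):
                    dd[key] = DelayDistribution(**dd[key])
            d["ddm"] = DDMParams(**dd)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path_or_text) -> "ScenarioConfig":
        try:
            with open(path_or_text) as f:
                text = f.read()
        except (OSError, TypeError):
            text = path_or_text
        return cls.from_dict(yaml.safe_load(text))


def default_sr_config(seed: int = 0, **kw) -> ScenarioConfig:
    return ScenarioConfig(scenario="SR", seed=seed, **kw)


def default_ramp_config(seed: int = 0, **kw) -> ScenarioConfig:
    return ScenarioConfig(scenario="RAMP", seed=seed, **kw)


def default_ddm_config(seed: int = 0, **kw) -> ScenarioConfig:
    return ScenarioConfig(scenario="DDM", seed=seed, **kw)
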