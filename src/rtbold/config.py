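"""Configuration objects for the simulation and analysis pipeline.

All defaults encode the experimental design being emulated: a multi-source
interference task (MSIT, congruent/incongruent digit arrays) and a simple
reaction-time task, scanned at TR 1.25 s with 297 volumes per run of which
the first five are discarded, 96 trials per run, 500 ms stimuli, and SOAs
drawn from a pseudo-exponential distribution over 2.5-6.25 s.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

MSIT = "msit"
SIMPLE = "simple"

CONGRUENT = "congruent"
INCONGRUENT = "incongruent"
SIMPLE_COND = "simple"

CONDITIONS = (CONGRUENT, INCONGRUENT, SIMPLE_COND)

TIME_ON_TASK = "time_on_task"
CONFLICT_MONITORING = "conflict_monitoring"


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class TaskDesignConfig:
    """Timing layout of one scanning run.

    SOA = stimulus onset asynchrony, the interval between consecutive trial
    onsets.  ``soa_weights`` must be non-increasing (short SOAs favoured,
    the pseudo-exponential convention for event-related jitter).
    """

    task: str = MSIT
    n_runs: int = 4
    n_trials_per_run: int = 96
    stimulus_duration: float = 0.5
    soa_values: tuple[float, ...] = (2.5, 3.75, 5.0, 6.25)
    soa_weights: tuple[float, ...] = (8 / 15, 4 / 15, 2 / 15, 1 / 15)
    tr: float = 1.25
    n_volumes_per_run: int = 297
    n_discard_volumes: int = 5
    congruent_proportion: float = 0.5

    def __post_init__(self) -> None:
        self.soa_values = tuple(float(v) for v in self.soa_values)
        self.soa_weights = tuple(float(w) for w in self.soa_weights)
        validate_soa_weights(self.soa_values, self.soa_weights)
        if self.tr <= 0:
            raise ConfigurationError("tr must be positive")
        if self.n_discard_volumes >= self.n_volumes_per_run:
            raise ConfigurationError("discard period consumes the whole run")
        # the *average* trial time must fit; individual SOA draws are
        # resampled by the design generator if a sequence overflows
        mean_soa = sum(v * w for v, w in zip(self.soa_values, self.soa_weights))
        needed = self.discard_duration + self.n_trials_per_run * mean_soa
        if needed > self.run_duration:
            raise ConfigurationError(
                f"{self.n_trials_per_run} trials at mean SOA {mean_soa:.2f}s "
                f"do not fit in a {self.run_duration:.2f}s run"
            )

    @property
    def run_duration(self) -> float:
        return self.n_volumes_per_run * self.tr

    @property
    def discard_duration(self) -> float:
        return self.n_discard_volumes * self.tr

    @property
    def n_kept_volumes(self) -> int:
        return self.n_volumes_per_run - self.n_discard_volumes


def validate_soa_weights(values: tuple[float, ...], weights: tuple[float, ...]) -> None:
    if len(values) != len(weights):
        raise ConfigurationError("soa_values and soa_weights must have equal length")
    if any(w < 0 for w in weights):
        raise ConfigurationError("soa_weights must be non-negative")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ConfigurationError("soa_weights must sum to 1")
    if any(b > a + 1e-12 for a, b in zip(weights, weights[1:])):
        raise ConfigurationError("soa_weights must be non-increasing (favour short SOAs)")


@dataclass
class ExGaussian:
    """Ex-Gaussian RT distribution: Normal(mu, sigma) + Exponential(tau), ms."""

    mu: float
    sigma: float
    tau: float

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.sigma < 0 or self.tau < 0:
            raise ConfigurationError("ex-Gaussian parameters must be positive")

    @property
    def mean(self) -> float:
        return self.mu + self.tau


@dataclass
class BehaviorConfig:
    """Per-condition RT distributions and accuracies.

    Defaults are calibrated so that condition mean RTs are 661 ms
    (congruent), 858 ms (incongruent) and 376 ms (simple), and accuracies
    99.8 / 98.1 / 98.9 % respectively.  ``subject_shift_sd`` is a shared
    between-subject shift of all condition means; ``condition_shift_sd`` is
    an additional independent per-condition shift (both ms).
    """

    rt: dict[str, ExGaussian] = field(
        default_factory=lambda: {
            CONGRUENT: ExGaussian(mu=551.0, sigma=60.0, tau=110.0),
            INCONGRUENT: ExGaussian(mu=688.0, sigma=80.0, tau=170.0),
            SIMPLE_COND: ExGaussian(mu=316.0, sigma=40.0, tau=60.0),
        }
    )
    accuracy: dict[str, float] = field(
        default_factory=lambda: {CONGRUENT: 0.998, INCONGRUENT: 0.981, SIMPLE_COND: 0.989}
    )
    subject_shift_sd: float = 60.0
    condition_shift_sd: float = 50.0
    rt_floor: float = 100.0

    def __post_init__(self) -> None:
        for cond, p in self.accuracy.items():
            if not 0.0 < p <= 1.0:
                raise ConfigurationError(f"accuracy for {cond} must be in (0, 1]")
        means = {c: d.mean for c, d in self.rt.items()}
        if not means[INCONGRUENT] > means[CONGRUENT] > means[SIMPLE_COND]:
            raise ConfigurationError(
                "default ordering incongruent > congruent > simple mean RT violated"
            )


@dataclass
class GenerativeModelConfig:
    """Per-trial neural amplitude model.

    time_on_task:        amplitude_i = a_cond + b * RT_i           (both tasks)
    conflict_monitoring: amplitude_i = a_cond + c * (RT_i - mean RT of cond)
                         for MSIT trials; amplitude_i = a_simple for simple
                         trials (a one-choice task engenders no response
                         conflict).

    Slopes are in signal units per second of RT.  Between-subject SDs apply
    to ``a`` (all conditions, shared draw), ``b`` and ``c``.
    """

    model: str = TIME_ON_TASK
    baseline: dict[str, float] = field(
        default_factory=lambda: {CONGRUENT: 1.0, INCONGRUENT: 1.0, SIMPLE_COND: 1.0}
    )
    time_on_task_slope: float = 1.0
    conflict_gain: float = 1.0
    baseline_sd: float = 0.25
    slope_sd: float = 0.25
    gain_sd: float = 0.25
    noise_sd: float = 1.0
    ar1_rho: float = 0.3
    drift_amplitude: float = 0.5
    n_units: int = 5
    unit_names: tuple[str, ...] = ("pMFC", "L_IFG", "R_IFG", "L_IPL", "R_IPL")
    miss_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in (TIME_ON_TASK, CONFLICT_MONITORING):
            raise ConfigurationError(f"unknown generative model {self.model!r}")
        if not -1.0 < self.ar1_rho < 1.0:
            raise ConfigurationError("ar1_rho must lie in (-1, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if len(self.unit_names) != self.n_units:
            self.unit_names = tuple(f"unit{i}" for i in range(self.n_units))

    @classmethod
    def time_on_task(cls, **kw: Any) -> "GenerativeModelConfig":
        return cls(model=TIME_ON_TASK, **kw)

    @classmethod
    def conflict_monitoring(cls, **kw: Any) -> "GenerativeModelConfig":
        """Conflict account: the congruency effect is a baseline difference
        (more conflict on incongruent trials) plus within-condition tracking
        of trialwise RT, in the MSIT only."""
        kw.setdefault(
            "baseline", {CONGRUENT: 1.0, INCONGRUENT: 1.2, SIMPLE_COND: 1.0}
        )
        return cls(model=CONFLICT_MONITORING, **kw)


@dataclass
class GLMConfig:
    """First-level model options."""

    highpass_cutoff: float = 128.0
    outlier_sd: float = 3.0
    oversampling: int = 16
    hrf_peak_delay: float = 6.0
    hrf_undershoot_delay: float = 16.0
    hrf_peak_dispersion: float = 1.0
    hrf_undershoot_dispersion: float = 1.0
    hrf_ratio: float = 6.0
    hrf_length: float = 32.0
    rt_centering: str = "run"  # "run" or "session"
    ar1: bool = True

    def __post_init__(self) -> None:
        if self.rt_centering not in ("run", "session"):
            raise ConfigurationError("rt_centering must be 'run' or 'session'")
        if self.oversampling < 1:
            raise ConfigurationError("oversampling must be >= 1")


@dataclass
class GroupConfig:
    """Group-level thresholding options."""

    q: float = 0.05
    alpha: float = 0.05
    extent_k: int = 20
    connectivity: int = 6


@dataclass
class ExperimentConfig:
    """Everything needed to run a full simulate-fit-equate-group experiment."""

    n_subjects: int = 24
    seed: int = 0
    msit: TaskDesignConfig = field(default_factory=lambda: TaskDesignConfig(task=MSIT, n_runs=4))
    simple: TaskDesignConfig = field(
        default_factory=lambda: TaskDesignConfig(task=SIMPLE, n_runs=2)
    )
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    model: GenerativeModelConfig = field(default_factory=GenerativeModelConfig)
    glm: GLMConfig = field(default_factory=GLMConfig)
    group: GroupConfig = field(default_factory=GroupConfig)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("group inference needs at least 2 subjects")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return _asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ExperimentConfig":
        d = dict(d)
        for key, sub in (
            ("msit", TaskDesignConfig),
            ("simple", TaskDesignConfig),
            ("behavior", BehaviorConfig),
            ("model", GenerativeModelConfig),
            ("glm", GLMConfig),
            ("group", GroupConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = _from_dict(sub, d[key])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(text))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _asdict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _asdict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _asdict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_asdict(v) for v in obj]
    return obj


def _from_dict(cls: type, d: dict[str, Any]) -> Any:
    kwargs = dict(d)
    if cls is BehaviorConfig and "rt" in kwargs:
        kwargs["rt"] = {
            c: v if isinstance(v, ExGaussian) else ExGaussian(**v)
            for c, v in kwargs["rt"].items()
        }
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            try:
                if isinstance(f.default, tuple) or (
                    f.default_factory is not dataclasses.MISSING
                    and isinstance(f.default_factory(), tuple)
                ):
                    kwargs[f.name] = tuple(kwargs[f.name])
            except TypeError:
                pass
    return cls(**kwargs)


def tiny_experiment(seed: int = 0, model: str = TIME_ON_TASK) -> ExperimentConfig:
    """Small configuration for fast end-to-end tests: 4 subjects, 1 run per
    task, 24 trials per run, 80 retained volumes, a single simulated unit."""
    msit = TaskDesignConfig(task=MSIT, n_runs=1, n_trials_per_run=24, n_volumes_per_run=85)
    simple = TaskDesignConfig(task=SIMPLE, n_runs=1, n_trials_per_run=24, n_volumes_per_run=85)
    gen = (
        GenerativeModelConfig.time_on_task(n_units=1, unit_names=("pMFC",))
        if model == TIME_ON_TASK
        else GenerativeModelConfig.conflict_monitoring(n_units=1, unit_names=("pMFC",))
    )
    return ExperimentConfig(n_subjects=4, seed=seed, msit=msit, simple=simple, model=gen)
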