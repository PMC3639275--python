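"""Generative simulator for multi-subject MSIT + simple-RT fMRI experiments.

Two competing accounts of the congruency effect (greater activity on
incongruent than congruent trials) are implemented as per-trial amplitude
models:

* ``time_on_task`` — the underlying process is recruited for as long as the
  trial takes, in any task: ``amplitude = a_cond + b * RT`` (RT in seconds)
  for MSIT and simple-RT trials alike, with one shared slope ``b``.

* ``conflict_monitoring`` — the process detects competition between
  response alternatives, which exists only when more than one response is
  possible: ``amplitude = a_cond + c * (RT - mean RT of the condition)``
  for MSIT trials, and a flat ``a_simple`` for simple-RT trials.

Amplitude-weighted delta functions at trial onsets are convolved with the
canonical double-gamma HRF, sampled at the TR, and corrupted with slow
drift plus AR(1) Gaussian noise.  The generator emulates post-preprocessing
data: no motion corruption, slice-timing or physiological artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import (
    CONFLICT_MONITORING,
    CONGRUENT,
    INCONGRUENT,
    MSIT,
    SIMPLE,
    SIMPLE_COND,
    TIME_ON_TASK,
    BehaviorConfig,
    ConfigurationError,
    ExperimentConfig,
    GenerativeModelConfig,
    TaskDesignConfig,
    validate_soa_weights,
)
from .hrf import canonical_hrf

EVENT_COLUMNS = ["run_index", "task", "onset", "condition", "rt_ms", "correct", "excluded_as"]


class DataError(ValueError):
    """Raised when event data violate a precondition."""


@dataclass
class SubjectDataset:
    """All runs of one (simulated) subject.

    ``events`` uses scanner-referenced onsets (seconds from the start of
    volume acquisition; the discard period occupies the first
    ``n_discard_volumes * tr`` seconds and contains no trials).
    ``timeseries[run]`` holds only the retained volumes, shape
    (n_units, n_kept_volumes).  ``truth`` records the subject-level
    generative parameters actually drawn.
    """

    subject_id: str
    events: pd.DataFrame
    timeseries: dict[int, np.ndarray] = field(default_factory=dict)
    motion: dict[int, np.ndarray] = field(default_factory=dict)
    truth: dict[str, Any] = field(default_factory=dict)
    unit_names: tuple[str, ...] = ()
    run_tasks: dict[int, str] = field(default_factory=dict)


def _rng(seed: int | np.random.Generator | np.random.SeedSequence) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# design


def sample_soas(
    n: int,
    cfg: TaskDesignConfig,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` stimulus onset asynchronies (seconds) from the configured
    pseudo-exponential distribution (discrete support, halving weights)."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    validate_soa_weights(cfg.soa_values, cfg.soa_weights)
    rng = _rng(seed)
    return rng.choice(np.asarray(cfg.soa_values), size=n, p=np.asarray(cfg.soa_weights))


_MAX_DESIGN_ATTEMPTS = 200


def generate_run_design(
    task: str,
    run_index: int,
    cfg: TaskDesignConfig,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Lay out one run: onsets from cumulative SOAs, conditions assigned.

    Onsets are scanner-referenced; the first trial lands at
    ``discard_duration + SOA_0`` so that no trial occurs during the
    discarded volumes.  SOA sequences whose cumulative sum overflows the
    run are redrawn (the discrete SOA distribution has positive overflow
    probability at 96 trials); a configuration that can never fit raises.
    """
    rng = _rng(seed)
    n = cfg.n_trials_per_run
    onsets = None
    for _ in range(_MAX_DESIGN_ATTEMPTS):
        soas = sample_soas(n, cfg, rng)
        candidate = cfg.discard_duration + np.cumsum(soas)
        if candidate[-1] + cfg.stimulus_duration <= cfg.run_duration:
            onsets = candidate
            break
    if onsets is None:
        raise ConfigurationError(
            f"could not fit {n} trials into a {cfg.run_duration:.1f}s run"
        )

    if task == MSIT:
        n_cong = int(round(n * cfg.congruent_proportion))
        conditions = np.array([CONGRUENT] * n_cong + [INCONGRUENT] * (n - n_cong))
        rng.shuffle(conditions)
    elif task == SIMPLE:
        conditions = np.array([SIMPLE_COND] * n)
    else:
        raise ConfigurationError(f"unknown task {task!r}")

    return pd.DataFrame(
        {
            "run_index": run_index,
            "task": task,
            "onset": onsets,
            "condition": conditions,
            "rt_ms": np.nan,
            "correct": pd.array([pd.NA] * n, dtype="boolean"),
            "excluded_as": "none",
        }
    )


# ---------------------------------------------------------------------------
# behaviour


def sample_behavior(
    events: pd.DataFrame,
    cfg: BehaviorConfig,
    subject_params: dict[str, Any] | None,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Fill ``rt_ms`` and ``correct`` for every trial.

    RTs are ex-Gaussian per condition, with the subject's shared and
    per-condition mean shifts added to ``mu``.  Correctness is Bernoulli
    per condition.  An incorrect simple-RT trial is a miss (the subject
    failed to respond): its RT is missing.  Incorrect MSIT trials are
    committed errors and keep their RT.
    """
    rng = _rng(seed)
    subject_params = subject_params or {}
    shared = float(subject_params.get("rt_shift", 0.0))
    cond_shift = subject_params.get("rt_cond_shift", {})

    out = events.copy()
    rts = np.full(len(out), np.nan)
    correct = np.zeros(len(out), dtype=bool)
    for cond, dist in cfg.rt.items():
        mask = (out["condition"] == cond).to_numpy()
        k = int(mask.sum())
        if k == 0:
            continue
        mu = dist.mu + shared + float(cond_shift.get(cond, 0.0))
        draw = rng.normal(mu, dist.sigma, size=k) if dist.sigma > 0 else np.full(k, mu)
        if dist.tau > 0:
            draw = draw + rng.exponential(dist.tau, size=k)
        if dist.sigma > 0 or dist.tau > 0:
            draw = np.maximum(draw, cfg.rt_floor)
        rts[mask] = draw
        correct[mask] = rng.random(k) < cfg.accuracy[cond]

    miss = (~correct) & (out["condition"] == SIMPLE_COND).to_numpy()
    rts[miss] = np.nan
    out["rt_ms"] = rts
    out["correct"] = pd.array(correct, dtype="boolean")
    return out


# ---------------------------------------------------------------------------
# neural amplitudes


def neural_amplitudes(
    events: pd.DataFrame,
    model_cfg: GenerativeModelConfig,
    subject_params: dict[str, Any] | None = None,
) -> np.ndarray:
    """Per-trial neural amplitude (signal units) under the configured model.

    Under ``conflict_monitoring`` the conflict term is the within-condition
    RT deviation, computed over all responded trials of that condition in
    the events passed (pool a subject's runs before calling for
    subject-level centering).  Miss trials get ``miss_amplitude``.
    """
    subject_params = subject_params or {}
    baseline = subject_params.get("baseline", model_cfg.baseline)
    b = float(subject_params.get("slope_b", model_cfg.time_on_task_slope))
    c = float(subject_params.get("gain_c", model_cfg.conflict_gain))

    rt_s = events["rt_ms"].to_numpy(dtype=float) / 1000.0  # ms -> s, once
    miss = np.isnan(rt_s)
    bad = miss & (events["condition"] != SIMPLE_COND).to_numpy()
    bad |= miss & events["correct"].fillna(True).to_numpy(dtype=bool)
    if bad.any():
        raise DataError("missing RT on a non-miss trial")

    amp = np.empty(len(events))
    cond = events["condition"].to_numpy()
    for cname in np.unique(cond):
        m = cond == cname
        a = float(baseline[cname])
        if model_cfg.model == TIME_ON_TASK:
            amp[m] = a + b * rt_s[m]
        elif cname == SIMPLE_COND:  # conflict monitoring, one-choice task
            amp[m] = a
        else:
            centred = rt_s[m] - np.nanmean(rt_s[m])
            amp[m] = a + c * centred
    amp[miss] = model_cfg.miss_amplitude
    return amp


# ---------------------------------------------------------------------------
# BOLD forward model


def neural_to_bold(
    onsets: np.ndarray,
    amplitudes: np.ndarray,
    cfg: TaskDesignConfig,
    oversampling: int = 16,
) -> np.ndarray:
    """Noise-free BOLD: amplitude-scaled deltas at the onsets on a fine time
    grid, convolved with the canonical HRF, sampled at volume times.
    Returns the full run (discarded volumes included)."""
    dt = cfg.tr / oversampling
    n_fine = cfg.n_volumes_per_run * oversampling
    sticks = np.zeros(n_fine)
    bins = np.round(np.asarray(onsets) / dt).astype(int)
    if np.any(bins < 0) or np.any(bins >= n_fine):
        raise DataError("trial onset outside the run")
    np.add.at(sticks, bins, np.asarray(amplitudes, dtype=float))
    kernel = canonical_hrf(cfg.tr, oversampling)
    fine = sps.fftconvolve(sticks, kernel)[:n_fine]
    return fine[:: oversampling]


def simulate_bold(
    events: pd.DataFrame,
    amplitudes: np.ndarray,
    model_cfg: GenerativeModelConfig,
    cfg: TaskDesignConfig,
    seed: int | np.random.Generator,
    oversampling: int = 16,
) -> np.ndarray:
    """One run's time series, shape (n_units, n_kept_volumes).

    signal (shared across units) + slow drift + AR(1) Gaussian noise
    (independent per unit, stationary marginal SD ``noise_sd``); the first
    ``n_discard_volumes`` volumes are dropped.
    """
    rng = _rng(seed)
    clean = neural_to_bold(
        events["onset"].to_numpy(), amplitudes, cfg, oversampling=oversampling
    )
    n_vol, n_units = cfg.n_volumes_per_run, model_cfg.n_units
    t = np.arange(n_vol) * cfg.tr

    series = np.tile(clean, (n_units, 1))
    if model_cfg.drift_amplitude > 0:
        for _ in range(2):  # two slow cosines, periods >= run duration
            period = cfg.run_duration * rng.uniform(1.0, 4.0)
            phase = rng.uniform(0, 2 * np.pi, size=n_units)
            series += (model_cfg.drift_amplitude / 2) * np.cos(
                2 * np.pi * t / period + phase[:, None]
            )
    if model_cfg.noise_sd > 0:
        rho = model_cfg.ar1_rho
        innov = rng.normal(0.0, model_cfg.noise_sd * np.sqrt(1 - rho**2), (n_units, n_vol))
        if rho != 0.0:
            x0 = rng.normal(0.0, model_cfg.noise_sd, n_units)
            noise = sps.lfilter([1.0], [1.0, -rho], innov, axis=1, zi=(rho * x0)[:, None])[0]
        else:
            noise = innov
        series += noise
    return series[:, cfg.n_discard_volumes :]


def simulate_motion(
    n_volumes: int,
    seed: int | np.random.Generator,
    scale: float = 0.05,
    smooth: int = 8,
) -> np.ndarray:
    """Six smooth, bounded random-walk motion traces (volumes x 6).

    Purely exercises the nuisance-regression code path; carries no signal.
    """
    rng = _rng(seed)
    steps = rng.normal(0.0, scale, size=(n_volumes + smooth, 6))
    walk = np.cumsum(steps, axis=0)
    kernel = np.hanning(smooth)
    kernel /= kernel.sum()
    smoothed = np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="same"), 0, walk)
    smoothed = smoothed[smooth // 2 : smooth // 2 + n_volumes]
    span = np.abs(smoothed).max(axis=0)
    span[span == 0] = 1.0
    return smoothed / span  # bounded to +-1 (mm / mrad scale)


# ---------------------------------------------------------------------------
# whole datasets


def _draw_subject_params(
    rng: np.random.Generator,
    behavior: BehaviorConfig,
    model: GenerativeModelConfig,
) -> dict[str, Any]:
    shared_baseline_offset = rng.normal(0.0, model.baseline_sd)
    return {
        "rt_shift": rng.normal(0.0, behavior.subject_shift_sd),
        "rt_cond_shift": {
            c: rng.normal(0.0, behavior.condition_shift_sd) for c in behavior.rt
        },
        "baseline": {c: a + shared_baseline_offset for c, a in model.baseline.items()},
        "slope_b": rng.normal(model.time_on_task_slope, model.slope_sd),
        "gain_c": rng.normal(model.conflict_gain, model.gain_sd),
    }


def generate_subject(
    subject_id: str,
    cfg: ExperimentConfig,
    seed: int | np.random.SeedSequence,
    events_only: bool = False,
) -> SubjectDataset:
    """Simulate one subject: 4 MSIT runs then 2 simple-RT runs by default."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    params = _draw_subject_params(rng, cfg.behavior, cfg.model)

    run_specs: list[tuple[str, TaskDesignConfig]] = []
    run_specs += [(MSIT, cfg.msit)] * cfg.msit.n_runs
    run_specs += [(SIMPLE, cfg.simple)] * cfg.simple.n_runs

    frames = []
    for run_index, (task, tcfg) in enumerate(run_specs):
        ev = generate_run_design(task, run_index, tcfg, rng)
        ev = sample_behavior(ev, cfg.behavior, params, rng)
        frames.append(ev)
    events = pd.concat(frames, ignore_index=True)

    ds = SubjectDataset(
        subject_id=subject_id,
        events=events,
        truth={k: v for k, v in params.items()},
        unit_names=cfg.model.unit_names,
        run_tasks={i: task for i, (task, _) in enumerate(run_specs)},
    )
    ds.truth["model"] = cfg.model.model
    if events_only:
        return ds

    # conflict centering is subject-level: pool the task's runs first
    amplitudes = np.empty(len(events))
    for task in (MSIT, SIMPLE):
        m = (events["task"] == task).to_numpy()
        if m.any():
            amplitudes[m] = neural_amplitudes(events.loc[m], cfg.model, params)

    for run_index, (task, tcfg) in enumerate(run_specs):
        m = (events["run_index"] == run_index).to_numpy()
        ds.timeseries[run_index] = simulate_bold(
            events.loc[m], amplitudes[m], cfg.model, tcfg, rng,
            oversampling=cfg.glm.oversampling,
        )
        ds.motion[run_index] = simulate_motion(tcfg.n_kept_volumes, rng)
    return ds


def generate_dataset(
    n_subjects: int | None = None,
    cfg: ExperimentConfig | None = None,
    seed: int | None = None,
    events_only: bool = False,
) -> list[SubjectDataset]:
    """Simulate a full experiment; reproducible from the master seed.

    Per-subject child seeds are spawned deterministically from the master
    seed, so subject k is identical no matter how many subjects are drawn.
    """
    cfg = cfg or ExperimentConfig()
    n = n_subjects if n_subjects is not None else cfg.n_subjects
    if n < 2:
        raise ConfigurationError("group inference needs at least 2 subjects")
    master = np.random.SeedSequence(cfg.seed if seed is None else seed)
    children = master.spawn(n)
    return [
        generate_subject(f"sub-{i + 1:02d}", cfg, child, events_only=events_only)
        for i, child in enumerate(children)
    ]
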