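"""First-level modelling: design matrices with parametric RT modulators,
nuisance blocks, and AR(1)-prewhitened least squares per unit.

The design for each run contains, in order: one condition-mean regressor
per condition present (unit-amplitude onsets of included trials convolved
with the canonical HRF), one parametric RT regressor per condition (the
same onsets weighted by within-condition mean-centered RT in seconds,
convolved) — mean-centering makes the modulator orthogonal to its
condition regressor before convolution — a pooled regressor for excluded
trials (errors, outliers, misses), a 24-column motion expansion, a
discrete-cosine high-pass drift block, and an intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import (
    CONDITIONS,
    MSIT,
    SIMPLE,
    SIMPLE_COND,
    ExperimentConfig,
    GLMConfig,
    TaskDesignConfig,
)
from .equating import ConditionEstimates, condition_mean_rts
from .hrf import canonical_hrf  # noqa: F401  (re-exported: part of this module's surface)

ROLE_CONDITION = "condition_mean"
ROLE_RT = "rt_modulator"
ROLE_EXCLUDED = "nuisance_excluded"
ROLE_MOTION = "motion"
ROLE_DRIFT = "drift"
ROLE_INTERCEPT = "intercept"


class DesignError(ValueError):
    """Raised for invalid or degenerate design matrices."""


# ---------------------------------------------------------------------------
# trial exclusions


@dataclass
class TrialExclusionReport:
    counts: dict[str, int]
    sd_multiplier: float
    condition_stats: dict[str, tuple[float, float]]  # condition -> (mean, SD) used


def mark_exclusions(
    events: pd.DataFrame, sd_multiplier: float = 3.0
) -> tuple[pd.DataFrame, TrialExclusionReport]:
    """Flag misses, errors, then RT outliers; categories are disjoint.

    A miss is a trial without a response (missing RT).  An error is an
    incorrect committed response.  Among the remaining correct, responded
    trials, the per-condition mean and SD are computed once (not
    iteratively) and trials with |RT - mean| > ``sd_multiplier`` * SD are
    outliers.  A condition with fewer than two usable trials has an
    undefined SD: nothing is flagged there, with a warning.
    """
    out = events.copy()
    rt = out["rt_ms"].to_numpy(dtype=float)
    correct = out["correct"].fillna(False).to_numpy(dtype=bool)
    status = np.full(len(out), "none", dtype=object)
    status[np.isnan(rt)] = "miss"
    status[(~correct) & ~np.isnan(rt)] = "error"

    stats: dict[str, tuple[float, float]] = {}
    cond = out["condition"].to_numpy()
    for cname in pd.unique(cond):
        usable = (cond == cname) & (status == "none")
        if usable.sum() < 2:
            warnings.warn(
                f"condition {cname!r} has <2 usable trials; outlier SD undefined",
                stacklevel=2,
            )
            continue
        m, s = rt[usable].mean(), rt[usable].std(ddof=1)
        stats[cname] = (float(m), float(s))
        outlier = usable & (np.abs(rt - m) > sd_multiplier * s)
        status[outlier] = "outlier"

    out["excluded_as"] = status
    counts = {k: int((status == k).sum()) for k in ("error", "outlier", "miss")}
    return out, TrialExclusionReport(counts, sd_multiplier, stats)


def included_mask(events: pd.DataFrame) -> np.ndarray:
    """Correct, responded, non-outlier trials (the analysed trials)."""
    return (events["excluded_as"] == "none").to_numpy()


# ---------------------------------------------------------------------------
# nuisance blocks


def motion_expansion(motion: np.ndarray) -> np.ndarray:
    """24-column motion nuisance block from 6 realignment parameters:
    [linear(6), squared(6), lag-1 shifted(6), squared-of-shifted(6)];
    the shift pads the first row with zeros."""
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise DesignError(f"expected 6 motion columns, got shape {motion.shape}")
    shifted = np.vstack([np.zeros((1, 6)), motion[:-1]])
    return np.hstack([motion, motion**2, shifted, shifted**2])


def dct_highpass_basis(n_volumes: int, tr: float, cutoff: float = 128.0) -> np.ndarray:
    """Orthonormal DCT drift basis: the ``floor(2 * n * tr / cutoff)``
    lowest-frequency discrete cosines (constant excluded; that is the
    intercept's job).  Shape (n_volumes, K)."""
    if n_volumes < 2:
        raise DesignError("need at least 2 volumes")
    k = int(np.floor(2.0 * n_volumes * tr / cutoff))
    t = np.arange(n_volumes)
    cols = [
        np.sqrt(2.0 / n_volumes) * np.cos(np.pi * (2 * t + 1) * j / (2 * n_volumes))
        for j in range(1, k + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_volumes, 0))


# ---------------------------------------------------------------------------
# design matrix


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # volumes x P
    column_names: list[str]
    column_roles: list[str]
    frame_times: np.ndarray  # scanner seconds of the retained volumes

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def index(self, name: str) -> int:
        return self.column_names.index(name)

    def columns_with_role(self, role: str) -> list[str]:
        return [n for n, r in zip(self.column_names, self.column_roles) if r == role]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.frame_times, columns=self.column_names)


def _convolve_sticks(
    onsets: np.ndarray,
    weights: np.ndarray,
    task_cfg: TaskDesignConfig,
    glm_cfg: GLMConfig,
) -> np.ndarray:
    """Weighted deltas on the microtime grid, convolved with the canonical
    HRF, sampled at the retained volumes."""
    os_ = glm_cfg.oversampling
    dt = task_cfg.tr / os_
    n_fine = task_cfg.n_volumes_per_run * os_
    sticks = np.zeros(n_fine)
    bins = np.round(onsets / dt).astype(int)
    np.add.at(sticks, bins, weights)
    kernel = canonical_hrf(
        task_cfg.tr,
        os_,
        peak_delay=glm_cfg.hrf_peak_delay,
        undershoot_delay=glm_cfg.hrf_undershoot_delay,
        peak_dispersion=glm_cfg.hrf_peak_dispersion,
        undershoot_dispersion=glm_cfg.hrf_undershoot_dispersion,
        ratio=glm_cfg.hrf_ratio,
        length=glm_cfg.hrf_length,
    )
    fine = sps.fftconvolve(sticks, kernel)[:n_fine]
    keep = (task_cfg.n_discard_volumes + np.arange(task_cfg.n_kept_volumes)) * os_
    return fine[keep]


def build_design_matrix(
    events: pd.DataFrame,
    motion: np.ndarray | None,
    task_cfg: TaskDesignConfig,
    glm_cfg: GLMConfig | None = None,
    session_rt_means_s: dict[str, float] | None = None,
) -> DesignMatrix:
    """Design matrix for one run.  ``events`` must have exclusions marked.

    RT modulator weights are mean-centered within condition over this
    run's included trials (default), or around ``session_rt_means_s``
    (seconds) when session-wise centering is configured.  All-zero columns
    (e.g. a modulator whose RTs are all equal) are dropped with a warning.
    """
    glm_cfg = glm_cfg or GLMConfig()
    inc = included_mask(events)
    onsets = events["onset"].to_numpy(dtype=float)
    rt_s = events["rt_ms"].to_numpy(dtype=float) / 1000.0
    cond = events["condition"].to_numpy()

    columns: list[np.ndarray] = []
    names: list[str] = []
    roles: list[str] = []

    conditions_present = [c for c in CONDITIONS if (cond == c).any()]
    for cname in conditions_present:
        m = inc & (cond == cname)
        if not m.any():
            raise DesignError(f"no included trials in modeled condition {cname!r}")
        columns.append(_convolve_sticks(onsets[m], np.ones(m.sum()), task_cfg, glm_cfg))
        names.append(f"{cname}_mean")
        roles.append(ROLE_CONDITION)

        center = (
            session_rt_means_s[cname]
            if glm_cfg.rt_centering == "session" and session_rt_means_s
            else rt_s[m].mean()
        )
        w = rt_s[m] - center
        if np.allclose(w, 0.0):
            warnings.warn(
                f"RT modulator for {cname!r} is all zero after centering; dropped",
                stacklevel=2,
            )
            continue
        columns.append(_convolve_sticks(onsets[m], w, task_cfg, glm_cfg))
        names.append(f"{cname}_rt")
        roles.append(ROLE_RT)

    excl = ~inc
    if excl.any():
        columns.append(_convolve_sticks(onsets[excl], np.ones(excl.sum()), task_cfg, glm_cfg))
        names.append("excluded")
        roles.append(ROLE_EXCLUDED)

    n_kept = task_cfg.n_kept_volumes
    if motion is not None:
        block = motion_expansion(motion)
        if block.shape[0] != n_kept:
            raise DesignError("motion rows must match retained volumes")
        for j in range(block.shape[1]):
            columns.append(block[:, j])
            names.append(f"motion_{j}")
            roles.append(ROLE_MOTION)

    drift = dct_highpass_basis(n_kept, task_cfg.tr, glm_cfg.highpass_cutoff)
    for j in range(drift.shape[1]):
        columns.append(drift[:, j])
        names.append(f"drift_{j + 1}")
        roles.append(ROLE_DRIFT)

    columns.append(np.ones(n_kept))
    names.append("intercept")
    roles.append(ROLE_INTERCEPT)

    keep_idx = []
    for i, col in enumerate(columns):
        if np.allclose(col, 0.0):
            warnings.warn(f"dropping all-zero design column {names[i]!r}", stacklevel=2)
        else:
            keep_idx.append(i)
    matrix = np.column_stack([columns[i] for i in keep_idx])
    frame_times = (task_cfg.n_discard_volumes + np.arange(n_kept)) * task_cfg.tr
    return DesignMatrix(
        matrix=matrix,
        column_names=[names[i] for i in keep_idx],
        column_roles=[roles[i] for i in keep_idx],
        frame_times=frame_times,
    )


# ---------------------------------------------------------------------------
# fitting


@dataclass
class GLMFit:
    betas: np.ndarray  # units x P
    residual_variance: np.ndarray  # units
    ar1_rho: float
    dof: float
    design: DesignMatrix
    xtx_inv: np.ndarray = field(repr=False, default=None)  # whitened (X'X)^-1


def _check_rank(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(x.shape) * np.finfo(float).eps
        bad = [names[i] for i in np.where(diag < tol)[0]]
        raise DesignError(f"rank-deficient design; collinear columns: {bad}")


def estimate_ar1_rho(residuals: np.ndarray) -> float:
    """Pooled lag-1 Yule-Walker autocorrelation; residuals units x volumes."""
    r = np.atleast_2d(residuals)
    num = float(np.sum(r[:, 1:] * r[:, :-1]))
    den = float(np.sum(r * r))
    return num / den if den > 0 else 0.0


def _whiten(a: np.ndarray, rho: float) -> np.ndarray:
    """Exact AR(1) whitening along the last (time) axis."""
    out = np.empty_like(a, dtype=float)
    out[..., 0] = np.sqrt(1.0 - rho**2) * a[..., 0]
    out[..., 1:] = a[..., 1:] - rho * a[..., :-1]
    return out


def fit_glm(
    timeseries: np.ndarray,
    design: DesignMatrix,
    ar1: bool = True,
    rho: float | None = None,
) -> GLMFit:
    """Two-pass prewhitened least squares.

    Pass 1: OLS, residuals pooled across units give a single global lag-1
    autocorrelation.  Pass 2: data and design are both AR(1)-whitened with
    that rho and refit by OLS.  Pass ``ar1=False`` (or ``rho=0``) for plain
    OLS; pass ``rho`` to reuse a rho pooled at a higher level.
    """
    y = np.atleast_2d(np.asarray(timeseries, dtype=float))  # units x volumes
    x = design.matrix
    if y.shape[1] != x.shape[0]:
        raise DesignError(
            f"timeseries has {y.shape[1]} volumes but design has {x.shape[0]} rows"
        )
    _check_rank(x, design.column_names)

    if rho is None:
        if ar1:
            beta0, *_ = np.linalg.lstsq(x, y.T, rcond=None)
            resid0 = y - (x @ beta0).T
            rho = estimate_ar1_rho(resid0)
        else:
            rho = 0.0
    rho = float(np.clip(rho, -0.999, 0.999))

    xw = _whiten(x.T, rho).T if rho != 0.0 else x
    yw = _whiten(y, rho) if rho != 0.0 else y
    beta, *_ = np.linalg.lstsq(xw, yw.T, rcond=None)
    resid = yw - (xw @ beta).T
    dof = x.shape[0] - np.linalg.matrix_rank(xw)
    sigma2 = np.sum(resid**2, axis=1) / dof
    xtx_inv = np.linalg.inv(xw.T @ xw)
    return GLMFit(
        betas=beta.T,
        residual_variance=sigma2,
        ar1_rho=rho,
        dof=float(dof),
        design=design,
        xtx_inv=xtx_inv,
    )


def contrast(fit: GLMFit, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linear contrast per unit: effect = w'beta and its t statistic on the
    whitened design, ``fit.dof`` degrees of freedom."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (fit.betas.shape[1],):
        raise DesignError(f"weights length {w.shape} != {fit.betas.shape[1]} columns")
    effect = fit.betas @ w
    var = float(w @ fit.xtx_inv @ w) * fit.residual_variance
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(var)
    return effect, t


# ---------------------------------------------------------------------------
# subject-level estimation


def estimate_conditions(ds, cfg: ExperimentConfig) -> ConditionEstimates:
    """Run the whole first level for one subject.

    Exclusions are marked with the conditional 3-SD rule (pooled across
    runs); one AR(1) rho is pooled over all runs and units; each run is
    refit whitened; condition-mean and RT-slope betas are averaged across
    runs (unweighted, runs are equal length).  Returns per-unit condition
    means, RT-BOLD slopes (signal units per second) and condition mean RTs.
    """
    events, report = mark_exclusions(ds.events, cfg.glm.outlier_sd)
    mean_rt_ms = condition_mean_rts(events)
    session_means_s = {c: v / 1000.0 for c, v in mean_rt_ms.items()}

    task_cfgs = {MSIT: cfg.msit, SIMPLE: cfg.simple}
    designs: dict[int, DesignMatrix] = {}
    resids = []
    ols_fits: dict[int, GLMFit] = {}
    for run, task in sorted(ds.run_tasks.items()):
        ev = events[events["run_index"] == run]
        dm = build_design_matrix(
            ev, ds.motion.get(run), task_cfgs[task], cfg.glm, session_means_s
        )
        designs[run] = dm
        f = fit_glm(ds.timeseries[run], dm, ar1=False)
        ols_fits[run] = f
        resids.append(ds.timeseries[run] - (dm.matrix @ f.betas.T).T)

    rho = estimate_ar1_rho(np.hstack(resids)) if cfg.glm.ar1 else 0.0

    per_run: dict[str, list[np.ndarray]] = {}
    for run in designs:
        f = fit_glm(ds.timeseries[run], designs[run], rho=rho)
        for name in designs[run].column_names:
            if name.endswith("_mean") or name.endswith("_rt"):
                per_run.setdefault(name, []).append(f.betas[:, designs[run].index(name)])

    n_units = next(iter(ds.timeseries.values())).shape[0]
    table = pd.DataFrame(index=list(ds.unit_names) or list(range(n_units)))
    colmap = {
        "congruent": "congruent_mean",
        "incongruent": "incongruent_mean",
        "simple": "simple_mean",
        "beta_rt_congruent": "congruent_rt",
        "beta_rt_incongruent": "incongruent_rt",
        "beta_rt_simple": "simple_rt",
    }
    for out_name, design_name in colmap.items():
        stacks = per_run.get(design_name)
        table[out_name] = np.mean(stacks, axis=0) if stacks else np.nan

    return ConditionEstimates(
        subject_id=ds.subject_id,
        table=table,
        mean_rt_ms=mean_rt_ms,
        ar1_rho=rho,
        exclusions=report,
    )
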