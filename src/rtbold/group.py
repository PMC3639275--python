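"""Random-effects group inference: one-sample t-tests over subjects,
Benjamini-Hochberg FDR, cluster-extent filtering, conjunctions, sphere ROI
summaries, and the three-column congruency report."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .equating import ConditionEstimates, subject_summary_table


class GroupError(ValueError):
    """Raised for invalid group-level inputs."""


# ---------------------------------------------------------------------------
# basic statistics


def one_sample_ttest(effects: np.ndarray, axis: int = 0) -> tuple[np.ndarray, np.ndarray, int]:
    """One-sample t against 0 with two-tailed p; df = n - 1.

    ``effects`` is subjects (axis 0) by units.  Zero-variance units get an
    infinite t and p = 0, with a warning.
    """
    e = np.asarray(effects, dtype=float)
    n = e.shape[axis]
    if n < 2:
        raise GroupError("need at least 2 subjects")
    mean = e.mean(axis=axis)
    sd = e.std(axis=axis, ddof=1)
    df = n - 1
    zero = (sd == 0) & (mean != 0)
    if np.any(zero):
        warnings.warn("zero variance across subjects; t is infinite", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        t = np.where(zero, np.sign(mean) * np.inf, t)
    t = np.where((sd == 0) & (mean == 0), 0.0, t)  # degenerate all-zero effects
    p = np.where(zero, 0.0, 2.0 * stats.t.sf(np.abs(t), df))
    return t, p, df


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up over all supplied units: reject the i
    smallest p-values where i is the largest index with p_(i) <= i*q/m."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise GroupError("p-values must lie in [0, 1]")
    flat = p.ravel()
    m = flat.size
    order = np.argsort(flat, kind="stable")
    ranked = flat[order]
    passing = np.nonzero(ranked <= (np.arange(1, m + 1) * q / m))[0]
    mask = np.zeros(m, dtype=bool)
    if passing.size:
        mask[order[: passing[-1] + 1]] = True
    return mask.reshape(p.shape)


# ---------------------------------------------------------------------------
# volumetric operations


_STRUCTURES = {6: 1, 18: 2, 26: 3}


def cluster_extent_filter(mask: np.ndarray, k: int = 20, connectivity: int = 6) -> np.ndarray:
    """Remove connected components smaller than ``k`` voxels from a 3-D
    boolean mask (face connectivity by default; 18 and 26 also supported)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise GroupError("cluster filtering needs a 3-D voxel grid")
    if connectivity not in _STRUCTURES:
        raise GroupError("connectivity must be 6, 18 or 26")
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= k
    keep[0] = False
    return keep[labels]


def conjunction(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Voxels (units) significant in each of two thresholded maps."""
    a, b = np.asarray(mask_a, dtype=bool), np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise GroupError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a & b


@dataclass
class ROISpec:
    """A sphere in MNI millimetre space."""

    name: str
    center: tuple[float, float, float]
    radius: float = 6.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise GroupError("ROI radius must be positive")


#: Interference-detection ROI set from a prior meta-analysis (MNI mm).
DEFAULT_ROIS = (
    ROISpec("pMFC", (2.0, 16.0, 46.0)),
    ROISpec("L_IFG", (-36.0, 16.0, 4.0)),
    ROISpec("R_IFG", (44.0, 14.0, 8.0)),
    ROISpec("L_IPL", (-36.0, -56.0, 44.0)),
    ROISpec("R_IPL", (40.0, -52.0, 42.0)),
)


def sphere_roi_mask(shape: tuple[int, int, int], affine: np.ndarray, roi: ROISpec) -> np.ndarray:
    """Voxels whose center lies within ``roi.radius`` mm of the ROI center
    (voxel-center distance rule)."""
    idx = np.indices(shape).reshape(3, -1)
    homog = np.vstack([idx, np.ones(idx.shape[1])])
    mm = (np.asarray(affine) @ homog)[:3]
    d2 = np.sum((mm - np.asarray(roi.center)[:, None]) ** 2, axis=0)
    return (d2 <= roi.radius**2).reshape(shape)


def sphere_roi_average(values: np.ndarray, affine: np.ndarray, roi: ROISpec) -> float:
    """Unweighted mean of a voxel map over a sphere ROI."""
    mask = sphere_roi_mask(values.shape, affine, roi)
    if not mask.any():
        raise GroupError(f"sphere {roi.name} at {roi.center} contains no voxels")
    return float(np.asarray(values)[mask].mean())


# ---------------------------------------------------------------------------
# group maps and reports


@dataclass
class GroupResult:
    """Random-effects summary for one contrast over units."""

    mean_effect: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df: int
    mask: np.ndarray
    threshold: dict = field(default_factory=dict)


def group_ttest(
    effects: np.ndarray,
    method: str = "fdr",
    q: float = 0.05,
    alpha: float = 0.05,
    extent_k: int = 0,
    connectivity: int = 6,
) -> GroupResult:
    """One-sample group test with FDR (or uncorrected) height thresholding
    and optional cluster-extent filtering (3-D unit grids only)."""
    t, p, df = one_sample_ttest(effects)
    if method == "fdr":
        mask = fdr_bh(p, q)
        threshold = {"method": "fdr", "q": q, "extent_k": extent_k}
    elif method == "uncorrected":
        mask = p < alpha
        threshold = {"method": "uncorrected", "alpha": alpha, "extent_k": extent_k}
    else:
        raise GroupError(f"unknown threshold method {method!r}")
    if extent_k > 1 and np.asarray(mask).ndim == 3:
        mask = cluster_extent_filter(mask, k=extent_k, connectivity=connectivity)
    return GroupResult(effects.mean(axis=0), t, p, df, mask, threshold)


_EFFECT_COLUMNS = {
    "original": "effect_uncorrected",
    "corrected_congruent": "effect_corrected_congruent",
    "corrected_simple": "effect_corrected_simple",
}

_SLOPE_COLUMNS = {
    "slope_msit": "beta_rt_msit_avg",
    "slope_simple": "beta_rt_simple",
}


def stack_estimates(estimates: Sequence[ConditionEstimates]) -> pd.DataFrame:
    """Concatenate every subject's summary table (one row per unit)."""
    return pd.concat([subject_summary_table(e) for e in estimates], ignore_index=False)


def congruency_table(
    estimates: Sequence[ConditionEstimates], alpha: float = 0.05
) -> pd.DataFrame:
    """Per-unit report of the congruency effect in (a) the original data,
    (b) after the congruent-slope RT correction, and (c) after the
    simple-task-slope RT correction, plus RT-BOLD slope tests for the MSIT
    (average of congruent and incongruent), the simple task, and their
    paired difference.

    Rows are units; columns ``<name>_{mean,t,p,sig}`` per contrast.
    """
    stacked = stack_estimates(estimates)
    units = stacked.index.unique()
    n = len(estimates)
    rows = []
    contrasts = dict(_EFFECT_COLUMNS)
    contrasts.update(_SLOPE_COLUMNS)
    for unit in units:
        sub = stacked.loc[[unit]]
        if len(sub) != n:
            raise GroupError(f"unit {unit!r} missing for some subjects")
        row: dict[str, float] = {}
        for label, col in contrasts.items():
            vals = sub[col].to_numpy()
            t, p, _ = one_sample_ttest(vals[:, None])
            row[f"{label}_mean"] = float(vals.mean())
            row[f"{label}_t"] = float(t[0])
            row[f"{label}_p"] = float(p[0])
            row[f"{label}_sig"] = bool(p[0] < alpha)
        diff = (sub["beta_rt_msit_avg"] - sub["beta_rt_simple"]).to_numpy()
        t, p, df = one_sample_ttest(diff[:, None])
        row["slope_diff_mean"] = float(diff.mean())
        row["slope_diff_t"] = float(t[0])
        row["slope_diff_p"] = float(p[0])
        row["slope_diff_sig"] = bool(p[0] < alpha)
        row["df"] = df
        rows.append(row)
    return pd.DataFrame(rows, index=units)
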