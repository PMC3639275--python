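"""RT-equated congruency contrasts.

The uncorrected congruency effect (Incongruent - Congruent) confounds
condition with time on task, because incongruent trials take longer.  To
remove the confound, congruent-trial activity is extrapolated to the
incongruent mean RT using an RT-BOLD slope:

    CongruentEQ_Congruent = Congruent + beta_RT-Congruent * dRT       (1)
    CongruentEQ_Simple    = Congruent + beta_RT-Simple    * dRT       (2)

where dRT = mean incongruent RT - mean congruent RT.  Slopes are in signal
units per second; dRT is carried in ms at the interface and converted to
seconds at the single multiplication point.  The corrected congruency
effect is Incongruent - CongruentEQ.  Under a pure time-on-task world both
corrections abolish the effect; under conflict monitoring the simple-task
slope is ~0, so correction (2) leaves the effect intact — that asymmetry
is what discriminates the two accounts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .config import CONDITIONS

SLOPE_SOURCES = ("congruent", "simple")


class EstimateError(ValueError):
    """Raised when condition estimates are unusable."""


@dataclass
class ConditionEstimates:
    """Per-subject, per-unit condition means and RT-BOLD slopes.

    ``table`` has one row per unit and columns: congruent, incongruent,
    simple (mean-activity betas, signal units), beta_rt_congruent,
    beta_rt_incongruent, beta_rt_simple (signal units per second).
    ``mean_rt_ms`` holds the subject's condition mean RTs over included
    trials.
    """

    subject_id: str
    table: pd.DataFrame
    mean_rt_ms: dict[str, float]
    ar1_rho: float = np.nan
    exclusions: Any = None

    @property
    def delta_rt_ms(self) -> float:
        return self.mean_rt_ms["incongruent"] - self.mean_rt_ms["congruent"]

    def msit_average_slope(self) -> pd.Series:
        """Unweighted mean of the congruent and incongruent RT-BOLD slopes."""
        return (self.table["beta_rt_congruent"] + self.table["beta_rt_incongruent"]) / 2.0


@dataclass
class RTEquatedEstimate:
    """Per-unit RT-equated congruent activity for one subject."""

    subject_id: str
    slope_source: str
    delta_rt_ms: float
    values: pd.Series  # per-unit CongruentEQ, signal units
    congruent: pd.Series = field(repr=False, default=None)


def condition_mean_rts(events: pd.DataFrame) -> dict[str, float]:
    """Arithmetic mean RT (ms) per condition over included trials, pooled
    across runs.  Requires exclusions to be marked."""
    out: dict[str, float] = {}
    inc = (events["excluded_as"] == "none").to_numpy()
    for cond in CONDITIONS:
        m = inc & (events["condition"] == cond).to_numpy()
        if (events["condition"] == cond).any():
            if not m.any():
                raise EstimateError(f"no included trials in condition {cond!r}")
            out[cond] = float(events.loc[m, "rt_ms"].mean())
    return out


def rt_equated_congruent(
    est: ConditionEstimates, slope_source: str = "congruent"
) -> RTEquatedEstimate:
    """Congruent activity extrapolated to the incongruent mean RT.

    ``slope_source='congruent'`` uses the congruent-condition RT-BOLD slope
    (equation 1 above); ``'simple'`` uses the simple-task slope (equation
    2).  With a zero slope or equal mean RTs the result equals the raw
    congruent estimate exactly.
    """
    if slope_source not in SLOPE_SOURCES:
        raise EstimateError(f"slope_source must be one of {SLOPE_SOURCES}")
    beta = est.table[f"beta_rt_{slope_source}"]
    delta_rt_s = est.delta_rt_ms / 1000.0  # ms -> s: the one conversion point
    values = est.table["congruent"] + beta * delta_rt_s
    return RTEquatedEstimate(
        subject_id=est.subject_id,
        slope_source=slope_source,
        delta_rt_ms=est.delta_rt_ms,
        values=values,
        congruent=est.table["congruent"],
    )


def corrected_congruency_effect(
    est: ConditionEstimates, slope_source: str = "congruent"
) -> pd.DataFrame:
    """Per-unit congruency effects for one subject.

    Columns: ``uncorrected`` (Incongruent - Congruent) and ``corrected``
    (Incongruent - CongruentEQ under the chosen slope source).
    """
    eq = rt_equated_congruent(est, slope_source)
    return pd.DataFrame(
        {
            "uncorrected": est.table["incongruent"] - est.table["congruent"],
            "corrected": est.table["incongruent"] - eq.values,
        }
    )


def subject_summary_table(est: ConditionEstimates) -> pd.DataFrame:
    """Flat per-unit table of every quantity entering the group analyses."""
    t = est.table.copy()
    t["congruent_eq_congruent"] = rt_equated_congruent(est, "congruent").values
    t["congruent_eq_simple"] = rt_equated_congruent(est, "simple").values
    t["effect_uncorrected"] = t["incongruent"] - t["congruent"]
    t["effect_corrected_congruent"] = t["incongruent"] - t["congruent_eq_congruent"]
    t["effect_corrected_simple"] = t["incongruent"] - t["congruent_eq_simple"]
    t["beta_rt_msit_avg"] = est.msit_average_slope()
    if "subject_id" in t.columns:
        t = t.drop(columns="subject_id")
    t.insert(0, "subject_id", est.subject_id)
    for cond, v in est.mean_rt_ms.items():
        t[f"mean_rt_{cond}_ms"] = v
    return t
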