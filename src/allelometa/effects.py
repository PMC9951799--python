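"""Small-sample-corrected log response ratios and the Geary normality screen.

The effect size is the delta log response ratio: the plain log ratio of
treatment to control means plus a second-order (delta-method) bias correction,
with a matching second-order sampling variance.  Writing m, s, n for a group
mean, SD and sample size and C/T for control/treatment,

    d = ln(m_T / m_C) + 1/2 * [ s_T^2/(n_T m_T^2) - s_C^2/(n_C m_C^2) ]
    v = s_T^2/(n_T m_T^2) + s_C^2/(n_C m_C^2)
        + 1/2 * [ s_T^4/(n_T^2 m_T^4) + s_C^4/(n_C^2 m_C^4) ]

The Geary screen (m/s)*sqrt(n) >= 3 verifies that a group mean is far enough
from zero for the log-normal approximation behind the ratio to hold; a record
is discarded only when BOTH groups fail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .records import GroupStats, StudyRecord, records_to_frame

GEARY_THRESHOLD = 3.0


@dataclass(frozen=True)
class EffectSize:
    """Delta log response ratio with its sampling variance."""

    d: float
    v: float
    se: float
    record_ref: tuple

    def __post_init__(self):
        if not math.isfinite(self.d):
            raise ValueError("effect size is not finite")
        if self.v <= 0:
            raise ValueError("sampling variance must be > 0")


@dataclass(frozen=True)
class GearyResult:
    control_stat: float
    treatment_stat: float
    control_pass: bool
    treatment_pass: bool
    keep: bool
    record_ref: tuple = ()


def _rel_var(g: GroupStats) -> float:
    # squared relative error of the group mean, s^2 / (n m^2)
    return g.sd ** 2 / (g.n * g.mean ** 2)


def delta_lrr(control: GroupStats, treatment: GroupStats,
              record_ref: tuple = (),
              variance_order: Literal["second", "first"] = "second") -> EffectSize:
    """Compute the bias-corrected log response ratio for one comparison.

    ``variance_order`` selects the two-term first-order variance or the
    default second-order variance that matches the bias correction.
    """
    for label, g in (("control", control), ("treatment", treatment)):
        if not g.mean > 0:
            raise ValueError(
                f"{label} mean must be > 0 to form a log ratio (record {record_ref})")
        if g.n < 2:
            raise ValueError(f"{label} n must be >= 2 (record {record_ref})")
    rc, rt = _rel_var(control), _rel_var(treatment)
    d = math.log(treatment.mean / control.mean) + 0.5 * (rt - rc)
    v = rt + rc
    if variance_order == "second":
        v += 0.5 * (rt ** 2 + rc ** 2)
    if v <= 0:
        # both SDs zero: degenerate but observed (all-or-nothing germination);
        # assign a tiny floor so downstream weighting stays finite
        v = 1e-12
    return EffectSize(d=d, v=v, se=math.sqrt(v), record_ref=record_ref)


def geary_statistic(g: GroupStats) -> float:
    """Geary's normality statistic (mean/SD)*sqrt(n); +inf when SD is zero."""
    if g.sd == 0:
        return math.inf
    return (g.mean / g.sd) * math.sqrt(g.n)


def apply_geary_filter(records: Sequence[StudyRecord],
                       threshold: float = GEARY_THRESHOLD,
                       rule: Literal["both", "either"] = "both",
                       variance_order: Literal["second", "first"] = "second",
                       ) -> tuple[list[EffectSize], list[GearyResult]]:
    """Screen records with the Geary check and convert survivors to effect sizes.

    Under the default rule a record is dropped only when the control AND the
    treatment statistic both fall below ``threshold``; the stricter
    ``rule='either'`` variant drops on a single failure.
    """
    kept: list[EffectSize] = []
    dropped: list[GearyResult] = []
    for rec in records:
        cs = geary_statistic(rec.control)
        ts = geary_statistic(rec.treatment)
        cp, tp = cs >= threshold, ts >= threshold
        drop = (not cp and not tp) if rule == "both" else not (cp and tp)
        if drop:
            dropped.append(GearyResult(cs, ts, cp, tp, keep=False,
                                       record_ref=rec.key))
        else:
            kept.append(delta_lrr(rec.control, rec.treatment, record_ref=rec.key,
                                  variance_order=variance_order))
    return kept, dropped


def percent_change(d: float) -> float:
    """Back-transform an effect size to a percent change, 100*(exp(d)-1).

    Negative values are read as percent suppression of magnitude ``abs(.)``.
    """
    if not math.isfinite(d):
        raise ValueError("d must be finite")
    return 100.0 * (math.exp(d) - 1.0)


def effect_table(records: Sequence[StudyRecord],
                 threshold: float = GEARY_THRESHOLD,
                 rule: Literal["both", "either"] = "both",
                 variance_order: Literal["second", "first"] = "second",
                 ) -> pd.DataFrame:
    """Build the analysis table: moderators plus d, v, se, Geary columns.

    All records appear with their Geary statistics; only rows with
    ``keep == True`` carry effect sizes and enter the model.
    """
    base = records_to_frame(records)
    d = np.full(len(records), np.nan)
    v = np.full(len(records), np.nan)
    keep = np.zeros(len(records), dtype=bool)
    gc = np.empty(len(records))
    gt = np.empty(len(records))
    for i, rec in enumerate(records):
        gc[i] = geary_statistic(rec.control)
        gt[i] = geary_statistic(rec.treatment)
        cp, tp = gc[i] >= threshold, gt[i] >= threshold
        drop = (not cp and not tp) if rule == "both" else not (cp and tp)
        if not drop:
            es = delta_lrr(rec.control, rec.treatment, record_ref=rec.key,
                           variance_order=variance_order)
            d[i], v[i], keep[i] = es.d, es.v, True
    base["d"] = d
    base["v"] = v
    base["se"] = np.sqrt(v)
    base["geary_control"] = gc
    base["geary_treatment"] = gt
    base["keep"] = keep
    return base
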