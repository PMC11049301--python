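"""Proficiency-testing performance scoring for glucose meter groups.

Two target protocols are supported: the reference (mass-spectrometry)
assigned value, and the participant consensus obtained by the iterative
winsorization robust procedure (robust mean and robust SD).  Each
participant result is scored against the target by the glucose-meter
system accuracy rule: the difference must stay within 15 mg/dL when the
target is below 100 mg/dL, and within 15% of the target otherwise.

The robust procedure starts from the median and the scaled median
absolute deviation (1.483 * MAD), then iterates

    delta = 1.5 * s*
    winsorize values into [x* - delta, x* + delta]
    x* = mean of winsorized values
    s* = 1.134 * SD of winsorized values

until both estimates are stable.  The 1.134 factor restores consistency
for a normal population after winsorization at 1.5 s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .datatypes import PTResultSet, TargetSpec

__all__ = [
    "RobustSummary", "PerformanceReport", "RobustConsensus",
    "PerformanceEvaluation", "algorithm_a", "iso15197_satisfied",
    "evaluate_scheme", "consensus_target", "round_half_up",
]

SATISFACTION_ABS_MGDL = 15.0
SATISFACTION_REL_FRACTION = 0.15


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (99.15 -> 99.2 at 1 digit)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RobustSummary:
    robust_mean: float
    robust_sd: float
    n_used: int
    iterations: int
    converged: bool
    degenerate: bool = False


@dataclass(frozen=True)
class PerformanceReport:
    n: int
    n_satisfied: int
    percent_satisfied: float
    n_absolute_rule: int
    n_relative_rule: int
    target: TargetSpec
    t_p: float | None

    def summary_row(self) -> dict:
        return {
            "target_source": self.target.source,
            "target_mg_dl": self.target.value,
            "n": self.n, "n_satisfied": self.n_satisfied,
            "percent_satisfied": self.percent_satisfied,
            "t_p": self.t_p,
        }


def algorithm_a(values, tol: float = 1e-6,
                max_iter: int = 100) -> RobustSummary:
    """Robust mean and SD by iterative winsorization.

    Raises for fewer than 3 values; a sample of identical values is
    returned with ``degenerate=True`` and zero robust SD.
    """
    v = np.asarray(values, float)
    if v.size < 3:
        raise ValueError("robust analysis needs at least 3 values")
    x_star = float(np.median(v))
    s_star = 1.483 * float(np.median(np.abs(v - x_star)))
    if s_star == 0.0:
        if np.all(v == v[0]):
            return RobustSummary(robust_mean=x_star, robust_sd=0.0,
                                 n_used=v.size, iterations=0,
                                 converged=True, degenerate=True)
        # majority at a single value: fall back to classical start
        s_star = float(v.std(ddof=1))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        delta = 1.5 * s_star
        w = np.clip(v, x_star - delta, x_star + delta)
        new_x = float(w.mean())
        new_s = 1.134 * float(w.std(ddof=1))
        dx = abs(new_x - x_star) / max(abs(x_star), 1e-12)
        ds = abs(new_s - s_star) / max(abs(s_star), 1e-12)
        x_star, s_star = new_x, new_s
        if dx < tol and ds < tol:
            converged = True
            break
        if s_star == 0.0:
            return RobustSummary(robust_mean=x_star, robust_sd=0.0,
                                 n_used=v.size, iterations=it,
                                 converged=True, degenerate=True)
    return RobustSummary(robust_mean=x_star, robust_sd=s_star,
                         n_used=int(v.size), iterations=it,
                         converged=converged)


def iso15197_satisfied(value: float, target: float) -> tuple[bool, str]:
    """Accuracy rule for one result against one target.

    Below 100 mg/dL the absolute rule (|diff| <= 15 mg/dL) applies;
    at or above 100 mg/dL the relative rule (|diff| <= 15% of target).
    At exactly 100 the two rules coincide (15% of 100 = 15 mg/dL); the
    relative branch is used.
    """
    if value <= 0 or target <= 0:
        raise ValueError("value and target must be positive")
    diff = abs(value - target)
    if target < 100.0:
        return diff <= SATISFACTION_ABS_MGDL, "absolute"
    return diff <= SATISFACTION_REL_FRACTION * target, "relative"


def evaluate_scheme(results: PTResultSet, target: TargetSpec,
                    ref_values=None) -> PerformanceReport:
    """Score every participant against the target.

    The significance mark of the group against a reference target comes
    from a two-sided one-sample t of the participant values against the
    target value; when ``ref_values`` (reference-method replicates) are
    supplied, a Welch two-sample t is used instead.
    """
    v = results.values
    sat, crit = zip(*(iso15197_satisfied(x, target.value) for x in v))
    n_sat = int(sum(sat))
    n_abs = sum(c == "absolute" for c in crit)
    n_rel = sum(c == "relative" for c in crit)
    pct = round_half_up(100.0 * n_sat / results.n, 1)
    t_p = None
    if target.source == "reference" and results.n >= 2:
        if ref_values is not None:
            t_p = float(stats.ttest_ind(v, np.asarray(ref_values, float),
                                        equal_var=False).pvalue)
        else:
            t_p = float(stats.ttest_1samp(v, target.value).pvalue)
    return PerformanceReport(n=results.n, n_satisfied=n_sat,
                             percent_satisfied=pct,
                             n_absolute_rule=int(n_abs),
                             n_relative_rule=int(n_rel),
                             target=target, t_p=t_p)


def consensus_target(results: PTResultSet, tol: float = 1e-6,
                     max_iter: int = 100) -> TargetSpec:
    """Robust consensus value of the meter group as a scoring target."""
    if results.n < 3:
        raise ValueError("consensus target needs at least 3 participants")
    rs = algorithm_a(results.values, tol, max_iter)
    return TargetSpec(source="consensus", value=rs.robust_mean,
                      sd=rs.robust_sd)


class RobustConsensus:
    """Robust location/scale model for one participant group.

    ``fit()`` returns a :class:`RobustSummary` with the winsorized mean
    and SD, iteration count and convergence status.
    """

    def __init__(self, values, tol: float = 1e-6, max_iter: int = 100):
        self.values = np.asarray(values, float)
        self.tol = tol
        self.max_iter = max_iter

    def fit(self) -> RobustSummary:
        return algorithm_a(self.values, self.tol, self.max_iter)


@dataclass(frozen=True)
class SchemeResults:
    """Scoring of one meter group against one or more targets."""

    results: PTResultSet
    consensus: RobustSummary | None
    reports: tuple[PerformanceReport, ...]

    def summary(self):
        import pandas as pd
        rows = []
        for r in self.reports:
            row = {"material_id": self.results.material_id,
                   "meter_group": self.results.meter_group}
            row.update(r.summary_row())
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        v = self.results.values
        d = {
            "material_id": self.results.material_id,
            "meter_group": self.results.meter_group,
            "n": self.results.n,
            "range": [float(v.min()), float(v.max())],
            "reports": [r.summary_row() for r in self.reports],
        }
        if self.consensus is not None:
            d["robust_mean"] = self.consensus.robust_mean
            d["robust_sd"] = self.consensus.robust_sd
        return d


class PerformanceEvaluation:
    """Performance model for a proficiency-testing meter group.

    Parameters
    ----------
    results : PTResultSet
        One value per participant.
    reference : TargetSpec, optional
        Assigned reference-method target (value and SD).
    use_consensus : bool
        Also score against the group's own robust consensus.
    """

    def __init__(self, results: PTResultSet,
                 reference: TargetSpec | None = None,
                 use_consensus: bool = True,
                 ref_values=None):
        self.results = results
        self.reference = reference
        self.use_consensus = use_consensus
        self.ref_values = ref_values

    @classmethod
    def from_dataframe(cls, df, **kw) -> "PerformanceEvaluation":
        return cls(PTResultSet.from_frame(df), **kw)

    def fit(self) -> SchemeResults:
        reports = []
        consensus = None
        if self.reference is not None:
            reports.append(evaluate_scheme(self.results, self.reference,
                                           self.ref_values))
        if self.use_consensus and self.results.n >= 3:
            consensus = algorithm_a(self.results.values)
            tgt = TargetSpec(source="consensus",
                             value=consensus.robust_mean,
                             sd=consensus.robust_sd)
            reports.append(evaluate_scheme(self.results, tgt))
        if not reports:
            raise ValueError("no target to score against")
        return SchemeResults(results=self.results, consensus=consensus,
                             reports=tuple(reports))
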