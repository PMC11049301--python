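"""Between-vial homogeneity assessment for candidate reference materials.

A batch is adjudicated by a one-way, single-factor analysis of variance
over vials: the batch is *adequately homogeneous* when the among-vial
mean square does not significantly exceed the within-vial (repeatability)
mean square, i.e. ``F_calculate < F_critical`` at the chosen level.
Gross variance outliers among vials are screened beforehand with an
iterative Cochran C test.  Variance components follow the reference-
material convention:

    s_r   = sqrt(MS_within)                      repeatability SD
    s_bb  = sqrt(max(0, (MS_among - MS_within)/n))  between-vial SD
    u*_bb = sqrt(MS_within/n) * (2/df_within)^(1/4)  resolution floor
    u_bb  = max(s_bb, u*_bb)                     between-vial uncertainty

where ``n`` is the (balanced) replicate count per vial.  The floor
``u*_bb`` prevents reporting an implausibly small uncertainty when the
study simply lacked the power to resolve between-vial variation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import ReplicateTable

__all__ = [
    "AnovaResult", "HomogeneityReport", "HomogeneityAnalysis",
    "cochran_critical_value", "cochran_outlier_screen",
    "one_way_anova", "between_vial_components",
]


@dataclass(frozen=True)
class AnovaResult:
    """Single-factor ANOVA decomposition over vials."""

    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    ms_among: float
    ms_within: float
    f_calculate: float
    f_critical: float
    alpha: float
    grand_mean: float
    cv_percent: float

    @property
    def adequate(self) -> bool:
        return self.f_calculate < self.f_critical


@dataclass(frozen=True)
class HomogeneityReport:
    """Full homogeneity verdict with variance components."""

    material_id: str
    anova: AnovaResult
    s_bb: float
    s_r: float
    u_bb: float
    adequate: bool
    outlier_vials: tuple[str, ...]

    def summary_row(self) -> dict:
        """One-row summary in the conventional report layout."""
        return {
            "material_id": self.material_id,
            "mean_mg_dl": round(self.anova.grand_mean, 1),
            "cv_percent": round(self.anova.cv_percent, 2),
            "f_calculate": round(self.anova.f_calculate, 2),
            "f_critical": round(self.anova.f_critical, 2),
            "interpretation": "Adequate" if self.adequate else "Inadequate",
        }

    def to_dict(self) -> dict:
        a = self.anova
        return {
            "material_id": self.material_id,
            "anova": {
                "ss_among": a.ss_among, "ss_within": a.ss_within,
                "df_among": a.df_among, "df_within": a.df_within,
                "ms_among": a.ms_among, "ms_within": a.ms_within,
                "f_calculate": a.f_calculate, "f_critical": a.f_critical,
                "alpha": a.alpha, "grand_mean": a.grand_mean,
                "cv_percent": a.cv_percent,
            },
            "s_bb": self.s_bb, "s_r": self.s_r, "u_bb": self.u_bb,
            "adequate": self.adequate,
            "outlier_vials": list(self.outlier_vials),
        }


def cochran_critical_value(alpha: float, k: int, n: int) -> float:
    """Upper critical value of Cochran's C for k variances on n-1 df each.

    Uses the exact F-based closed form
    ``C = [1 + (k-1)/F_{alpha/k}(n-1, (k-1)(n-1))]^{-1}``.
    """
    if k < 2 or n < 2:
        raise ValueError("Cochran critical value needs k >= 2 and n >= 2")
    f_upper = stats.f.isf(alpha / k, n - 1, (k - 1) * (n - 1))
    return 1.0 / (1.0 + (k - 1) / f_upper)


def cochran_outlier_screen(
    table: ReplicateTable, alpha: float = 0.05,
) -> tuple[list[str], ReplicateTable]:
    """Iteratively flag vials whose replicate variance is a Cochran outlier.

    The max-variance vial is flagged when ``C = max(s_i^2)/sum(s_i^2)``
    exceeds the critical value; the screen repeats on the reduced table
    until nothing is flagged or fewer than 3 vials remain.

    Returns
    -------
    (flagged, cleaned)
        Flagged vial ids in removal order, and the table without them.
    """
    if table.n_vials < 3:
        raise ValueError("Cochran screen needs at least 3 vials")
    if not table.is_balanced:
        raise ValueError(
            f"unbalanced replicate table: vial "
            f"{table._unbalanced_vial()!r} breaks balance")
    n = table.replicate_counts[0]
    if n < 2:
        raise ValueError("Cochran screen needs >= 2 replicates per vial")

    flagged: list[str] = []
    current = table
    while current.n_vials >= 3:
        mat = current.value_matrix()
        variances = mat.var(axis=1, ddof=1)
        total = variances.sum()
        if total == 0.0:
            warnings.warn(
                "all vial variances are zero; Cochran statistic undefined",
                stacklevel=2)
            break
        k = current.n_vials
        c_stat = variances.max() / total
        if c_stat <= cochran_critical_value(alpha, k, n):
            break
        worst = current.rows[int(np.argmax(variances))][0]
        flagged.append(worst)
        current = current.drop_vials([worst])
    return flagged, current


def one_way_anova(table: ReplicateTable, alpha: float = 0.05) -> AnovaResult:
    """Single-factor ANOVA of value on vial, with the homogeneity verdict.

    ``cv_percent`` is the SD of all individual results over the grand
    mean — a between-samples spread summary, not the SD of vial means.
    """
    if table.n_vials < 2:
        raise ValueError("ANOVA needs at least 2 vials")
    if any(c < 2 for c in table.replicate_counts):
        raise ValueError("ANOVA needs >= 2 replicates in every vial")
    groups = [np.asarray(vals, float) for _, vals in table.rows]
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_among = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_among = len(groups) - 1
    df_within = sum(len(g) - 1 for g in groups)
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    if ms_within > 0:
        f_calc = ms_among / ms_within
    elif ms_among > 0:
        f_calc = math.inf  # zero repeatability scatter but vials differ
    else:
        f_calc = 0.0
    f_crit = float(stats.f.isf(alpha, df_among, df_within))
    cv = 100.0 * allv.std(ddof=1) / grand
    return AnovaResult(
        ss_among=float(ss_among), ss_within=float(ss_within),
        df_among=df_among, df_within=df_within,
        ms_among=float(ms_among), ms_within=float(ms_within),
        f_calculate=float(f_calc), f_critical=f_crit, alpha=alpha,
        grand_mean=float(grand), cv_percent=float(cv))


def between_vial_components(
    anova: AnovaResult, n_rep: int,
) -> tuple[float, float, float]:
    """Variance components (s_bb, s_r, u_bb) from a balanced ANOVA."""
    if n_rep < 2:
        raise ValueError("variance components need >= 2 replicates per vial")
    s_r = math.sqrt(anova.ms_within)
    s_bb = math.sqrt(max(0.0, (anova.ms_among - anova.ms_within) / n_rep))
    u_star = math.sqrt(anova.ms_within / n_rep) * (2.0 / anova.df_within) ** 0.25
    return s_bb, s_r, max(s_bb, u_star)


class HomogeneityAnalysis:
    """Homogeneity model for a vial-replicate table.

    Parameters
    ----------
    table : ReplicateTable
        Balanced vial x replicate measurements.
    alpha : float
        Significance level for both the Cochran screen and the F test.
    screen_outliers : bool
        Run the iterative Cochran screen before the ANOVA (default True).

    Examples
    --------
    >>> from commutakit import HomogeneityAnalysis, ReplicateTable
    >>> table = ReplicateTable("B1", [("v1", [98, 100]), ("v2", [101, 103]),
    ...                               ("v3", [97, 99])])
    >>> report = HomogeneityAnalysis(table, screen_outliers=False).fit()
    >>> report.adequate
    True
    """

    def __init__(self, table: ReplicateTable, alpha: float = 0.05,
                 screen_outliers: bool = True):
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        self.table = table
        self.alpha = alpha
        self.screen_outliers = screen_outliers

    @classmethod
    def from_dataframe(cls, df, material_id: str | None = None, **kw):
        return cls(ReplicateTable.from_frame(df, material_id), **kw)

    def fit(self) -> HomogeneityReport:
        table = self.table
        flagged: list[str] = []
        if self.screen_outliers:
            flagged, table = cochran_outlier_screen(table, self.alpha)
        if not table.is_balanced:
            raise ValueError(
                f"unbalanced replicate table: vial "
                f"{table._unbalanced_vial()!r} breaks balance")
        anova = one_way_anova(table, self.alpha)
        n_rep = table.replicate_counts[0]
        s_bb, s_r, u_bb = between_vial_components(anova, n_rep)
        return HomogeneityReport(
            material_id=table.material_id, anova=anova,
            s_bb=s_bb, s_r=s_r, u_bb=u_bb,
            adequate=anova.adequate, outlier_vials=tuple(flagged))
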