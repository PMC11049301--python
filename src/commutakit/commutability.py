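"""Commutability assessment via Deming regression prediction bands.

A candidate processed material is *commutable* between a reference
method (x) and a field method (y) when its (x_mean, y_mean) point
behaves like the native clinical samples: it must fall inside the 95%
prediction band of an errors-in-variables (Deming) regression fitted to
the native-sample method pairs.  The band boundary is inclusive.

Deming regression allows measurement error in both axes, weighted by
``lambda_ = Var(y-error) / Var(x-error)``.  With centred sample moments
``s_xx, s_yy, s_xy`` the slope is

    b = [s_yy - lambda*s_xx + sqrt((s_yy - lambda*s_xx)^2
                                   + 4*lambda*s_xy^2)] / (2*s_xy)

which reduces to ordinary least squares of y on x as ``lambda -> inf``
(all error in y) and to ``s_yy/s_xy`` as ``lambda -> 0`` (all error in
x); ``lambda = 1`` is orthogonal regression, the default here since
replicate error variances for the native pairs are rarely available.

The prediction band uses the vertical residual SD around the Deming
line with OLS-style leverage — the single band in y conventionally
drawn on method-comparison scatter plots.

Separately from the band verdict, each material carries a *mean
difference* classification: compatible when the paired mean difference
between field and reference method is at most 5% (of the reference mean
by default), and a Tukey HSD characterisation of the method factor from
a two-way ANOVA over method x material replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MaterialPoint, PairedSampleSet

__all__ = [
    "DemingFit", "CommutabilityVerdict", "DemingRegression",
    "deming_fit", "prediction_band", "classify_commutability",
    "paired_difference", "characterize_materials", "tukey_stars",
]

COMPATIBILITY_THRESHOLD_PCT = 5.0


@dataclass(frozen=True)
class DemingFit:
    """Errors-in-variables straight-line fit."""

    slope: float
    intercept: float
    lambda_: float   # Var(y-error)/Var(x-error)
    s_res: float     # SD of vertical residuals, df = n - 2
    n: int
    mean_x: float
    sxx: float       # centred sum of squares of x

    def predict(self, x0: float) -> float:
        return self.intercept + self.slope * x0


@dataclass(frozen=True)
class CommutabilityVerdict:
    material_id: str
    commutable: bool
    band_lower: float
    band_upper: float
    y_mean: float
    diff: float
    diff_percent: float
    compatible: bool
    tukey_p: float | None = None

    def summary_row(self) -> dict:
        return {
            "material_id": self.material_id,
            "verdict": "C" if self.commutable else "NC",
            "band_lower": round(self.band_lower, 1),
            "band_upper": round(self.band_upper, 1),
            "diff_mg_dl": round(self.diff, 1),
            "diff_percent": round(self.diff_percent, 1),
            "compatibility": "A" if self.compatible else "B",
            "tukey_stars":
                "" if self.tukey_p is None else tukey_stars(self.tukey_p),
        }


def tukey_stars(p: float) -> str:
    """Conventional significance marks: * p<0.05, ** p<0.001."""
    if p < 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def deming_fit(pairs: PairedSampleSet, lambda_: float = 1.0) -> DemingFit:
    """Fit the Deming line to native-sample method pairs.

    ``lambda_`` is the ratio of y-error variance to x-error variance;
    1.0 gives orthogonal regression.
    """
    if pairs.n < 3:
        raise ValueError("Deming fit needs at least 3 pairs")
    if lambda_ <= 0:
        raise ValueError("lambda_ must be positive")
    x, y = pairs.x, pairs.y
    mean_x, mean_y = x.mean(), y.mean()
    dx, dy = x - mean_x, y - mean_y
    s_xx = float((dx ** 2).sum())
    s_yy = float((dy ** 2).sum())
    s_xy = float((dx * dy).sum())
    if s_xx == 0.0:
        raise ValueError("x values are all equal; line is vertical")
    if s_xy == 0.0:
        if s_yy == lambda_ * s_xx:
            raise ValueError("degenerate fit: slope undetermined "
                             "(zero covariance, balanced variances)")
        raise ValueError("degenerate fit: zero x-y covariance")
    disc = (s_yy - lambda_ * s_xx) ** 2 + 4 * lambda_ * s_xy ** 2
    slope = (s_yy - lambda_ * s_xx + math.sqrt(disc)) / (2 * s_xy)
    intercept = mean_y - slope * mean_x
    resid = y - (intercept + slope * x)
    s_res = math.sqrt(float((resid ** 2).sum()) / (pairs.n - 2))
    return DemingFit(slope=float(slope), intercept=float(intercept),
                     lambda_=float(lambda_), s_res=s_res, n=pairs.n,
                     mean_x=float(mean_x), sxx=s_xx)


def prediction_band(fit: DemingFit, x0: float,
                    level: float = 0.95) -> tuple[float, float]:
    """95%-style prediction interval in y for a new sample at ``x0``."""
    df = fit.n - 2
    if df < 1:
        raise ValueError("prediction band needs n >= 3")
    centre = fit.predict(x0)
    if fit.s_res == 0.0:
        return centre, centre  # degenerate: band collapses to the line
    t_q = stats.t.ppf((1 + level) / 2, df)
    half = t_q * fit.s_res * math.sqrt(
        1 + 1 / fit.n + (x0 - fit.mean_x) ** 2 / fit.sxx)
    return centre - half, centre + half


def paired_difference(
    material: MaterialPoint, denominator: str = "reference",
    threshold_pct: float = COMPATIBILITY_THRESHOLD_PCT,
) -> tuple[float, float, bool]:
    """Mean difference of the field method from the reference, with the
    <=5% compatibility verdict.

    ``denominator`` selects the percent base: ``"reference"`` (x_mean,
    default) or ``"meter"`` (y_mean).
    """
    diff = material.y_mean - material.x_mean
    base = {"reference": material.x_mean,
            "meter": material.y_mean}.get(denominator)
    if base is None:
        raise ValueError("denominator must be 'reference' or 'meter'")
    pct = 100.0 * abs(diff) / base
    return diff, pct, pct <= threshold_pct


def classify_commutability(
    fit: DemingFit, material: MaterialPoint, level: float = 0.95,
    denominator: str = "reference", tukey_p: float | None = None,
) -> CommutabilityVerdict:
    """Band verdict plus mean-difference compatibility for one material."""
    lower, upper = prediction_band(fit, material.x_mean, level)
    diff, pct, compatible = paired_difference(material, denominator)
    return CommutabilityVerdict(
        material_id=material.material_id,
        commutable=lower <= material.y_mean <= upper,
        band_lower=lower, band_upper=upper, y_mean=material.y_mean,
        diff=diff, diff_percent=pct, compatible=compatible,
        tukey_p=tukey_p)


def _tukey_p_value(diff: float, se_mean: float, k: int, df: int) -> float:
    """Tukey HSD p for one pairwise contrast: studentized-range tail of
    q = |diff| / se_mean among k group means on df error df."""
    if se_mean == 0.0:
        return 0.0 if diff != 0 else 1.0
    q = abs(diff) / se_mean
    return float(stats.studentized_range.sf(q, k, df))


def characterize_materials(
    replicates: Mapping[str, Mapping[str, Sequence[float]]] | pd.DataFrame,
    reference_method: str,
    include_interaction: bool = False,
) -> tuple[pd.DataFrame, dict[tuple[str, str], float]]:
    """Characterise materials per method and compare methods to the
    reference by two-way ANOVA with Tukey HSD.

    Parameters
    ----------
    replicates
        Either a nested mapping ``method -> material -> values`` or a
        tidy frame with columns material_id, method, value.
    reference_method : str
        Method against which Tukey contrasts are reported.
    include_interaction : bool
        Add a method x material interaction to the ANOVA (off by
        default; with it on, the error df shrink accordingly).

    Returns
    -------
    (table, tukey_p)
        ``table`` has one row per method x material cell (mean, sd, n);
        ``tukey_p`` maps (method, material='*') pooled method contrasts:
        keyed by (method, reference_method).
    """
    if isinstance(replicates, pd.DataFrame):
        df = replicates.rename(columns={"value_mg_dl": "value"})
    else:
        recs = [{"material_id": m, "method": meth, "value": float(v)}
                for meth, mats in replicates.items()
                for m, vals in mats.items() for v in vals]
        df = pd.DataFrame.from_records(recs)
    methods = sorted(df["method"].unique())
    if reference_method not in methods:
        raise ValueError(f"reference method {reference_method!r} absent")
    if len(methods) < 2:
        raise ValueError("need at least 2 methods")
    cell_n = df.groupby(["method", "material_id"])["value"].count()
    if (cell_n < 2).any():
        bad = cell_n[cell_n < 2].index[0]
        raise ValueError(f"cell {bad} has a single replicate")

    table = (df.groupby(["method", "material_id"])["value"]
               .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
               .reset_index())

    import statsmodels.formula.api as smf
    formula = ("value ~ C(method) * C(material_id)" if include_interaction
               else "value ~ C(method) + C(material_id)")
    model = smf.ols(formula, data=df).fit()
    mse = float(model.mse_resid)
    df_resid = int(model.df_resid)

    method_means = df.groupby("method")["value"].mean()
    method_ns = df.groupby("method")["value"].count()
    k = len(methods)
    tukey_p: dict[tuple[str, str], float] = {}
    for meth in methods:
        if meth == reference_method:
            continue
        # balanced-design HSD standard error of a single group mean
        n_h = 2.0 / (1.0 / method_ns[meth] + 1.0 / method_ns[reference_method])
        se_mean = math.sqrt(mse / n_h)
        diff = float(method_means[meth] - method_means[reference_method])
        tukey_p[(meth, reference_method)] = _tukey_p_value(
            diff, se_mean, k, df_resid)
    return table, tukey_p


@dataclass(frozen=True)
class DemingResults:
    """Fitted commutability assessment for one method pair."""

    fit: DemingFit
    level: float
    verdicts: tuple[CommutabilityVerdict, ...]
    x_method: str
    y_method: str

    @property
    def n_commutable(self) -> int:
        return sum(v.commutable for v in self.verdicts)

    def summary(self) -> pd.DataFrame:
        rows = [v.summary_row() for v in self.verdicts]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "x_method": self.x_method, "y_method": self.y_method,
            "slope": self.fit.slope, "intercept": self.fit.intercept,
            "lambda": self.fit.lambda_, "s_res": self.fit.s_res,
            "n_pairs": self.fit.n, "level": self.level,
            "verdicts": [v.summary_row() | {"commutable": v.commutable,
                                            "compatible": v.compatible}
                         for v in self.verdicts],
        }


class DemingRegression:
    """Commutability model: Deming fit on native pairs, band verdicts on
    candidate materials.

    Parameters
    ----------
    pairs : PairedSampleSet
        Native-sample method pairs (reference x, field y).
    lambda_ : float or "estimate"
        Error-variance ratio Var(y-err)/Var(x-err); ``"estimate"``
        derives it from replicate SDs carried by the materials.
    level : float
        Prediction-band coverage for the commutability verdict.

    Examples
    --------
    >>> from commutakit import DemingRegression, PairedSampleSet
    >>> pairs = PairedSampleSet([("s1", 50, 52), ("s2", 100, 98),
    ...                          ("s3", 150, 151), ("s4", 200, 197)])
    >>> res = DemingRegression(pairs).fit()
    >>> round(res.fit.slope, 2)
    0.98
    """

    def __init__(self, pairs: PairedSampleSet,
                 lambda_: float | str = 1.0, level: float = 0.95,
                 denominator: str = "reference"):
        self.pairs = pairs
        self.lambda_ = lambda_
        self.level = level
        self.denominator = denominator

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "DemingRegression":
        return cls(PairedSampleSet.from_frame(df), **kw)

    def _resolve_lambda(self, materials: Sequence[MaterialPoint]) -> float:
        if self.lambda_ != "estimate":
            return float(self.lambda_)
        pts = [m for m in materials if m.x_sd > 0 or m.y_sd > 0]
        if not pts:
            return 1.0
        vy = np.mean([m.y_sd ** 2 for m in pts])
        vx = np.mean([m.x_sd ** 2 for m in pts])
        return float(vy / vx) if vx > 0 else 1.0

    def fit(self, materials: Sequence[MaterialPoint] = (),
            tukey_p: Mapping[str, float] | None = None) -> DemingResults:
        lam = self._resolve_lambda(materials)
        dfit = deming_fit(self.pairs, lam)
        verdicts = tuple(
            classify_commutability(
                dfit, m, self.level, self.denominator,
                None if tukey_p is None else tukey_p.get(m.material_id))
            for m in materials)
        return DemingResults(fit=dfit, level=self.level, verdicts=verdicts,
                             x_method=self.pairs.x_method,
                             y_method=self.pairs.y_method)
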