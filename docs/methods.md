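# Methods

This note records the statistical models the package implements, the
conventions and numerical choices behind them, and what the synthetic
data generators do and do not emulate.

## Scope and model overview

The package covers the qualification life cycle of a processed blood
material (PBM) used as a control or proficiency-testing item for blood
glucose: vials of stabilised whole-blood-like material whose glucose
concentration must be (i) homogeneous across the batch, (ii) stable
over the distribution period, (iii) commutable with native patient
samples between a reference measurement procedure and the glucose
meters under evaluation, and (iv) usable as a scoring target in a
proficiency-testing (PT) scheme. All concentrations are mg/dL; a
mmol/L conversion (factor 18.016) is provided but never applied
implicitly.

## Homogeneity

Between-vial homogeneity is adjudicated by a single-factor ANOVA over
vials on a balanced a x n design (default emulating 15 vials in
duplicate). The batch is *adequate* when `F = MS_among / MS_within`
is below the upper-alpha F quantile at (a-1, a(n-1)) degrees of
freedom. The reported CV uses the SD of all individual results over
the grand mean — a between-samples spread summary — rather than the SD
of vial means; this is stated in every report.

Variance components follow the reference-material convention:
`s_r = sqrt(MS_within)`, `s_bb = sqrt(max(0, (MS_among-MS_within)/n))`,
and the between-vial uncertainty is `u_bb = max(s_bb, u*_bb)` with
`u*_bb = sqrt(MS_within/n) * (2/df_within)^(1/4)`, the resolution floor
that prevents an under-powered study from reporting an implausibly
small uncertainty. Unbalanced tables are rejected with the offending
vial named rather than approximated by REML: the basic formulas assume
balance and the verdict stays auditable.

Before the ANOVA, vials with outlying replicate variance are screened
by an iterative Cochran C test at the same alpha (default 0.05). The
critical value uses the exact F-based closed form
`C = [1 + (k-1)/F_{alpha/k}(n-1, (k-1)(n-1))]^{-1}`, which we verified
against classical Cochran tables (e.g. 0.8413 vs the tabulated 0.8412
at k=5, n=2) before trusting it. The max-variance vial is removed and
the screen repeats until nothing is flagged or fewer than three vials
remain.

A note on critical values: published homogeneity tables for the 15-vial
duplicate design sometimes print F criticals near 3.0, which does not
correspond to F(0.05, 14, 15) ≈ 2.42. This package always computes the
critical value from the declared design and level; no tabulated
constant is hard-coded.

## Stability and shelf life

The degradation model is a straight line in storage day, fitted by OLS
to individual vial measurements (not day means), so the residual SD
represents single-measurement scatter. Stability at a checkpoint day
is a cumulative-window slope test: all checkpoint measurements up to
that day enter the fit and `t = |b1|/se(b1)` is compared with the
two-sided Student-t critical at `n-2` df. With 5 values per day and
checkpoints at days 30..180, the critical sequence at test days
60/90/120/150/180 is 2.31/2.16/2.10/2.07/2.05 (df 8/13/18/23/28).

Two design choices matter here. First, day-0 records are excluded from
the cumulative windows by default (`include_baseline=False`); the
baseline anchors acceptance limits, and this membership is what yields
df = 8 at the first test day. Second, the checkpoint set is
configuration, not a constant — schedules drift in practice (a day may
be added or dropped mid-study), so windows are defined by the
configured list, with the distinct days present as the default. A
per-day Welch comparison of each day against day 0 is available as an
alternative mode.

Shelf life is the first day at which the two-sided prediction band for
a single new measurement,
`b0 + b1*t ± t_{(1+level)/2, n-2} * s_res * sqrt(1 + 1/n + (t - t̄)²/S_tt)`,
leaves the acceptance limits. Crossings are found by a 0.1-day grid
scan with Brent refinement (well below the 0.1-day tolerance quoted in
reports). Acceptance limits have no default: they are a product
decision (absolute mg/dL or percent of the day-0 fit) and must be
supplied explicitly. The instability uncertainty over a horizon T is
`u_sta = se(b1) * T`, zero at T = 0 and linear in T.

Degenerate inputs: a perfect line with zero slope is stable (t = 0); a
perfect line with nonzero slope is certain drift and is flagged with an
infinite-t sentinel — zero residual scatter around a sloping line is
unambiguous. A zero-residual fit collapses the band to the line and
disables shelf-life search.

## Commutability

A material is commutable between the reference method (x) and a meter
(y) when its (x̄, ȳ) point lies inside the level-95% prediction band of
a Deming regression fitted to native-sample pairs. Deming regression
is errors-in-variables: with `lambda = Var(y-error)/Var(x-error)` and
centred moments s_xx, s_yy, s_xy,

    slope = [s_yy - λ·s_xx + sqrt((s_yy - λ·s_xx)² + 4λ·s_xy²)] / (2·s_xy)

This convention is fixed throughout the package and is verified by its
two analytic limits: λ→∞ recovers OLS of y on x (all error in y) and
λ→0 recovers s_yy/s_xy (all error in x). λ defaults to 1 (orthogonal
regression) because replicate error variances for native pairs are
rarely available; when material replicate SDs are supplied, λ can be
estimated as the ratio of mean replicate variances.

The band uses the SD of vertical residuals around the Deming line with
OLS-style leverage — the single band in y conventionally drawn on
method-comparison plots. Jackknife-based slope/intercept variance
bands are deliberately out of scope in this version. The band boundary
is inclusive: a point exactly on the limit is commutable.

The band's nominal error rate assumes homoscedastic residuals. Real
meter noise is partly proportional to concentration, so the pooled
residual SD over a wide native range makes the band conservative at
mid-range levels (observed false-flag rates of ~1% instead of 5% in
simulations with a 2% proportional CV). Likewise the band covers a
*single* new observation: a material characterised by the mean of n
replicates has variance reduced by 1/n and is flagged far less often
than nominal. The simulation suite therefore measures the nominal rate
with constant-SD noise and single-measurement characterisation; with
replicated characterisation the verdict errs on the side of calling
materials commutable.

Separate from the band verdict, each material carries a mean-difference
classification: compatible when |ȳ - x̄| is at most 5% of the reference
mean (threshold and denominator configurable; the reference denominator
is the default, the meter-mean denominator selectable). Method-level
characterisation uses a two-way fixed-effects ANOVA (method + material,
no interaction by default — the interaction df are better spent on the
error term at typical replicate counts) with Tukey HSD p-values for
each meter against the reference method from the studentized-range
distribution; significance marks use the conventional * p<0.05 and
** p<0.001.

## Proficiency-testing performance

The robust consensus of a meter group is the iterative-winsorization
robust mean/SD: start at the median and 1.483·MAD, then repeatedly
winsorize into x* ± 1.5·s*, recompute x* as the winsorized mean and s*
as 1.134 times the winsorized SD (n-1 denominator), until both change
by less than 1e-6 relative (max 100 iterations). An all-identical
sample short-circuits with a degenerate flag and zero robust SD; if the
MAD is zero but values differ, the classical SD seeds the iteration.

Each participant result is scored against a target by the glucose-meter
system accuracy rule: within 15 mg/dL when the target is below
100 mg/dL, within 15% of the target at or above. At a target of
exactly 100 the two branches coincide (15% of 100 = 15 mg/dL); the
relative branch is used and the choice is value-identical. Percentages
are reported at 1 decimal with half-up rounding; rounding happens only
at render time. The group-vs-reference significance mark comes from a
two-sided one-sample t of participant values against the target value;
a Welch two-sample mode against reference replicates is available when
those replicates exist.

## Synthetic data

The generators emulate the campaign the analysis assumes: 30 native
samples uniform over 60–350 mg/dL (uniform rather than lognormal so
leverage is even across the band; configurable), reference-method SD
1 mg/dL, meters with linear response and noise
`sqrt(sd_const² + (cv_prop·truth)²)`, 15 vials x 2 replicates for
homogeneity, and 5 values per checkpoint day at days 0–180 for
stability. Default dispersions (σ_bb = 0.5, σ_r = 1.5 mg/dL, i.e. a
~1.2% CV at 120 mg/dL; drift −0.02 mg/dL/day; participant CV 3.5%)
were chosen once as realistic for amperometric meters on stabilised
material. Matrix effects are additive or proportional perturbations
applied only to meter readings of processed material — the mechanism
that makes a processed material non-commutable while native samples
are unaffected. Meter presets spanning −20% to +16% bias ship for
demonstrations; they are illustrative, not calibrations of any real
device.

All randomness flows through one integer seed via independent named
streams, so regenerating one input kind never perturbs another and
equal seeds give byte-identical CSVs.

What the generators do not emulate: physiological glucose dynamics,
hematocrit/temperature interference, non-linear meter response,
day-to-day calibration drift of participants, and non-normal noise
other than planted gross outliers. Passing simulation suites therefore
demonstrate the statistical machinery under its stated assumptions, not
meter behaviour on real blood.

## Bundled example data

`commutakit.datasets` ships the printed characterisation (mean ± SD per
method and material) and PT satisfaction tallies of a two-material,
five-meter glucose study as a small example dataset. These are summary
statistics, not raw measurements; they exercise the reporting paths
(mean differences, compatibility letters, percentage formatting)
exactly. Printed percent deviations in such tables are typically
computed from unrounded means, so reproductions from rounded means can
differ in the percent column while the integer mean differences
reproduce exactly — both denominators are supported and the reference
denominator is the default.

## Problem sizes and tolerances

Monte-Carlo suites use 2000 replicates for error-rate and coverage
checks (binomial SE ≈ 0.5% at rates near 5%), 500 replicates for
parameter-recovery means, and n = 500 for single-fit recovery; these
sizes give comfortable margins at the asserted tolerances while keeping
the full suite around a minute on one core. Numerical tie-breaks and
tolerances: relative convergence 1e-6 in the robust procedure,
shelf-life crossings to 0.1 day, iterative Cochran screening stops
below 3 vials.

## Known limitations

- Unbalanced homogeneity designs are rejected, not analysed.
- The commutability framework is the prediction-band style; the newer
  difference-in-bias framework with uncertainty-based criteria is not
  implemented.
- Deming bands ignore slope/intercept estimation error beyond the
  leverage term (vertical-residual band), which is slightly
  anti-conservative far outside the native range.
- PT scoring implements the accuracy-rule satisfaction tally and
  t-test marks only; z/zeta/En scores and error-grid analyses are out
  of scope.
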