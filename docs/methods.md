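# Methods

## The vulnerability framework

The package scores each nation's grazing-livestock food system on three
indices and combines them into a single relative vulnerability. Sensitivity
(S) captures nutritional reliance on home-produced grazing-animal products
and current food security; exposure (E) captures the magnitude of projected
climate change and population growth; adaptive capacity (AC) captures the
ability to cope, via health, economy and governance. The model is
deliberately static: exposure does not feed back into S or AC (there is no
defensible quantitative basis for predicting how governance or GDP respond
to climate change per nation), and robustness to such future shifts is
instead explored with the perturbation grid described below.

## Indicator preparation

**Scaling.** Every indicator is scaled linearly over the cohort:
`(x − min)/(max − min)`, so 0 and 1 are the observed extremes. Values are
*not* normalised to any distribution — a heavy-tailed indicator such as
total GDP legitimately concentrates most nations near 0. Each indicator
carries a polarity flag; `lower` polarity reverses the scaled score
(`1 − scaled`) so that a higher score always means more of the index
construct (e.g. life expectancy and under-5 mortality both end up pointing
toward higher adaptive capacity / lower adaptive capacity consistently).
A constant indicator has no defined scaling and is reported as a zero-range
error for the caller to drop.

**Category reduction.** Categories with several candidate indicators are
reduced to one: each member is scored by its mean |Spearman ρ| (midranks on
ties, pairwise-complete observations) against the other members, and the
highest-scoring member is retained. Absolute ρ is used because an indicator
that inversely tracks its category is equally informative; a config switch
(`absolute_correlation=False`) restores signed ρ. Exact ties — inevitable
for two-member categories, where the two means are identical by symmetry —
go to the first-listed member and are logged.

**Climate composite.** The three climate members are not redundant measures
of one construct and are combined rather than reduced:
`cc_raw = |Δt|·|Δp|·w`. Absolute values encode that the *degree* of change
matters regardless of direction; the multiplication by w weights change by
demonstrated historical impact. A consequence, preserved deliberately, is
that a nation with `w = 0` scores `cc = 0` however large its projected
change; such nations are logged.

**Other primitives.** Livestock-unit conversion is the linear form
`LU = Σ count_s · coeff_s` with a reference cow at 1.0 and sheep at 0.15;
the remaining default coefficients (buffalo 1.0, goat 0.10, camel 1.10,
horse 0.80, donkey 0.50, mule 0.60) are nominal values overridable from a
two-column CSV. The self-sufficiency ratio is
`(production − exports)/(production − exports + imports)`; when exports
exceed production (re-export artefacts), net production is clamped to zero
with a warning, giving a ratio of 0; a zero denominator (no apparent
consumption) marks the nation missing.

**Missing data.** The default policy is listwise exclusion of nations with
any missing minimal indicator, matching the exclusion-based construction of
the original cohort; median imputation per indicator is available as a
config switch. Validation is report-only and never mutates the table.

## Index composition and models

S, E and AC are equal-weight means of their category scores, min-max
rescaled over the cohort. The additive model uses `V_raw = S + E − AC`;
since the final rescaling is invariant to positive-affine maps, this is
identical to the "average of S, E and (1 − AC)" formulation. The
multiplicative model defaults to `V_raw = S·E·(1 − AC)`: AC must reduce
vulnerability, and the pure product makes extreme index values dominate. A
ratio alternative `S·E/(AC + ε)` (ε = 0.01) is available; both are
rescaled, so the choice only affects ordering. Ranks are descending in V
with the minimum-rank convention for ties (ties arise naturally in the
multiplicative model, where the S-minimum and E-minimum nations both score
exactly zero); ties are logged.

**Scenario variants.** "Climate only" and "population only" freeze the
other exposure driver. Frozen means replaced by its cohort mean (default),
which removes its between-nation variance while keeping E on a comparable
scale; a `drop-term` policy that builds E from the varying driver alone is
available for sensitivity checks. "Held constant" could also have meant a
reference-year value or zeroing; the cohort-mean reading was chosen because
it is the only one that leaves a cohort with an already-constant driver
bit-identical to the combined model.

## Aggregation and statistics

Extremes are the `ceil(fraction·n)` highest- and lowest-ranked nations
(tenth percentile of 148 → 15 a side; the ceiling rule is the only one
consistent with that count). Group summaries are population-weighted means
of the rescaled scores, ranked descending. Indicator influence is Spearman
ρ with two-sided p-values at α = 0.05. Model agreement is a Wilcoxon
signed-rank test on paired per-nation values: zero differences are dropped
before ranking (so N can fall below the cohort size), the statistic is the
sum of positive-difference ranks (the V of R's `wilcox.test`), and the
two-sided p-value is exact (full enumeration of sign assignments,
midrank-safe) for n ≤ 15 and a tie-corrected normal approximation
otherwise. The comparison defaults to scores; passing ranks is equally
valid and often more informative, because the multiplicative model shifts
mid-range scores systematically even when the ordering barely moves.

## The perturbation grid

S and AC are varied from −100% to +100% of their baseline values in 10%
increments — multiplicative perturbation of the *composite indices*, not of
their component indicators — with results clamped to [0, 1] (clamps
logged) and E left at its projected values. Percent change per nation is
computed on **baseline anchors**: the simulated raw V is rescaled with the
baseline cohort min and max, not per cell. Per-cell rescaling would cancel
any cohort-wide perturbation exactly (rescaling is affine-invariant) and
make every median zero; anchoring is the only reading under which uniform
scenarios produce non-zero medians. Nations whose baseline rescaled V falls
below a floor (default 0.01 — e.g. the least vulnerable nation, which
rescales to exactly 0) are excluded from the medians, since percent change
from ≈0 is unbounded; exclusions are counted per cell. The origin cell is
identically 0%, and medians are monotone non-decreasing in ΔS and
non-increasing in ΔAC for the additive model.

## Synthetic data generator

The generator provides cohorts with the statistical structure the pipeline
assumes and a known answer sheet. Per nation it draws latent standard
normal z_S, z_E, z_AC with corr(z_S, z_AC) = −0.4 by default (highly
sensitive nations tend to have low adaptive capacity, as the published
extremes show) and z_E independent. Each category observes its parent index
with noise `noise_sd`; each redundant member of a category adds indicator
noise τ calibrated from the target intra-category Spearman ρ via the
bivariate-normal identity ρ_s = (6/π)·asin(r/2) with r = 1/(1+τ²). Members
are mapped through strictly monotone, unit-bearing marginal transforms
(ratios in [0, 1], prevalences in %, life expectancy in years, lognormal
GDP, WGI-style governance scores in ±2.5, population growth spanning −15%
to +175% so negative growth occurs, precipitation change with mixed signs,
extreme-weather share in [0, 60]%). Populations are lognormal
(μ = 16, σ = 1.3, median ≈ 9 M); group labels follow proportions of a
realistic 148-nation cohort, with the food-deficit probability rising with
latent sensitivity.

Defaults — 148 nations, 3 indicators per category, intra-category ρ = 0.8,
noise_sd = 0.05 — are fixed study conditions, not tuning knobs. Ground
truth stores the noiseless-pipeline composites: with `noise_sd = 0` and one
indicator per category the pipeline reproduces them exactly (the
zero-noise identity used in tests); at the default noise the recovered
vulnerability ordering correlates with truth at Spearman ρ ≈ 0.96
(threshold 0.9, pre-validated over 20 seeds at n = 100). The generator does
*not* imitate real per-indicator marginal distributions, real spatial or
trade structure, or realistic correlation between group labels and
indicators beyond the food-deficit link — so passing recovery tests show
the pipeline's arithmetic and reduction logic are sound under the assumed
copula structure, not that real-world indicator quality is sufficient.

## Numerical choices and limitations

* Min-max scaling needs ≥ 2 observed values and positive range; violations
  raise typed errors rather than propagating NaN.
* Reduction ties use exact comparison at 1e-12 and fall to declared order.
* The exact Wilcoxon path enumerates 2^n assignments (n ≤ 15: ≤ 32768).
* Grid problem size: 441 cells × cohort-size vector arithmetic; a full
  148-nation run of every stage completes in seconds.
* Published-score reproduction is limited by the two-decimal rounding of
  the printed inputs: every recomputed V lands within ±0.02, but adjacent
  nations whose printed scores differ by ≤ 0.01 can swap ranks. The tests
  therefore assert exact membership of the extreme groups and correct
  pairwise ordering wherever printed scores differ by more than 0.02.
* Relative, cohort-internal scores: V = 0 means least vulnerable *within
  the cohort*, not invulnerable; scores are not comparable across cohorts.
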