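# Methods

This note documents the statistical procedures the package implements, the
modeling choices made where the design was genuinely open, the synthetic
data generator's assumptions, and known limitations. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Trait spaces

A *trait space* for a social category is the Pearson correlation matrix
among trait ratings of members of that category. The correlation unit is
design-dependent and is made explicit by an enum:

- **targets** — between-subjects face ratings: each rater contributes a
  single trait, so ratings are first aggregated to unweighted target-level
  means and correlations are taken across targets. Weighting targets by
  their number of contributing ratings is *not* done; with unequal cell
  counts this can move third-decimal digits, and the unweighted mean keeps
  the estimator simple and auditable.
- **perceivers** — abstract category ratings: correlations across
  participants' ratings of the category itself.
- **within_perceiver_targets** — within-subjects face ratings:
  correlations across one perceiver's own targets in a group.

At least 3 complete units per trait pair are required (Pearson is
degenerate below that); a pair with zero variance in either trait is marked
missing rather than fabricated, and missing values propagate with logged
counts and pairwise deletion downstream.

Matrices are reduced to the strictly-upper-triangular trait-pair vector in
row-major order of the declared trait list. The declared order is the
14-trait alphabetical list for the between-subjects design and the 6-trait
list for the within-subjects design; no source specifies an order, so one
canonical order is fixed for determinism. Fisher's variance-stabilizing
z = arctanh(r) is applied at the pair level after vectorization; |r| = 1
(possible in small within-perceiver samples) is clamped to 1 − 10⁻¹² rather
than rejected. Per-group vectors are stacked in declared group order
(6 groups × 91 pairs = 546 rows for 14 traits).

**Per-pair centering.** Subtracting each trait pair's mean across the six
categories — independently within the face stack and within the stereotype
stack — removes structure shared by all categories (e.g. dominance and
strength correlating everywhere), so the similarity statistic reflects only
group-specific deviations. Centering an already-centered stack is a state
error, preventing accidental double centering.

## Space similarity

Because the stacked values are themselves correlations, the comparison uses
Spearman's ρ (rank-based, invariant to monotone distortion of the Fisher
scale) rather than Pearson. Ranks use average-rank ties; the p-value is an
exact permutation enumeration for n ≤ 9 and the t approximation otherwise.

The 95% CI construction is not dictated by any single convention, so two are
offered and the result records which was used: a seeded percentile
bootstrap over rows (default, 10,000 resamples) and a Bonett–Wright normal
approximation on the arctanh scale with SE = √((1 + ρ²/2)/(n − 3)). Rows
within a trait pair are not independent across groups, so the row bootstrap
is approximate; the permutation null (shuffling group labels within each
trait pair, which respects the exchangeability actually at issue) is the
preferred inferential check and is what the acceptance script reports.

## Homogeneity ANOVA

The uncentered z-scale stack is pivoted to trait pairs × groups (91 × 6)
and analyzed as a 2 (gender) × 3 (race) fully within-subjects ANOVA with
the trait pair as the blocking unit. Sums of squares use the classical
fully-within partition; each effect is tested against its own
pair-by-effect interaction error term; partial η² = SS_effect /
(SS_effect + SS_error). Incomplete rows are listwise-deleted with a logged
count (repeated-measures completeness), and at least 3 complete rows are
required.

Mauchly's W uses the likelihood-ratio form on orthonormalized contrast
scores with the standard χ² approximation (df = 2 for the race factor);
Greenhouse–Geisser ε comes from the eigenvalues of the contrast-score
covariance, and GG-corrected p-values multiply both df by ε. A two-level
factor has a single difference variance, so sphericity holds trivially
(ε = 1, Mauchly skipped). The implementation is validated against
pingouin's two-way repeated-measures ANOVA and sphericity test in the
suite; it is computed in-package because the result contract requires
per-effect error SS and per-effect Mauchly statistics that pingouin does
not expose.

**Analysis scale.** The pipeline stacks Fisher-z values and the ANOVA runs
on z; marginal means are reported both on z and back-transformed through
tanh to the correlation scale (the scale on which "average trait-pair
correlation" is interpretable). tanh of a mean z is not the mean of r, so
the back-transformed means are a transformation of the z-scale analysis,
not a separate r-scale analysis; a switch allows running the ANOVA on raw r
instead. Margin SEs are the between-pair variability of each margin's
per-pair mean (divided by √n), with t-based CIs.

## Cross-classified multilevel model

Each analysis row is one perceiver × race group × trait pair: the outcome
is the perceiver's Fisher-z face-rating correlation for that pair and
group; the predictor is the perceiver's pairwise stereotype-likelihood
rating for the same pair and group. The two directed question forms
("how likely is an aggressive X to be attractive" and the reverse) are
averaged into one undirected rating by default (pairs are undirected and
question order is randomized in the designs this serves); a flag keeps them
separate. The predictor is centered within perceiver (CWC), its
perceiver mean entering as a grand-mean-centered Level-2 predictor so the
intercept remains the grand mean.

Random structure: crossed random intercepts for perceiver and trait pair
plus an independent perceiver random slope on the CWC predictor; no
intercept–slope covariance (the model equations list independent residual
terms; an unstructured block is out of scope). Estimation is REML via an
in-package profiled-deviance fitter for mutually independent variance
components on sparse crossed designs (the same profiling lme4 uses:
penalized least squares through the blocked normal equations, one sparse
factorization per objective evaluation, L-BFGS-B over
standard-deviation ratios with deterministic multi-starts and a
Nelder-Mead polish on small problems). Convergence tolerance is 10⁻⁸ on
the relative REML criterion. The fitter is validated in the suite against
statsmodels MixedLM on small crossed instances and against the closed-form
balanced two-way random-effects ANOVA estimators (agreement ~10⁻⁸). A
slope variance estimated on the zero boundary triggers a refit without the
slope component and a `slope_dropped` flag.

Inference on fixed effects is Wald (z): cross-classified Satterthwaite df
are out of scope, and with thousands of observations the normal reference
is adequate. The standardized slope is γ100 · SD(x_cwc)/SD(y) over the
analysis rows.

**Variance partitions.** Intercept-only models give ICCs: each component's
variance over total. For the stereotype outcome a perceiver × pair
interaction component is added (identified because each perceiver rates
each pair once per race group). The full model's integrated R² splits
model-implied variance into γ100²·var(x_cwc) (fixed within),
γ010²·var(x_pmean) (fixed between), τ_slope·E[x_cwc²] (random slope),
τ_perceiver + τ_pair (both crossed intercepts pooled into the intercept
share), and σ² (residual); shares sum to 1 by construction. All five
shares are reported separately rather than pooled, since poolings like
"between-perceiver plus trait-pair variance" are ambiguous.

## Synthetic data generator

The generator emulates the statistical skeleton of the two designs, not
their demographic or stimulus composition.

**Structures.** A shared base correlation matrix is drawn from a two-factor
model (one general positive factor, one bipolar factor), giving mostly
positive trait-pair correlations (mean r ≈ 0.26, across-pair Fisher-z SD
≈ 0.21 — chosen so that trait-pair heterogeneity produces a trait-pair
variance share of the outcome in the empirically typical range). Each
group's face structure perturbs the base on the Fisher-z scale of the
off-diagonals (SD `sigma_group_scale`, default 0.15) and is repaired to a
valid correlation matrix by eigenvalue clipping and diagonal
renormalization. The stereotype structure is κ·face + (1−κ)·independent
perturbation, projected back to a correlation matrix; κ = 1 reproduces the
face structure exactly, κ = 0 makes group-specific deviations independent.

**Between-subjects mode.** Targets carry latent trait vectors from their
group's face structure; a rating is 4 + latent + rater bias + noise,
rounded and clipped to 1–7 when `likert` is set (round-then-clip is the
simplest monotone map; the coarsening attenuates recovered correlations,
which recovery tolerances account for). Each face rater is assigned one
trait and one target gender (between-subjects trait assignment), with
8 raters per gender × trait cell by default. Abstract raters rate every
group on every trait with latents from the group's stereotype structure.

**Within-subjects mode.** Each perceiver rates 10 targets per race group
(one target gender per perceiver) on all 6 traits. The perceiver's
stereotype z for a (group, pair) is the population structure plus a
perceiver-level shift (SD 0.18), a perceiver × pair deviation shared
across groups (SD 0.2), and a group-specific deviation (SD 0.33); these
three knobs realize perceiver / pair / interaction variance in the
stereotype outcome. Pairwise ratings map the personal z affinely onto 1–7
(4 + 2z, i.e. [−1.5, 1.5] → [1, 7], invertible on the interior) and are
asked in both directions. The perceiver's face-space z for a pair equals
the group face structure plus a perceiver shift (SD 0.08) plus the
perceiver's own slope (γ + N(0, 0.02)) times the perceiver's *centered
emitted* stereotype rating — so the regression truth is the planted slope
itself, up to the attenuation from rating noise (SD 0.25) and Likert
coarsening (≈ 10–15% combined, verified by the recovery suite). The
within-subjects preset fixes κ = 0: with coupled group structures the
group-level association would load onto the within-perceiver slope and the
plant would not be identified.

Default variance parameters are a *calibration*, not ground truth: they
were chosen so the intercept-only partitions land in the empirically
typical range (outcome ICCs near 0.04 / 0.26; stereotype partitions near
0.11 / 0.19 / 0.13), since perceiver-level variance magnitudes are not
otherwise constrained.

One seed fans out through named substreams (structures, targets, face
raters, abstract raters, perceivers), so identical configurations are
byte-identical and components are independently reproducible.

**What passing tests show — and don't.** Recovery results on this
generator demonstrate that the estimators are consistent and approximately
unbiased *under the generator's assumptions*: Gaussian latents, monotone
Likert coarsening, independent random effects, exchangeable targets. Real
rating data add features the generator omits — shared target-level
variance across perceivers in the within-subjects mode, response styles
beyond an additive bias, missing data mechanisms, response-time-quality
interactions — so passing recovery tests does not certify unbiasedness on
real data, only correctness of the implementations.

## Numerical choices and problem sizes

- Fisher transform clamps |r| = 1 at 1 − 10⁻¹²; correlation repair clips
  eigenvalues at 10⁻⁸; Cholesky draws add 10⁻¹⁰ jitter.
- Spearman p-values switch from exact enumeration to the t approximation
  above n = 9.
- REML ratios are bounded in [0, 10³]; a component below ~10⁻⁴ of the
  largest ratio is flagged as a boundary (singular) fit.
- The acceptance script runs one full-size within-subjects study
  (181 perceivers, 8,145 rows) and one between-subjects study
  (252 abstract raters, 60 targets per group); heavier Monte-Carlo checks
  in the test suite use 20 seeds at full size for slope bias, 100
  replicates at 60 perceivers for CI coverage, and 20 replicates per κ on
  a 4-point grid for coupling monotonicity — sizes at which each check's
  Monte-Carlo error is comfortably inside its acceptance band.

## Limitations

- The row bootstrap for the Spearman CI ignores within-pair dependence
  across groups; use the permutation null for hypothesis tests.
- Wald intervals for variance components are not provided; boundary
  estimates are flagged but not profiled.
- The cleaning module implements only the printed rules (zero-variance
  responders, opt-outs, optional perceiver-race filter) plus a pluggable
  predicate hook; response-time-based cleaning is deliberately not
  reimplemented.
- Factor-analytic summaries of trait spaces (CFA/EFA/parallel analysis)
  are out of scope by design; the pipeline is model-free at the trait-pair
  level.
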