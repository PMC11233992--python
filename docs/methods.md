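# Methods

This note documents the statistical model behind `ecostatus`, the
choices made where the methodology was genuinely open, and what the
bundled synthetic data can and cannot demonstrate.

## Index battery

All indices operate on one sample's abundance vector n₁…n_S
(individuals·m⁻³, non-negative reals), with N = Σnᵢ, pᵢ = nᵢ/N.
Natural logarithms throughout (Shannon in nats), so exp(H) equals Hill
N1 exactly; Odum's index alone is defined on log₁₀.

Families and formulas (S = observed richness, λ = Σpᵢ², U = √Σnᵢ²):

- **Diversity**: Margalef (S−1)/ln N; Gleason S/ln N; Menhinick S/√N;
  Odum S/log₁₀N; Shannon H = −Σpᵢ ln pᵢ; Hill N0 = S, N1 = e^H,
  N2 = 1/λ; Simpson λ; Brillouin (ln N! − Σ ln nᵢ!)/N via log-gamma;
  McIntosh (N−U)/(N−√N); Camargo 1 − Σ_{i<j}|pᵢ−pⱼ|/S; Hurlbert's PIE
  (N/(N−1))(1−λ); Fisher's α solving S = α ln(1+N/α) (Brent's method,
  residual < 1e−9); Chao2; Kothe's species deficit 100(S_ref−S)/S_ref.
- **Evenness**: E1 = H/ln S (Pielou's J′), E2 = e^H/S,
  E3 = (e^H−1)/(S−1), E4 = (1/λ)/e^H, E5 = (1/λ−1)/(e^H−1), Simpson
  evenness (1/λ)/S, Patten's redundancy (H_max−H)/(H_max−H_min) with
  H_max = ln S and H_min the entropy of the most uneven integer
  partition (N−S+1, 1, …, 1).
- **Dominance**: Berger-Parker max nᵢ/N; McNaughton, percent share of
  the two most abundant species.
- Total abundance ΣN is carried as a *demo* variable, not a diversity
  index.

Index names without one universally fixed formula (Gleason, Odum, "M",
"Pie", "Redundancy", "Camargo") are bound to the canonical published
variants given above; each registry entry records its formula so a user
can check or override the binding. The historical battery name "Tu"
has no recoverable canonical formula and is deliberately not shipped.
The two evenness slots beyond E1/E2/E3/E5 and redundancy are filled
with E4 and Simpson evenness as interpretive defaults.

Numerical conventions:

- Abundances are reals (ind·m⁻³ after volume normalization), so
  formulas requiring integer individual counts (Brillouin, the
  single-sample Chao estimator, redundancy's H_min partition) round
  half-to-even first and log a warning when rounding is lossy.
- Out-of-domain values (E1 at S = 1, Fisher's α at N ≤ S, richness
  ratios at N ≤ 1 …) are stored as NaN — the table-level "undefined"
  marker — and excluded pairwise downstream, never silently zeroed.
- A constant group in screening yields NaN assumption p-values and
  fails the parametric gate (routing to the rank test) rather than
  raising.

### Chao2 per sample

Chao2 is an incidence estimator across m sampling units:
S_obs + ((m−1)/m)·q₁(q₁−1)/(2(q₂+1)), with q₁/q₂ the species present
in exactly one/two units. When a sample carries a replicate-unit
incidence matrix (the synthetic generator emits one; real data may
supply tows or depth layers), the classic multi-unit form is used.
For a lone abundance vector the abundance analogue
S_obs + f₁(f₁−1)/(2(f₂+1)) (f₁/f₂ = species with rounded count 1/2) is
substituted so the per-sample pipeline stays runnable.

### Kothe's reference richness

Kothe's deficit needs an explicit unpolluted baseline S_ref, which the
method itself does not fix. Default: the pooled species richness of
the samples labelled *good* (`reference_richness="auto"`), overridable
with an integer. Note that with any single S_ref the deficit is an
affine function of richness; see the collinearity paragraph below.

## Screening

Group comparison is gated exactly as monitoring practice prescribes:
Shapiro-Wilk on each group and Bartlett across groups, all at α = 0.05;
only if all three pass is the equal-variance Student t-test used
(Bartlett has already vouched for homoscedasticity; Welch is available
by flag). Otherwise the two-sided Wilcoxon rank-sum (Mann-Whitney)
test is applied — exact enumeration when both groups are ≤ 25 and
tie-free, normal approximation with continuity correction otherwise.
Direction of change is read from group means (parametric route) or
medians with mean tie-break (rank route). No multiple-testing
correction is applied by default, matching the screening's exploratory
role (≈ 27 tests at α = 0.05 expects ~1.4 false positives); Holm
step-down is available via `correction="holm"`.

## Ordination

Sensitive indices are z-scored (sample sd, ddof = 1) and the sample
covariance of the standardized matrix eigendecomposed — equivalent to
correlation PCA, making indices on wildly different scales (percent
deficits vs entropies) commensurable. Constant columns are dropped
with a warning; samples with any undefined sensitive index are excluded
(imputation would be invented methodology). Loadings follow a
deterministic sign convention (largest-magnitude loading positive) so
results are platform-reproducible.

## Discriminant scale

Two-class LDA with class-conditional Gaussians and pooled within-class
covariance Σ_w (denominator n−2). The discriminant direction
w ∝ Σ_w⁻¹(μ_good − μ_non-good) is scaled so wᵀΣ_w w = 1: projected
class scores then have unit standard deviation and the score is in
within-class sd units. The quality score of a sample is the
intercept-free linear form w·x, matching the form in which the
published seasonal functions are printed.

Posterior of good status at score s is logistic:

  P(good | s) = expit( ln(π_g/π_n) + (μ̃_g − μ̃_n)(s − (μ̃_g+μ̃_n)/2) )

with μ̃ the projected class means. The score threshold attaining
posterior level ℓ is the closed-form logit inversion; it is strictly
increasing in ℓ and decreasing in π_g — an asymmetric prior
(0.71 non-good / 0.29 good from the 20-vs-8 reference design) makes
the good-status rule stricter, which is the conservative direction for
certification.

Two decision rules coexist deliberately: fitted models assign by
posterior > 0.5 and flag *confident* when the assigned class's
posterior exceeds the level (rule A); the published seasonal functions
carry only a raw-score threshold, so samples above it are good and
confident, and samples below are conservatively non-good and flagged
uncertain (rule B). Published coefficients, thresholds and posterior
levels are stored verbatim and never re-derived — including the annual
Kothe coefficient whose sign differs from its warm/cold analogues; no
"correction" is applied to printed values.

### Collinearity

With a single Kothe reference, Kothe = 100(1 − S/S_ref) is exactly
affine in HillN0 = S, so the default feature trio has a rank-deficient
pooled covariance. A strict fit (`fit_lda` default) raises, because a
silent inversion of a singular matrix is numerically meaningless. The
tolerant mode (`allow_collinear=True`, used by the pipeline and the
resampling validators) computes w on the covariance's range via the
pseudo-inverse (relative eigenvalue cutoff 1e−10) with a logged
warning — the warn-and-continue behavior users of the standard LDA
implementations will recognize. The discriminant direction, scores
and accuracies are unaffected by which of the collinear copies carries
the weight. Strict fits also require ≥ p+1 samples per class; the
tolerant mode only ≥ 2 per class, since resampling draws from small
reference groups routinely produce such splits.

## Resampling validation

Both validators stratify by class: with an 8-sample minority class,
unstratified draws would routinely produce single-class training sets
and silently skew the estimate.

- **Repeated k-fold CV** (default k = 5, 100 repeats): class-stratified
  folds, refit per training split, accuracy pooled over the held-out
  cases of one repetition, averaged over repetitions.
- **Out-of-bootstrap** (default 1000 iterations): per-class resampling
  with replacement at the original class sizes; the model is fit on the
  resample and scored on the never-drawn cases; iterations with an
  empty out-of-bag set or a degenerate (singular) training resample are
  redrawn, capped at 10× the requested iterations.

Accuracy is the overall fraction correct. All randomness flows from
`numpy.random.Generator` seeds; the pipeline splits one run seed into
independent generation/CV/bootstrap streams via `SeedSequence.spawn`.

## Synthetic communities

The generator emulates the reference design of a sewage-gradient
monitoring study; it is the package's test bed, not a mechanistic
plankton model.

| parameter | default | meaning |
| --- | --- | --- |
| n_good / n_non_good | 8 / 20 | reference group sizes |
| richness_good | 30–45 | species per good sample (uniform) |
| richness_non_good | 8–15 | species per non-good sample |
| dominance_k_good | 0.08 | geometric-series parameter, even assemblage |
| dominance_k_non_good | 0.60 | steep series: top-two share k+k(1−k) ≈ 0.84 |
| total_abundance | lognormal, median 2000 ind·m⁻³, log-sd 0.4 | sample total |
| season_mix | 0.5 | fraction of warm-season samples per group |
| replicate_units | 3 | units for the incidence matrix |

The geometric series was chosen over a lognormal because its top-two
cumulative share is analytic — k = 0.6 directly realizes the ≥ 80%
two-species dominance that is the non-good signature — and weakening k
gives a graded contrast for power studies. Species identities come
from a shared 86-taxon pool; the rank-1 taxon is a fixed season-specific
id (warm ≠ cold), emulating the observed seasonal swap between a
dominant cladoceran and a dominant copepod. Counts are an integer
multinomial on the lognormal total (scaled by a nominal filtered volume
of 1 m³), keeping singleton/doubleton logic exact; the total is also
split multinomially across replicate units to build the incidence
matrix.

What the defaults do **not** emulate: overlapping richness ranges,
temporal autocorrelation between cruises, station-level structure,
abundance–richness covariance, or taxonomic turnover beyond the single
dominant swap. Because the two conditions are separable by
construction (disjoint richness ranges), perfect CV/bootstrap accuracy
on the defaults demonstrates that the pipeline *recovers* a designed
signal — it says nothing about effect sizes in real monitoring data.
Screening's false-positive calibration and the power trend in the
dominance contrast are checked separately with overlapping-richness
configurations.

## Season handling

Warm = May–October, cold = November–April; a date maps to exactly one
season, and an explicit season in metadata overrides the date-derived
one (observation campaigns often pre-assign seasons). The pipeline's
`season_scope` filters samples before *every* stage, so annual, warm
and cold analyses are fully parallel; depth-layer integration is out of
scope and inputs are assumed pre-integrated.

## Problem sizes used in the checked examples

The default test suite and the acceptance script run the 28-sample
reference design with the full 26-column battery, 100×5-fold CV,
1000 bootstrap iterations, 1000-replicate null calibration of the
screening gate and 200-replicate power curves over three dominance
contrasts — sizes chosen to match the reference analysis exactly where
it is cheap (CV, bootstrap, PCA) and to give ±1.4-point Monte-Carlo
resolution on the 5% type-I rate.

## Known limitations

- The single-sample Chao estimator is an abundance-based stand-in for
  the incidence form; with few replicate units Chao2 is a minimum-
  richness estimator, not an unbiased one.
- Kothe's deficit inherits whatever arbitrariness is in the reference
  richness; with one reference it adds no information beyond richness
  to a linear classifier (see Collinearity).
- The LDA posterior assumes projected-Gaussian classes with equal
  variance; heavy-tailed index distributions will miscalibrate the
  posterior level even when the assignment is correct.
- No multiple-testing correction by default: the sensitive set's size
  is an exploratory, not confirmatory, statement.
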