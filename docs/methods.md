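# Methods

## Model and partitioning

The observed data are modelled as **Y** = **M**ψ + ε with a full-rank
N × r design **M**; the hypothesis is H₀: **C**′ψ = 0 for a full-rank r × s
contrast **C**, 1 ≤ s ≤ r.  Coefficients are estimated by least squares,
ψ̂ = **M**⁺**Y**, vectorised over the V data columns.

For permutation testing the design is re-expressed as
**Y** = **X**β + **Z**γ + ε.  The partition is not unique; we use the
contrast-driven construction

    X = M (M′M)⁻¹ C (C′(M′M)⁻¹C)⁻¹,      Z = M · Cv,

with Cv an orthonormal basis of the null space of **C**′.  This choice has
the convenient property that β = **C**′ψ exactly (so testing β = 0 in the
partitioned model is the same hypothesis), and the F statistic computed
from either form is identical for any data — an equivalence the test suite
asserts to ~1e−15 on random problems.  When a contrast simply selects
design columns, a `columns` scheme is also available that takes **X** as
the selected columns and **Z** as the remainder without any rotation; the
two schemes coincide when interest and nuisance are orthogonal, and the
difference is only the route by which collinearity is apportioned.
Pseudo-inverses treat singular values below N·eps·σ_max as zero.  Each
contrast gets its own partition.

## Statistics

- **F** — (ψ̂′C(C′(M′M)⁻¹C)⁻¹C′ψ̂ / s) / (ε̂′ε̂ / (N − rank M)).  For s = 1,
  t = sign(β̂)√F.
- **G** — with *variance groups* (VGs), subsets of observations assumed to
  share an error variance, the weight matrix is diagonal with
  Wnn = (Σ_{n′∈g} R_{n′n′}) / (ε̂_g′ε̂_g): the group's effective degrees of
  freedom over its residual sum of squares, i.e. the reciprocal estimated
  group variance.  Then

      G = ψ̂′C (C′(M′WM)⁻¹C)⁻¹ C′ψ̂ / (Λ·s),
      Λ = 1 + [2(s−1)/(s(s+2))] · Σ_g (1/Σ_{n∈g}R_nn)(1 − Σ_{n∈g}Wnn/tr W)².

  Special cases, each verified against an independent implementation:
  one VG ⇒ Λ = 1 and G = F; s = 1 with several VGs ⇒ sign(β̂)√G is the
  Aspin–Welch v (scipy's Welch t on cell-means designs); several groups
  with the all-means-equal contrast ⇒ Welch's v² (pingouin's Welch ANOVA);
  replacing Λ by 1 gives James's statistic (available as a diagnostic
  toggle).  The factor 2(s−1)/(s(s+2)) with s = k−1 groups reproduces
  Welch's classical 2(k−2)/(k²−1).

Statistics are computed with solves rather than explicit inverses where the
shape allows; because W differs per data column, the weighted Gram matrices
are assembled from per-group crossproducts and inverted in a batch.  A
degenerate fit (residual variance at rounding-error level, detected as
F > 1e12, which is legitimate because F is scale-free) is reported as +inf
with a warning; +inf participates in p-value counting as a largest value.
Variance groups of size 1 are permitted with a warning — the variance is
then estimated from a single residual.  One-sided convention throughout:
evidence against H₀ is *large* T, and signed statistics (t, v) give
one-sided tests.

## Shufflings

A shuffling is a sign-flip vector followed by a row permutation.  Which
rearrangements are admissible depends on the error assumptions:
permutations under exchangeable errors (EE), sign flips under independent
symmetric errors (ISE), their product when both hold.  Exchangeability
blocks restrict the set: `within` blocks permute rows inside each block
only (sign flips remain per-observation), `whole` blocks permute
equally-sized blocks as units (sign flips act per block).  With blocks, the
default variance groups follow: one VG per within-block EB; for whole-block
EBs, the k-th observations of all blocks form VG k.

Maximum counts follow the closed forms (multinomial coefficients over
repeated rows of the shuffled partition — **X** for most strategies, **M**
for Manly and ter Braak; factorials over blocks; powers of two for flips),
in exact integer arithmetic.  When the count fits within the requested J,
the set is enumerated exhaustively without duplicates (multiset
enumeration for permutations, radix-2 integers for sign flips, Kronecker
expansion of block-level shufflings) and returned in randomised order with
the identity first, since truncating a lexicographic enumeration would
bias a subset.  Otherwise the identity plus J−1 conditional-Monte-Carlo
draws are used; duplicates are allowed by default, with an optional
rejection-sampling dedup capped at the unique count.

One subtlety is worth recording: a permutation applied to the *data* is
equivalent to its transpose applied to the *design*, so "synonymous
permutations" (those that merely interchange identical rows) form
different classes depending on which side is shuffled.  The enumeration
therefore dedups on the pattern of **P′X** for data-shuffling strategies
and on **P X** for design-shuffling ones (Draper–Stoneman, Smith).
Deduping on the wrong side produces a set that is not a transversal of the
statistic's equivalence classes and destroys the exactness of the test —
with repeated rows this inflated the type-I error of an N = 8 exhaustive
test from 4.3% to 33% before the side was made explicit.

## Strategies and the engine

The nine nuisance-handling strategies follow the standard one-line forms
(see the engine module docstring).  Implementation notes:

- Freedman–Lane uses the fast form (**P R_Z** + **H_Z**)**Y**, asserted
  equal to the literal six-step procedure to 1e−10.
- Still–White and Kennedy fit only the (residualised) interest partition;
  degrees of freedom are those of the fitted model, emulating the common
  use of these methods — this is what makes Kennedy anticonservative.  A
  flag restores full-model dof for Still–White.
- Huh–Jhun projects into the residual space of **Z** with an orthonormal
  basis **Q** (from the SVD of **R_Z**, sign-fixed by making each column's
  largest-magnitude entry positive, for reproducibility) and shuffles the
  N − rank **Z** reduced space; it cannot honour exchangeability blocks
  and refuses them.
- The transformation matrix of a shuffling is formed once and applied to
  all V columns; for fixed-design strategies the projections **R_Z Y**,
  **H_Z Y** are precomputed so each shuffle costs one gather and one fit.
- Ties between T*ⱼ and T₀ are genuine under exhaustive enumeration but can
  be split by floating-point noise; both sides of the ≥ comparison are
  rounded to 12 significant digits first.
- The full J × V statistic table is not retained unless requested; counts
  and per-shuffle maxima are accumulated streaming.

p-values: uncorrected, p = count/J ∈ {1/J, …, 1}; FWER-corrected from the
distribution of the per-shuffle maximum across tests (plus the (1−α)
quantile of that distribution as a single map threshold); FDR by step-up
Benjamini–Hochberg adjustment (statsmodels).  The minimum-p alternative to
the maximum statistic is deliberately not used.

## Synthetic scenarios

Group scenarios are cell-means designs; the canonical table spans two- and
four-group layouts with sizes (8,4), (20,5), (80,30), (40,30,20,10),
(4,4), (20,20), (4,4,4,4), (20,20,20,20) and per-group variance
configurations ranging from homoscedastic to 15:1 ratios.  Errors are
normal with the specified group variances; under signal the true group
means are (0, −1) for two groups and (0, −0.33, −0.67, −1) for four.  The
hypothesis is all-means-equal (successive-difference contrast); the
nuisance partition is then the grand-mean direction, so Freedman–Lane and
Manly coincide exactly for these designs.  Shuffling is by permutation;
rank-1 contrasts use the signed one-sided v/t — with exhaustive
enumeration of the 70 relabelings of the (4,4) null scenario this yields a
rejection rate of exactly 3/70 ≈ 4.3% at α = 0.05, which identifies the
one-sided convention unambiguously.

Regression scenarios use x₁ = linear trend on [−1, 1] (or a ±1 split),
z₁ = the mean-centred squared trend (or a discrete pattern orthogonal to
x₁), plus an intercept; γ = (0.5, 1); correlation ρ between x₁ and z₁ is
induced by the upper-triangular Cholesky factor of the 2 × 2 correlation
matrix.  Errors: normal(0,1); uniform(−√3, √3) (unit variance exactly);
exponential(1) − 1; Weibull(shape 1/3) standardised by its exact moments
Γ(4) and √(Γ(7) − Γ(4)²) — this law is extremely skewed and heavy-tailed,
which is what stresses the strategies.

`run_error_power_study` evaluates 1000 simulated datasets as the columns
of one data matrix, sharing a shuffling set exactly as the voxels of one
image would; each dataset's p-value remains marginally valid.  The
replicates are split into 10 chunks with independently seeded shuffling
sets so the estimate does not hinge on a single CMC draw, and every
replicate is reproducible in isolation through the SeedSequence ladder.
`run_distribution_comparison` pools observed (unshuffled) statistics over
simulated voxels per variance configuration and applies pairwise
two-sample Kolmogorov–Smirnov tests, Bonferroni-corrected within scenario.

What the generator does *not* emulate: spatial correlation between tests,
temporal autocorrelation within observations, and non-normal errors in the
group scenarios — so passing the group-study checks says nothing about
autocorrelated data, and spatial statistics (cluster extent/mass, TFCE)
are out of scope.

## Reproduction notes and limitations

- The one-sided v/t convention for rank-1 contrasts and the permutation
  (EE) regime for the group study follow the published evaluation's
  realised error rates and stated procedure; under these conditions the
  four-group power and type-I values and the small-sample regression row
  reproduce within their printed 95% intervals, while the power of the
  unbalanced two-group scenario with the larger variance in the smaller
  group runs 2–4 points above the printed value — consistent with the
  slight liberality of any unrestricted permutation reference in that
  configuration (our type-I error there is ~5.4%).  Asymptotically the
  one-sided Welch power of that scenario is ≈76%, which is where our
  estimate sits.
- Small heteroscedastic unbalanced scenarios (e.g. sizes (8,4), variances
  5:1) are where unrestricted permutation is least trustworthy; sign
  flipping (`regime="ise"`) is the appropriate regime there when the
  errors are symmetric, and is what a user of this package should choose.
- The p ≤ α decision uses a 1e−12 absolute guard so that p-values that are
  exact multiples of 1/J landing on α are counted as rejections.
- Nested (multi-level) block structures and variance-smoothed statistics
  are not implemented; a single level of within- or whole-block structure
  is supported.
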