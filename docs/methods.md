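# Methods

## Diversity model

All diversity statistics are plug-in Hill numbers (effective numbers of
species) of order `q`, partitioned multiplicatively: gamma is the Hill
number of the weighted pooled assemblage, alpha the weighted
generalized mean of within-sample Hill numbers, and `beta = gamma /
alpha`. Sample weights are equal (`w_j = 1/N`) throughout the pipeline;
with equal weights beta is independent of alpha at every order and
bounded by `1 <= beta <= N`. Weighted variants are exposed on
`partition_diversity` but unused by the pipeline stages, so a single
weights policy holds within any run. Conventions: natural logarithms,
`0·ln 0 := 0`, and `q = 1` evaluated by its exact Shannon limit rather
than a numerical limit. No bias correction (Chao-type or
coverage-based) is applied anywhere: the package computes the same
plug-in quantities at every depth, and rarefaction (below) is the
instrument for judging their sampling sensitivity.

The two orders reported by the summary stages are `q = 0` ("diversity":
mean within-sample richness) and `q = 1` ("effective diversity":
exponential Shannon). The magnitudes differ by design — richness counts
every rare OTU once, the effective number discounts them — which is why
an eDNA marker can report thousands of OTUs of richness but a few
hundred effective species.

Pairwise turnover, `(D_beta - 1)/(N - 1)` with `N = 2`, is the bounded
[0, 1] dissimilarity used for all cross-method work. It is 0 only for
identical relative compositions and 1 for disjoint ones; raw `D_beta`
is never used as a distance because its range depends on `N`.

## Rarefaction

`rarefy_diversity` subsamples the *pooled* read multiset without
replacement (every read tagged by sample and OTU, a multivariate
hypergeometric draw over the flattened matrix), because the natural
x-axis for a multi-marker comparison is total sequencing effort.
Per-sample rarefaction (equal depth in every sample) is available via
`per_sample=True`. Samples emptied by a shallow draw are dropped for
that replicate, so `N` — and with it the beta ceiling — can shrink at
very low depths; this is visible as the inflated spread of beta at
depth ~100. Replicate `r` uses an independent child stream spawned from
the seed (`SeedSequence.spawn`), so any replicate is reproducible in
isolation and adding replicates never perturbs earlier ones.

## Permutation tests

Mantel tests correlate the `n(n-1)/2` off-diagonal entries and permute
one matrix's labels jointly over rows and columns. The p-value is
one-tailed (greater), matching the directional hypotheses (turnover
*increases* with elevational separation; methods are *positively*
correlated), with +1 smoothing in numerator and denominator so `p >=
1/(n_perm + 1)`. When `n! <= 5040` the test enumerates all relabelings
and reports the exact p instead (no smoothing; the identity counts
itself, preserving the floor). PROTEST centers and unit-scales both
configurations, takes the optimal rotation from the SVD of the
cross-product (`m12² = 1 - (Σ singular values)²`), and permutes row
labels of the second configuration with the same exhaustive/sampled
switch. Permutations are drawn as `argsort` of uniform variates, which
is exchangeable and vectorizes; both tests are calibrated to nominal
type-I error in the acceptance suite (1000 null datasets, n = 10, 999
permutations).

The significance machinery is deliberately Mantel-only: the comparison
stages report Mantel's statistic and its permutation p, and no separate
PERMANOVA is implemented.

## Ordination

NMDS minimizes stress-1 via SMACOF with monotone regression
(scikit-learn backend), taking the best of a classical-scaling start
plus 20 random starts; the classical start protects against the poor
local optima random starts occasionally find. The final configuration
is centered and rotated to principal axes with a fixed sign convention,
making runs reproducible coordinate-for-coordinate from the seed. Note
a genuine property of non-metric scaling: a zero dissimilarity does not
force two points to coincide, because isotonic regression leaves the
lowest-ranked disparity free (primary tie treatment); such pairs end up
closest, not identical.

PCoA eigendecomposes the Gower-centered matrix `-0.5·J·D²·J`; axes are
scaled by the square root of their eigenvalue. Negative eigenvalues
(non-Euclidean distances such as turnover or Jaccard) are dropped with
their summed magnitude reported as `negative_inertia` — no
Lingoes/Cailliez correction, mirroring common constrained-ordination
practice.

Jaccard is computed on presence/absence by default (the quantitative
Ružička form sits behind `quantitative_jaccard=True`); Horn-Morisita
uses the abundance overlap `1 - 2Σxy / [(Σx²/X² + Σy²/Y²)XY]`.

## Distance-based RDA

`dbrda` embeds the community distance by PCoA (positive axes), then
projects the site scores onto the z-scored predictors by least squares.
Constrained inertia is the sum of squared fitted values; the reported
proportion divides by the **total positive inertia**. One convention
caveat: implementations that net the imaginary (negative-eigenvalue)
inertia out of the denominator report slightly *larger* proportions on
non-Euclidean distances; `DbRDAResult.negative_inertia` is exposed so
either convention can be computed, and the pseudo-F — which uses only
constrained and residual inertia — is identical under both (verified
against an independent reference implementation to 14 digits on a
frozen fixture; see `tests/test_crosscheck.py`). Significance permutes
site rows freely (999 default); forward selection adds the
smallest-p candidate while `p < alpha` using added-variable F-tests on
residual scores, backward drops the largest-p variable while
`p >= alpha`.

VIF screening regresses each variable on all the others (`VIF =
1/(1-R²)`, exact singularities treated as infinite) and removes the
maximum until all survive below 10. Predictors are standardized inside
the modeling entry points rather than stored standardized: that keeps
`sin.aspect`/`cos.aspect` on their natural [-1, 1] scale in the
environment table while every VIF and inertia fraction remains
scale-free. The default log-transform list is {Olsen-P, EC, NO3-N,
NH4-N} — the right-skewed concentration variables — and is a
configurable choice, not an inference; with only 10 plots any model
with more than ~7 predictors is saturated, which is precisely why the
VIF screen precedes the db-RDA stage.

## Site prioritization

The greedy rule removes, at each step, the plot whose removal leaves
the remaining set with maximal effective beta (order 1 by default,
exposed as a parameter): first removed = most redundant = lowest
conservation priority. Ties break lexicographically by plot id. The
loop stops when two plots remain, since beta of a single plot is
degenerate; the final pair is appended in lexicographic order so the
removal order is a full permutation, and rank 1 (highest priority) is
the last plot standing. This final-pair convention is a stated choice.
Rank agreement uses tie-corrected Spearman rho with an exact
enumeration p for `n <= 8` plots and the t-approximation beyond.

## Synthetic data

The generator emulates the statistical structure the analyses assume,
at desk scale:

- **Gradient**: a single latent elevational gradient. Species optima
  are uniform over the transect's elevation range, niche width sigma is
  common (default 50 m), regional abundances lognormal (sigma 1.0), and
  the mixture weight `g` interpolates between the pure niche model
  (`g=1`) and a flat community (`g=0`) so power and type-I calibrations
  share one code path. The niche acts on *elevation*, not temperature:
  temperature is derived from elevation (intercept 15.5 °C, slope
  -0.005 °C/m, noise SD 0.2 °C) so the driver analysis faces a planted
  collinear pair, as in real transect data.
- **Sampling**: 10 plots at the packaged transect elevations
  (50-640 m), 2 subplots per plot, and multinomial reads per subplot at
  the profile's depth (default 5000). Default pool 200 species.
- **Environment**: 13 further variables with a planted collinear
  fertility block (EC, organic C, total N, NH4-N, water content, and
  the derived C/N ratio) and independent nuisance covariates (pH,
  Olsen-P, NO3-N, slope, aspect).

What the generator does *not* emulate — and what passing tests
therefore do not demonstrate about real data: sequencing error, chimera
formation and OTU-clustering noise; PCR/primer amplification bias;
marker-specific taxonomic breadth (each synthetic marker draws an
independent species pool); spatial autocorrelation beyond the single
elevation axis; and the order-of-magnitude read-depth imbalance *within*
a marker across samples. Recovery rates measured here are upper bounds
on what identical analyses achieve on real amplicon data.

The packaged transect fixture (10 plots with coordinates, elevations
50-640 m, and mean annual surface soil temperatures 15.27-12.22 °C,
including the Plot 8 warm anomaly) is stored as one reviewed constant
block and doubles as the default elevation set.

## Problem sizes and numerical choices

The acceptance suite and `scripts/acceptance.py` use: 100 random
matrices x 4 orders against a 50-digit mpmath oracle (agreement
demanded at 1e-10 relative; observed ~1e-15); 1000 null datasets x 999
permutations for each calibration; 100 simulation seeds per recovery
claim; 100 greedy instances at 5-6 plots; 50 rarefaction replicates.
These sizes make every stochastic assertion a >=99% binomial band
around its nominal value while keeping the whole verification run in
seconds. Degenerate inputs fail loudly by design: empty samples,
all-zero distance matrices, saturated db-RDA models, zero-variance
Mantel vectors and sub-minimum plot counts raise typed errors rather
than propagating NaNs, so a filtering step that silently empties a
sample can never bias a downstream N.

One master seed governs a pipeline run; each stage derives its stream
by stable hashing of the stage name, so adding a stage never perturbs
the numbers of existing ones.

## Known limitations

- NMDS inherits SMACOF's local-optimum risk; the classical start
  mitigates but cannot eliminate it (stress is reported — treat values
  above ~0.2 as inadequate embeddings).
- db-RDA drops imaginary inertia rather than correcting the distance
  matrix; strongly non-Euclidean distances shrink the denominator
  convention gap but never the pseudo-F.
- Exact Spearman p-values stop at n = 8 (40,320 enumerations); beyond
  that the t-approximation is used, which is anticonservative for
  n < ~15 at extreme rho.
- The greedy ranking is a heuristic: it matches exhaustive greedy
  search by construction, but no claim is made against globally optimal
  (non-greedy) reserve selection.
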