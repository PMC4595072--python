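# ednacompare

Tools for comparing soil eDNA metabarcoding surveys with traditional
biodiversity measures along an environmental gradient.

Multigene eDNA surveys census a site with several marker amplicons
(16S, 18S, trnL, ITS, COI, ...), each returning a sample-by-OTU read-count
matrix of very different richness and depth. The question this package
addresses is the one ecologists and conservation planners actually ask of
such data: do the molecular methods *see the same biodiversity structure*
as conventional surveys of seedlings, trees, invertebrates and birds — the
same turnover between plots, the same response to elevation, the same
conservation priorities — and which environmental variables drive the
community differences?

## What it computes

**Diversity partitions (Hill numbers).** For a community matrix with row
compositions $p_{ij}$ and sample weights $w_j$ (equal by default), the
order-$q$ gamma diversity is the Hill number of the pooled assemblage
$\bar p_i = \sum_j w_j p_{ij}$,

$$^qD_\gamma = \Big(\sum_i \bar p_i^{\,q}\Big)^{1/(1-q)},\qquad
  ^qD_\alpha = \Big(\frac{\sum_i\sum_j (w_j p_{ij})^q}{\sum_j w_j^q}\Big)^{1/(1-q)},\qquad
  ^qD_\beta = {}^qD_\gamma / {}^qD_\alpha,$$

with the $q\to 1$ (exponential-Shannon) limits evaluated exactly. Beta is
the effective number of distinct communities, $1 \le D_\beta \le N$, and
the normalized pairwise beta — the *turnover* $(D_\beta-1)/(N-1) \in [0,1]$
— is the canonical between-plot dissimilarity used everywhere downstream.

**Cross-method comparison.** Mantel tests (one-tailed, 4,999 permutations,
exhaustive enumeration when $n! \le 5040$) between turnover matrices;
a method-by-method correlation matrix ordinated by second-stage MDS;
distance-decay regressions of turnover on $|\Delta\,\mathrm{elevation}|$;
NMDS of each method's samples; Procrustes/PROTEST concordance of
ordinations ($m_{12}^2$ with a permutation test); within- vs between-plot
turnover contrasts; and read-rarefaction curves of all three diversity
components.

**Site prioritization.** Greedy reserve ranking: repeatedly remove the
plot whose removal maximizes the effective beta of the remaining plots;
rank agreement between methods by tie-corrected Spearman rho with exact
small-$n$ p-values.

**Environmental drivers.** Covariate preparation (log transforms, sin/cos
aspect decomposition), stepwise exclusion of the highest variance
inflation factor until all VIF < 10, and distance-based RDA (PCoA of the
Jaccard distance followed by least-squares projection of site scores onto
standardized predictors) with marginal, full, and forward/backward
permutation-selected models.

**Synthetic gradient metacommunities.** A generator plants a Gaussian
niche response on elevation — species $i$ has optimum $\mu_i$, width
$\sigma$, lognormal abundance $A_i$, and expected plot abundance
$A_i\,[g\,e^{-(e_s-\mu_i)^2/2\sigma^2} + (1-g)]$ — with multinomial read
sampling per subplot, a structureless null ($g=0$), and an environment
table with planted elevation/temperature collinearity. Every analysis
stage is therefore testable without any sequence data.

## Worked example

`examples/03_distance_decay.py` simulates a 10-plot elevational transect
(200-species pool, 5000 reads per sample, 50 m niche width) plus a
structureless control, and tests each for distance decay:

```
     gradient: Mantel r=+0.821 (p=0.0010)  R2=0.675  slope=+1.80e-03 per m
structureless: Mantel r=-0.114 (p=0.7530)  R2=0.013  slope=-2.99e-07 per m
```

The gradient community's turnover climbs by ~0.0018 per meter of
elevational separation and the Mantel test rejects at its permutation
floor, while the structureless community shows no decay — the same
contrast that separates gradient-tracking markers from a patternless
method (e.g. highly mobile taxa) in real surveys. The other scripts in
`examples/` demonstrate diversity partitioning, rarefaction, the method
correlation matrix with second-stage MDS, PROTEST, greedy ranking, the
VIF/db-RDA driver analysis, and the one-call `run_full_comparison`
pipeline. A thin CLI wraps the same functions:
`ednacompare simulate|diversity|rarefy|compare|ordinate|rank|drivers|run-all`.

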