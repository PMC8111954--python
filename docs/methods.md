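# Methods

## The composite density model

For a group-living species whose social groups occupy clusters of burrow
systems (setts), site-level density is decomposed as

    D_Ad  = D_C × (p_SSC·ad_SSC + p_MSC·ad_MSC + p_MSCR·ad_MSCR)
    D_Bad = D_C × (p_SSC·badger_SSC + p_MSC·badger_MSC + p_MSCR·badger_MSCR)

with D_C the sett-cluster density per km² (distance sampling, corrected for
the proportion of suitable habitat), p_c the proportion of clusters in
occupancy category c among **all** clusters (including unoccupied), and
ad_c / badger_c the mean adult / total group size in category c.  The model
assumes (i) each occupied cluster houses exactly one social group, (ii)
group sizes estimated on the surveyed subset of clusters are representative
of all occupied clusters of that category at the site, and (iii) occupancy
proportions and group sizes are estimated without sampling error relative
to the cluster-density bootstrap — composite uncertainty therefore carries
only the CV of D_C.

Proportions are held as integer count fractions throughout and converted to
floats only at output: two-decimal rounded proportions can displace a
composite density by ~0.02/km², while count fractions are exact.  Reported
tables round half-up to 2 decimals at serialization only.

## Sett clustering

Two setts join the same cluster when their centroids are within a threshold
(default 500 m); clusters are the connected components of this graph
(single-linkage chaining), which is order-independent and reproduces the
behaviour of a fixed between-setts grouping distance.  Distances are
Euclidean; coordinates must be in a metric projection.  Clusters never
merge across sites.  Occupancy classification is a strict precedence:
MSCR if any member is an occupied main sett with reproduction, else MSC if
any occupied main sett, else SSC if all members are secondary and one is
occupied, else unoccupied.  The cluster's detection distance is that of its
first-detected member (an input flag); without the flag the smallest
member distance is used and a warning logged.  The threshold is a
parameter: cluster counts are non-increasing in it, and density estimates
at 100 m / 900 m bracket the 500 m choice.

## Distance sampling

The detection function g(x) uses uniform, half-normal
(exp(−x²/2σ²)) or hazard-rate (1 − exp(−(x/σ)^−b), b > 1) keys with
optional cosine, simple-polynomial or Hermite series adjustments; cosine
and polynomial terms are scaled by the truncation distance w, Hermite terms
by σ, and the product is renormalized so g(0) = 1.  Parameters maximize the
conditional likelihood Π g(x_i)/∫₀ʷ g, with σ and b−1 fitted on the log
scale by multi-start L-BFGS-B (5 seeded restarts; the hazard-rate surface
can be multimodal).  Likelihood integrals use a fixed 61-node
Gauss–Legendre rule; the reported ESW uses adaptive quadrature to 1e-6 m.
Adjustment terms are added sequentially while AIC improves; candidates
whose g increases by more than 1e-6 anywhere on a 1000-point grid are
rejected.  CDS post-stratification fits independent detection functions per
stratum (summed log-likelihood, parameters and AIC); MCDS puts a log-linear
model on σ with treatment-coded categorical covariates (reference level
lexicographically first) and, by default, no adjustments on top of the
covariate scale.  Model selection is by AIC (AICc reported alongside); ties
break toward fewer parameters, then uniform < half-normal < hazard-rate.
Goodness of fit uses equal-width bins with expected counts from the fitted
g, merging adjacent bins with expected < 1 (never below n_params + 2 bins);
df = bins − parameters − 1.

Density in suitable habitat is D = n/(2·ESW·L).  The bootstrap resamples
transects with replacement within a site (B = 999 by default), holding the
detection function fixed, because between-transect encounter-rate
variability dominates the variance in this design; a full exhaustive
enumeration mode (K ≤ 8 transects) returns the exact bootstrap
distribution and is used to validate the resampling path.  Default
truncation is w = 55 m (fixed) with a percentage mode available.

## Group sizes

Per cluster, camera nights give componentwise maxima of simultaneous adult
and total counts over all nights and member setts; hair-trap samples give
the number of distinct multilocus genotypes.  Two samples match when they
agree at every locus where both are typed and each has at most 4 missing
loci (configurable); matching is closed transitively, with warnings when
chaining merges samples that are not pairwise identical.  Samples exceeding
the missing-locus threshold are excluded from counting: under the match
rule they can match nothing, and counting unmatchable low-quality samples
as individuals would inflate group sizes.  The cluster total is
max(camera total, genetic count); adults are camera-only, since genotypes
cannot be aged.  Missing (site × category) cells are imputed with the mean
of observed cells for the same category among sites of the same habitat
type (forested vs hedgerow); imputed cells are flagged, never feed further
imputation, and are excluded from cross-site category means.

## Correlation screen

Spearman's rho from midranks; exact two-sided permutation p-values by full
enumeration for n ≤ 9, the t approximation otherwise; Bonferroni adjustment
min(1, m·p).  With m = 7 tests at α = 0.05 the per-test cutoff is 0.00714.

## The synthetic-site generator

The generator emulates the study conditions the estimator assumes:

* a square site (default 50 km²) with a binary suitable-habitat mask built
  from random axis-aligned patches at 100-m resolution hitting the target
  suitable fraction (default 0.35, typical of hedgerow-dominated sites) —
  only the suitable fraction enters the estimator, so irregular real-site
  geometry is not modelled;
* sett clusters as a Thomas-like parent–offspring process on suitable
  habitat (default 10 clusters/km² of suitable habitat; cluster sizes
  1 + Poisson with mean 2 setts; members uniform in a 150-m disc, so no
  sett lies farther than the spread from its parent and true clusters are
  recoverable at the 500-m rule);
* occupancy categories drawn per cluster with probabilities
  (0.352, 0.209, 0.300, 0.139) for (unoccupied, SSC, MSC, MSCR), the pooled
  field shares; group rosters of 1 + Poisson adults with category means
  (1.34, 1.37, 1.95) and Poisson(2.51) cubs in reproducing clusters;
* a walked survey on a 1-km grid of theoretical points, each moved to the
  nearest suitable cell, with planned 1–2-km transects clipped to the grid
  cell (so effort never overlaps between neighbouring points) and trimmed
  to the contiguous suitable run — realized transects are therefore shorter
  than planned, as in the field;
* per-sett detection with probability g(d) at the perpendicular distance d
  to the nearest transect segment (default hazard-rate, σ = 15 m, b = 2.5,
  giving ESW ≈ 21 m); camera nights as binomial draws over the roster
  (p = 0.4/night, 14 nights; nights with no animals produce no row) and
  genetic capture per individual (p = 0.6) with 24-locus genotypes drawn
  from site-level allele frequencies and 3% missing loci.

One seeded generator stream drives all draws, so identical configurations
give byte-identical tables.

What the generator does **not** emulate: real land-cover geometry,
territorial inhibition between neighbouring clusters (parents are Poisson,
so distinct groups can sit arbitrarily close), badger movement and
behaviour, genotyping error, or setts in unsampled open habitat (none are
placed there, so the known slight field underestimation from unsampled open
habitat is absent by construction).  Passing recovery tests therefore shows
the estimator chain is consistent under its own assumptions, not that those
assumptions hold in any particular landscape.

## Validation experiments and problem sizes

Desk-scale checks recompute all published composite quantities from the
built-in survey tables in milliseconds.  Simulation experiments use sizes
chosen to give tight Monte-Carlo error at modest cost: ESW quadrature
checked against a 10⁶-point Riemann oracle over 50 random parameter draws;
hazard-rate parameter recovery at n = 2000 distances over 20 seeds (3
likelihood-SE criterion); AIC key selection over 100 replicates at n = 500;
bootstrap CV verified exactly by exhaustive enumeration on a two-transect
toy; and end-to-end recovery over 300 replicate sites at true cluster
density 5/km².  The recovery experiment uses single-sett clusters and a
fully suitable site: with multi-sett clusters the cluster-level detection
curve has g(0) < 1 (the recorded distance is the nearest *detected*
member's), a known field bias that the fitted detection function absorbs
in practice but which would confound a parameter-recovery check of the
distance-sampling chain itself.  Field-realistic defaults (multi-sett
clusters, patchy habitat) are used everywhere else, including the pipeline
integration test whose encounter-rate CVs fall in the broad range reported
from field surveys.

## Known limitations

* Group-size and occupancy sampling error is not propagated into composite
  CIs (only the cluster-density bootstrap CV is).
* Binned (interval) distance data, left truncation and size-biased
  detection of larger clusters are not supported.
* The genotype matcher is a documented artifact rule (agreement with ≤ 4
  missing loci, transitive closure), not a probabilistic genotype-error
  model; allelic dropout will split individuals.
* Exact Spearman p-values are limited to n ≤ 9 by factorial enumeration.
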