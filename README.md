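# settdens

Composite population-density estimation for group-living, burrow-dwelling
species, motivated by the European badger (*Meles meles*).

Estimating density of a social species from field sign is hard because
density factors into components that respond to different ecological
drivers: how many territories (social groups) an area holds, what fraction
of them is occupied, and how many animals each group contains.  `settdens`
implements a standardised composite pipeline that estimates each component
separately from standard survey data and multiplies them back together:

1. **Sett clustering** — burrow systems (setts) recorded on walked transects
   are grouped into *sett clusters* (one social group's residence) by
   single-linkage chaining at a between-centroid distance threshold (500 m
   by default), and each cluster is classified as MSCR (occupied main sett
   with reproduction), MSC (occupied main sett), SSC (secondary setts only,
   at least one occupied) or unoccupied.
2. **Distance sampling** — cluster density in suitable habitat,
   *D*<sub>C.Distance</sub>, comes from line-transect distance sampling of
   the perpendicular detection distances: detection functions g(x) with
   uniform, half-normal or hazard-rate keys, series adjustments,
   CDS post-stratification or MCDS scale covariates, AIC selection,
   effective strip width ESW = ∫₀ʷ g, the estimator
   D = n / (2·ESW·L), and a transect-resampling bootstrap for CV and CI.
   Multiplying by the site's proportion of suitable habitat gives the
   whole-site cluster density *D*<sub>C</sub>.
3. **Group size** — per surveyed cluster, the maximum number of animals seen
   simultaneously by camera traps (adults distinguished from cubs) is merged
   with the count of distinct multilocus genotypes from hair traps by taking
   the maximum; per-site category means are imputed across same-habitat
   sites where a category went unsampled.
4. **Composite densities** — per site,

   D_Ad  = D_C · (p_SSC·ad_SSC + p_MSC·ad_MSC + p_MSCR·ad_MSCR)
   D_Bad = D_C · (p_SSC·badger_SSC + p_MSC·badger_MSC + p_MSCR·badger_MSCR)

   give adult and total (adults + cubs) badger densities per km², with
   occupancy proportions carried as exact count fractions.
5. **Correlation screen** — Spearman rank correlations (exact permutation
   p-values for n ≤ 9) with Bonferroni adjustment relate density to its
   components and to site covariates.

A synthetic-site generator (`settdens.synthetic`) produces sett, transect,
camera and genetic tables with known ground truth — clustered sett placement
in suitable habitat, a 1-km gridded transect survey with distance-dependent
detection, and per-individual capture — so the whole pipeline is validated
by parameter recovery.

## Worked example

The package ships the per-site summary tables of a 13-site national badger
survey (`settdens.datasets`).  Recomputing the composite densities:

```python
from settdens.study import study_density_table, study_summary

table = study_density_table()
print(table[["site_id", "D_C", "p_SSC", "p_MSC", "p_MSCR",
             "D_Ad", "D_Bad", "D_occupied_main"]].round(2).head(4))
```

```
site_id  D_C  p_SSC  p_MSC  p_MSCR  D_Ad  D_Bad  D_occupied_main
      A 5.39   0.12   0.12    0.12  3.71   5.85             1.35
      B 5.50   0.13   0.26    0.22  5.97  13.28             2.63
      C 3.55   0.10   0.14    0.33  3.75   7.08             1.69
      D 5.17   0.52   0.17    0.14  7.85  11.28             1.60
```

Site B, for instance, combines a cluster density of 5.50/km² with high
occupancy (11 of 23 clusters hold an occupied main sett) and large group
sizes into the highest total density, 13.28 badgers/km².  Across sites:

```python
print(study_summary().round(2))
```

```
                 mean    sd   min argmin    max argmax
D_Ad             3.85  1.75  1.66      J   7.85      D
D_Bad            5.85  3.25  2.42      G  13.28      B
D_occupied_main  1.72  0.52  0.76      G   2.63      B
```

Adult densities span 1.66–7.85 per km² (mean 3.85 ± 1.75 SD); the density
of occupied main clusters — roughly the density of family groups — spans
0.76–2.63 per km².  Fitting a detection function to simulated distances:

```python
from settdens.distsamp import fit_detection, simulate_distances

x = simulate_distances(400, "hazard_rate", 55.0, sigma=15.0, b=2.5, rng=0)
print(fit_detection(x, w=55.0, key="hazard_rate").summary())
```

```
Detection function (line-transect, conditional likelihood)
  key: hazard_rate   adjustment: none (0 terms)
  n obs: 400   truncation w: 55 m
  log-likelihood: -1453.921   AIC: 2911.84   AICc: 2911.87
  sigma: 15.516 m (SE 1.412)
  ESW: 22.225 m
  b: 2.277 (SE 0.241)
```

The generating scale (15 m) and shape (2.5) are recovered within their
likelihood-based standard errors; the effective strip width of ~22 m is the
half-width of the strip that, surveyed perfectly, would yield the same
expected number of detections.

A `settdens` command-line tool wraps the stages (`simulate`, `cluster`,
`fit-ds`, `groupsize`, `density`, `correlate`, `study-tables`); run
`settdens --help`.

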