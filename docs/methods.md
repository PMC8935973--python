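# Methods

`beescape` infers habitat quality for a social, central-place-foraging bee
(modelled on the Common Eastern Bumblebee, *Bombus impatiens*, in a large
city) from two field observables: multilocus microsatellite genotypes of
netted workers and the coordinates where each worker was netted. The chain
is: genotypes → full-sib families → triangulated colony locations → per-cell
colony density and foraging distance → landscape/demographic drivers.

## Genetic model and sibship reconstruction

Bumblebees are haplodiploid: females are diploid, males haploid. Under
monogyny (one queen per colony) and monoandry (one mate per queen) — both
well supported for this species, whose effective mate number is ~1.06 —
all workers of a colony are full sisters sharing their father's single
allele at every locus and drawing one of the queen's two alleles
independently.

The family likelihood marginalises the unknown parents. Per locus with
allele frequencies p,

L(cluster) = Σ_{a,b,c} p_a p_b p_c Π_w ½ (M_w[a,c] + M_w[b,c]),

where (a, b) ranges over ordered queen genotypes, c over father alleles, and
M_w[t1, t2] = P(worker w's observed genotype | true {t1, t2}) under the
error model: each observed allele is, with probability e, replaced by a
frequency-weighted random allele (mistyping; default e = 0.01), and with an
independent probability dropped to missing (default 0). Loci are independent
and summed on the log scale; a worker's missing locus contributes a factor
of 1. A genotype with one missing allele is treated as locus-missing — the
dropout default is 0, so this path is essentially cold. The null model is
the product of Hardy–Weinberg genotype probabilities under the same error
model. Allele frequencies are estimated from all workers before
reconstruction (a slight upward kinship bias, accepted as common practice);
alleles observed but absent from a supplied frequency table get a floor
frequency 1/(2n+1) and the table is renormalised.

Partitioning is a randomized-order agglomerative search: start from
singletons, repeatedly apply the merge with the largest positive
log-likelihood gain, stop when no gain exceeds τ (default 0; an optional
per-cluster BIC-style reward is available). Pairs of workers that fail to
share any observed allele at more than 2 typed loci are never candidates for
merging: full sisters always share the paternal allele, so with e = 0.01
and 12 hypervariable loci the probability that a true sib pair fails 3 or
more loci is of order 10⁻³, while almost all unrelated pairs are pruned.
This pruning makes the search quadratic in practice at ~10³ workers.

The search is restarted (default 3, per the field study's practice of three
independent runs); the reported partition is the highest-likelihood restart
and a cluster's support is the fraction of restarts whose final partition
contains exactly that member set. This restart consensus is a stated
stand-in for a posterior inclusion probability, not a reimplementation of
any particular pedigree program's internals; the same ≥ 0.80 support cut is
applied, inclusively. Clusters below the cut or below 2 members are returned
as singletons.

Note on a tempting invariant: the merge gain of a *true* sib pair is
positive only in expectation (KL inequality), not instance by instance;
on low-diversity loci ~8% of generated sib pairs have a negative pairwise
gain. Accuracy therefore comes from many informative loci, which the panel
provides.

## Colony locations and foraging distances

A retained cluster with members netted at ≥ 2 distinct locations is a
triangulable colony. "Distinct" uses a 0.5 m tolerance by default (GPS
records of a single netting spot); exact equality is available via
`coord_tol_m=0`. The colony location is the mean center of its members'
capture coordinates, computed by projecting to a local azimuthal-equidistant
plane about the coordinate centroid, averaging, and unprojecting — at city
extents this matches spherical averaging to well under a meter (the
equirectangular shortcut was measured at ~3.5 m error over a 14 km span and
rejected). Worker foraging distance is the great-circle (haversine,
R = 6 371 008.8 m) distance from capture point to colony center; sisters
netted in other grid cells still count toward their own colony.

Per grid cell: N = number of triangulated colony centers in the cell
(half-open cell bounds [west, east) × [south, north), so a center on a grid
line belongs to exactly one cell — a declared convention); the effective
number of colonies colNe = 4.5 N m n / (1 + 2m) with mating frequency m and
queens-per-colony n defaulting to 1, giving colNe = 1.5 N; aveMeanFD = mean
over the cell's colonies of each colony's mean member distance, with a
natural-log transform carried alongside (the log scale is what the
normality screen favours for distance data). Shapiro–Wilk is exposed for
that screen.

## Population-genetics QC

Descriptive statistics are computed on a pruned dataset retaining one
randomly chosen sister per multi-member cluster (family structure otherwise
pseudo-replicates the queen's genotype). Ho is the heterozygote fraction;
He is Nei's unbiased estimator (2n/(2n−1))(1 − Σp²) — the small-sample
correction is a deliberate choice and is stated so external comparisons know
which estimator is in play. Hardy–Weinberg deviation per locus uses a seeded
Monte-Carlo permutation of alleles among genotypes (default 10 000
shuffles), comparing the observed heterozygote count to the permutation
null; the two-sided p doubles the smaller tail with an add-one correction.
With L loci, the Bonferroni flag threshold is α/L (0.05/12 ≈ 0.004).
Missing genotypes are excluded locus-wise. Null-allele and stutter
diagnostics are out of scope; the homozygote-excess direction of the
permutation test is the only scoring-error screen.

## Landscape statistics

Covariates arrive as per-cell values or are derived from polygon-overlap
tables by three modes: counts of point features, percent cover
(100 × Σ overlap fractions), and overlap-weighted averages
(Σ v_i w_i / Σ w_i). Raw GIS reprojection is out of scope; a
rectangle-intersection helper covers synthetic grids.

The battery mirrors standard practice in community ecology:

- **Spearman + FDR.** Pairwise Spearman ρ (mid-ranks) with two-sided p and
  Benjamini–Hochberg step-up adjustment over the tested pairs. Because the
  log is monotone, Spearman correlations with foraging distance are
  identical on the raw and log scales.
- **VIF screen.** VIF_j = 1/(1 − R²_j); the > 5 flag is advisory, with an
  explicit keep-list, since collinear variables are sometimes retained for
  interpretability.
- **Best-subset regression.** Exhaustive OLS over predictor subsets up to
  `max_size` (beam search beyond 2²⁰ subsets), ranked by adjusted R²; the
  parsimonious pick is the lowest AIC among the top ten. AIC is fixed as
  n ln(RSS/n) + 2(p+2) — the Gaussian convention with the variance counted;
  only differences matter, so the ordering is convention-invariant.
  Per-predictor "variance explained" is defined as the adjusted-R² drop on
  removing that predictor from the subset — a declared definition, since
  several reasonable ones exist. Note that an added pure-noise predictor
  lowers adjusted R² only when its partial F < 1, i.e. with probability
  ≈ 0.68, not always.
- **RDA.** Responses (ln aveMeanFD, colNe) and predictors are standardized
  so the two responses are unit-comparable; fitted values from multivariate
  least squares; canonical eigenvalues from the spectral decomposition of
  the fitted covariance; R² = tr(Ŷ'Ŷ)/tr(Y'Y); adjusted R² by Ezekiel's
  formula; global significance by permuting response rows (default 999
  permutations, seeded), p = (1 + #{F* ≥ F})/(n_perm + 1). Variable scores
  are correlations of predictors/responses with the site scores (biplot
  geometry). Verified to 10 decimals against vegan on a frozen fixture.
- **Variation partitioning.** Adjusted R² of the seven unions of three
  predictor sets (demography / infrastructure / natural habitat by default),
  unique and shared fractions by inclusion–exclusion. Fractions are reported
  as computed — negatives included — so the sum identity to the full-model
  adjusted R² is exact. Because the adjusted-R² penalty depends on model
  size, unique fractions equal per-set adjusted R² only asymptotically even
  for orthogonal designs.

## Synthetic data generator

The generator emulates the study design so every stage is testable by
parameter recovery; its defaults are the study's conditions.

- **Grid.** 270 cells of 2 × 2 km (10 × 27 by default), WGS84, anchored
  near the study city. The grid lives on a local equirectangular plane;
  cell polygons export to GeoJSON.
- **Covariates.** The 28 physical and demographic variables (buildPerc …
  famTI) as smooth spatial gradient + noise, optionally with a cross-
  variable correlation matrix (PSD enforced); percents clipped to [0, 100],
  counts nonnegative integers. Means and spreads are plausible for a large
  North American city and are constants of the package.
- **Colonies.** Per-cell Poisson counts with a linear covariate link
  (negative expectations rejected, not clipped), uniform locations within
  the cell, worker counts 1 + Poisson(mean − 1).
- **Genotypes.** 12 microsatellite loci calibrated to the study panel:
  allele counts 12–30, fragment sizes on a 2-bp ladder spanning each locus's
  printed range, and truncated-geometric allele frequencies solved by root
  finding to hit each locus's expected heterozygosity (0.43–0.92), so
  synthetic data are format- and information-identical to real calls.
  Inheritance is haplodiploid with one queen and one father per colony;
  errors follow the mistype/dropout model above (defaults 1% / 0%).
- **Captures.** Worker capture point = colony location + isotropic
  displacement with half-normal distance (scale = the cell's covariate-
  linked kernel; default base 1000 m, chosen so triangulated per-cell
  foraging distances land in the high-hundreds-of-meters range typical of
  urban bumblebees). The half-normal was chosen as a one-parameter kernel
  with closed-form mean σ√(2/π). Captures land wherever they land — sisters
  may be netted in different cells — and are then restricted to the sampled
  cells (default: a seeded random 86 of 270) and truncated at 60 per cell,
  mirroring the field protocol. Capture points are i.i.d. kernel draws; the
  generator does not model within-netting-window drift, weather, phenology,
  queen dispersal, or multi-year dynamics.

What passing recovery tests do **not** show about real data: real foraging
kernels are anisotropic and barrier-distorted, real colony densities are
overdispersed relative to Poisson, and real sampling is opportunistic
within cells; the generator's clean versions of these are exactly what make
truth tables possible.

## Problem sizes and numerical choices

Reconstruction of ~500 workers (3 restarts) takes about a minute on one
CPU; the full default pipeline (270-cell grid, 86 sampled cells, ~750–1000
workers) completes in a few minutes. The test suite's recovery checks use
30-cell landscapes with kernel scales 200–1500 m on a smooth 2-D gradient
(spatially smooth scales keep the truth comparison meaningful when a
triangulated center drifts into a neighbouring cell), 20-family × 5-worker
sibship simulations over 10 seeds, and 50 replicate RDA sign-recovery
simulations. Ties in the merge search are broken randomly per restart;
cluster product arrays are max-renormalised to avoid underflow; grid cell
assignment snaps coordinates by 1 µm so boundary points survive lon/lat
round-tripping; eigenvalues are clipped at 0 before proportions are formed.

## Known limitations

- Support values are restart-consensus frequencies with very coarse
  resolution at 3 restarts; they are conservative gates, not posteriors.
- Half-sib families arising from rare multiple mating are out of model and
  will fragment into full-sib subsets (the expected behaviour, but it
  slightly inflates colony counts).
- The colNe formula corrects detected counts for unsampled colonies only
  through the mating-system constants; it is not a detection-probability
  model.
- Per-predictor variance-explained values depend on the removal-based
  definition above and are not comparable across definitions.
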