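# Methods

pleurokit bundles the bespoke computations of an integrative study design
for rapidly radiated plant clades: dissecting gene-tree/species-tree
discordance, deriving genome-wide traits from flow cytometry (FCM),
mapping those traits over reconstructed ranges, and testing their
evolution with phylogenetic comparative statistics.  This note documents
the models, the parameters that matter, the numerical choices, and what
the synthetic-data generators do and do not emulate.

## Trees and bipartitions

Trees are rooted; tips carry unique string labels; polytomies are
first-class.  A bipartition (split) is the two-way partition of the taxon
set induced by a tree edge, stored in canonical orientation
(lexicographically smallest side first) so equality is orientation-free.
Two splits on the same taxon set are incompatible iff all four pairwise
side-intersections are non-empty.

`bipartitions` reports the split of every internal non-root node,
including splits with a singleton complement (the rooted reading: a clade
of two tips opposite one outgroup tip is informative).  A consequence
worth knowing: the restriction of a tree's splits to a taxon subset can
contain singleton-side splits that the pruned tree does not realize as a
node (the clade shrank to a single tip and was suppressed); for classic
min-side >= 2 splits, pruning and restriction commute exactly, and the
property suite asserts this.

Newick internal-node labels are read as support values by default (the
convention of maximum-likelihood bootstrap outputs); `internal_labels="name"`
keeps them as clade names instead.  `collapse_low_support` contracts
internal edges with support strictly below the threshold, matching the
convention of collapsing branches below a bootstrap cutoff into polytomies.

## Concordance accounting

For each internal non-root node of the species tree with split B, each
gene tree is classified after restricting B to the gene tree's tip set:

* **uninformative** — the restriction loses a whole side, or the gene tree
  neither contains nor contradicts it (e.g. the relevant region is a
  polytomy after support collapsing);
* **concordant** — the restricted split is among the gene tree's splits;
* **conflicting** — some gene-tree split is incompatible with it.

The three counts always sum to the number of gene trees.  The reported
`top_alternative` is the incompatible split held by the most gene trees
(each conflicting gene tree votes once per distinct incompatible split it
contains; ties break lexicographically), so its count never exceeds the
conflicting count.  Pie fractions are (concordant, top-conflict,
other-conflict, uninformative).

The taxon jackknife prunes a removal set from the species tree and every
gene tree and recounts; original nodes are matched to pruned nodes by the
restriction of their defining splits, and nodes whose split becomes
trivial are reported as dropped.  A node whose concordant count rises
sharply after a removal attributes its conflict to the removed taxa.

## Scenario ranking

The alternative-topology test reduces the tree space: with k clade-level
tips there are (2k−3)!! rooted binary topologies (3.16 × 10¹¹ at k = 13),
so instead of exhaustive scoring (refused above k = 9) the candidate set
is the fully resolved topologies *observed* among the gene trees after
pruning to one representative per clade and relabeling representatives by
clade name.  A majority-rule-consensus candidate mode is also available.
Each candidate is scored by the mean concordant gene-tree count per
internal node, excluding the root; scores are averaged over repeated
random representative draws (every candidate is scored on every draw so
means are comparable), and candidates are ranked.

Split-based scoring cannot separate rootings of the same unrooted
topology except through a double-counted basal split, which makes rootings
near-ties.  The procedure therefore accepts a designated outgroup clade;
pruned gene trees are rerooted on its representative before enumeration,
which pins the candidate rooting — the same role an outgroup genus plays
when gene trees are rooted before concordance analysis.  The recovery
benchmark (200 multispecies-coalescent gene trees, 13 clades of two
accessions, internal branches of 3 coalescent units, outgroup rooting)
recovers the true clade-level topology at rank 1 in ≥95 of 100 seeds.

## Flow-cytometry traits

Inputs are relative-fluorescence peak positions: the 2C peak and the
endoreplicated series under propidium iodide (PI, intercalating,
quantitative) and DAPI (AT-preferential), plus an internal standard.

* **Genome size**: GS(2C) = (sample 2C PI / standard 2C PI) × standard 2C
  in Mbp; GS(1C) = GS(2C)/2.
* **Replicated fraction P**: under partial endoreplication only a fraction
  P of the genome participates in each endocycle, so the r-th peak sits at
  F_r = F_0 (1 + (2^r − 1) P).  P is estimated by least squares on **log**
  peak positions (peak noise is multiplicative, so log residuals are the
  homoskedastic scale and the fit is maximum likelihood under lognormal
  noise), profiling out the per-series baseline and minimizing over
  P ∈ (0, 1] with a bounded scalar optimizer (xatol 1e-10, explicit
  boundary check at P = 1).  When both stains' series are available the
  default derivation fits them jointly with a single shared P and one free
  baseline per series, roughly halving the estimator's variance; this
  assumes the replicated fraction's base composition does not distort the
  DAPI spacing, and can be disabled (`use_both_stains=False`).  A short
  single series at realistic noise cannot reach the desired classification
  reliability: the Cramér–Rao bound puts sd(P̂) near 0.026 for five peaks
  at 2% CV, and the joint two-series fit is what brings mis-classification
  of conventional endoreplication below 1%.
* **CE/PE classification**: P ≥ 0.95 is conventional endoreplication (CE),
  inclusive on the CE side because measurement error motivates the
  threshold in the first place; below it, partial endoreplication (PE).
* **GC content**: from the dye factor DF = DAPI/PI at 2C.  DAPI
  fluorescence is modeled as proportional to (AT fraction)^n with binding
  length n (default 4); then AT_s = AT_std (DF_s/DF_std)^{1/n} and
  GC = 100 − AT_s.  The binding-length model is this package's documented
  choice of calibration; n is a parameter so alternative calibrations are
  drop-in.
* **Replicated-fraction GC**: mass balance over a nucleus carrying the
  full genome plus the replicated fraction gives
  GC_rep = (GC_1 (1+P) − GC_0)/P; values outside (0, 100) are returned but
  flagged as a mixing-model violation.

Peak-series validation enforces strictly increasing peaks with successive
ratios in (1, 2] — the PE model bound — with headroom to 2.5 so that noisy
CE runs (whose true ratio is exactly 2) are not rejected.

## Spatial surfaces

Ranges are pseudo-occurrences: a taxon is placed in every fine raster
cell whose region id is in its recorded region list and whose elevation
lies inside its recorded band (both bounds inclusive — they are attained
values).  Cells lacking region or elevation data are out of range.  Fine
cells aggregate onto a coarse grid (default 0.5 arc degree; the
resolution is a parameter) as occupied area, with fine-cell area
∝ cos(latitude of the row center) — the spherical approximation, adequate
at 30-arc-second scale.  Presence requires occupied area strictly
exceeding 5% of the coarse cell's area.  Trait surfaces are
occupied-area-weighted means over present taxa (nodata where none);
species-density grids count present taxa in total, per endoreplication
mode, and as the PE:CE ratio (nodata where the CE count is zero).
Per-taxon environmental statistics are percentiles (10/25/50/75/90), mean
and standard deviation of a layer over the range mask, plus the
47.5–52.5% and 45–55% percentile bounds that feed the uncertainty-aware
regression.  Rasters are plain arrays with ESRI ASCII grid text I/O.

## Comparative statistics

All methods assume Brownian motion (BM) on a tree with branch lengths;
the covariance C has entries equal to shared root-to-MRCA path lengths,
and Pagel's λ multiplies its off-diagonals.  Dense linear algebra
throughout (trees of at most a few hundred tips).

* **λ (ML)**: profile likelihood over λ ∈ [0, 1] with a 21-point grid
  pre-scan plus bounded refinement (xatol 1e-6) and explicit boundary
  checks; the 95% CI comes from the χ²(1) likelihood-ratio cutoff, with
  the upper bound reported as NA when λ = 1 cannot be excluded.  The
  log-likelihood agrees with an independent GLS implementation to 1e-6
  on a frozen fixture.
* **PGLS**: GLS under λ-transformed C (λ fixed or ML); slope p-value from
  the t statistic with n − 2 degrees of freedom; explained variance is the
  whitened-space R² (1 − RSS/RSS₀ against the intercept-only GLS fit),
  in percent.  λ = 0 reduces exactly to OLS on ultrametric trees, and any
  λ does on a star tree.
* **Predictor uncertainty**: replicates draw the predictor uniformly
  within per-taxon (lo, hi) bounds — order-statistic bounds, hence uniform
  rather than Gaussian sampling — rerun PGLS, and report the replicate
  p-values as median (min–max).
* **Phylogenetic ANOVA**: classical one-way F, with a phylogenetic
  p-value as the +1-smoothed fraction of F statistics from BM-simulated
  traits (σ² estimated from the data by ML) at least as large as the
  observed one.  Because F is location/scale-invariant, the null p-values
  are uniform by construction, which the calibration suite verifies.
* **Independent contrasts**: Felsenstein's algorithm (polytomies resolved
  with zero-length edges); correlation forced through the origin with
  n_contrasts − 1 degrees of freedom.
* **Ancestral states**: joint ML under BM by solving the weighted-Laplacian
  normal equations (weights 1/branch length); the root estimate equals the
  GLS phylogenetic mean.  Estimation variances are σ̂² times the diagonal
  of the inverse precision of internal states given tips, with σ̂² from
  the REML-style quadratic form (n − 1 denominator).
* **Significant changes**: a branch is flagged when its reconstructed
  change exceeds the two-sided (1 − α) normal quantile of N(0, v) with
  v = σ̂²·t plus the estimation variances of both endpoint states.
  Omitting the (negative) endpoint covariance makes v conservative, so the
  realized false-positive rate sits below α; an effectively constant trait
  (σ̂² at floating-point noise level) flags nothing by an explicit guard.

## Synthetic data

* **MSC gene trees**: species-tree branch lengths are in coalescent units
  (2N generations); within each branch, j lineages coalesce at rate
  j(j−1)/2.  The sampler's core correctness check is the analytic triplet
  law — a rooted triplet with internal branch t yields the concordant
  topology with probability 1 − (2/3)e^{−t} — verified at 20,000 genes per
  t ∈ {0, 0.5, 1, 2} within 3 binomial SE.
* **Hybrid signal**: a topological SPR applied to a seeded Bernoulli(γ)
  subset of gene trees (no network simulation); trees where the target
  clade is not monophyletic are passed through with a warning.  Note that
  re-attaching a clade across the root of a symmetric tree can leave the
  unrooted topology unchanged; detectable signals require an attachment
  that breaks some split.
* **BM traits**: multivariate normal with λ-transformed covariance
  (Cholesky with a 1e-12 relative jitter).
* **FCM runs**: PI peaks at F_0 (1 + (2^r − 1)P) for r = 0..4 by default
  (a 2C–32C′ series, the shape partial-endoreplication histograms
  display), DAPI peaks scaled so the implied GC equals the requested
  value, independent multiplicative lognormal noise per peak with the
  given CV (mean-corrected so E[noise] = 1).  At cv = 0 the trait
  derivation round-trips exactly.
* **Landscape**: DEM from Gaussian-filtered seeded noise rescaled to an
  elevation range; regions and ecoregions as nearest-center mosaics;
  environmental layers as smooth fields with a requested correlation ρ to
  the standardized DEM (ρ·ẑ + sqrt(1−ρ²)·noise).
* **Fixture suite**: writes a complete miniature study (species tree with
  13 clades × 2 accessions, 200 gene trees with one injected hybrid
  signal, FCM peak and trait tables, landscape rasters, range table) in
  the same text formats the analysis functions read.

What the generators do **not** emulate: gene-tree estimation error beyond
topology noise, sequence-level processes, FCM histogram shape (peak
positions are simulated directly, not detected), instrument drift,
real-geography region shapes, or spatial autocorrelation structures
beyond smooth Gaussian fields.  Passing tests therefore demonstrate the
correctness and calibration of the computations under their stated
models, not robustness to every artifact of real data.

## Problem sizes and determinism

The statistical suites run at these sizes: 500 random instances for the
concordance oracle, 100 seeds × 200 genes for scenario recovery, 20,000
genes per branch length for the triplet law, 1000 replicates for FCM
recovery, a 1000×1000-cell landscape for spatial conservation, 1000
simulations for PGLS type-I error, 200 seeds for λ recovery, 500 datasets
for ANOVA calibration, and 500 replicates for change-detection false
positives.  Every stochastic procedure takes an explicit integer seed and
is reproducible bit-for-bit under it; independent generators derive their
streams from `numpy.random.default_rng(seed)`.

## Known limitations

* Concordance semantics are split-based; strictly clade-based (rooted)
  accounting would classify some singleton-side restrictions differently.
* The GC calibration is a single-parameter binding-length model; real
  dye-genome interactions are more complex, and the model is a documented
  stand-in for instrument-specific calibrations.
* The λ transform is applied to possibly non-ultrametric trees by scaling
  off-diagonals only, the standard convention; reference implementations
  that normalize C to a correlation matrix differ off the ultrametric
  case.
* `pgls_with_uncertainty` perturbs the predictor only; response
  uncertainty is out of scope.
* The significant-change variance omits endpoint covariance
  (conservative); exact joint variances would sharpen power slightly.
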