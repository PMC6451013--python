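# Methods

This note documents the models behind each stage, the defaults that
matter, what the synthetic-data generator does and does not emulate, and
the numerical choices a maintainer would want stated.

## Genotype model and formats

Genotypes are diploid, codominant, genotype-level missing (a half-called
genotype is demoted to missing with a warning).  Allele codes are positive
integers — fragment sizes or repeat counts; stepwise arithmetic (R_ST, SMM)
divides codes by a per-locus motif length supplied by the caller (default
1, i.e. codes already in repeat units).  Three dialects are read and
written: GenePop (the writer emits `pop:individual` name fields so
population labels survive a round trip; plain files fall back to the
first-individual-names-the-POP convention), STRUCTURE two-row (−9 or 0
missing), and a long CSV.

## QC

*Null alleles.* Per population × locus, the observed homozygote count is
compared with a Monte-Carlo Hardy–Weinberg reference (genotypes assembled
from the cell's own allele frequencies; flag when observed exceeds the
97.5th percentile).  The Brookfield-1 frequency r = (H_E − H_O)/(1 + H_E)
is reported, clamped to [0, 1].  Stutter and large-allele-dropout
diagnostics are out of scope.

*Linkage disequilibrium.* A log-likelihood-ratio G statistic on the
two-locus genotype table; the null permutes single-locus genotypes among
individuals within the population.  All permutation p-values in the
package use the (b + 1)/(R + 1) convention, so p ≥ 1/(R + 1) always.
Monomorphic loci give p = 1.

*Multiple testing.* Sequential Bonferroni is implemented as Holm's
step-down procedure.

## Diversity and inbreeding

H_E is the unbiased (Nei 1978) form m/(m−1)(1 − Σp̂²) averaged over loci;
rarefied allelic richness uses the exact hypergeometric expectation at a
depth g defaulting to the smallest non-missing gene-copy count over
population × locus cells (the FSTAT convention).  F_IS is the
Weir–Cockerham (1984) multilocus f: per-allele variance components
b = n/(n−1)[p(1−p) − (2n−1)/(4n)·h̄] and c = h̄/2 are summed over alleles
and loci before the ratio f = 1 − Σc/Σ(b+c).  At exact Hardy–Weinberg
genotype proportions this estimator is O(1/n) positive, not zero — tests
assert the limit, not the point value.  The HWE test permutes gene copies
among individuals within each population and is two-sided on |F_IS|; the
pooled group of isolated individuals is excluded from F_IS by default
because it is not one panmictic unit.

## AMOVA

One-level decomposition on gene copies.  Per locus, total and
within-population sums of squared inter-copy distances are computed in
closed form (identity metric: (N² − Σn_a²)/2N; squared-size metric:
N·Σx² − (Σx)² over copies), variance components come from mean squares
with the unequal-size coefficient n_c, and components are summed over loci
before the index σ²_a/(σ²_a + σ²_w).  Degrees of freedom follow the
gene-copy convention (among = P − 1, within = 2n − P).  Missing copies
drop that locus for that individual only.  Negative components are
reported as computed; percent variation clamps them to zero with a flag.
Significance permutes whole individuals among populations.

## Admixture model

The independent-allele-frequency admixture model (the correlated-frequency
F-model is deliberately not implemented; the ΔK and alignment machinery is
agnostic to that choice).  A fully vectorised Gibbs sampler updates the
latent origin of every gene copy, per-individual memberships
q_i ~ Dirichlet(α + counts), and cluster frequencies
p_kl ~ Dirichlet(λ + counts) with λ = 1; α is inferred by a Metropolis
step (uniform(0, 10) prior, step 0.05) by default.  The reported
log-likelihood trace is the mixture form Σ log Σ_k q_ik p_kla, and the
model-choice table uses its post-burn-in mean.  Desk-scale defaults are
burn-in 5 000 / 20 000 sweeps / 5 replicates; the recovery experiments in
the test suite use 150/600 sweeps, which the stationarity check
(Geweke-style split comparison) supports at these data sizes.  ΔK is the
Evanno second difference normalised by the across-replicate standard
deviation (ε = 1e−9 guard); it is undefined at the grid edges.  Replicate
alignment searches all K! label permutations (K ≤ 8) maximising
Σ_i Q_ref·Q_perm.

ΔK has a well-known bias toward K = 2: in a star topology the 1→2
likelihood gain is about twice the 2→3 gain, so the statistic hinges on
the across-replicate sd at each K.  With sparse panels the K = 2 merge is
unimodal and its sd collapses; the 3-deme recovery experiment therefore
uses a 24-locus panel, where the three candidate merges are
near-equivalent, replicate runs spread across modes, and ΔK peaks at the
true K in 16 of 20 datasets.

## Bottleneck test

For each polymorphic locus the equilibrium heterozygosity distribution
H_eq | (n copies, k alleles) is simulated: Kingman genealogies with
Poisson(θ/2 × branch length) mutations under IAM (fresh allele), SMM (±1
repeat) or TPM (±1 with probability 0.70, else a geometric multi-step with
p = 0.36, giving step variance ≈ 30 — the conventional two-phase
setting); θ is calibrated by log-space bisection so the mean simulated
allele count matches k (tolerance 0.05), and only replicates realising
exactly k alleles are retained (minimum 500).  Conditioning on k makes the
retained distribution nearly θ-free — for IAM it is exactly the Ewens
conditional distribution, which the tests verify by enumeration.  Each
locus contributes DH = (H_E − mean H_eq)/sd H_eq; the one-tailed Wilcoxon
signed-rank over loci (exact null for ≤ 25 loci) tests for excess.  The
reference seed for a locus depends only on (seed, n, k, model), so loci
and replicate analyses with the same configuration share one cached
distribution — statistically equivalent, and what keeps the 500-dataset
calibration suite fast.  Reported summaries: N = mean gene copies and
k = mean equilibrium allele count, per model.

## Coancestry N_E

Pairwise kinship defaults to the Loiselle estimator with the bias term
p(1−p)/(m_l − 1) counted in gene copies (m_l = 2 × typed individuals);
Ritland is selectable.  F_i = 2θ̂_ii − 1, clamped to [−1, 1].  Group
coancestry Θ = [Σ 0.5(1+F_i) + Σ_{i≠j} θ̂_ij]/n² and N_E = 0.5/Θ; a
non-positive Θ (possible on small samples) yields NaN with a warning.
An important property: with the focal sample as its own frequency
reference, per-allele deviations sum to zero, so the mean pairwise kinship
recentres to ≈ 0 regardless of true relatedness and the estimator's
ceiling is N_E ≈ n.  A `reference="dataset"` option (pooled frequencies
across all populations) preserves within-population relatedness structure
and is what the relatives-lower-N_E property test uses.  The coalescent
conversions are exact arithmetic: N_E·m = M·Θ/4 and N_E = Θ/(4μ) with
μ = 4.76×10⁻³ per locus per generation by default.

## Geospatial assessment

Coordinates are projected with a Lambert cylindrical equal-area projection
on the authalic sphere (R = 6371.0072 km), centred on the records' mean
longitude — at continental extents this matches dedicated geodesy
libraries to well under the 1% tolerance that matters for threshold
classification.  EOO is the shapely convex-hull area; degenerate hulls get
area 0 and the classifier enforces EOO ≥ AOO.  AOO snaps projected points
to a 2-km grid anchored at the projection origin (4 km² per occupied
cell); because the grid origin is a genuine degree of freedom, a 3×3
sub-cell offset scan reporting the min/max AOO is available.  Locality
dedup keeps the most recent record (undated loses to dated; date ties
break to the smallest id).  Criterion-B thresholds: EOO CR < 100,
EN < 5 000, VU < 20 000 km²; AOO CR < 10, EN < 500, VU < 2 000 km².  The
B2 subconditions (severe fragmentation, continuing decline) are declared
by the user — they come from habitat context, not coordinates — and both
must be present for the threatened category to stand.

## Distribution model

Rasters are plain numpy grids with a (x0, dx, y0, dy) geotransform in
WGS84 degrees; NODATA is NaN and propagates across layers; cell areas use
the exact spherical band formula.  The surface range envelope declares a
cell suitable iff every layer lies inside the [q, 1−q] empirical quantiles
(linear interpolation — stated because the envelope boundary depends on
it) of the training presences, q = 0.025 by default.  Splits are
floor(0.75·n) train; background defaults to 10× presences drawn uniformly
from valid non-presence cells; replicate runs use independent
SeedSequence substreams.  AUC uses the tie-corrected rank formula; TSS is
maximised over the observed score thresholds; models with TSS ≤ 0.7 are
discarded and the consensus is the TSS-weighted mean of the rest.
Projection substitutes layers by name and reports suitable-area change.
An optional pairwise-correlation filter stands in for factor-analysis
variable pre-selection; only the envelope algorithm is implemented, with
the evaluation/ensemble machinery algorithm-agnostic.

## Synthetic data

The simulator is forward-time Wright–Fisher with non-overlapping
generations: each offspring picks a parental deme through a backward
migration matrix, selfs with probability s or mates randomly, and every
transmitted allele mutates under IAM/SMM/TPM (repeat counts start at 20
with a reflecting floor at 2).  Crashes multiply a deme's census at a set
number of generations before sampling.  Null alleles are injected at
sampling by masking the allele nearest a target frequency.  Two
initialisation details proved load-bearing for calibration: the founder
pool is a single coalescent draw of exactly 2·ΣN gene copies dealt out
without replacement (a smaller or multinomially-resampled pool truncates
rare alleles and mimics a bottleneck), and its θ should match 4Nμ of the
run (the `study_regime` preset does).  With those in place the bottleneck
test's type-I error at equilibrium is at its nominal 0.05.

The `study_regime` preset emulates a small fragmented-tree study: demes of
250/250/150 plus a 90-strong isolated group, samples 20/22/13/7 (62
total), 11 TPM loci at μ = 2×10⁻³, selfing 0.25, low migration (0.008
between core demes), 150 generations, and 10-fold crashes in all three
core demes 5 generations before sampling.  Over replicates this yields
mean per-population H_E ≈ 0.45–0.60 and global F_ST ≈ 0.10–0.20.

What the generator does *not* emulate: genotyping error and allele
binning noise, linked loci, overlapping generations, spatially explicit
isolation-by-distance, and real climate surfaces (layers are smooth
gradients plus white noise).  Passing calibration and power tests
therefore demonstrates correctness of the estimators under the stated
models, not robustness to those real-data artefacts.

## Problem sizes in the test suite

Calibration uses 400–500 simulated equilibrium datasets per test at small
n (8–20 individuals, 2–10 loci, 200 permutations); power/recovery uses 50
forward simulations for crash detection and N_E, 15 per selfing level,
and 20 datasets × 6 K × 5 replicates for ΔK.  The full suite runs in
about seven minutes on one core; the acceptance script in about one.

## Known limitations

- The admixture sampler has no correlated-frequency (F-model) variant, so
  it needs more divergence than STRUCTURE's default model to separate
  very recently split demes.
- The heterozygosity-excess machinery conditions on the realised allele
  count by rejection; configurations with k close to n under SMM/TPM can
  be unreachable (collisions) and raise a diagnostic.
- Contemporary N_E by group coancestry is bounded near the sample size
  with self-referenced frequencies (see above); treat it as "effective
  number represented by the sample".
- EOO/AOO use a fixed equal-area projection; at extreme latitudes a local
  azimuthal projection would be preferable.
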