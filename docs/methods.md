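# Methods

This note documents the models and estimators implemented in popgenscan,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions.

## The synthetic-data generator

The generator produces the statistical structure the downstream analyses
assume, not sequence data.

**Drift.** Allele frequencies follow the Balding–Nichols model: given a
parent frequency *p* and a differentiation parameter *F* ∈ (0, 1), a
daughter population draws from Beta(p(1−F)/F, (1−p)(1−F)/F), whose mean is
*p* and whose variance is F·p(1−p). Applied along a rooted population tree
(one drift step per branch; leaf branches use each population's `drift_F`,
internal branches `internal_F`, default 0.05), this yields the shared-drift
covariance on which the f₄ test depends, and an expected Weir–Cockerham
F\_ST between two sister populations approximately equal to their common
*F*. Balding–Nichols was preferred over a full coalescent because it is
closed-form, fast, and makes the F\_ST calibration target exact; msprime
remains available as an optional independent cross-check but is not the
reference path. Ancestral frequencies are uniform on (0.05, 0.95) so that
most sites are informative, mimicking a SNP-ascertained panel rather than
full-site data.

**Admixture.** An edge (source, target, α) replaces the target's frequency
by (1−α)·own + α·source after drift — a single frequency-level pulse. This
is sufficient to generate the positive f₄ expected for B→D gene flow under
the (A,B;C,D) sign convention, without simulating migration histories.

**Linkage disequilibrium.** Each individual carries two haplotypes. Within
an `ld_block_bp` block on a linkage group a haplotype samples its allele at
every site through one shared latent uniform *U* (allele = 1 iff
*U* < p_site), re-drawn independently per site with probability
`site_noise` (default 0.1). This copula device leaves every site's marginal
exactly Binomial(2, p) while producing high dosage r² within blocks and
background-level r² across blocks and linkage groups. The block span is the
single knob controlling the decay distance; it mimics the empirical decay
of LD to background at a few hundred kb, not recombination dynamics.

**Noise layers.** Genotypes are masked missing i.i.d. at `missing_rate`;
Poisson(20) depths and depth-tracking genotype qualities (capped at 99) are
attached so the filter cascade has something to act on. Defaults are
study-shaped: ~25 000 SNPs over 22 equally sized linkage groups
(40 Mb each), 4–40 diploids per population, 10% missingness.

**What passing tests do not show.** The generator has no selection, no
site-specific error structure, no allele dropout or restriction-site
polymorphism, no unplaced scaffolds, and its LD is block-uniform rather
than recombination-graded. Calibration results on it validate the
estimators and their variance machinery under their own assumptions; they
do not certify behaviour under real RAD ascertainment artefacts.

## Filtering cascade

Site masks: QUAL ≥ 20 and mapping quality ≥ 20 (missing annotations pass).
Genotype masks: GQ ≥ 20, depth ≥ 5 reads, and depth ≤ the sample's own
99.5th-percentile depth. All comparisons pass at the threshold
(value ≥ threshold passes quality; value > cutoff fails high depth). The
high-depth cutoff uses the nearest-rank percentile of each sample's own
non-missing per-site depth distribution; the per-site reading was adopted
because it is the only interpretation that yields a genotype-level mask.
Site filters then drop non-biallelic sites, sites with more than 25%
missing genotypes, and sites with minor-allele frequency below 10%
(defaults; MAF is computed from non-missing dosages only).

Distance thinning is greedy and leftmost-first per linkage group: keep the
first site, then keep a site iff it lies at least `min_bp` (default
500 kb, the LD background distance) beyond the last kept site. The rule is
deterministic and idempotent; note that thinning is *not* invariant to a
prior pass with a smaller spacing (a coarse pre-thin can remove a site the
direct pass would anchor on), which is an inherent property of greedy
thinning rather than an implementation choice.

SNAPP preparation keeps complete-data thinned biallelic sites and derives
the backward/forward mutation rates from the mean alternate-allele
frequency π₁: u = 1/(2π₁), v = 1/(2π₀). These satisfy the stationarity and
unit-rate normalisation π₁u + π₀v = 1 and π₁ = v/(u+v). The population-size
prior is Gamma(α = 2, β = 2000), mean θ = α/β = 0.001, appropriate for
small populations. A panel whose π₁ is 0 or 1 has no defined rates and
raises a degenerate-panel error.

## LD decay

r² is the squared Pearson correlation of unphased 0/1/2 dosages (composite
LD) over pairwise-complete samples — genotype-based because RAD genotypes
are unphased. Pairs need ≥ 4 jointly genotyped samples and both sites
polymorphic among them; otherwise the pair is excluded (signalled by NaN,
not an exception). Default distance bins are 0–10 kb, 10–50, 50–100,
100–500 kb, 0.5–1 Mb and 1–5 Mb; bins are configurable since any choice is
a convention. Within-bin pairs are subsampled uniformly (seeded) above
`max_pairs_per_bin`; the cross-LG background is estimated from up to
2×10⁶ random cross-LG pairs (smaller caps are used in the bundled pipeline
for speed). The reported "background crossing" is the first bin whose mean
r² is at or below the background mean.

## Divergence

F\_ST uses the Weir & Cockerham (1984) variance components a (among
populations), b (among individuals within populations) and c (within
individuals), computed per biallelic site from sample sizes, allele
frequencies and observed heterozygote proportions; sites with fewer than
two genotyped diploids in either population are skipped. Window F\_ST is
the ratio of summed components Σa/Σ(a+b+c) — ratio-of-averages — which is
stable when individual sites carry little information; averaging per-site
ratios was rejected for its small-sample noise. D\_XY per site is
p\_A(1−p\_B)+p\_B(1−p\_A) from non-missing frequencies, averaged over the
window's usable sites.

Windows are 0-based half-open internally (VCF positions convert from
1-based on ingest). Both window makers anchor at each linkage group's
origin and emit only full-size windows — except that a linkage group
shorter than one window yields a single truncated window — so that
non-overlapping tiles are equal-sized, which the bin-distance NNI statistic
relies on. Defaults follow the scan conventions: 1 Mb windows sliding by
100 kb (minimum 10 000 sites) and 100-kb tiles (minimum 1 000 sites); the
site minima refer to usable sites and must be set far lower for SNP-only
panels than for all-sites alignments.

Genome-wide F\_ST between two populations is the unweighted mean of
non-negative 100-kb tile values (negative tiles are estimation noise below
zero and are removed before averaging; if nothing survives the result is
undefined/NaN). Because the negative tail is clipped, the estimator is
slightly biased upward when per-tile information is low — visible in the
acceptance output for the small 25k-site panels at low drift — while at
the calibration scale (50k sites, 20 diploids per population) it recovers
the drift parameter within the stated band.

Uncorrected p-distance between two samples is the mean over jointly
genotyped sites of |d_i − d_j|/2 for dosages d: identical genotypes 0,
het vs hom 0.5, opposite homozygotes 1.

Per-comparison sample balancing (e.g. capping each population at eight
individuals) is pipeline configuration, implemented as a deterministic
top-n by quality rank (default: genotype call rate) with lexicographic
sample-id tie-breaks.

## f4 test and block jackknife

f₄(A,B;C,D) is the mean over usable sites of (p\_A−p\_B)(p\_C−p\_D), with
all frequencies taken for the alternate allele at the site (a consistent
per-site polarity; flipping a site's polarity changes only that site's
sign and cancels in expectation). A site is usable when all four
populations have at least one genotyped diploid (configurable). Positive
values indicate drift shared by A–C and/or B–D.

Variance uses a delete-one-block jackknife over contiguous 500-kb tiles
anchored at each linkage group's origin (deterministic and independent of
where SNPs happen to fall; blocks never span linkage groups; empty tiles
drop out). Because RAD blocks hold unequal numbers of usable sites, the
weighted jackknife of Busing et al. (1999) is used, with block weights
proportional to site counts; with equal-sized blocks it reduces exactly to
the classical delete-one formula (verified to 1e-12 in the tests). Z is
the estimate over its jackknife SE, and the two-tailed p-value is
2(1−Φ(|Z|)) evaluated via the complementary error function, which keeps at
least two significant figures down to p ≈ 1e-300 instead of underflowing
at p ≈ 1e-16 like the naive 1−cdf form. If the SE is exactly zero (e.g.
one population duplicates another so every site's f₄ is 0), the result is
reported as Z = 0, p = 1 rather than 0/0.

## Outlier windows and the modified NNI

Outliers are the ⌈q·n⌉ highest-F\_ST valid non-overlapping windows
(nearest-rank; q = 1% and 5% by default), with cutoff ties broken by
genome order for determinism. An empirical quantile was used rather than a
Bayesian outlier model; model-based outlier detection is out of scope.

The clustering statistic is the mean over outlier windows of the minimum
within-linkage-group distance to another outlier, in window-bin units;
outliers alone on their linkage group contribute no distance (counted and
logged). The null distribution re-draws the same number of outliers
uniformly without replacement among all valid windows genome-wide —
distances remain confined within linkage groups in the statistic itself,
which is what removes the linear-genome assumption of the classical NNI
denominator; per-LG stratified permutation was considered and rejected as
a stronger null than the procedure being emulated. The modified NNI is
observed/permutation-mean (< 1 means clustering), the Z-statistic is
(observed − mean)/sd over permutation replicates, and the empirical p is
one-sided toward clustering with the +1 correction, so it is never zero.
Replicates whose outliers share no linkage group have an undefined
statistic; they are excluded from the permutation mean/sd and reported as
a count. Defaults: 10 000 permutations, seeded.

## Geography and isolation by distance

Distances use Vincenty's iterative inverse solution on the WGS84 ellipsoid
(a = 6 378 137 m, f = 1/298.257223563), converged to 1e-12 rad (≤ 200
iterations), with the standard cos²α = 0 guard for equatorial geodesics.
Near-antipodal non-convergence raises an explicit error; no fallback is
implemented because sampling sites within a lake basin never approach that
regime. Perimeter distances sum successive legs through intermediate
sites; both straight-line and perimeter matrices can feed the Mantel test.

The Mantel test correlates lower-triangle entries of two labelled distance
matrices (Pearson r) and permutes rows and columns of one matrix
simultaneously; the empirical p is (1 + #{|r_perm| ≥ |r_obs|})/(n_perm+1),
two-sided (conservative when the direction is not prespecified), with
9 999 permutations by default. The genetic input at population level is
the pairwise genome F\_ST matrix.

## Pipeline and reproducibility

The `run` orchestrator executes data → filter → LD → scans → F\_ST matrix
→ f₄ → NNI → IBD, writing TSV outputs plus a JSON manifest (seed, config,
per-stage seeds, site counts). One global seed fans out to per-stage child
seeds by SHA-256 hashing of the stage name, so inserting a new stage never
perturbs earlier stages' randomness, and reruns are byte-identical apart
from manifest timestamps. A stage failure aborts with the stage name;
partial outputs are preserved.

## Problem sizes in tests and the acceptance script

Calibration checks run at the sizes that make their targets meaningful
while keeping the whole suite quick: f₄ size/power uses 100 replicates of
20 000 sites with 8 diploids per population on the 22-LG layout; F\_ST
recovery uses 50 000 sites with 20 diploids per population (and 25 000 /
12 for the monotonicity sweep); the NNI null calibration uses a
study-shaped index of 8 800 tiles on 22 linkage groups with 5% outliers
and 1 000 permutations per run (10 000 for the single planted-signal
test); Mantel type-I uses 100 seed pairs of 8-label matrices at 499
permutations. These sizes are the package's chosen defaults for its own
validation; all are configurable at call sites.

## Known limitations

- The Weir–Cockerham implementation covers the two-population case the
  scans need; multi-population θ is out of scope.
- D\_XY from SNP-only panels is conditional on the ascertained sites; it is
  not per-bp divergence unless divided by the windows' monomorphic-site
  counts, which a reduced-representation matrix does not carry.
- The LD estimator is composite (genotype) r²; haplotype-phase D'/r² EM
  estimation is not implemented.
- Merging separately genotyped call sets intersects on position with
  allele-consistency checks; no attempt is made to re-call or re-code
  conflicting sites.
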