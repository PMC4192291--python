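# Methods

## The masking experiment

The package evaluates genotype imputation by simulation of the deployment
setting: a *reference* set of animals keeps its complete high-density (HD)
genotypes; a *validation* set has every genotype hidden except those on the
low-density chip under evaluation; an imputer fills the hidden cells; the
fill is scored against the hidden truth. The `ImputationScenario` object
enforces the information barrier: imputers receive only the masked matrix,
and the test suite includes a perturbation check (changing a hidden truth
cell must not change any imputer's output).

Genotypes are coded as 0/1/2 copies of the B allele with a distinct MISSING
sentinel (−1); quality scores (GenCall-like, in [0, 1]) ride in a sidecar
file because none of the supported formats (PLINK PED/MAP, BED/BIM/FAM,
VCF) can carry them. A note on PED/MAP: the standard 4-column `.map` has no
allele columns, so the identity of the B allele is unrecoverable for
monomorphic markers. The writer therefore emits a 6-column extended map
(alleles appended; the second listed allele is B) and the reader accepts
both layouts, falling back to sorted-observed-alleles for 4-column maps.
Only the extended layout round-trips exactly.

## Quality control

Five SNP filters run in a fixed order — non-autosomal placement, duplicate
genomic position, Hardy–Weinberg disequilibrium (p ≤ 10⁻⁵), MAF < 0.02,
call rate < 0.98 — followed by an individual call-rate filter (< 0.90
removed). Per-SNP statistics are computed on the designated reference
individuals only; the resulting exclusion list is applied to every matrix
sharing the map (`harmonize`), keeping validation panels consistent.

Two semantics choices matter:

- **First-attribution with order-independent predicates.** Each filter is a
  predicate of the input data alone; in particular the duplicate rule keeps
  the first record at each (chromosome, position) *of the input map*, not
  of the post-filter remainder. Exclusion counts attribute each SNP to the
  first failing filter, but the surviving set is the intersection of
  predicate passes and does not depend on filter order. This also makes QC
  idempotent.
- **HWE test form.** The z-test on the heterozygote proportion:
  z = (h_obs − h_exp) / √(h_exp(1 − h_exp)/n), h_exp = 2p̂(1 − p̂), two-sided
  normal p-value; a monomorphic sample is defined to be in equilibrium
  (p = 1). This is the simplest statistic consistent with calling the
  procedure a z-test; an exact test would differ in the deep tail but both
  are far beyond the 10⁻⁵ cutoff for the gross violations the filter
  targets.
- The GenCall < 0.70 masking applies to the per-SNP call-rate statistic and,
  for consistency, to the per-individual call rate as well (the latter is an
  assumption; the convention is stated only for the per-SNP statistic in
  the literature this mirrors).

## LD, the genomic relationship matrix, and Maxr/Mean10

r² is the squared Pearson correlation of genotype dosages over
pairwise-complete individuals (composite LD). No phasing step exists in the
pipeline, so a haplotype-frequency (EM) estimator would claim information
the pipeline does not have. Monomorphic-on-complete-subset pairs are
undefined and propagate as NaN, excluded from every average.

G = MM′ / Σ 2pᵢ(1−pᵢ), with M the dosage matrix centered by 2pᵢ and
residual missing dosages mean-imputed (a zero in M). The **frequency
source** is a genuine degree of freedom:

- By default pᵢ comes from the genotyped sample itself (reference +
  validation, post-QC). This is what a practitioner with no outside data
  can compute, and within-row *rankings* — which is all that Maxr (largest
  relationship with any reference animal) and Mean10 (mean of the 10
  largest) consume — are robust to it.
- E[G] equals the pedigree numerator relationship matrix A only when pᵢ are
  *base-population* frequencies. Centering by frequencies estimated from a
  related sample distorts off-diagonals structurally (the distortion does
  not shrink with more markers). The simulator's founder generation is the
  base population and is genotyped, so pedigree-recovery checks pass founder
  frequencies through the `freqs` parameter; the measured Spearman rank
  agreement between G and A over all pairs is ~0.83 with base frequencies
  versus ~0.54 with sample frequencies on the same data.

Mean10 uses the mean of all relationships when the reference holds fewer
than 10 animals. Note the direction of its monotonicity: growing the
reference can *decrease* Mean10 while the reference is below 10 (a new
below-average relationship drags the mean of all), and is non-decreasing
once 10 is reached (a new animal either displaces the smallest of the top
10 or changes nothing). Maxr is always non-decreasing.

## Chip design

The post-QC map is partitioned per chromosome into consecutive windows of
k markers (remainders form a short final window; windows never span
chromosomes), and one SNP is selected per window by the criterion: last
marker (even spacing), max MAF, max average within-window r², or max
MAF × average-r² product. Criterion statistics are computed on the
reference individuals, mirroring QC. Ties break to the lowest bp position;
windows where a criterion is undefined for every member (e.g. all r²
undefined) fall back to the even-spacing choice. Chip size is therefore
exactly Σ_c ⌈m_c / k⌉ and designs are deterministic.

Add-on panels partition the map *excluding* the base-chip markers, so the
result is base ∪ selected with |result| = |base| + (window count), and no
added marker duplicates the base.

With this rule, even-spacing chips at window sizes k and 2k are nested
(index k−1 of every window is also index 2k−1 of every second window, and
both keep the chromosome's last marker), which is what the density-ladder
experiments rely on.

## Baseline imputers

The two built-in imputers are deliberately simple baselines for exercising
the evaluation stack, not reimplementations of population phasing/HMM
imputation, and results from them quantify the *pipeline's* behaviour, not
achievable accuracy:

- **mode**: each masked cell takes the most frequent reference genotype at
  that SNP (ties to the lower dosage). Relatedness-blind; useful as a floor.
- **nn-window**: per validation animal and per window of consecutive
  markers, the reference animal with the smallest Hamming distance on the
  window's chip SNPs donates its genotypes (ties to the first reference
  animal in id order; windows without chip SNPs fall back to mode). Donor
  no-calls are mode-filled afterwards.

The nn-window baseline responds to both chip density and relatedness, the
two effects the masking experiment is designed to expose. In the bundled
experiments its window is scaled to chip spacing — 8 map markers per chip
marker, i.e. window = 8k for an even-spacing chip of window size k — so a
donor is always chosen on a comparable number of chip SNPs. A fixed window
either starves sparse chips (near-random donors) or fragments dense ones.
Both imputers accept a pedigree argument so any imputer can be driven with
and without family information through one interface; the baselines ignore
it.

## Accuracy

PERC = 100 × (identical genotypes)/(scored genotypes); CORR = Pearson
correlation of imputed vs true dosages. Both are computed over masked cells
only, per individual (all of that animal's masked SNPs genome-wide) and per
SNP (across validation animals). Cells whose *truth* is itself a no-call
cannot be scored and are skipped. CORR is undefined when either vector is
constant; undefined values are stored as NaN, counted in the summary, and
excluded from means and SDs (sample SD, n−1). PERC = 100 forces CORR = 1
where defined; the converse fails (a constant one-allele shift has CORR 1
and PERC 0), which is why both metrics are reported.

Accuracy-vs-relatedness is an ordinary least-squares polynomial fit
(degree 1 or 2) of per-individual CORR on Mean10, returning coefficients,
R² and fitted values. Both degrees are exposed because the curvature of the
relationship differs between sparse chips (strong saturation) and dense
ones (nearly flat).

The genome-window scan averages per-SNP CORR in consecutive windows of 50
markers (same partition rule as chip design) and flags windows below 0.60,
reporting each window's mean MAF and mean pairwise r² alongside — flagged
windows in practice coincide with regions of erratic local LD, the
signature of mapping/assembly problems.

## The simulator

No real genotypes ship with the package; the simulator generates data with
the statistical structure the analysis assumes.

**Genome.** 29 autosomes (the cattle karyotype) of 1 Morgan each, 400
markers per chromosome 5 kb apart (11,600 SNPs). The karyotype is the one
default that is *not* scaled down: the precision with which a genomic
relationship estimates a pedigree relationship is limited by Mendelian
sampling noise, which scales with the inverse square root of the number of
independently segregating segments. On a toy 5-chromosome genome that noise
(~0.06 per relationship) is the same order as the entire spread of
mid-range pedigree relationships, and no pedigree structure makes G
recover A to the fidelity the acceptance checks require; with 29 autosomes
it does.

**Founder haplotypes.** Allele frequencies uniform on
[maf_floor, 1 − maf_floor] (floor 0.05). LD blocks have geometric lengths
(mean 20 markers); within a block each marker copies its left neighbour's
allele with probability 0.9, otherwise draws fresh — a first-order Markov
model giving adjacent-marker r² around 0.6–0.8 decaying geometrically with
lag, the modest short-range LD characteristic of indicine HD data. A
configurable `low_ld_region` forces the copy probability to zero across a
marker range, planting the erratic-LD phenomenon the window scan detects.
The block model is used instead of a coalescent simulator because it gives
direct, interpretable control over exactly the quantity the chip-design
criteria and the nn baseline consume; it makes no claim of demographic
realism.

**Pedigree.** 20 founder males and 40 founder females (birth year 1996).
Half the founder males plus all founder females seed a breeding line; each
of 4 breeding generations produces 50 males and 60 females, with sires
drawn from a 10-male *active* subset of the previous generation — the
artificial-insemination bottleneck that gives real sire panels their wide,
continuous spread of relationships. All 200 breeding-line males form the
reference set (born before the 2005 cutoff). The final generation (born
2006) holds the validation sets: 50 young sires fathered by active
reference sires, and 100 validation dams fathered by the *outside* founder
males that never entered the breeding line — making dams genomically more
distant from the reference than young sires, the gradient the study design
turns on. Full-sib pairs exist because matings produce 2 offspring each.
For the recorded pedigree, 38% of validation dams get their sire censored
to unknown, emulating incomplete field records; gene-dropping always uses
the true parents.

**Gene-dropping and noise.** Each non-founder receives one gamete per
parent; crossovers per chromosome are Poisson(length in Morgans) with
uniformly placed breakpoints on the marker index (markers are evenly
spaced, so index position approximates the genetic scale) and random start
phase. Genotyping noise: 0.2% of calls missing, 0.5% assigned quality below
0.70 (uniform on [0, 0.70)), the rest uniform on [0.70, 1] — enough to
exercise the call-rate and GenCall filters at realistic exclusion rates
(~1.5% of SNPs) without dominating the data.

**What the simulator does not emulate.** Site-frequency spectra from real
demography, selection, genotyping error that changes a called genotype
(errors here are only missingness/low quality), linkage map heterogeneity,
sex chromosomes, and the actual LD decay profile of any real breed. Tests
passing on this generator therefore demonstrate that the *pipeline
machinery* behaves correctly and that the qualitative relationships
(accuracy vs density, accuracy vs relatedness, low-LD detectability) are
reproduced — not that any particular accuracy level transfers to real data.

## Numerical conventions

- MISSING is −1 in an int8 matrix; dosage 0 and MISSING are never conflated.
- Undefined statistics (r², CORR, MAF on empty data) are NaN and excluded
  from averages; they are never silently zeroed.
- Ties: chip-design criteria break to the lowest bp position; the mode
  imputer to the lower dosage; the nn imputer to the first reference animal
  in id order. All outputs are deterministic given inputs and seed.
- GRM symmetry holds to 1e-10; the VanRaden denominator must be positive
  (all-monomorphic input is an error, not a NaN matrix).
- Every random process consumes a `numpy.random.Generator` seeded from
  `SimConfig.seed`; identical configs produce byte-identical datasets.

## Problem sizes

The default study is 650 simulated animals (60 founders, 440 breeding-line
animals, 150 validation) × 11,600 markers; a fixture builds in ~2 s and the
full evaluation ladder (four chip densities, nearest-neighbour baseline,
scoring, regressions) runs in well under a minute on one CPU. These sizes
were chosen so the complete test suite and the acceptance script rerun
comfortably on a laptop while keeping enough markers per chromosome (400)
for the windowing, LD and relationship structure to be non-trivial.

## Known limitations

- The nn-window baseline copies genotypes, not haplotypes; it cannot
  exploit phase and its absolute accuracy is far below real imputation
  software. It exists to make the evaluation machinery testable.
- The HWE z-test form is a convention choice (see above); results at the
  10⁻⁵ threshold are insensitive to it for gross violations but an exact
  test would disagree near the boundary.
- Sample-frequency GRMs are reported as-is; no base-frequency estimation or
  G–A blending is attempted for real data where founders are ungenotyped.
- PED/MAP without the extended 6-column map cannot round-trip the B-allele
  identity of monomorphic markers (format limitation, documented above).
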