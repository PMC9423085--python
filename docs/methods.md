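# Methods

`lenspop` implements a joint SNP + copy-number population-genomics analysis
for exome-capture diversity panels of highly selfing crops, together with a
synthetic-panel generator that reproduces the statistical structure such an
analysis assumes. This note documents the models, the parameters that
matter, the numerical choices, and what the synthetic data can and cannot
show.

## The synthetic panel

The generator (`lenspop.sim`) emulates a diversity panel of a selfing
diploid genotyped by exome capture. It does **not** simulate sequences,
reads, or recombination; it draws the summary objects the analysis consumes
(genotype dosages, per-target read depths, gene annotations) from explicit
probability models.

**Population structure.** Ancestral allele frequencies are drawn from a
density proportional to 1/p (the stationary neutral infinite-sites shape,
log-uniform on [1e-3, 1-1e-3]), so that under no structure and no selfing
the sample site-frequency spectrum matches the Watterson expectation
θ_W / i. Cluster frequencies disperse around the ancestral value under a
Balding–Nichols beta model. Each of the K clusters gets its own drift
parameter spanning [0.5, 1.5] × `fst_between_clusters`: real panels are
unevenly diverged (peripheral gene pools drift more than those near the
center of origin), and the spread makes pairwise differentiation genuinely
rankable rather than exchangeable noise.

**Selfing.** Genotypes are drawn with the equilibrium inbreeding
coefficient F = s/(2−s) implied by the selfing rate s (default 0.95, a
modeling choice for a crop whose selfing rate is high but not published for
this panel; configurable). At s = 1 every genotype is homozygous.

**Exome geometry.** Genes tile each chromosome on a fixed grid (default one
3-kb gene per 50 kb); capture targets (120–500 bp) are spread along the
chromosomes. 80% of SNP positions fall inside genes — exome-capture
variants are in or near coding sequence, and this is what makes mapping
selection hits to genes meaningful at all.

**CNVs.** Implanted CNVs span ≥ `cnv_min_targets` contiguous targets
(default 5, plus a Poisson(3) extension). Global carrier frequency follows
Beta(0.5, 15) — mean ≈ 3%, matching the arithmetic of a panel where each
accession carries a few dozen of a few thousand CNV regions — and is
dispersed across clusters with the same per-cluster drift, then capped at
`cnv_max_freq` (default 0.08): a depth caller that normalizes against the
panel itself cannot see variants carried by a large fraction of the panel,
and the burden arithmetic says real CNVs are rare. Carrier zygosity follows
the inbreeding coefficient (a selfing-crop carrier is almost always
homozygous); copy ratios are 0 / 0.5 for deletions and 1.5 / 2 for
duplications.

**Read depth.** Depth is multiplicative:
`base_depth × gamma(6) target effect × lognormal sample effect ×
exp(low-rank batch field) × copy ratio × lognormal noise`. The noise
coefficient of variation is calibrated as `0.36 / cnv_z_shift` so that a
heterozygous deletion realizes a residual z-shift of about `cnv_z_shift`
(default 3) *after* the carrier's own contribution to the per-target spread
is accounted for; homozygous carriers land near 4 z. The two batch
components (amplitude 0.15) dominate the log-depth covariance (> 50% of
variance), which is what the PCA normalization exists to remove.

**Sweeps.** A hard sweep at (chromosome, position) forces a randomly drawn
haplotype to ~92% frequency over a `sweep_width_bp` window (default 400 kb;
selfing stretches sweeps) in one designated cluster. Every gene inside the
swept interval is recorded as a truth sweep gene: within the shared
haplotype no method — nor the real data — can single out the causal gene.

**Determinism.** All stages draw from substreams spawned from one
`SeedSequence(seed)`; identical configs produce byte-identical output
files.

## CNV discovery

The caller follows the exome-HMM recipe: drop targets shorter than 100 bp
or with cross-sample mean depth outside [3×, 3000×]; center raw depth per
target; remove the top principal components across samples ("auto" =
components holding > 0.7/n_samples of the variance); z-score residuals per
target (n−1 denominator; residuals at float-noise level give z = 0); decode
a 3-state HMM (DEL, DIPLOID, DUP) per sample and chromosome with Gaussian
emissions at −3/0/+3 z (sd 1), entry probability `p_cnv` and geometric
dwell of `mean_targets_per_cnv` targets (default 6). Viterbi gives the
calls; the forward–backward posterior of the call state, averaged over its
targets, is the call quality.

`p_cnv` defaults to 1e-6. Larger values (1e-4) admit short spurious runs
from the right tail of multiplicative depth noise; the classical
exome-tool default (1e-8) costs recall on marginal heterozygous events.
1e-6 balances the two at panel sizes of tens of samples; the parameter is
configurable and echoed in the run log.

Two properties of the normalization are worth knowing. First, the "auto"
variance threshold will absorb *common* CNV structure into the removed
components — fine for discovery of rare CNVs, but it attenuates (and can
invert) differentiation signals carried by frequent CNVs; when V_ST is the
goal and the nuisance rank is known, remove a fixed component count
instead. Second, per-target z-scores include the carriers themselves, so a
CNV at carrier frequency f loses roughly a factor √(1 + f(1−f)·δ²/cv²) of
its z-shift; above f ≈ 0.15 heterozygous events become undetectable by
construction.

Calls are union-merged across samples into CNV regions (a region may have
both deletion and duplication carriers, as observed in real panels);
frequencies are carriers/cluster-size; a region is private to a cluster iff
all carriers belong to it.

## SNP filtering

First pass (after CNV discovery, whose regions are excluded): site quality
≥ 30, per-site mean depth ≥ 3×, missingness ≤ 0.10, biallelic only,
minor-allele count ≥ 5 (computed on non-missing genotypes; "allele count"
read as minor-allele count, the common VCF-filtering semantics). The
removal report attributes each dropped site to the first failed rule in the
fixed order quality → depth → missingness → biallelic → MAC → region, so
counts are reproducible. Second pass, applied only before the outlier scan:
MAC ≥ 10, greedy 2000-bp thinning (first site per chromosome kept), CNV
regions excluded.

## Statistics

**F_ST.** Weir–Cockerham (1984) variance components a, b, c for diploid
data with unequal sample sizes; θ = a/(a+b+c) per site, ratio of sums
Σa/Σ(a+b+c) for windows (100 kb / 50 kb step) and multi-locus means. Sites
where either group has < 2 called genotypes are flagged missing.

**V_ST.** Per CNV region, the per-sample value is the mean normalized depth
over the region's targets; V_T is the pooled two-cluster sample variance,
V_S the sample-size-weighted mean of within-cluster variances, V_ST =
(V_T − V_S)/V_T. All variances use n−1 — the statistic's sign near zero
depends on this convention (e.g. {0,2} vs {0,2} gives exactly −0.5). V_ST
is invariant under affine rescaling of the depth values.

**Tajima's D.** 100-kb nonoverlapping windows per cluster; π from per-site
allele counts, θ_W = S/a₁, variance via the standard a₁…e₂ constants, with
n the (rounded mean) number of called chromosomes; windows with S < 3 are
missing.

**Diversity.** Segregating sites per cluster; rarefied allelic and private
allelic richness by the exact hypergeometric formulation (presence
probability 1 − C(N−N_a, g)/C(N, g); private = presence in the focal
cluster × absence in size-g subsamples of every other cluster); observed
SFS with alt-as-derived polarization (folded option available), sites with
uneven missingness standardized to a common n by hypergeometric
down-projection; expected SFS as θ_W/i, which totals S exactly.

**Selection.** H12 = (p₁+p₂)² + Σ_{i>2} p_i² over sliding windows of 50
SNPs stepped by 5. Samples are reduced to pseudo-haplotypes: heterozygous
calls are treated as missing, haplotypes with > 20% missing in a window are
dropped, remaining gaps take the window major allele — defensible only
because the organism is highly selfing. Peaks are runs of windows above
median + 2×MAD (configurable; an invented threshold, as the original peak
caller's rule is not published), discarded if spanning ≤ 150 kb (the LD
scale), ranked by max H12, top 5 per chromosome. The PCA outlier scan
standardizes genotypes, regresses each SNP on the top K sample PCs,
converts the K z-statistics to a robust-covariance Mahalanobis distance,
rescales by a genomic-inflation factor (null median matched to χ²_K), and
flags SNPs by Benjamini–Hochberg-adjusted p < 0.01 (the source threshold
"0.01" is interpreted as an FDR level; raw p-values are also returned, and
type-I calibration is assessed on them because an FDR flag count under a
true null is degenerately zero). Genes detected by ≥ 2 methods form the
consensus; an externally produced outlier gene list can serve as a third
method. SNP-to-gene mapping is direct overlap with a configurable flank
(0 by default; ~10 kb is reasonable for a selfing genome with 150-kb LD).

**Enrichment.** Affected genes per cluster are those overlapped by a CNV
region at cluster carrier frequency strictly greater than 0.20. The
category test compares observed (gene, label) counts against genome-wide
label fractions with a χ² statistic whose null comes from resampling
equally sized uniform gene sets (default 10,000 draws); p = (1 + #{null ≥
obs})/(n+1), so the floor is 1/(n+1) and p is reproducible bit-exactly
given the seed. Multi-label genes contribute one count per label in both
observed and null sets; unlabeled genes count as "Not assigned".
Standardized residuals beyond ±2 mark over/under-represented categories.
The resistance-gene overlap test is the analogous one-sided count test.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen to keep the
statistical checks well-powered while finishing in minutes: recovery panels
of 50 samples × 2000 targets with 30 implanted CNVs (5 seeds); sweep panels
of 60 samples × 4000 exome SNPs with one 500-kb sweep (5 seeds);
calibration panels of 90 samples × 5000 SNPs; enrichment backgrounds of
5000 genes. The full-pipeline summary panel uses 160 accessions in 8
clusters over 7 chromosomes.

## What passing tests do and do not show

The generator reproduces the *statistical* structure the analysis assumes:
cluster-dispersed frequencies, inbred genotypes, low-frequency multi-target
CNVs with calibrated depth shifts, low-rank batch noise, hard sweeps. Real
exome data additionally contain GC- and mappability-driven depth bias
correlated along the genome, linkage disequilibrium decaying with distance
(synthetic sites are independent draws outside sweep windows), reference
bias, genotyping error correlated with depth, and partially admixed
individuals. Passing the recovery and calibration tests therefore shows the
estimators and the caller are correct and well-calibrated under the model's
assumptions — not that the pipeline is robust to every artifact of a real
capture assay. The H12 scan in particular sees no background LD here, so
its null distribution on real data will be wider than in these tests.
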