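# Methods

This note records the models, the defaults and why they were chosen,
the numerical conventions, and what the synthetic benchmark does and
does not demonstrate.

## Data model and filtering

Genotypes live in a samples × variants dosage matrix (0/1/2 alternate
alleles, −1 missing) with 1-based coordinates; variants are never
reordered within a chromosome, and missing calls are never imputed —
every statistic defines its own missing-data handling.

The filter chain runs in a fixed, logged order: depth masking of
individual calls (DP < 6 → missing, when depth is present), autosome
restriction, per-variant call rate (> 0.9, strict), per-sample call rate
(> 0.9), MAF ≥ 0.01, exact Hardy–Weinberg test p ≥ 1e-6. Variant-level
call rate is applied before sample-level (the thresholds themselves do
not determine an order, so one is fixed and reported). MAF and HWE use
the pooled non-degraded samples of the matrix at hand; to filter per
population, filter each population's matrix separately. The chain is
idempotent.

The HWE test is the exact conditional test on the heterozygote count
given the allele counts, summing the probabilities of all configurations
no more probable than the observed one (Wigginton/Cutler/Abecasis
convention, no mid-p); it is validated against an integer-arithmetic
enumeration oracle for every configuration up to n = 50.

Samples flagged *degraded* (e.g. archival material with very low
coverage) bypass the call-rate/MAF/HWE filters, contribute to no site
statistic, and receive only F_HOM, provided they carry at least 1,000
non-missing SNPs.

## Diversity, LD pruning, GRM, PCA

Per-site nucleotide diversity is the unbiased per-site heterozygosity
2·c_ref·c_alt / (n(n−1)) over the n observed alleles. LD r² is the
squared Pearson correlation of unphased dosages (composite LD — no
phasing exists in this pipeline) over pairwise-complete samples.
Pruning slides a 50-SNP window in 5-SNP steps and greedily drops the
later SNP of any pair with r² > 0.9; the window/step are conventional
defaults, the cutoff is the method's parameter. The first SNP of a
chromosome can never be removed (it is always the earlier member of its
pairs), which anchors determinism.

The GRM is VanRaden method 1: centred cross-products scaled by
Σ2p(1−p), with a missing dosage contributing zero to the numerator and
its 2p(1−p) term removed from that sample pair's denominator. This makes
diag(GRM) − 1 algebraically identical to F_VR1, which is asserted to
1e-10 in the tests. PCA is the eigendecomposition of the GRM; variance
explained is the eigenvalue over the sum of positive eigenvalues.

## Windowed F_ST

Per SNP, the Weir–Cockerham (1984) two-population variance components
(a, b, c) including the heterozygosity correction; windows of 200 kb
sliding by 100 kb are anchored at position 1 of each chromosome, the
final partial window retained. A window's weighted F_ST is Σa/Σ(a+b+c);
SNP-free or zero-denominator windows are emitted flagged (NaN) and
excluded from threshold statistics. Negative window values are retained
in the mean + 3.5·SD threshold (dropping them would bias the mean
upward). Significant windows that overlap or abut merge into maximal
regions carrying the per-region maximum.

## SNP-by-SNP estimators

The five estimators (formulas in the README) are computed per sample on
that sample's non-missing SNPs. Allele frequencies default to the
observed frequencies in the sample's own population, focal individual
included (matching standard GRM tooling); a flag excludes the focal
individual, and an external frequency vector can be supplied. SNPs
monomorphic in the frequency source are excluded from the four
frequency-adjusted estimators (their 2p(1−p) weight is zero) and kept
for F_HOM. With plug-in frequencies from n individuals, the null
expectation of the adjusted estimators is ≈ −1/(2n), not exactly zero;
the null tests account for this.

## ROH detection

The four-stage sliding-run procedure: (1) every 15-SNP window is
*homozygous* iff it holds ≤1 heterozygous and ≤1 missing call; (2) a SNP
is *in-run* iff the proportion of windows covering it that are
homozygous exceeds 0.05, with the reduced denominator at chromosome ends
(edge-correct); (3) maximal stretches of consecutive in-run SNPs, split
at inter-SNP gaps > 1 Mb, become candidates; (4) candidates must hold
≥20 SNPs, span ≥500 kb, and average at least one SNP per 200 kb.
Segment coordinates are the first/last SNP positions (not window
edges), length = end − start + 1, and tolerated heterozygotes inside a
run count toward its SNP total. The in-run threshold (0.05) and maximum
gap (1 Mb) are the customary defaults of the sliding-run method; the
SNP-count/length/density floors are the analysis parameters.

A consequence worth knowing: because one window may hold one
heterozygote, the single SNP flanking a homozygous block on each side is
itself in-run, so a block of H homozygous SNPs yields an (H+2)-SNP run
when flanked by heterozygotes. A second consequence is that the detector
has a small but strictly positive false-positive rate on genuinely
outbred genotypes — with HWE genotypes at MAF ≥ 0.2 and one SNP per
40 kb, about 0.2 qualifying chance runs appear per 100 Mb of genome.
This is a property of the window rules themselves (the detector agrees
exactly with a brute-force transcription of the four stages), so
specificity claims of "zero chance ROH" do not hold at these marker
densities; the test suite documents this.

F_ROH divides each individual's summed segment lengths by the autosomal
length covered by SNPs (per chromosome, last SNP − first SNP + 1).
Incidence hotspots flag SNPs covered by segments in more than 70% of all
samples (pooled across populations by default; a per-population split is
available) and merge ±100 kb flanks around flagged SNPs.

## HBD hidden-Markov model

Each genome is a mosaic over K = 7 HBD classes plus one non-HBD class.
Segment lengths are exponential on the genetic map with fixed rates
R_k = 2^k per Morgan (k = 1…7); smaller rates mean longer segments from
older inbreeding. The non-HBD class shares the largest rate. Physical
positions convert at a constant 1 cM/Mb (no species genetic map is
assumed; configurable). Transitions over distance d Morgans:
T(k,j) = e^(−R_k·d)·δ_kj + (1 − e^(−R_k·d))·γ_j — leave the current
segment with rate R_k and re-enter class j with mixing weight γ_j; the
chain starts from γ at each chromosome.

Emissions: non-HBD SNPs emit Hardy–Weinberg genotype probabilities; HBD
SNPs emit the two homozygotes at their allele frequencies and never a
heterozygote; both are mixed with an error mass ε = 0.001 toward the HWE
distribution. ε is the dominant knob for how many short segments are
called: larger ε absorbs isolated heterozygotes into long HBD segments,
smaller ε fragments them. Missing genotypes emit 1 in every class.
Fixed sites (p ∈ {0,1}) carry no information and are excluded.

Only the mixing weights γ are fitted (per sample, EM); rates are never
re-estimated. The E-step accumulates the expected number of γ-choice
events — chromosome starts plus segment re-entries — from the scaled
forward–backward pass; the M-step renormalises them. This is exact EM
for the mixture construction, so the log-likelihood is non-decreasing
(asserted in tests); iteration stops at a gain < 1e-6 or 1,000
iterations, with unconverged samples flagged. The forward pass exploits
the transition structure to run in O(K) per SNP and is verified against
exhaustive path enumeration on small instances to 1e-10 relative.

Realized autozygosity per class is the genome-mean posterior class
membership; F_HBD sums the seven HBD classes. Segments are decoded as
maximal stretches with total HBD posterior > 0.5 (the dominant class is
the argmax of the mean within-stretch posterior); the 0.5 threshold is
this package's convention and is configurable.

## Synthetic-data generator

The generator emulates the statistical structure of a two-population
resequencing panel: ancestral MAF uniform on [0.05, 0.5], per-population
frequencies from the Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F) with
divergence F (default 0.05, matching a pair of recently separated
breeds), clipped 1e-4 from fixation; SNPs on a regular grid (default one
per 25 kb); per-individual autozygous tracts placed by an alternating
exponential renewal process whose HBD rate (default 8/Morgan, i.e.
12.5-Mb mean tracts at 1 cM/Mb) is shared with the HBD model's scale so
planted lengths and model rates agree; symmetric genotype-code errors
and uniform missingness applied last. Inside a tract both gametes copy
one allele draw; outside they are independent. Truth tables record every
tract, each individual's realized fraction (= Σ tract length / genome
length, exactly), and the drawn frequencies.

What it does **not** emulate — and therefore what passing recovery tests
do not show about real data: background LD (sites are independent given
frequencies, so chance ROH are far rarer than on real genomes and
LD pruning is a near no-op), a realistic site-frequency spectrum,
variable recombination, call-rate structure correlated with depth, and
reference bias. Recovery results on this benchmark bound the method's
algorithmic correctness, not its field accuracy.

## Problem sizes in the test suite

The bundled benchmarks use genomes of 2–4 chromosomes × 20–50 Mb with
2,000–8,000 SNPs and 20–100 individuals — large enough that window
statistics, tract placement and EM fitting operate in their asymptotic
regime, while a full run of the suite and the acceptance script each
complete in minutes on a single core.

## Known limitations

- The constant 1 cM/Mb map makes HBD class rates only nominally
  calibrated in physical units for any real species.
- Frequency-adjusted estimators inherit the −1/(2n) plug-in bias when
  frequencies come from small samples; no leave-one-out correction is
  applied by default.
- The ROH detector's chance-run rate at moderate marker density is
  nonzero (see above); length/count comparisons across datasets with
  different densities need care.
- Per-population MAF/HWE filtering requires splitting the matrix per
  population before filtering; the chain itself pools.
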