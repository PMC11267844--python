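# inbredscan

Genomic inbreeding analysis for diploid resequencing panels: variant
filtering, diversity and population-structure statistics, a windowed
Weir–Cockerham F<sub>ST</sub> differentiation scan, five SNP-by-SNP
inbreeding estimators, sliding-window detection of runs of homozygosity
(ROH) with F<sub>ROH</sub>, and a multi-class homozygosity-by-descent
(HBD) hidden-Markov model yielding F<sub>HBD</sub>. A synthetic
two-population genotype simulator with known truth is included so every
stage can be validated against planted signal.

The package is aimed at population and livestock geneticists who start
from a multi-sample VCF of biallelic SNPs (plus a sample-to-population
map) and want per-individual inbreeding coefficients, differentiated
regions, and ROH/HBD hotspot regions as plain TSV/BED tables.

## The statistics

With dosages x<sub>k</sub> ∈ {0, 1, 2} counting the alternate allele at
SNP k, allele frequency p<sub>k</sub> from the individual's own
population, and S SNPs:

- **F_HOM** = 1 − Σ x<sub>k</sub>(2 − x<sub>k</sub>) / S — observed
  homozygosity.
- **F_L&H** = 1 − Σ x<sub>k</sub>(2 − x<sub>k</sub>) / Σ 2p<sub>k</sub>(1 − p<sub>k</sub>)
  — homozygosity adjusted by expected heterozygosity.
- **F_VR1** = Σ (x<sub>k</sub> − 2p<sub>k</sub>)² / Σ 2p<sub>k</sub>(1 − p<sub>k</sub>) − 1
  — the VanRaden GRM diagonal minus one (ratio of sums).
- **F_VR2** = mean over SNPs of (x<sub>k</sub> − 2p<sub>k</sub>)² / (2p<sub>k</sub>(1 − p<sub>k</sub>)) − 1
  (sum of ratios).
- **F_YAN** = mean over SNPs of
  (x<sub>k</sub>² − (1 + 2p<sub>k</sub>)x<sub>k</sub> + 2p<sub>k</sub>²) / (2p<sub>k</sub>(1 − p<sub>k</sub>))
  — correlation between uniting gametes.
- **F_ROH** = Σ L<sub>ROH</sub> / L<sub>AUTO</sub>, where ROH come from
  the classic 15-SNP sliding-window scan (≤1 het and ≤1 missing call per
  window; runs kept at ≥20 SNPs, ≥500 kb, ≥1 SNP/200 kb) and
  L<sub>AUTO</sub> is the autosomal length covered by SNPs.
- **F_HBD** = summed realized autozygosity over seven HBD classes of an
  exponential-length hidden-Markov model with fixed rates
  R<sub>k</sub> = 2<sup>k</sup> per Morgan (k = 1…7) plus a non-HBD
  class; class mixing weights are fitted per individual by EM.

Differentiation uses the Weir–Cockerham (1984) variance components; a
window's weighted F<sub>ST</sub> is Σa / Σ(a+b+c) over its SNPs
(200-kb windows, 100-kb step), and windows above mean + 3.5 SD merge
into significant regions.

## Worked example

```python
from inbredscan import (SimConfig, sim_dataset, detect_roh, f_roh,
                        fit_em, genome_wide_fst, inbreeding_table)

cfg = SimConfig(
    pop_sizes=(("popA", 20), ("popB", 20)),
    n_chrom=2, chrom_length_bp=50_000_000, snp_spacing_bp=25_000,
    divergence_f=0.05, autozygosity_fraction=0.2, tract_rate=8.0, seed=42,
)
G, truth = sim_dataset(cfg)
print("true mean autozygosity: %.3f" % truth.fractions["true_fraction"].mean())
print("genome-wide weighted Fst: %.4f" % genome_wide_fst(G))
table = inbreeding_table(G)
print("mean F_HOM: %.3f   mean F_L&H: %.3f" % (table.f_hom.mean(), table.f_lh.mean()))
segments = detect_roh(G)
print("ROH detected: %d, mean length %.2f Mb" % (len(segments), segments.length.mean() / 1e6))
print("mean F_ROH: %.3f" % f_roh(segments, G)["f_roh"].mean())
print("mean F_HBD: %.3f" % fit_em(G).autozygosity["f_hbd"].mean())
```

prints

```
true mean autozygosity: 0.199
genome-wide weighted Fst: 0.0520
mean F_HOM: 0.723   mean F_L&H: 0.175
ROH detected: 194, mean length 4.54 Mb
mean F_ROH: 0.220
mean F_HBD: 0.200
```

The simulator planted autozygous tracts covering 19.9% of each genome at
a Balding–Nichols divergence of 0.05; the windowed scan recovers the
divergence (0.052) and both segment-based coefficients recover the
planted autozygosity (0.220 and 0.200). F_HOM is high because most SNPs
are homozygous in any individual; F_L&H corrects by the expected
heterozygosity and lands near the true inbreeding.

The same analyses run from the shell:

```bash
inbredscan simulate --out sim/ --seed 7 --fraction 0.2
inbredscan run sim/simulated.vcf sim/pop_map.tsv --out report/
```

`report/` then holds the filter report, per-site statistics, PCA scores,
F<sub>ST</sub> windows and significant regions, the per-sample table of
all seven inbreeding measures, ROH segments and incidence regions, HBD
segments, and a JSON summary, with the merged configuration echoed
alongside.

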