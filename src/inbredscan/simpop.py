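"""Synthetic genotype generator with known truth.

Emulates the statistical structure of a two-population resequencing
panel: Balding-Nichols allele-frequency divergence between populations,
per-individual autozygous (HBD) tracts placed by an alternating
exponential renewal process on a constant genetic map, genotyping error,
and missingness.  Sites are independent given their frequencies — no
background LD is simulated — so chance long runs of homozygosity are
vanishingly rare and planted-tract recovery tests stay sharp.

Truth tables record every planted tract, each individual's realized
autozygous fraction, and the per-population frequencies actually drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix
from .genotype_io import write_tsv, write_vcf

_MORGAN_BP = 1e8  # bp per Morgan at 1 cM/Mb


@dataclass
class SimConfig:
    """Study-shaped defaults: two diverged populations on a small genome.

    ``autozygosity_fraction`` may be a scalar (shared target) or a
    sequence with one target per individual (populations concatenated in
    order).  ``tract_rate`` is the exponential rate per Morgan of HBD
    tract lengths (rate 8 => 12.5 Mb mean tracts at 1 cM/Mb).
    """

    n_chrom: int = 2
    chrom_length_bp: int = 50_000_000
    snp_spacing_bp: int = 25_000
    maf_low: float = 0.05
    maf_high: float = 0.5
    divergence_f: float = 0.05
    pop_sizes: tuple = (("pop1", 30), ("pop2", 30))
    autozygosity_fraction: float | tuple = 0.0
    tract_rate: float = 8.0
    error_rate: float = 0.0
    missing_rate: float = 0.0
    cm_per_mb: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence_f < 1.0:
            raise ValueError("divergence_f outside [0, 1)")
        for v in np.atleast_1d(np.asarray(self.autozygosity_fraction, float)):
            if not (0.0 <= v <= 0.95 or v == 1.0):
                raise ValueError(
                    f"target autozygous fraction {v} unreachable "
                    "(must be <= 0.95, or exactly 1)"
                )
        for r in (self.error_rate, self.missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return sum(n for _, n in self.pop_sizes)

    @property
    def genome_length(self) -> int:
        return self.n_chrom * self.chrom_length_bp

    def positions(self) -> np.ndarray:
        """SNP positions on one chromosome: a regular grid."""
        return np.arange(self.snp_spacing_bp, self.chrom_length_bp + 1,
                         self.snp_spacing_bp, dtype=np.int64)

    def fractions(self) -> np.ndarray:
        f = np.atleast_1d(np.asarray(self.autozygosity_fraction, float))
        if f.size == 1:
            f = np.repeat(f, self.n_samples)
        if f.size != self.n_samples:
            raise ValueError("one autozygosity fraction per individual needed")
        return f


@dataclass
class SimTruth:
    """Recovery-test oracle for a simulated dataset."""

    tracts: pd.DataFrame      # sample, chrom, start, end, length
    fractions: pd.DataFrame   # sample, population, true_fraction
    freqs: pd.DataFrame       # chrom, pos, p_ancestral, p_<pop>...
    divergence_f: float

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_tsv(self.tracts, outdir / "truth_tracts.tsv")
        write_tsv(self.fractions, outdir / "truth_fractions.tsv")
        write_tsv(self.freqs, outdir / "truth_freqs.tsv")


# ----------------------------------------------------------------------

def sim_freqs(cfg: SimConfig, rng: np.random.Generator):
    """Ancestral alt-allele frequencies and per-population Balding-Nichols
    draws ``Beta(p(1-F)/F, (1-p)(1-F)/F)``, clipped away from fixation.

    With F = 0 the per-population frequencies equal the ancestral ones.
    """
    n_snps = cfg.positions().size * cfg.n_chrom
    maf = rng.uniform(cfg.maf_low, cfg.maf_high, n_snps)
    p_anc = np.where(rng.random(n_snps) < 0.5, maf, 1.0 - maf)
    F = cfg.divergence_f
    per_pop = {}
    for pop, _ in cfg.pop_sizes:
        if F == 0.0:
            per_pop[pop] = p_anc.copy()
        else:
            scale = (1.0 - F) / F
            draws = rng.beta(p_anc * scale, (1.0 - p_anc) * scale)
            per_pop[pop] = np.clip(draws, 1e-4, 1.0 - 1e-4)
    return p_anc, per_pop


def sim_tracts(cfg: SimConfig, fraction: float,
               rng: np.random.Generator) -> list:
    """Plant autozygous tracts on every chromosome by alternating
    exponential segments; returns (chrom_index, start, end) tuples.

    HBD lengths are Exp(``tract_rate``) on the genetic map; the non-HBD
    waiting scale is set so the stationary autozygous fraction equals the
    target.
    """
    if fraction == 0.0:
        return []
    tracts = []
    L = cfg.chrom_length_bp
    if fraction == 1.0:
        return [(c, 1, L) for c in range(cfg.n_chrom)]
    mean_hbd_bp = _MORGAN_BP / cfg.tract_rate / cfg.cm_per_mb
    mean_non_bp = mean_hbd_bp * (1.0 - fraction) / fraction
    for c in range(cfg.n_chrom):
        pos = 1
        in_hbd = rng.random() < fraction
        while pos <= L:
            if in_hbd:
                length = max(1, int(rng.exponential(mean_hbd_bp)))
                tracts.append((c, pos, min(pos + length - 1, L)))
            else:
                length = max(1, int(rng.exponential(mean_non_bp)))
            pos += length
            in_hbd = not in_hbd
    return tracts


def sim_individual(pop_freqs: np.ndarray, positions: np.ndarray,
                   tracts_bp: list, chrom_index: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Genotypes for one individual on one chromosome.

    Inside a tract both gametes copy a single allele draw (fully
    autozygous); outside, the two gametes are independent.
    """
    n = positions.size
    in_tract = np.zeros(n, dtype=bool)
    for c, start, end in tracts_bp:
        if c == chrom_index:
            in_tract |= (positions >= start) & (positions <= end)
    geno = rng.binomial(2, pop_freqs)
    auto = 2 * rng.binomial(1, pop_freqs[in_tract])
    geno[in_tract] = auto
    return geno.astype(np.int8)


def sim_dataset(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate the full dataset: genotype matrix plus truth tables.

    Deterministic for a fixed config (including seed).  Genotyping errors
    flip a call to a uniformly chosen different dosage; missingness is
    applied last.
    """
    rng = np.random.default_rng(cfg.seed)
    p_anc, per_pop = sim_freqs(cfg, rng)
    positions = cfg.positions()
    n_per_chrom = positions.size
    chroms = [f"chr{c + 1}" for c in range(cfg.n_chrom)]

    sample_ids, pop_labels = [], []
    for pop, n in cfg.pop_sizes:
        sample_ids += [f"{pop}_{i + 1:03d}" for i in range(n)]
        pop_labels += [pop] * n
    fractions = cfg.fractions()

    calls = np.empty((len(sample_ids), n_per_chrom * cfg.n_chrom),
                     dtype=np.int8)
    tract_rows, frac_rows = [], []
    for i, (sid, pop) in enumerate(zip(sample_ids, pop_labels)):
        tracts = sim_tracts(cfg, fractions[i], rng)
        realized = sum(e - s + 1 for _, s, e in tracts)
        frac_rows.append((sid, pop, realized / cfg.genome_length))
        for c, s, e in tracts:
            tract_rows.append((sid, chroms[c], s, e, e - s + 1))
        for c in range(cfg.n_chrom):
            sl = slice(c * n_per_chrom, (c + 1) * n_per_chrom)
            calls[i, sl] = sim_individual(
                per_pop[pop][sl], positions, tracts, c, rng)

    if cfg.error_rate > 0:
        err = rng.random(calls.shape) < cfg.error_rate
        shift = rng.integers(1, 3, size=calls.shape)  # +1 or +2 mod 3
        calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
    if cfg.missing_rate > 0:
        calls[rng.random(calls.shape) < cfg.missing_rate] = MISSING

    variants = pd.DataFrame({
        "chrom": np.repeat(chroms, n_per_chrom),
        "pos": np.tile(positions, cfg.n_chrom),
        "ref": "A",
        "alt": "G",
    })
    G = GenotypeMatrix(sample_ids, np.array(pop_labels, dtype=object),
                       variants, calls)
    freqs = variants[["chrom", "pos"]].copy()
    freqs["p_ancestral"] = p_anc
    for pop, _ in cfg.pop_sizes:
        freqs[f"p_{pop}"] = per_pop[pop]
    truth = SimTruth(
        tracts=pd.DataFrame(
            tract_rows, columns=["sample", "chrom", "start", "end", "length"]),
        fractions=pd.DataFrame(
            frac_rows, columns=["sample", "population", "true_fraction"]),
        freqs=freqs,
        divergence_f=cfg.divergence_f,
    )
    return G, truth


def sim_to_files(cfg: SimConfig, outdir) -> tuple[Path, Path]:
    """Simulate and export VCF + truth TSVs + pop map; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    G, truth = sim_dataset(cfg)
    vcf_path = outdir / "simulated.vcf"
    write_vcf(G, vcf_path)
    truth.write(outdir)
    pop_map = outdir / "pop_map.tsv"
    pd.DataFrame({"sample": G.sample_ids, "population": G.pop_labels}).to_csv(
        pop_map, sep="\t", index=False, header=False)
    return vcf_path, pop_map
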