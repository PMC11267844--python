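"""VCF/BED/TSV input-output and the post-calling variant and sample filters.

The filter chain mirrors standard resequencing QC: restrict to biallelic
autosomal SNPs, mask low-depth calls, drop variants and samples with call
rate at or below 0.9, then drop variants with MAF < 0.01 or an exact
Hardy-Weinberg test P below 1e-6.  The order is fixed and every step's
removal count is reported so the chain can be audited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotype import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# Hardy-Weinberg exact test
# ----------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test on one biallelic site.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote configuration no more probable than the observed one
    (the Wigginton/Cutler/Abecasis convention, no mid-p correction).

    Returns a p-value in (0, 1]; a monomorphic site returns 1.0 since only
    one configuration exists.
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype count in {counts}")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n - n_A
    if n_A == 0 or n_a == 0:
        return 1.0
    n_rare = min(n_A, n_a)
    # het counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    n_AA_all = (n_A - hets) // 2
    n_aa_all = (n_a - hets) // 2
    ok = (n_AA_all >= 0) & (n_aa_all >= 0)
    hets, n_AA_all, n_aa_all = hets[ok], n_AA_all[ok], n_aa_all[ok]
    # P(n_Aa = h | n, n_A) = n! 2^h n_A! n_a! / (n_AA! n_Aa! n_aa! (2n)!)
    logp = (
        gammaln(n + 1)
        - gammaln(n_AA_all + 1)
        - gammaln(hets + 1)
        - gammaln(n_aa_all + 1)
        + hets * np.log(2.0)
        + gammaln(n_A + 1)
        + gammaln(n_a + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_Aa][0]
    pval = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(pval, 1.0))


def hwe_exact_vector(calls: np.ndarray) -> np.ndarray:
    """HWE exact p-value per variant for a (samples, variants) call matrix."""
    out = np.empty(calls.shape[1])
    for k in range(calls.shape[1]):
        x = calls[:, k]
        x = x[x != MISSING]
        if x.size == 0:
            out[k] = np.nan
            continue
        out[k] = hwe_exact_test(
            int(np.sum(x == 0)), int(np.sum(x == 1)), int(np.sum(x == 2))
        )
    return out


# ----------------------------------------------------------------------
# Filtering
# ----------------------------------------------------------------------

@dataclass
class FilterConfig:
    """Thresholds for the post-calling filter chain."""

    min_depth: int = 6
    min_call_rate_variant: float = 0.9
    min_call_rate_sample: float = 0.9
    min_maf: float = 0.01
    hwe_alpha: float = 1e-6
    autosomes: frozenset | None = None  # None = keep every chromosome
    min_snps_degraded: int = 1000

    def __post_init__(self) -> None:
        for name in ("min_call_rate_variant", "min_call_rate_sample", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if self.autosomes is not None:
            self.autosomes = frozenset(self.autosomes)


@dataclass
class FilterReport:
    """Removal counts per filter step, in execution order."""

    steps: list = field(default_factory=list)  # (step name, n removed)
    n_variants_in: int = 0
    n_variants_out: int = 0
    n_samples_in: int = 0
    n_samples_out: int = 0
    messages: list = field(default_factory=list)

    def add(self, step: str, removed: int) -> None:
        self.steps.append((step, int(removed)))
        logger.info("filter step %-22s removed %d", step, removed)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["step", "n_removed"])


def apply_filters(
    G: GenotypeMatrix, cfg: FilterConfig | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Run the fixed-order filter chain on a genotype matrix.

    Order: (0) mask calls below the depth threshold when depth is stored,
    (1) autosomal chromosomes, (2) per-variant call rate, (3) per-sample
    call rate, (4) MAF, (5) HWE.  Call-rate, MAF and HWE statistics are
    computed over non-degraded samples; degraded samples bypass those
    filters entirely (they are only ever used for F_HOM downstream).
    Idempotent: running the chain twice equals running it once.
    """
    cfg = cfg or FilterConfig()
    rep = FilterReport(
        n_variants_in=G.n_variants, n_samples_in=G.n_samples
    )

    if G.depth is not None:
        low = (G.depth < cfg.min_depth) & (G.calls != MISSING)
        if low.any():
            calls = G.calls.copy()
            calls[low] = MISSING
            G = GenotypeMatrix(
                G.sample_ids, G.pop_labels, G.variants, calls,
                depth=G.depth, degraded=G.degraded,
            )
        rep.add("depth_mask_calls", low.sum())

    # (1) autosomes
    if cfg.autosomes is not None:
        keep = G.variants["chrom"].isin(cfg.autosomes).to_numpy()
        rep.add("autosomal", (~keep).sum())
        G = G.take_variants(keep)
    else:
        rep.add("autosomal", 0)

    core = ~G.degraded  # samples that count toward rates and site statistics
    if not core.any():
        raise ValueError("no non-degraded samples to filter on")

    # (2) per-variant call rate (strict >, matching 'calling rate > 0.9')
    called = G.calls[core] != MISSING
    rate_v = called.mean(axis=0)
    keep = rate_v > cfg.min_call_rate_variant
    rep.add("variant_call_rate", (~keep).sum())
    G = G.take_variants(keep)

    # (3) per-sample call rate; degraded samples bypass
    called = G.calls != MISSING
    rate_s = called.mean(axis=1)
    keep_s = (rate_s > cfg.min_call_rate_sample) | G.degraded
    rep.add("sample_call_rate", (~keep_s).sum())
    G = G.take_samples(keep_s)
    core = ~G.degraded

    # (4) MAF over non-degraded samples
    p = alt_freq(G.calls[core])
    maf = np.minimum(p, 1.0 - p)
    keep = np.where(np.isnan(maf), False, maf >= cfg.min_maf)
    rep.add("maf", (~keep).sum())
    G = G.take_variants(keep)

    # (5) HWE exact test over non-degraded samples
    pvals = hwe_exact_vector(G.calls[core])
    keep = np.where(np.isnan(pvals), False, pvals >= cfg.hwe_alpha)
    rep.add("hwe", (~keep).sum())
    G = G.take_variants(keep)

    if G.n_variants == 0:
        raise ValueError(
            "all variants removed by filtering; review thresholds "
            f"(steps: {rep.steps})"
        )
    rep.n_variants_out = G.n_variants
    rep.n_samples_out = G.n_samples
    return G, rep


def alt_freq(calls: np.ndarray) -> np.ndarray:
    """Alt-allele frequency per variant over non-missing calls (NaN if none)."""
    ok = calls != MISSING
    n_alleles = 2 * ok.sum(axis=0)
    alt = np.where(ok, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_alleles > 0, alt / n_alleles, np.nan)


# ----------------------------------------------------------------------
# VCF / BED / TSV
# ----------------------------------------------------------------------

def read_pop_map(path) -> dict:
    """Two-column TSV (sample, population) -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                     dtype=str, comment="#")
    return dict(zip(df["sample"], df["population"]))


def read_vcf(path, pop_map, min_depth: int | None = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a GenotypeMatrix.

    Multiallelic and non-SNP records are dropped (count logged).  When
    ``min_depth`` is given and the file carries FORMAT/DP, calls below the
    threshold are masked to MISSING.  Every sample in the VCF must appear
    in ``pop_map`` (a dict or a path to a two-column TSV).
    """
    import cyvcf2

    if not isinstance(pop_map, dict):
        pop_map = read_pop_map(pop_map)
    vcf = cyvcf2.VCF(str(path))
    samples = list(vcf.samples)
    missing_samples = [s for s in samples if s not in pop_map]
    if missing_samples:
        raise ValueError(
            f"samples absent from population map: {missing_samples}"
        )

    rows, dosages, depths = [], [], []
    n_dropped = 0
    has_dp = False
    dp_in_header = "DP" in [
        line.split("ID=")[1].split(",")[0]
        for line in vcf.raw_header.splitlines()
        if line.startswith("##FORMAT=")
    ]
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_dropped += 1
            continue
        gts = np.asarray(var.genotype.array())[:, :2]
        dos = np.where((gts < 0).any(axis=1), MISSING,
                       (gts > 0).sum(axis=1)).astype(np.int8)
        dp = var.format("DP") if dp_in_header else None
        if dp is not None:
            has_dp = True
            depths.append(np.asarray(dp).reshape(-1).astype(np.int32))
        else:
            depths.append(np.full(len(samples), -1, dtype=np.int32))
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        dosages.append(dos)
    vcf.close()
    if n_dropped:
        logger.info("read_vcf: dropped %d multiallelic/non-SNP records", n_dropped)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    calls = (np.array(dosages, dtype=np.int8).T if dosages
             else np.zeros((len(samples), 0), dtype=np.int8))
    depth = np.array(depths, dtype=np.int32).T if has_dp else None
    G = GenotypeMatrix(
        sample_ids=samples,
        pop_labels=np.array([pop_map[s] for s in samples], dtype=object),
        variants=variants,
        calls=calls,
        depth=depth,
    )
    if min_depth is not None and depth is not None:
        masked = G.calls.copy()
        masked[(depth >= 0) & (depth < min_depth)] = MISSING
        G = GenotypeMatrix(G.sample_ids, G.pop_labels, G.variants, masked,
                           depth=depth, degraded=G.degraded)
    return G


_GT_FOR_DOSE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 (GT, plus DP when depth is stored)."""
    path = Path(path)
    fmt = "GT" if G.depth is None else "GT:DP"
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if G.depth is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in G.chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.sample_ids) + "\n")
        v = G.variants
        for k in range(G.n_variants):
            cells = []
            for i in range(G.n_samples):
                gt = _GT_FOR_DOSE[int(G.calls[i, k])]
                if G.depth is not None:
                    gt += f":{int(G.depth[i, k])}"
                cells.append(gt)
            fh.write(
                f"{v.chrom.iat[k]}\t{v.pos.iat[k]}\t.\t{v.ref.iat[k]}\t"
                f"{v.alt.iat[k]}\t.\tPASS\t.\t{fmt}\t" + "\t".join(cells) + "\n"
            )


def write_bed(regions, path) -> None:
    """Write regions as BED (0-based half-open).

    ``regions`` is an iterable of (chrom, start, end) with 1-based inclusive
    coordinates, or a DataFrame with chrom/start/end columns.
    """
    if isinstance(regions, pd.DataFrame):
        regions = regions[["chrom", "start", "end"]].itertuples(index=False)
    with Path(path).open("w") as fh:
        for chrom, start, end in regions:
            fh.write(f"{chrom}\t{int(start) - 1}\t{int(end)}\n")


def write_tsv(table: pd.DataFrame, path) -> None:
    """Deterministic TSV dump (column order preserved, full float precision)."""
    table.to_csv(path, sep="\t", index=False)
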