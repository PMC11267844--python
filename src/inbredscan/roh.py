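"""Sliding-window detection of runs of homozygosity (ROH).

The detector follows the classic four-stage window procedure: slide a
15-SNP window one SNP at a time; a window is "homozygous" when it holds at
most one heterozygous and at most one missing call; a SNP is in-run when
the proportion of windows covering it that are homozygous exceeds a small
threshold (0.05); maximal stretches of in-run SNPs, split at large
inter-SNP gaps, become runs and are kept when they satisfy the minimum
SNP-count, length and density rules.

F_ROH is the summed run length over the autosomal length covered by SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix
from .popdiv import merge_intervals

logger = logging.getLogger(__name__)


@dataclass
class RohConfig:
    window_snps: int = 15
    step_snps: int = 1
    max_missing_in_window: int = 1
    max_het_in_window: int = 1
    snp_in_run_threshold: float = 0.05
    min_snps: int = 20
    min_length_bp: int = 500_000
    min_density_bp_per_snp: int = 200_000   # at least one SNP per this many bp
    max_gap_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if not 0.0 < self.snp_in_run_threshold <= 1.0:
            raise ValueError("snp_in_run_threshold outside (0, 1]")
        for name in ("window_snps", "min_snps", "min_length_bp",
                     "min_density_bp_per_snp", "max_gap_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "n_snps", "length"]


def _in_run_snps(calls: np.ndarray, cfg: RohConfig) -> np.ndarray:
    """Boolean (samples, snps) matrix of stage-2 in-run SNPs for one
    chromosome block.  Edge SNPs covered by fewer than ``window_snps``
    windows use the reduced denominator."""
    n_samp, n = calls.shape
    w = cfg.window_snps
    if n < w:
        return np.zeros_like(calls, dtype=bool)
    het = (calls == 1).astype(np.int32)
    mis = (calls == MISSING).astype(np.int32)
    # window sums via cumulative sums along the SNP axis
    chet = np.concatenate([np.zeros((n_samp, 1), np.int32),
                           np.cumsum(het, axis=1)], axis=1)
    cmis = np.concatenate([np.zeros((n_samp, 1), np.int32),
                           np.cumsum(mis, axis=1)], axis=1)
    win_het = chet[:, w:] - chet[:, :-w]       # (n_samp, n - w + 1)
    win_mis = cmis[:, w:] - cmis[:, :-w]
    hom_win = ((win_het <= cfg.max_het_in_window)
               & (win_mis <= cfg.max_missing_in_window)).astype(np.int32)
    # SNP j is covered by windows starting in [j - w + 1, j]
    n_win = n - w + 1
    chom = np.concatenate([np.zeros((n_samp, 1), np.int32),
                           np.cumsum(hom_win, axis=1)], axis=1)
    starts = np.maximum(np.arange(n) - w + 1, 0)
    stops = np.minimum(np.arange(n), n_win - 1) + 1
    n_hom = chom[:, stops] - chom[:, starts]
    n_cov = (stops - starts)[None, :]
    return n_hom / n_cov > cfg.snp_in_run_threshold


def _runs_from_mask(mask: np.ndarray, pos: np.ndarray, cfg: RohConfig):
    """Stage 3+4 on one sample/chromosome: maximal in-run stretches, split
    at gaps > max_gap_bp, filtered by SNP count, length and density."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    # break at non-consecutive indices or large physical gaps
    brk = np.flatnonzero(
        (np.diff(idx) != 1) | (np.diff(pos[idx]) > cfg.max_gap_bp)
    )
    for chunk in np.split(idx, brk + 1):
        n_snps = chunk.size
        start, end = int(pos[chunk[0]]), int(pos[chunk[-1]])
        length = end - start + 1
        if (n_snps >= cfg.min_snps
                and length >= cfg.min_length_bp
                and n_snps * cfg.min_density_bp_per_snp >= length):
            yield start, end, n_snps, length


def detect_roh(G: GenotypeMatrix, cfg: RohConfig | None = None) -> pd.DataFrame:
    """Detect ROH per sample per chromosome; returns the segment table
    (sample, chrom, start, end, n_snps, length), 1-based inclusive."""
    cfg = cfg or RohConfig()
    rows = []
    pos_all = G.variants["pos"].to_numpy()
    for chrom in G.chroms:
        sl = G.chrom_slice(chrom)
        if sl.stop - sl.start < cfg.window_snps:
            logger.warning("chromosome %s has fewer than %d SNPs, skipped",
                           chrom, cfg.window_snps)
            continue
        pos = pos_all[sl]
        in_run = _in_run_snps(G.calls[:, sl], cfg)
        for i, sid in enumerate(G.sample_ids):
            for start, end, n_snps, length in _runs_from_mask(
                    in_run[i], pos, cfg):
                rows.append((sid, chrom, start, end, n_snps, length))
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def autosomal_span(G: GenotypeMatrix) -> int:
    """Total length covered by SNPs: sum over chromosomes of
    (last SNP position - first SNP position + 1)."""
    pos = G.variants["pos"].to_numpy()
    total = 0
    for chrom in G.chroms:
        sl = G.chrom_slice(chrom)
        total += int(pos[sl.stop - 1]) - int(pos[sl.start]) + 1
    return total


def f_roh(segments: pd.DataFrame, G: GenotypeMatrix) -> pd.DataFrame:
    """Per-sample F_ROH = sum of segment lengths / autosomal span."""
    l_auto = autosomal_span(G)
    if l_auto == 0:
        raise ValueError("zero autosomal span: no SNPs")
    sums = segments.groupby("sample")["length"].sum() if len(segments) else {}
    rows = [(sid, G.pop_labels[i],
             float(sums.get(sid, 0)) / l_auto if len(segments) else 0.0)
            for i, sid in enumerate(G.sample_ids)]
    return pd.DataFrame(rows, columns=["sample", "population", "f_roh"])


def roh_incidence(
    segments: pd.DataFrame,
    G: GenotypeMatrix,
    frac: float = 0.70,
    flank: int = 100_000,
) -> pd.DataFrame:
    """ROH-incidence hotspot regions.

    For every SNP, incidence is the fraction of all samples whose segments
    cover it; SNPs with incidence > ``frac`` are flagged and the intervals
    ``[pos - flank, pos + flank]`` (clipped at 1) around flagged SNPs are
    merged when overlapping.  Returns regions with the per-region maximum
    incidence and flagged-SNP count.
    """
    if G.n_samples == 0:
        raise ValueError("no samples")
    pos = G.variants["pos"].to_numpy()
    chrom_arr = G.variants["chrom"].to_numpy()
    cover = np.zeros(G.n_variants, dtype=np.int32)
    for seg in segments.itertuples(index=False):
        sl = G.chrom_slice(seg.chrom)
        in_seg = (pos[sl] >= seg.start) & (pos[sl] <= seg.end)
        cover[sl.start:sl.stop] += in_seg
    incidence = cover / G.n_samples
    flagged = np.flatnonzero(incidence > frac)
    intervals = [
        (chrom_arr[k], max(1, int(pos[k]) - flank), int(pos[k]) + flank)
        for k in flagged
    ]
    regions = merge_intervals(intervals, values=incidence[flagged])
    regions = regions.rename(columns={"max_value": "max_incidence",
                                      "n_windows": "n_flagged_snps"})
    return regions
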