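"""SNP-by-SNP genomic inbreeding estimators.

Five per-individual estimators computed from dosages x_k in {0, 1, 2} and
reference allele frequencies p_k:

* ``F_HOM``  = 1 - sum x(2-x) / S                     (observed homozygosity)
* ``F_L&H``  = 1 - sum x(2-x) / sum 2p(1-p)           (frequency-adjusted)
* ``F_VR1``  = sum (x-2p)^2 / sum 2p(1-p) - 1         (GRM ratio of sums)
* ``F_VR2``  = mean[ (x-2p)^2 / (2p(1-p)) - 1 ]       (GRM sum of ratios)
* ``F_YAN``  = mean[ (x^2 - (1+2p)x + 2p^2) / (2p(1-p)) ]  (uniting gametes)

Missing genotypes are dropped per sample (numerators and denominators both
restricted to the non-missing SNPs); SNPs monomorphic in the frequency
source are excluded from the four frequency-adjusted estimators and kept
for F_HOM.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix
from .genotype_io import alt_freq

logger = logging.getLogger(__name__)


def _clean(x, p=None):
    x = np.asarray(x, dtype=float)
    ok = x != MISSING
    if p is None:
        return x[ok]
    p = np.asarray(p, dtype=float)
    ok &= np.isfinite(p) & (p > 0.0) & (p < 1.0)
    return x[ok], p[ok]


def f_hom(x) -> float:
    """Proportion of homozygous SNPs: 1 - het count / S."""
    x = _clean(x)
    if x.size == 0:
        return float("nan")
    return float(1.0 - np.sum(x * (2.0 - x)) / x.size)


def f_lh(x, p) -> float:
    """Homozygosity adjusted by expected heterozygosity (Li & Horvitz)."""
    x, p = _clean(x, p)
    den = np.sum(2.0 * p * (1.0 - p))
    if x.size == 0 or den == 0.0:
        return float("nan")
    return float(1.0 - np.sum(x * (2.0 - x)) / den)


def f_vr1(x, p) -> float:
    """VanRaden ratio-of-sums estimator (GRM diagonal minus one)."""
    x, p = _clean(x, p)
    den = np.sum(2.0 * p * (1.0 - p))
    if x.size == 0 or den == 0.0:
        return float("nan")
    return float(np.sum((x - 2.0 * p) ** 2) / den - 1.0)


def f_vr2(x, p) -> float:
    """VanRaden sum-of-ratios estimator (per-SNP standardised, averaged)."""
    x, p = _clean(x, p)
    if x.size == 0:
        return float("nan")
    w = 2.0 * p * (1.0 - p)
    return float(np.mean((x - 2.0 * p) ** 2 / w - 1.0))


def f_yan(x, p) -> float:
    """Correlation-between-uniting-gametes estimator (Yang et al.)."""
    x, p = _clean(x, p)
    if x.size == 0:
        return float("nan")
    w = 2.0 * p * (1.0 - p)
    return float(np.mean((x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p) / w))


# ----------------------------------------------------------------------

def inbreeding_table(
    G: GenotypeMatrix,
    freqs: np.ndarray | None = None,
    min_snps_degraded: int = 1000,
    exclude_focal: bool = False,
) -> pd.DataFrame:
    """All five estimators per sample, on the same SNP subset per sample.

    Allele frequencies default to the observed frequencies within each
    sample's own population (degraded samples excluded from frequency
    computation); pass ``freqs`` to override with an external source for
    every sample.  Degraded samples receive F_HOM only and are excluded
    with a warning when they carry fewer than ``min_snps_degraded``
    non-missing SNPs.
    """
    rows = []
    core = ~G.degraded
    for i, sid in enumerate(G.sample_ids):
        x = G.calls[i].astype(float)
        n_used = int(np.sum(x != MISSING))
        if n_used == 0:
            logger.warning("sample %s: all genotypes missing, excluded", sid)
            continue
        if G.degraded[i]:
            if n_used < min_snps_degraded:
                logger.warning(
                    "degraded sample %s: %d non-missing SNPs < %d, excluded",
                    sid, n_used, min_snps_degraded,
                )
                continue
            rows.append((sid, G.pop_labels[i], f_hom(x), np.nan, np.nan,
                         np.nan, np.nan, n_used))
            continue
        if freqs is not None:
            p = np.asarray(freqs, dtype=float)
        else:
            in_pop = core & (G.pop_labels == G.pop_labels[i])
            if exclude_focal:
                in_pop = in_pop.copy()
                in_pop[i] = False
            p = alt_freq(G.calls[in_pop])
        rows.append((sid, G.pop_labels[i], f_hom(x), f_lh(x, p),
                     f_vr1(x, p), f_vr2(x, p), f_yan(x, p), n_used))
    table = pd.DataFrame(
        rows,
        columns=["sample", "population", "f_hom", "f_lh", "f_vr1", "f_vr2",
                 "f_yan", "n_snps_used"],
    )
    return table


def population_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-population mean ± SD of every estimator column, plus a pooled row."""
    cols = [c for c in table.columns if c.startswith("f_")]
    rows = []
    groups = list(table.groupby("population", sort=False))
    groups.append(("pooled", table))
    for pop, sub in groups:
        row = {"population": pop, "n": len(sub)}
        for c in cols:
            row[f"{c}_mean"] = sub[c].mean()
            row[f"{c}_sd"] = sub[c].std(ddof=1)
        rows.append(row)
    return pd.DataFrame(rows)
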