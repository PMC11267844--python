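"""Diversity, relatedness, structure, and the windowed Fst differentiation scan.

Per-site statistics follow the usual population-genetic definitions:
nucleotide diversity is the unbiased per-site heterozygosity
``2 * c_ref * c_alt / (n * (n - 1))`` over the ``n`` observed alleles, and
differentiation uses the Weir & Cockerham (1984) variance components, with
windows summarised as the ratio of summed components ("weighted" Fst).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotype import MISSING, GenotypeMatrix
from .genotype_io import alt_freq, hwe_exact_vector

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# Per-site statistics
# ----------------------------------------------------------------------

def site_stats(G: GenotypeMatrix, hwe: bool = False) -> pd.DataFrame:
    """Per-variant allele frequency, MAF, expected het, pi and counts.

    Sites where every call is missing are flagged with NaN statistics but
    never dropped.  ``hwe=True`` adds the exact-test p-value column (it is
    the slow part, so opt-in).
    """
    if G.n_variants == 0:
        raise ValueError("empty genotype matrix")
    calls = G.calls
    ok = calls != MISSING
    n_ref = np.where(ok, 2 - calls, 0).sum(axis=0).astype(float)
    n_alt = np.where(ok, calls, 0).sum(axis=0).astype(float)
    n = n_ref + n_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, n_alt / n, np.nan)
        pi = np.where(n > 1, 2.0 * n_ref * n_alt / (n * (n - 1.0)), np.nan)
    out = G.variants[["chrom", "pos"]].copy()
    out["p"] = p
    out["maf"] = np.minimum(p, 1.0 - p)
    out["exp_het"] = 2.0 * p * (1.0 - p)
    out["n_AA"] = (calls == 0).sum(axis=0)
    out["n_Aa"] = (calls == 1).sum(axis=0)
    out["n_aa"] = (calls == 2).sum(axis=0)
    out["pi"] = pi
    if hwe:
        out["hwe_p"] = hwe_exact_vector(calls)
    return out


# ----------------------------------------------------------------------
# LD and pruning
# ----------------------------------------------------------------------

def ld_r2(x_i: np.ndarray, x_j: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (composite LD).

    Computed over pairwise-complete samples; NaN when fewer than two
    complete pairs remain or either site has zero variance.
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    ok = (x_i != MISSING) & (x_j != MISSING)
    a, b = x_i[ok], x_j[ok]
    if a.size < 2 or a.std() == 0.0 or b.std() == 0.0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def r2_matrix(calls: np.ndarray) -> np.ndarray:
    """Pairwise r² among the columns of a dosage block, pairwise-complete
    over missing calls; NaN where a pair has < 2 complete samples or a
    zero-variance site."""
    ok = (calls != MISSING).astype(float)
    X = np.where(calls != MISSING, calls, 0).astype(float)
    n = ok.T @ ok
    sx = X.T @ ok
    sxx = (X * X).T @ ok
    sxy = X.T @ X
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy / n - (sx / n) * (sx.T / n)
        var_x = sxx / n - (sx / n) ** 2
        r2 = cov ** 2 / (var_x * var_x.T)
        r2 = np.where((n >= 2) & (var_x > 0) & (var_x.T > 0), r2, np.nan)
    return r2


def prune(
    G: GenotypeMatrix,
    r2_max: float = 0.9,
    window_snps: int = 50,
    step_snps: int = 5,
) -> GenotypeMatrix:
    """Greedy LD pruning: drop one SNP of every within-window pair with
    r² > ``r2_max``, keeping the earlier SNP by position, window advancing
    by ``step_snps`` SNPs.  Performed independently per chromosome; the
    first SNP of a chromosome can only be removed by a comparison in which
    it is the later member, i.e. never (determinism anchor).
    """
    keep = np.ones(G.n_variants, dtype=bool)
    for chrom in G.chroms:
        sl = G.chrom_slice(chrom)
        idx = np.arange(sl.start, sl.stop)
        n = idx.size
        start = 0
        while start < n:
            win = idx[start:start + window_snps]
            win = win[keep[win]]
            if win.size >= 2:
                r2 = r2_matrix(G.calls[:, win])
                local_keep = np.ones(win.size, dtype=bool)
                for a_pos in range(win.size):
                    if not local_keep[a_pos]:
                        continue
                    hits = np.flatnonzero(
                        np.nan_to_num(r2[a_pos, a_pos + 1:]) > r2_max
                    )
                    local_keep[a_pos + 1 + hits] = False
                keep[win[~local_keep]] = False
            if start + window_snps >= n:
                break
            start += step_snps
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("prune: removed %d of %d SNPs at r2 > %g",
                    n_removed, G.n_variants, r2_max)
    return G.take_variants(keep)


# ----------------------------------------------------------------------
# GRM and PCA
# ----------------------------------------------------------------------

@dataclass
class Grm:
    matrix: np.ndarray         # (n, n) symmetric
    sample_ids: list
    pop_labels: np.ndarray

    def offdiag_summary(self) -> pd.DataFrame:
        """Mean and SD of off-diagonal relatedness within each population."""
        rows = []
        for pop in dict.fromkeys(self.pop_labels):
            sel = np.flatnonzero(self.pop_labels == pop)
            sub = self.matrix[np.ix_(sel, sel)]
            off = sub[np.triu_indices(len(sel), k=1)]
            rows.append((pop, len(sel), off.mean() if off.size else np.nan,
                         off.std(ddof=1) if off.size > 1 else np.nan))
        return pd.DataFrame(rows, columns=["population", "n", "mean", "sd"])


def grm(G: GenotypeMatrix, freqs: np.ndarray | None = None) -> Grm:
    """VanRaden method-1 genomic relationship matrix.

    ``G_ij = sum_k (x_ik - 2 p_k)(x_jk - 2 p_k) / sum_k 2 p_k (1 - p_k)``,
    where a missing dosage contributes zero to the numerator and the
    corresponding ``2 p (1 - p)`` term is removed from that pair's
    denominator.  Fixed sites (p in {0, 1}) are excluded throughout, so
    ``diag(G) - 1`` reproduces the F_VR1 estimator exactly.
    """
    p = alt_freq(G.calls) if freqs is None else np.asarray(freqs, float)
    usable = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    p = p[usable]
    calls = G.calls[:, usable].astype(float)
    ok = calls != MISSING
    centred = np.where(ok, calls - 2.0 * p, 0.0)
    w = 2.0 * p * (1.0 - p)
    num = centred @ centred.T
    den = (ok * w) @ ok.T  # pairwise-complete sum of 2p(1-p)
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(den > 0, num / den, np.nan)
    M = (M + M.T) / 2.0
    return Grm(M, list(G.sample_ids), G.pop_labels.copy())


def pca(g: Grm, k: int = 3) -> tuple[pd.DataFrame, np.ndarray]:
    """Eigendecomposition of the GRM: top-k sample scores and the fraction
    of (positive) variance each component explains."""
    n = g.matrix.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds sample count {n}")
    vals, vecs = np.linalg.eigh(g.matrix)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals[vals > 0].sum()
    var_exp = np.where(vals[:k] > 0, vals[:k] / pos, 0.0)
    scores = vecs[:, :k] * np.sqrt(np.maximum(vals[:k], 0.0))
    df = pd.DataFrame(scores, columns=[f"PC{i + 1}" for i in range(k)])
    df.insert(0, "sample", g.sample_ids)
    df.insert(1, "population", g.pop_labels)
    return df, var_exp


# ----------------------------------------------------------------------
# Weir-Cockerham Fst
# ----------------------------------------------------------------------

def wc_fst_per_snp(counts_pop1, counts_pop2) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) variance components (a, b, c) for two
    populations at one biallelic site.

    ``counts_pop*`` are genotype counts (n_AA, n_Aa, n_aa).  Returns
    (0, 0, 0) when the site is monomorphic across the pooled sample.
    Per-SNP Fst is a / (a + b + c) where defined.
    """
    r = 2
    n_i = np.array([sum(counts_pop1), sum(counts_pop2)], dtype=float)
    if (n_i == 0).any():
        raise ValueError("a population has no called genotypes at this site")
    # alt ('a' allele here) frequency and observed het proportion per pop
    p_i = np.array(
        [(counts_pop1[1] + 2 * counts_pop1[2]) / (2 * n_i[0]),
         (counts_pop2[1] + 2 * counts_pop2[2]) / (2 * n_i[1])]
    )
    h_i = np.array([counts_pop1[1] / n_i[0], counts_pop2[1] / n_i[1]])
    n_bar = n_i.mean()
    p_bar = (n_i * p_i).sum() / (r * n_bar)
    if p_bar in (0.0, 1.0):
        return 0.0, 0.0, 0.0
    n_c = (r * n_bar - (n_i ** 2).sum() / (r * n_bar)) / (r - 1)
    s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum() / (r * n_bar)
    a = (n_bar / n_c) * (
        s2
        - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - (r - 1) / r * s2
        - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2.0
    return float(a), float(b), float(c)


def _wc_components(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (a, a+b+c) per SNP for the two populations in G."""
    pops = G.populations
    if len(pops) != 2:
        raise ValueError(f"exactly two populations required, got {pops}")
    split = G.by_population()
    counts = []
    for pop in pops:
        c = split[pop].calls
        counts.append(np.stack([(c == g).sum(axis=0) for g in (0, 1, 2)], axis=1))
    a = np.full(G.n_variants, np.nan)
    abc = np.full(G.n_variants, np.nan)
    for k in range(G.n_variants):
        c1, c2 = counts[0][k], counts[1][k]
        if c1.sum() == 0 or c2.sum() == 0:
            continue
        ak, bk, ck = wc_fst_per_snp(tuple(c1), tuple(c2))
        if ak == bk == ck == 0.0:
            continue  # monomorphic across pooled sample: flagged undefined
        a[k], abc[k] = ak, ak + bk + ck
    return a, abc


def genome_wide_fst(G: GenotypeMatrix) -> float:
    """Ratio-of-sums Weir-Cockerham Fst over all defined SNPs."""
    a, abc = _wc_components(G)
    ok = np.isfinite(a)
    return float(a[ok].sum() / abc[ok].sum())


def windowed_fst(
    G: GenotypeMatrix, window: int = 200_000, step: int = 100_000
) -> pd.DataFrame:
    """Sliding-window weighted Fst: windows of ``window`` bp advancing by
    ``step`` bp, anchored at position 1 of each chromosome; per window
    ``weighted_fst = sum(a) / sum(a + b + c)`` over its SNPs.  Windows with
    no SNPs or zero denominator are emitted with NaN (flagged) Fst.
    """
    a, abc = _wc_components(G)
    pos = G.variants["pos"].to_numpy()
    rows = []
    for chrom in G.chroms:
        sl = G.chrom_slice(chrom)
        cpos, ca, cabc = pos[sl], a[sl], abc[sl]
        last = int(cpos.max())
        start = 1
        while True:
            end = start + window - 1
            in_win = (cpos >= start) & (cpos <= end)
            ok = in_win & np.isfinite(ca)
            sa, sabc = ca[ok].sum(), cabc[ok].sum()
            fst = sa / sabc if ok.any() and sabc != 0.0 else np.nan
            rows.append((chrom, start, end, int(in_win.sum()), sa, sabc, fst))
            if end >= last:
                break
            start += step
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_snps", "sum_a", "sum_abc",
                 "weighted_fst"],
    )


def significant_regions(windows: pd.DataFrame, k_sd: float = 3.5) -> pd.DataFrame:
    """Call windows with weighted Fst above mean + ``k_sd``·SD (over defined
    windows, negative values retained) and merge overlapping or abutting
    significant windows into maximal regions."""
    vals = windows["weighted_fst"].to_numpy()
    defined = windows[np.isfinite(vals)]
    if len(defined) < 2:
        raise ValueError("need at least two defined windows")
    mean = defined["weighted_fst"].mean()
    sd = defined["weighted_fst"].std(ddof=1)
    threshold = mean + k_sd * sd
    sig = defined[defined["weighted_fst"] > threshold]
    regions = merge_intervals(
        sig[["chrom", "start", "end"]].itertuples(index=False),
        values=sig["weighted_fst"].to_numpy(),
    )
    regions.attrs["threshold"] = float(threshold)
    regions.attrs["mean"] = float(mean)
    regions.attrs["sd"] = float(sd)
    return regions


def merge_intervals(intervals, values=None) -> pd.DataFrame:
    """Merge 1-based inclusive intervals that overlap or abut (share >= 1 bp
    when sorted per chromosome); carries the max of ``values`` per region."""
    items = []
    vals = list(values) if values is not None else None
    for i, (chrom, start, end) in enumerate(intervals):
        items.append((chrom, int(start), int(end),
                      vals[i] if vals is not None else np.nan))
    items.sort(key=lambda t: (str(t[0]), t[1], t[2]))
    out = []
    for chrom, start, end, v in items:
        if out and out[-1][0] == chrom and start <= out[-1][2] + 1:
            prev = out[-1]
            best = v if np.isnan(prev[3]) else (
                prev[3] if np.isnan(v) else max(prev[3], v))
            out[-1] = (chrom, prev[1], max(prev[2], end), best, prev[4] + 1)
        else:
            out.append((chrom, start, end, v, 1))
    return pd.DataFrame(
        out, columns=["chrom", "start", "end", "max_value", "n_windows"]
    )


# ----------------------------------------------------------------------
# Estimator correlations
# ----------------------------------------------------------------------

def estimator_correlations(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r (and two-sided p) among estimator columns.

    Constant columns yield NaN (flagged undefined) rather than an error.
    """
    cols = [c for c in table.columns if table[c].dtype.kind == "f"]
    if len(table) < 3:
        raise ValueError("need at least three samples")
    n = len(cols)
    r = np.full((n, n), np.nan)
    p = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            x, y = table[cols[i]].to_numpy(), table[cols[j]].to_numpy()
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
                continue
            res = sps.pearsonr(x[ok], y[ok])
            r[i, j], p[i, j] = res.statistic, res.pvalue
    return (pd.DataFrame(r, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols))
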