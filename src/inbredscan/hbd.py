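"""Multi-class homozygosity-by-descent (HBD) hidden-Markov model.

Each individual genome is modelled as a mosaic of segments drawn from K
HBD classes plus one non-HBD class.  Segment lengths are exponential on
the genetic map with fixed per-class rates ``R_k = rate_base ** k``
(k = 1..K, per Morgan); smaller rates mean longer, older-inbreeding HBD
segments.  The non-HBD class shares the largest rate.  Class mixing
weights form a simplex and are the only fitted parameters (EM); rates are
never re-estimated.

Emissions: a non-HBD SNP emits Hardy-Weinberg genotype probabilities; an
HBD SNP emits the two homozygotes with their allele frequencies and never
a heterozygote, each mixed with a genotyping-error mass ``eps`` toward the
HWE distribution.  Physical positions convert to Morgans with a constant
map (default 1 cM/Mb).

F_HBD for an individual is the genome-averaged posterior probability of
being in any HBD class (the sum of per-class realized autozygosities).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix
from .genotype_io import alt_freq

logger = logging.getLogger(__name__)


@dataclass
class HbdModel:
    """Model configuration: class rates, error rate, and map constant."""

    n_classes: int = 7          # number of HBD classes
    rate_base: float = 2.0      # R_k = rate_base ** k, k = 1..n_classes
    err: float = 0.001          # genotyping-error rate epsilon
    cm_per_mb: float = 1.0      # constant genetic map
    em_tol: float = 1e-6        # log-likelihood gain threshold
    em_max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.err < 0.1:
            raise ValueError("err must lie in (0, 0.1)")
        if self.n_classes < 1:
            raise ValueError("need at least one HBD class")

    @property
    def rates(self) -> np.ndarray:
        """Exponential rates per Morgan: K HBD classes (strictly increasing)
        then the non-HBD class sharing the largest rate."""
        r = self.rate_base ** np.arange(1, self.n_classes + 1, dtype=float)
        return np.concatenate([r, [r[-1]]])

    def distances_morgans(self, pos_bp: np.ndarray) -> np.ndarray:
        """Inter-SNP distances in Morgans (1 cM/Mb default map)."""
        return np.diff(pos_bp) * self.cm_per_mb * 1e-8


@dataclass
class HbdResult:
    """Fit output: per-sample realized autozygosity, weights, segments."""

    autozygosity: pd.DataFrame   # sample, population, class_1..class_K, non_hbd, f_hbd
    gamma: np.ndarray            # (n_samples, K+1) fitted mixing weights
    log_likelihood: np.ndarray   # (n_samples,)
    converged: np.ndarray        # (n_samples,) bool
    n_iter: np.ndarray
    segments: pd.DataFrame | None = None


# ----------------------------------------------------------------------
# Model pieces
# ----------------------------------------------------------------------

def emission_probs(x, p, err: float, n_classes: int = 7) -> np.ndarray:
    """Per-class emission likelihoods for genotypes ``x`` at alt-allele
    frequencies ``p``.

    Returns an array of shape ``(n_snps, n_classes + 1)``; all HBD classes
    share one emission column set, the last column is non-HBD.  A missing
    genotype emits 1 in every class (no information).
    """
    x = np.atleast_1d(np.asarray(x))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("allele frequencies must lie strictly in (0, 1); "
                         "pre-filter fixed sites")
    q = 1.0 - p  # ref-allele frequency
    hwe = np.select([x == 0, x == 1, x == 2], [q * q, 2 * p * q, p * p], 1.0)
    hbd = np.select([x == 0, x == 1, x == 2], [q, 0.0, p], 1.0)
    e_hbd = (1.0 - err) * hbd + err * hwe
    e_non = hwe  # mixing HWE with HWE is a no-op
    e_hbd = np.where(x == MISSING, 1.0, e_hbd)
    e_non = np.where(x == MISSING, 1.0, e_non)
    out = np.empty((len(x), n_classes + 1))
    out[:, :n_classes] = e_hbd[:, None]
    out[:, n_classes] = e_non
    return out


def transition_matrix(d_morgans: float, rates: np.ndarray,
                      gamma: np.ndarray) -> np.ndarray:
    """One-step transition matrix over ``d_morgans``:
    ``T[k, j] = exp(-R_k d) δ_kj + (1 - exp(-R_k d)) γ_j``.
    """
    if d_morgans < 0:
        raise ValueError("negative genetic distance")
    stay = np.exp(-np.asarray(rates, float) * d_morgans)
    T = (1.0 - stay)[:, None] * np.asarray(gamma, float)[None, :]
    T[np.diag_indices_from(T)] += stay
    return T


# ----------------------------------------------------------------------
# Forward-backward (batched over samples, one chromosome)
# ----------------------------------------------------------------------

@numba.njit(cache=True)
def _fb_kernel(e_hbd, e_non, stay, gamma):  # pragma: no cover - jitted
    n_samp, n = e_hbd.shape
    kp1 = gamma.shape[1]
    K = kp1 - 1
    alpha = np.empty((n_samp, n, kp1))
    beta = np.empty((n_samp, n, kp1))
    cs = np.empty((n_samp, n))
    entries = np.zeros((n_samp, kp1))
    loglik = np.zeros(n_samp)
    for i in range(n_samp):
        g = gamma[i]
        # forward, scaled
        c = 0.0
        for j in range(kp1):
            e = e_hbd[i, 0] if j < K else e_non[i, 0]
            alpha[i, 0, j] = g[j] * e
            c += alpha[i, 0, j]
        cs[i, 0] = c
        for j in range(kp1):
            alpha[i, 0, j] /= c
        for t in range(1, n):
            u = 0.0
            for k in range(kp1):
                u += alpha[i, t - 1, k] * (1.0 - stay[t - 1, k])
            c = 0.0
            for j in range(kp1):
                e = e_hbd[i, t] if j < K else e_non[i, t]
                a = (alpha[i, t - 1, j] * stay[t - 1, j] + u * g[j]) * e
                alpha[i, t, j] = a
                c += a
            cs[i, t] = c
            for j in range(kp1):
                alpha[i, t, j] /= c
        # backward, same scale; accumulate expected gamma-branch entries
        for j in range(kp1):
            beta[i, n - 1, j] = 1.0
        for t in range(n - 2, -1, -1):
            tot = 0.0
            for j in range(kp1):
                e = e_hbd[i, t + 1] if j < K else e_non[i, t + 1]
                tot += g[j] * e * beta[i, t + 1, j]
            u = 0.0
            for k in range(kp1):
                u += alpha[i, t, k] * (1.0 - stay[t, k])
            for j in range(kp1):
                e = e_hbd[i, t + 1] if j < K else e_non[i, t + 1]
                eb = e * beta[i, t + 1, j]
                beta[i, t, j] = (stay[t, j] * eb
                                 + (1.0 - stay[t, j]) * tot) / cs[i, t + 1]
                entries[i, j] += u * g[j] * eb / cs[i, t + 1]
        tot_ll = 0.0
        for t in range(n):
            tot_ll += np.log(cs[i, t])
        loglik[i] = tot_ll
        for j in range(kp1):
            entries[i, j] += alpha[i, 0, j] * beta[i, 0, j]
    post = alpha * beta
    for i in range(n_samp):
        for t in range(n):
            s = 0.0
            for j in range(kp1):
                s += post[i, t, j]
            for j in range(kp1):
                post[i, t, j] /= s
    return post, loglik, entries


def _fb_chrom(e_hbd, e_non, stay, gamma):
    """Scaled forward-backward for one chromosome, all samples at once.

    Parameters: ``e_hbd``/``e_non`` (n_samp, n_snps) emission likelihoods,
    ``stay`` (n_snps - 1, K+1) per-step stay probabilities, ``gamma``
    (n_samp, K+1).  Returns posteriors (n_samp, n_snps, K+1), per-sample
    log-likelihood, and the expected γ-choice counts used by the EM M-step
    (initial occupancy plus expected re-entry events).
    """
    return _fb_kernel(
        np.ascontiguousarray(e_hbd, dtype=np.float64),
        np.ascontiguousarray(e_non, dtype=np.float64),
        np.ascontiguousarray(stay, dtype=np.float64),
        np.ascontiguousarray(gamma, dtype=np.float64),
    )


def forward_backward(G: GenotypeMatrix, model: HbdModel,
                     gamma: np.ndarray, freqs: np.ndarray | None = None):
    """Posterior class probabilities and log-likelihood for every sample.

    ``gamma`` may be one simplex vector (shared) or one per sample.
    Returns (posteriors, log_likelihoods, entry_counts, keep_mask) where
    ``keep_mask`` marks the SNPs used (fixed sites are excluded).
    """
    p = alt_freq(G.calls) if freqs is None else np.asarray(freqs, float)
    keep = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    rates = model.rates
    kp1 = rates.size
    gamma = np.atleast_2d(np.asarray(gamma, float))
    if gamma.shape[0] == 1:
        gamma = np.repeat(gamma, G.n_samples, axis=0)

    posts = np.zeros((G.n_samples, int(keep.sum()), kp1))
    loglik = np.zeros(G.n_samples)
    entries = np.zeros((G.n_samples, kp1))
    pos_all = G.variants["pos"].to_numpy()
    chrom_all = G.variants["chrom"].to_numpy()
    kept_idx = np.flatnonzero(keep)
    offset = 0
    for chrom in G.chroms:
        sel = kept_idx[chrom_all[kept_idx] == chrom]
        if sel.size == 0:
            continue
        x = G.calls[:, sel]
        pk = p[sel]
        q = 1.0 - pk
        hwe = np.select([x == 0, x == 1, x == 2],
                        [q * q, 2 * pk * q, pk * pk], 1.0)
        hbd_e = np.select([x == 0, x == 1, x == 2], [q, 0.0, pk], 1.0)
        e_hbd = np.where(x == MISSING, 1.0,
                         (1.0 - model.err) * hbd_e + model.err * hwe)
        e_non = np.where(x == MISSING, 1.0, hwe)
        d = model.distances_morgans(pos_all[sel])
        stay = np.exp(-np.outer(d, rates))
        post, ll, ent = _fb_chrom(e_hbd, e_non, stay, gamma)
        posts[:, offset:offset + sel.size] = post
        loglik += ll
        entries += ent
        offset += sel.size
    return posts, loglik, entries, keep


# ----------------------------------------------------------------------
# EM fit and decoding
# ----------------------------------------------------------------------

def fit_em(G: GenotypeMatrix, model: HbdModel | None = None,
           freqs: np.ndarray | None = None,
           decode: bool = True, min_post: float = 0.5) -> HbdResult:
    """Fit per-sample mixing weights by EM and summarise autozygosity.

    Rates stay fixed; the E-step accumulates expected occupancies of the
    γ-choice events (chromosome starts and segment re-entries) from the
    forward-backward pass, the M-step renormalises them.  The data
    log-likelihood is non-decreasing across iterations.  Samples that do
    not reach ``em_tol`` within ``em_max_iter`` are flagged unconverged.
    """
    model = model or HbdModel()
    kp1 = model.n_classes + 1
    gamma = np.full((G.n_samples, kp1), 1.0 / kp1)
    prev_ll = np.full(G.n_samples, -np.inf)
    converged = np.zeros(G.n_samples, dtype=bool)
    n_iter = np.zeros(G.n_samples, dtype=int)
    for it in range(model.em_max_iter):
        posts, ll, entries, keep = forward_backward(G, model, gamma, freqs)
        gain = ll - prev_ll
        newly = (gain < model.em_tol) & ~converged
        converged |= newly
        n_iter[~converged] = it + 1
        if converged.all():
            break
        prev_ll = ll
        new_gamma = entries / entries.sum(axis=1, keepdims=True)
        gamma = np.where(converged[:, None], gamma, new_gamma)
    if not converged.all():
        logger.warning("EM not converged for %d samples after %d iterations",
                       int((~converged).sum()), model.em_max_iter)

    realized = posts.mean(axis=1)                  # (n_samp, K+1)
    cols = [f"class_{k}" for k in range(1, model.n_classes + 1)] + ["non_hbd"]
    auto = pd.DataFrame(realized, columns=cols)
    auto.insert(0, "sample", G.sample_ids)
    auto.insert(1, "population", G.pop_labels)
    auto["f_hbd"] = realized[:, :model.n_classes].sum(axis=1)

    segments = None
    if decode:
        segments = decode_segments(
            posts, G, keep, n_classes=model.n_classes, min_post=min_post
        )
    return HbdResult(auto, gamma, ll, converged, n_iter, segments)


def decode_segments(posteriors: np.ndarray, G: GenotypeMatrix,
                    keep: np.ndarray, n_classes: int = 7,
                    min_post: float = 0.5) -> pd.DataFrame:
    """Maximal stretches where the total HBD posterior exceeds ``min_post``.

    Segment coordinates are the first/last SNP positions of the stretch;
    the dominant class is the argmax of the mean per-class posterior
    within it.
    """
    kept_idx = np.flatnonzero(keep)
    pos = G.variants["pos"].to_numpy()[kept_idx]
    chrom = G.variants["chrom"].to_numpy()[kept_idx]
    total_hbd = posteriors[:, :, :n_classes].sum(axis=2)
    rows = []
    for i, sid in enumerate(G.sample_ids):
        mask = total_hbd[i] > min_post
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        brk = np.flatnonzero((np.diff(idx) != 1)
                             | (chrom[idx[1:]] != chrom[idx[:-1]]))
        for chunk in np.split(idx, brk + 1):
            mean_post = posteriors[i, chunk, :n_classes].mean(axis=0)
            rows.append((
                sid, chrom[chunk[0]], int(pos[chunk[0]]), int(pos[chunk[-1]]),
                chunk.size, int(np.argmax(mean_post)) + 1,
            ))
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "n_snps",
                       "dominant_class"],
    )
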