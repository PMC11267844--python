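"""Site statistics, LD pruning, GRM/PCA, and the Weir-Cockerham Fst scan."""

import numpy as np
import pandas as pd
import pytest

from inbredscan import fcoef
from inbredscan.genotype import MISSING
from inbredscan.genotype_io import alt_freq
from inbredscan.popdiv import (estimator_correlations, genome_wide_fst, grm,
                               ld_r2, merge_intervals, pca, prune, r2_matrix,
                               significant_regions, site_stats, wc_fst_per_snp,
                               windowed_fst)
from inbredscan.simpop import SimConfig, sim_dataset

from conftest import make_matrix


# ----------------------------------------------------------------------
# site_stats
# ----------------------------------------------------------------------

def test_pi_all_het_four_diploids():
    # c_ref = c_alt = 4 over n = 8 alleles: pi = 2*16/56
    G = make_matrix(np.ones((4, 1)))
    s = site_stats(G)
    assert s["pi"].iloc[0] == pytest.approx(2 * 16 / 56)


def test_monomorphic_site_stats():
    G = make_matrix(np.zeros((5, 1)))
    s = site_stats(G)
    assert s["pi"].iloc[0] == 0.0
    assert s["maf"].iloc[0] == 0.0


def test_maf_exp_het_formula():
    # 10 diploids, p = 0.7 -> maf 0.3, exp_het 0.42
    calls = np.array([[2] * 7 + [0] * 3, [2] * 4 + [1] * 6]).T
    G = make_matrix(calls.astype(np.int8))
    s = site_stats(G)
    assert s["p"].iloc[0] == pytest.approx(0.7)
    assert s["maf"].iloc[0] == pytest.approx(0.3)
    assert s["exp_het"].iloc[0] == pytest.approx(0.42)


def test_all_missing_site_flagged_not_dropped():
    calls = np.array([[MISSING, 1], [MISSING, 0]], dtype=np.int8)
    s = site_stats(make_matrix(calls))
    assert len(s) == 2
    assert np.isnan(s["p"].iloc[0])


# ----------------------------------------------------------------------
# LD r2 and pruning
# ----------------------------------------------------------------------

def test_identical_vectors_r2_one_and_pruned():
    rng = np.random.default_rng(0)
    x = rng.integers(0, 3, 30)
    assert ld_r2(x, x) == pytest.approx(1.0)
    G = make_matrix(np.stack([x, x], axis=1).astype(np.int8))
    out = prune(G)
    assert out.n_variants == 1
    assert out.variants["pos"].iloc[0] == 1000  # first by position kept


def test_zero_variance_site_r2_undefined():
    assert np.isnan(ld_r2(np.zeros(10), np.arange(10) % 3))


def test_independent_sites_mean_r2_and_no_pruning():
    rng = np.random.default_rng(1)
    n = 500
    calls = rng.binomial(2, 0.4, size=(n, 40)).astype(np.int8)
    G = make_matrix(calls)
    r2 = r2_matrix(calls)
    off = r2[np.triu_indices(40, k=1)]
    # E[r2] ~ 1/(n-1) for independent sites
    assert np.nanmean(off) == pytest.approx(1 / (n - 1), abs=3e-3)
    assert prune(G).n_variants == 40


def test_prune_postcondition_no_high_r2_pairs_remain(two_pop_sim):
    G, _ = two_pop_sim
    # duplicate a few columns to create perfect LD
    idx = np.arange(G.n_variants)
    calls = G.calls.copy()
    calls[:, 10] = calls[:, 9]
    calls[:, 11] = calls[:, 9]
    G2 = make_matrix(calls[:, :200],
                     positions=G.variants["pos"].to_numpy()[:200])
    out = prune(G2, r2_max=0.9)
    r2 = r2_matrix(out.calls)
    np.fill_diagonal(r2, np.nan)
    # exhaustive within-window replay: no retained pair above the cutoff
    for a in range(out.n_variants):
        hi = np.flatnonzero(np.nan_to_num(r2[a, a + 1:a + 50]) > 0.9)
        assert hi.size == 0


def test_ld_r2_pairwise_complete_missing():
    x = np.array([0, 1, 2, MISSING, 2], dtype=float)
    y = np.array([0, 1, 2, 2, MISSING], dtype=float)
    assert ld_r2(x, y) == pytest.approx(1.0)


# ----------------------------------------------------------------------
# GRM / PCA
# ----------------------------------------------------------------------

def test_duplicate_samples_offdiag_equals_diag():
    rng = np.random.default_rng(3)
    row = rng.integers(0, 3, 100).astype(np.int8)
    other = rng.integers(0, 3, (4, 100)).astype(np.int8)
    calls = np.vstack([row, row, other])
    g = grm(make_matrix(calls))
    assert g.matrix[0, 1] == pytest.approx(g.matrix[0, 0], abs=1e-12)


def test_grm_diagonal_is_f_vr1_plus_one(two_pop_sim):
    G, _ = two_pop_sim
    g = grm(G)
    p = alt_freq(G.calls)
    for i in range(G.n_samples):
        fv = fcoef.f_vr1(G.calls[i].astype(float), p)
        assert g.matrix[i, i] - 1.0 == pytest.approx(fv, abs=1e-10)


def test_pca_separates_diverged_populations():
    cfg = SimConfig(pop_sizes=(("A", 30), ("B", 30)), n_chrom=1,
                    chrom_length_bp=10_000_000, snp_spacing_bp=5_000,
                    divergence_f=0.1, seed=2)
    G, _ = sim_dataset(cfg)
    scores, var_exp = pca(grm(G), k=3)
    pc1 = scores["PC1"].to_numpy()
    a, b = pc1[G.pop_labels == "A"], pc1[G.pop_labels == "B"]
    assert a.max() < b.min() or b.max() < a.min()  # zero overlap
    assert 0.0 < var_exp.sum() <= 1.0


def test_pca_k_exceeds_samples_error(random_matrix):
    with pytest.raises(ValueError):
        pca(grm(random_matrix), k=11)


# ----------------------------------------------------------------------
# Weir-Cockerham Fst
# ----------------------------------------------------------------------

def wc_1984_oracle(c1, c2):
    """Independent transcription straight from the 1984 variance-component
    equations (r populations, here r=2), kept deliberately literal."""
    r = 2
    n = [sum(c1), sum(c2)]
    ptilde = [(c[1] + 2 * c[2]) / (2 * nn) for c, nn in zip((c1, c2), n)]
    htilde = [c[1] / nn for c, nn in zip((c1, c2), n)]
    nbar = sum(n) / r
    nc = (sum(n) - sum(ni ** 2 for ni in n) / sum(n)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, ptilde)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2
             for ni, pi in zip(n, ptilde)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, htilde)) / (r * nbar)
    a = nbar / nc * (s2 - 1 / (nbar - 1)
                     * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def test_fixed_difference_fst_one():
    a, b, c = wc_fst_per_snp((20, 0, 0), (0, 0, 20))
    assert a / (a + b + c) == pytest.approx(1.0, abs=1e-12)


def test_identical_counts_fst_nonpositive():
    a, b, c = wc_fst_per_snp((10, 20, 10), (10, 20, 10))
    assert a <= 0
    assert a / (a + b + c) <= 0


def test_wc_components_against_1984_oracle():
    rng = np.random.default_rng(11)
    for _ in range(50):
        c1 = tuple(rng.integers(0, 30, 3))
        c2 = tuple(rng.integers(0, 30, 3))
        if sum(c1) == 0 or sum(c2) == 0:
            continue
        got = wc_fst_per_snp(c1, c2)
        if got == (0.0, 0.0, 0.0):
            continue  # monomorphic pooled site, flagged
        want = wc_1984_oracle(c1, c2)
        assert got == pytest.approx(want, rel=1e-10, abs=1e-12)


def test_windowed_fst_and_snp_order_invariance(two_pop_sim):
    G, _ = two_pop_sim
    fw = windowed_fst(G)
    assert (fw["end"] - fw["start"] + 1 == 200_000).all()
    # weighted Fst of a window must not depend on SNP order within it
    win = fw.iloc[0]
    sl = G.chrom_slice(win["chrom"])
    pos = G.variants["pos"].to_numpy()[sl]
    in_win = (pos >= win["start"]) & (pos <= win["end"])
    from inbredscan.popdiv import _wc_components
    a, abc = _wc_components(G.take_variants(np.arange(sl.start, sl.stop)))
    ok = in_win & np.isfinite(a)
    assert a[ok].sum() / abc[ok].sum() == pytest.approx(win["weighted_fst"])
    perm = np.concatenate([np.flatnonzero(ok)[::-1]])
    assert a[perm].sum() / abc[perm].sum() == pytest.approx(
        win["weighted_fst"])


def test_balding_nichols_genomewide_fst_recovery():
    cfg = SimConfig(pop_sizes=(("p1", 50), ("p2", 50)), n_chrom=2,
                    chrom_length_bp=50_000_000, snp_spacing_bp=5_000,
                    divergence_f=0.05, seed=1)
    G, _ = sim_dataset(cfg)
    assert genome_wide_fst(G) == pytest.approx(0.05, abs=0.01)


def test_empty_window_flagged(two_pop_sim):
    G, _ = two_pop_sim
    # thin to create SNP-free windows
    thin = G.take_variants(np.arange(0, G.n_variants, 60))
    fw = windowed_fst(thin)
    empty = fw[fw["n_snps"] == 0]
    assert len(empty) > 0
    assert empty["weighted_fst"].isna().all()


def test_one_population_fatal(two_pop_sim):
    G, _ = two_pop_sim
    only = G.take_samples(G.pop_labels == "pop1")
    with pytest.raises(ValueError):
        windowed_fst(only)


# ----------------------------------------------------------------------
# Significant regions
# ----------------------------------------------------------------------

def _window_frame(fsts, chrom="chr1", size=200_000, step=100_000):
    rows = []
    for i, f in enumerate(fsts):
        start = 1 + i * step
        rows.append((chrom, start, start + size - 1, 10, np.nan, np.nan, f))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps",
                                       "sum_a", "sum_abc", "weighted_fst"])


def test_overlapping_significant_windows_merge():
    base = [0.01] * 40
    fw = _window_frame(base + [0.9, 0.9] + base)
    regions = significant_regions(fw)
    assert len(regions) == 1
    assert regions["start"].iloc[0] == 1 + 40 * 100_000
    assert regions["end"].iloc[0] == 1 + 41 * 100_000 + 200_000 - 1


def test_no_window_above_threshold_empty():
    rng = np.random.default_rng(0)
    fw = _window_frame(rng.normal(0.01, 0.001, 100))
    assert len(significant_regions(fw)) == 0


def test_planted_block_yields_single_region():
    fw = _window_frame([0.01] * 150 + [0.8] * 5 + [0.01] * 150)
    regions = significant_regions(fw)
    assert len(regions) == 1
    assert regions["n_windows"].iloc[0] == 5


def test_merge_intervals_abutting():
    out = merge_intervals([("c", 1, 100), ("c", 101, 200), ("c", 300, 400)])
    assert len(out) == 2
    assert (out.loc[0, "start"], out.loc[0, "end"]) == (1, 200)


# ----------------------------------------------------------------------
# Estimator correlations
# ----------------------------------------------------------------------

def test_correlation_self_and_negation():
    rng = np.random.default_rng(5)
    x = rng.normal(size=20)
    table = pd.DataFrame({"a": x, "b": x, "c": -x})
    r, p = estimator_correlations(table)
    assert r.loc["a", "b"] == pytest.approx(1.0)
    assert r.loc["a", "c"] == pytest.approx(-1.0)


def test_constant_column_flagged_nan():
    table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 1.0, 1.0]})
    r, p = estimator_correlations(table)
    assert np.isnan(r.loc["a", "b"])


def test_inbreeding_gradient_all_estimators_positively_correlated():
    cfg = SimConfig(pop_sizes=(("p1", 30),), n_chrom=2,
                    chrom_length_bp=25_000_000, snp_spacing_bp=10_000,
                    divergence_f=0.0,
                    autozygosity_fraction=tuple(np.linspace(0, 0.4, 30)),
                    tract_rate=8.0, seed=6)
    G, _ = sim_dataset(cfg)
    table = fcoef.inbreeding_table(G)
    r, _ = estimator_correlations(
        table[["f_hom", "f_lh", "f_vr1", "f_vr2", "f_yan"]])
    off = r.to_numpy()[np.triu_indices(5, k=1)]
    assert (off > 0).all()
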