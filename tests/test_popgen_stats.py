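"""Kinship, relative pruning, PCA, diversity, F_ST, Tajima's D, Mantel."""

import numpy as np
import pandas as pd
import pytest

from panmix import popgen_stats as ps
from panmix.vcf_io import MISSING

from conftest import hwe_genotypes, make_gm


# ---------------------------------------------------------------------------
# KING kinship
# ---------------------------------------------------------------------------


def test_king_self_kinship_is_half():
    rng = np.random.default_rng(0)
    geno = hwe_genotypes(rng, 10, 500)
    km = ps.king_kinship(make_gm(geno))
    assert np.allclose(np.diag(km.phi), 0.5)


def test_king_duplicated_individual_is_half():
    rng = np.random.default_rng(1)
    geno = hwe_genotypes(rng, 6, 500)
    geno[5] = geno[0]
    km = ps.king_kinship(make_gm(geno))
    assert km.phi[0, 5] == pytest.approx(0.5)


def test_king_unrelated_mean_near_zero():
    rng = np.random.default_rng(2)
    geno = hwe_genotypes(rng, 40, 4000)
    km = ps.king_kinship(make_gm(geno))
    iu = np.triu_indices(40, k=1)
    assert abs(np.nanmean(km.phi[iu])) < 0.01


def test_king_missingness_gives_nan():
    geno = np.array([[1, 1, MISSING], [MISSING, MISSING, 1]], dtype=np.int8)
    km = ps.king_kinship(make_gm(geno))
    assert np.isnan(km.phi[0, 1])  # zero jointly called sites


def test_planted_parent_offspring_detected_and_pruned():
    from panmix.synthetic_data import SimConfig, simulate_coalescent_dataset

    gm = simulate_coalescent_dataset(
        SimConfig(epochs=((20_000, 0),), n_loci=8000, n_diploids=46,
                  n_planted_parent_offspring_pairs=3, seed=3)
    )
    km = ps.king_kinship(gm)
    flagged = km.flagged_pairs()
    assert len(flagged) == 3
    assert all(phi > 0.177 for _, _, phi in flagged)
    pruned = ps.prune_relatives(km, gm)
    assert pruned.n_individuals == 43
    km2 = ps.king_kinship(pruned)
    assert len(km2.flagged_pairs()) == 0


def test_prune_identity_when_no_relatives():
    rng = np.random.default_rng(3)
    geno = hwe_genotypes(rng, 20, 3000)
    gm = make_gm(geno)
    km = ps.king_kinship(gm)
    assert ps.prune_relatives(km, gm).n_individuals == 20


def test_prune_removes_member_with_more_missing():
    rng = np.random.default_rng(4)
    geno = hwe_genotypes(rng, 8, 2000)
    geno[1] = geno[0]  # duplicate pair (0, 1)
    geno[1, :100] = MISSING  # individual 1 has more missing calls
    gm = make_gm(geno)
    pruned = ps.prune_relatives(ps.king_kinship(gm), gm)
    assert "ind_0001" not in list(pruned.sample_meta["id"])
    assert "ind_0000" in list(pruned.sample_meta["id"])


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def test_pca_duplicated_individuals_have_identical_scores():
    rng = np.random.default_rng(5)
    geno = hwe_genotypes(rng, 12, 800)
    geno[11] = geno[0]
    res = ps.pca_with_outlier_removal(make_gm(geno))
    a = res.scores.iloc[0, 1:].to_numpy(float)
    b = res.scores.iloc[11, 1:].to_numpy(float)
    assert np.allclose(a, b)


def test_pca_panmictic_low_explained_variance():
    """No structure: PC1 and PC2 each explain <2% of the variance."""
    rng = np.random.default_rng(6)
    geno = hwe_genotypes(rng, 80, 4000)
    res = ps.pca_with_outlier_removal(make_gm(geno))
    assert res.explained_var[0] < 0.02
    assert res.explained_var[1] < 0.02
    assert res.removed_ids == []


def test_pca_divergent_individual_removed_first_round():
    rng = np.random.default_rng(7)
    p = rng.uniform(0.05, 0.3, 2000)
    # n must comfortably exceed 6^2 for a 6-SD call: a single outlier can
    # contribute at most sqrt(n-1) SDs to the PC it dominates
    geno = rng.binomial(2, p, size=(60, 2000)).astype(np.int8)
    geno[0] = rng.binomial(2, np.minimum(1.0, p * 3.0), size=2000)
    gm = make_gm(geno)
    res = ps.pca_with_outlier_removal(gm, sd_threshold=6)
    assert res.removed_ids == ["ind_0000"]


def test_pca_monomorphic_errors():
    gm = make_gm(np.ones((5, 10), dtype=np.int8) * 2)
    with pytest.raises(ValueError, match="polymorphic"):
        ps.pca_with_outlier_removal(gm)


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------


def test_diversity_all_homozygous_group():
    geno = np.array([[0, 2, 0], [2, 0, 2], [0, 2, 0], [2, 2, 0]], dtype=np.int8)
    df = ps.diversity(make_gm(geno))
    assert df["H_O"].iloc[0] == 0.0
    assert df["F_IS"].iloc[0] == pytest.approx(1.0)


def test_diversity_hwe_fis_near_zero():
    rng = np.random.default_rng(8)
    geno = hwe_genotypes(rng, 60, 4000, p_low=0.1, p_high=0.5)
    df = ps.diversity(make_gm(geno))
    assert abs(df["F_IS"].iloc[0]) < 0.02
    assert 0 <= df["H_O"].iloc[0] <= 1
    assert 0 <= df["H_E"].iloc[0] <= 1


def test_diversity_homogeneous_across_panmictic_colonies(panmictic_gm):
    df = ps.diversity(panmictic_gm)
    assert len(df) >= 4
    assert df["H_O"].max() - df["H_O"].min() < 0.05
    assert df["F_IS"].abs().max() < 0.15


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------


def test_wc_fst_hand_computed_toy():
    """Two demes of 10, one site, p = 0.2 vs 0.8, all ALT carriers het.

    Hand calculation with the 1984 variance components:
    nbar=10, nc=10, pbar=0.5, s2=0.18, hbar=0.4 ->
    a = 0.18 - (0.25 - 0.09 - 0.1)/9 = 0.1733...,
    b = (10/9)(0.25 - 0.09 - 0.19) = -0.0333..., c = 0.2,
    theta = a/(a+b+c) = 0.50980392...
    """
    deme1 = np.array([1] * 4 + [0] * 6, dtype=np.int8)
    deme2 = np.array([1] * 4 + [2] * 6, dtype=np.int8)
    geno = np.concatenate([deme1, deme2])[:, None]
    gm = make_gm(geno, colony=["A"] * 10 + ["B"] * 10)
    fst = ps.pairwise_fst(gm, min_n=3)
    assert fst.values[0, 1] == pytest.approx(0.509803921568, abs=1e-9)
    assert fst.values[0, 0] == 0.0


def test_wc_fst_null_split_near_zero():
    rng = np.random.default_rng(9)
    geno = hwe_genotypes(rng, 40, 4000)
    labels = ["A"] * 20 + ["B"] * 20
    fst = ps.pairwise_fst(make_gm(geno, colony=labels))
    assert abs(fst.values[0, 1]) < 0.005


def test_wc_fst_group_size_threshold():
    rng = np.random.default_rng(10)
    geno = hwe_genotypes(rng, 12, 500)
    labels = ["A"] * 6 + ["B"] * 4 + ["C"] * 2  # C below min_n=3
    fst = ps.pairwise_fst(make_gm(geno, colony=labels))
    assert fst.groups == ["A", "B"]
    with pytest.raises(ValueError):
        ps.pairwise_fst(make_gm(geno, colony=["A"] * 11 + ["C"]))


def test_fst_panmictic_colonies_small(panmictic_gm):
    fst = ps.pairwise_fst(panmictic_gm, min_n=3)
    assert abs(fst.mean_offdiag()) < 0.05


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------


def classical_tajimas_d(n, alt_counts):
    """Textbook formula, independently coded for the complete-data limit."""
    s = len(alt_counts)
    k = np.asarray(alt_counts, float)
    pi = np.sum(2 * k * (n - k) / (n * (n - 1)))
    i = np.arange(1, n)
    a1 = np.sum(1 / i)
    a2 = np.sum(1 / i**2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))


def test_tajimas_d_matches_classical_hand_case():
    """4 haplotypes, 3 segregating sites with ALT counts (1, 2, 1)."""
    geno = np.array([[1, 1, 0], [0, 1, 1]], dtype=np.int8)  # 2 diploids
    res = ps.tajimas_d(make_gm(geno), n_sims=50, seed=0, n_boot=50)
    expected = classical_tajimas_d(4, [1, 2, 1])
    assert res.d == pytest.approx(expected, abs=1e-12)


def test_tajimas_d_complete_data_equals_classical():
    rng = np.random.default_rng(11)
    geno = hwe_genotypes(rng, 15, 400)
    seg = (geno.sum(0) > 0) & (geno.sum(0) < 30)
    geno = geno[:, seg]
    res = ps.tajimas_d(make_gm(geno), n_sims=50, seed=1, n_boot=50)
    expected = classical_tajimas_d(30, geno.sum(0))
    assert res.d == pytest.approx(expected, abs=1e-12)
    assert res.ci_low <= res.d <= res.ci_high


def test_tajimas_d_contraction_history_positive():
    """A strong old contraction leaves a deficit of rare alleles (D>0)."""
    from panmix.synthetic_data import SimConfig, simulate_coalescent_dataset

    ds = []
    for seed in range(3):
        gm = simulate_coalescent_dataset(
            SimConfig(epochs=((3000, 0), (60_000, 6000)), n_loci=2500,
                      n_diploids=20, seed=40 + seed)
        )
        ds.append(ps.tajimas_d(gm, n_sims=50, seed=seed, n_boot=50).d)
    assert np.mean(ds) > 0.5


def test_tajimas_d_requires_segregating_sites():
    gm = make_gm(np.zeros((5, 10), dtype=np.int8))
    with pytest.raises(ValueError, match="segregating"):
        ps.tajimas_d(gm)


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------


def _random_fst_matrix(rng, k=6):
    m = rng.uniform(0.0, 0.2, size=(k, k))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    coords = pd.DataFrame(
        {"group": [f"g{i}" for i in range(k)],
         "lat": rng.uniform(33, 41, k), "lon": rng.uniform(-124, -115, k)}
    )
    return ps.FstMatrix(m, [f"g{i}" for i in range(k)], coords)


def test_mantel_identical_matrices():
    # k=9 groups: 9! permutations, so a random draw virtually never
    # reproduces the identity and p attains its floor
    rng = np.random.default_rng(12)
    fst = _random_fst_matrix(rng, k=9)
    geo = ps.geographic_distance_matrix(fst.coords)
    fst_geo = ps.FstMatrix(geo, fst.groups, fst.coords)
    r, p = ps.mantel_ibd(fst_geo, n_perm=999, seed=0)
    assert r == pytest.approx(1.0)
    assert p <= 1 / (999 + 1) + 1e-12


def test_mantel_null_p_uniform():
    """Independent matrices: permutation p-values look uniform (KS)."""
    from scipy.stats import kstest

    rng = np.random.default_rng(13)
    ps_ = []
    for i in range(60):
        fst = _random_fst_matrix(rng, k=7)
        _, p = ps.mantel_ibd(fst, n_perm=499, seed=i)
        ps_.append(p)
    assert kstest(ps_, "uniform").pvalue > 0.01


def test_mantel_degenerate_matrix_errors():
    coords = pd.DataFrame(
        {"group": list("abcd"), "lat": [34, 35, 36, 37],
         "lon": [-120, -119, -118, -117]}
    )
    fst = ps.FstMatrix(np.zeros((4, 4)), list("abcd"), coords)
    with pytest.raises(ValueError, match="degenerate"):
        ps.mantel_ibd(fst)


def test_mantel_panmictic_no_ibd(panmictic_gm):
    fst = ps.pairwise_fst(panmictic_gm, min_n=3)
    r, p = ps.mantel_ibd(fst, n_perm=999, seed=3)
    assert p > 0.01  # no isolation-by-distance signal


def test_haversine_known_distance():
    # ~1 degree of latitude is ~111 km
    assert ps.haversine_km(38.0, -121.0, 39.0, -121.0) == pytest.approx(111.2, rel=0.01)
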