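"""SNP filter rules, nucleotide diversity, Weir-Cockerham F_ST, genotype PCA."""
import itertools

import numpy as np
import pytest

from popxome import genotype_stats as gs
from popxome.containers import MISSING
from popxome.synthetic_data import SimConfig, build_popmap, simulate_genotypes

from conftest import make_genotypes


# ---------------------------------------------------------------- filtering

def test_quality_exactly_at_threshold_is_removed():
    g = make_genotypes([[0, 1, 2, 1]], individuals=list("abcd"), qual=[10.0])
    assert gs.filter_snps(g).n_snps == 0


def test_clean_snp_passes_all_criteria():
    g = make_genotypes(
        [[0, 1, 2, 1]], individuals=list("abcd"), qual=[99.0],
        depth=np.full((1, 4), 100.0),
    )
    assert gs.filter_snps(g).n_snps == 1


def test_each_criterion_removes_its_violator():
    """Toy table: one SNP violating each rule plus three clean survivors."""
    M = MISSING
    rows = [
        [M, M, M, 1, 1, 2],    # 50%+ missing? 3/6 = 0.5 allowed; see next
        [M, M, M, M, 1, 2],    # 66% missing -> removed
        [0, 1, 2, 1, 0, 1],    # low depth -> removed
        [0, 0, 0, 0, 0, 1],    # MAF = 1/12 ok; qual low -> removed
        [0, 0, 0, 0, 0, 0],    # MAF 0 -> removed
        [2, 2, 2, 2, 2, 2],    # MAF 0 (alt fixed) -> removed
        [0, 1, 2, 1, 0, 1],    # clean
        [2, 1, 0, 1, 2, 1],    # clean
        [0, 0, 1, 1, 2, 2],    # clean
    ]
    qual = [99, 99, 99, 5, 99, 99, 99, 99, 99]
    depth = np.full((9, 6), 50.0)
    depth[2] = 2.0
    g = make_genotypes(rows, individuals=list("abcdef"), qual=qual, depth=depth)
    kept = gs.filter_snps(g)
    assert list(kept.snp_ids) == ["snp0", "snp6", "snp7", "snp8"]


def test_missing_depth_skips_depth_filter():
    g = make_genotypes([[0, 1, 2, 1]], individuals=list("abcd"))
    with pytest.warns(UserWarning, match="depth"):
        assert gs.filter_snps(g).n_snps == 1


# ------------------------------------------------------ nucleotide diversity

def test_monomorphic_site_has_zero_pi(two_pop_map):
    g = make_genotypes([[0] * 20], individuals=two_pop_map.individuals, transcripts=["t"])
    df = gs.nucleotide_diversity(g, two_pop_map)
    assert (df["pi"] == 0).all()


def test_per_site_pi_matches_pairwise_difference_oracle():
    """4 diploids at 4 ref / 4 alt alleles: mean pairwise difference oracle."""
    genotypes = [[0, 2, 1, 1]]
    alleles = [0, 0, 1, 1, 0, 1, 0, 1]  # the 8 alleles those genotypes carry
    pairs = list(itertools.combinations(range(8), 2))
    oracle = np.mean([alleles[i] != alleles[j] for i, j in pairs])
    import pandas as pd
    from popxome.containers import PopMap
    pm = PopMap(pd.DataFrame({
        "individual": list("abcd"), "population": ["P"] * 4, "group": ["north"] * 4,
    }))
    g = make_genotypes(genotypes, individuals=list("abcd"), transcripts=["t"])
    df = gs.nucleotide_diversity(g, pm)
    assert df["pi"].iloc[0] == pytest.approx(oracle)
    assert df["pi"].iloc[0] == pytest.approx(2 * 16 / (8 * 7))


def test_transcript_pi_is_mean_over_variant_sites():
    import pandas as pd
    from popxome.containers import PopMap
    pm = PopMap(pd.DataFrame({
        "individual": list("abcd"), "population": ["P"] * 4, "group": ["north"] * 4,
    }))
    g = make_genotypes([[0, 2, 1, 1], [0, 0, 0, 0]], individuals=list("abcd"),
                       transcripts=["t", "t"])
    df = gs.nucleotide_diversity(g, pm)
    assert df["pi"].iloc[0] == pytest.approx((2 * 16 / 56 + 0.0) / 2)
    assert df["n_sites"].iloc[0] == 2


def test_pi_invariant_under_allele_relabeling(two_pop_map):
    rng = np.random.default_rng(0)
    geno = rng.integers(0, 3, size=(30, 20)).astype(np.int8)
    g = make_genotypes(geno, individuals=two_pop_map.individuals,
                       transcripts=["t"] * 30)
    flipped = make_genotypes(2 - geno, individuals=two_pop_map.individuals,
                             transcripts=["t"] * 30)
    a = gs.nucleotide_diversity(g, two_pop_map)
    b = gs.nucleotide_diversity(flipped, two_pop_map)
    np.testing.assert_allclose(a["pi"], b["pi"])


# ----------------------------------------------------------------------- FST

def _wc_oracle_site(geno_row, idx1, idx2):
    """Direct transcription of the two-population variance components.

    Independent of the vectorized implementation: scalar arithmetic on one
    site, two units, no missing data.
    """
    g1 = [geno_row[i] for i in idx1]
    g2 = [geno_row[i] for i in idx2]
    n1, n2 = len(g1), len(g2)
    p1 = sum(g1) / (2 * n1)
    p2 = sum(g2) / (2 * n2)
    h1 = sum(1 for x in g1 if x == 1) / n1
    h2 = sum(1 for x in g2 if x == 1) / n2
    r = 2
    n_bar = (n1 + n2) / r
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (n1 + n2)
    a = (n_bar / nc) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    return a, b, c


def test_multilocus_fst_matches_direct_formula_oracle(two_pop_map):
    rng = np.random.default_rng(3)
    geno = rng.integers(0, 3, size=(50, 20)).astype(np.int8)
    g = make_genotypes(geno, individuals=two_pop_map.individuals)
    mat = gs.pairwise_fst(g, two_pop_map)
    idx1, idx2 = list(range(10)), list(range(10, 20))
    num = den = 0.0
    for row in geno:
        a, b, c = _wc_oracle_site(row, idx1, idx2)
        num += a
        den += a + b + c
    assert mat.values[0, 1] == pytest.approx(num / den, rel=1e-10)


def test_fixed_difference_gives_fst_one(two_pop_map):
    geno = np.array([[0] * 10 + [2] * 10] * 5)
    g = make_genotypes(geno, individuals=two_pop_map.individuals)
    assert gs.pairwise_fst(g, two_pop_map).values[0, 1] == pytest.approx(1.0)


def test_identical_all_het_columns_give_exact_zero(two_pop_map):
    # the estimator's exact-zero configuration: duplicated columns, all het
    geno = np.ones((5, 20), dtype=np.int8)
    g = make_genotypes(geno, individuals=two_pop_map.individuals)
    assert gs.pairwise_fst(g, two_pop_map).values[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_fst_matrix_symmetric_and_ordered_by_divergence():
    vals = {}
    for target in (0.1, 0.5):
        cfg = SimConfig(n_transcripts=200, snps_per_transcript=8, fst_target=target,
                        n_per_pop=10, seed=31)
        g, _ = simulate_genotypes(cfg)
        mat = gs.pairwise_fst(g, build_popmap(cfg), level="group")
        np.testing.assert_allclose(mat.values, mat.values.T)
        vals[target] = mat.values[0, 1]
    assert vals[0.5] > vals[0.1]


def test_all_missing_unit_raises(two_pop_map):
    geno = np.zeros((3, 20), dtype=np.int8)
    geno[:, 10:] = MISSING
    g = make_genotypes(geno, individuals=two_pop_map.individuals)
    with pytest.raises(ValueError, match="no called genotypes"):
        gs.pairwise_fst(g, two_pop_map)


# ----------------------------------------------------------------------- PCA

def test_pc1_separates_divergent_groups():
    cfg = SimConfig(n_transcripts=200, snps_per_transcript=8, fst_target=0.5,
                    n_per_pop=10, seed=41)
    g, _ = simulate_genotypes(cfg)
    pm = build_popmap(cfg)
    res = gs.genotype_pca(g, n_components=2)
    pc1 = res.coordinates["PC1"]
    grp = dict(zip(pm.table["individual"], pm.table["group"]))
    north = [pc1[i] for i in pc1.index if grp[i] == "north"]
    south = [pc1[i] for i in pc1.index if grp[i] == "south"]
    assert max(north) < min(south) or max(south) < min(north)
    # silhouette of the two clusters on PC1
    from sklearn.metrics import silhouette_score
    labels = [grp[i] for i in pc1.index]
    assert silhouette_score(pc1.to_numpy().reshape(-1, 1), labels) > 0.8


def test_identical_individuals_have_zero_eigenvalues(two_pop_map):
    geno = np.tile(np.array([[1], [0], [2]], dtype=np.int8), (1, 20))
    g = make_genotypes(geno, individuals=two_pop_map.individuals)
    res = gs.genotype_pca(g, n_components=3)
    assert np.allclose(res.coordinates.to_numpy(), 0.0)


def test_explained_variance_fractions_sum_to_one(small_sim):
    res = gs.genotype_pca(small_sim.genotypes, n_components=5)
    assert res.explained_variance_ratio.sum() == pytest.approx(1.0)


def test_pca_invariant_under_snp_permutation(small_sim):
    g = small_sim.genotypes
    rng = np.random.default_rng(1)
    perm = rng.permutation(g.n_snps)
    res_a = gs.genotype_pca(g, n_components=3)
    res_b = gs.genotype_pca(g.subset_snps(perm), n_components=3)
    np.testing.assert_allclose(
        np.abs(res_a.coordinates.to_numpy()),
        np.abs(res_b.coordinates.to_numpy()),
        atol=1e-8,
    )


def test_too_many_components_raise(small_sim):
    with pytest.raises(ValueError, match="n_components"):
        gs.genotype_pca(small_sim.genotypes, n_components=len(small_sim.genotypes.individuals))
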