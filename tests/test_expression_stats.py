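"""FPKM filter, Ep/Ed, similarity, expression PCA, dispersion comparison."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from popxome import expression_stats as es
from popxome.containers import ExpressionTable, PopMap

from conftest import make_expression


@pytest.fixture
def four_pop_map():
    rows = []
    for pop, group in [("N1", "north"), ("N2", "north"), ("S1", "south"), ("S2", "south")]:
        for k in range(3):
            rows.append({"individual": f"{pop}_{k}", "population": pop, "group": group})
    return PopMap(pd.DataFrame(rows))


# ------------------------------------------------------------------- filter

def test_constant_high_expression_is_retained(four_pop_map):
    x = make_expression(np.full((1, 12), 10.0), four_pop_map.individuals)
    kept, report = es.filter_expression(x, four_pop_map)
    assert kept.transcripts == ["T0"]
    assert report["retained"].all()


def test_one_population_below_floor_removes_transcript(four_pop_map):
    vals = np.full((1, 12), 50.0)
    vals[0, :3] = 3.9  # population N1 mean below the floor of 4
    x = make_expression(vals, four_pop_map.individuals)
    kept, _ = es.filter_expression(x, four_pop_map)
    assert kept.transcripts == []


def test_high_variance_in_one_population_removes_transcript(four_pop_map):
    vals = np.full((1, 12), 10.0)
    vals[0, :3] = [0.1, 0.2, 40.0]  # N1 SD far above its mean
    x = make_expression(vals, four_pop_map.individuals)
    kept, _ = es.filter_expression(x, four_pop_map)
    assert kept.transcripts == []


def test_planted_fixture_keeps_exactly_the_survivors(four_pop_map):
    rng = np.random.default_rng(8)
    n = 20
    vals = rng.uniform(8, 12, size=(n, 12))
    survivors = {0, 3, 5, 8, 12, 17, 19}
    for i in range(n):
        if i in survivors:
            continue
        if i % 2:
            vals[i, 3:6] = rng.uniform(0.1, 3.0, 3)  # N2 mean below floor
        else:
            vals[i, 6:9] = [0.0, 0.0, 60.0]  # S1 SD above mean
    x = make_expression(vals, four_pop_map.individuals)
    kept, _ = es.filter_expression(x, four_pop_map)
    assert kept.transcripts == [f"T{i}" for i in sorted(survivors)]


def test_filter_is_idempotent(four_pop_map):
    rng = np.random.default_rng(9)
    vals = rng.lognormal(2.0, 1.5, size=(50, 12))
    x = make_expression(vals, four_pop_map.individuals)
    once, _ = es.filter_expression(x, four_pop_map)
    twice, _ = es.filter_expression(once, four_pop_map)
    assert once.transcripts == twice.transcripts


def test_single_library_population_skips_sd_criterion():
    pm = PopMap(pd.DataFrame({
        "individual": ["a", "b", "c"],
        "population": ["P1", "P2", "P2"],
        "group": ["north", "south", "south"],
    }))
    x = make_expression([[5.0, 5.0, 5.0]], pm.individuals)
    with pytest.warns(UserWarning, match="one library"):
        kept, _ = es.filter_expression(x, pm)
    assert kept.transcripts == ["T0"]


def test_global_scope_uses_sd_over_all_libraries(four_pop_map):
    # constant within populations but very different between them:
    # per-population SD is 0 (passes), global SD exceeds one pop's mean
    vals = np.repeat([[4.5, 4.5, 4.5, 100.0]], 3, axis=1).reshape(1, 12)
    vals = np.array([[4.5] * 3 + [4.5] * 3 + [100.0] * 3 + [100.0] * 3])
    x = make_expression(vals, four_pop_map.individuals)
    kept_pop, _ = es.filter_expression(x, four_pop_map, scope="population")
    kept_glob, _ = es.filter_expression(x, four_pop_map, scope="global")
    assert kept_pop.transcripts == ["T0"]
    assert kept_glob.transcripts == []


# -------------------------------------------------------------------- Ep/Ed

@pytest.mark.parametrize(
    "values,expected_ep",
    [([5.0, 5.0, 5.0], 5.0), ([1.0, 2.0, 3.0], 2.0)],
)
def test_population_expression_is_mean_fpkm(values, expected_ep):
    pm = PopMap(pd.DataFrame({
        "individual": list("abc"), "population": ["P"] * 3, "group": ["north"] * 3,
    }))
    x = make_expression([values], pm.individuals)
    df = es.population_expression(x, pm)
    assert df["Ep"].iloc[0] == pytest.approx(expected_ep)


def test_single_individual_ep_is_identity():
    pm = PopMap(pd.DataFrame({
        "individual": ["a"], "population": ["P"], "group": ["north"],
    }))
    x = make_expression([[7.25]], pm.individuals)
    assert es.population_expression(x, pm)["Ep"].iloc[0] == pytest.approx(7.25)


def test_expression_diversity_hand_example():
    pm = PopMap(pd.DataFrame({
        "individual": list("abc"), "population": ["P"] * 3, "group": ["north"] * 3,
    }))
    x = make_expression([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0], [0.0, 0.0, 0.0]], pm.individuals)
    df = es.expression_diversity(x, pm)
    assert df["Ed"].iloc[0] == pytest.approx(0.5)  # (1+0+1)/((3-1)*2)
    assert df["Ed"].iloc[1] == pytest.approx(0.0)
    assert np.isnan(df["Ed"].iloc[2])  # Ep = 0 flagged missing


@settings(max_examples=25, deadline=None)
@given(
    values=st.lists(st.floats(0.01, 1e4), min_size=2, max_size=8),
    scale=st.floats(0.01, 100.0),
)
def test_ed_is_scale_invariant(values, scale):
    pm = PopMap(pd.DataFrame({
        "individual": [f"i{k}" for k in range(len(values))],
        "population": ["P"] * len(values),
        "group": ["north"] * len(values),
    }))
    a = es.expression_diversity(make_expression([values], pm.individuals), pm)
    b = es.expression_diversity(
        make_expression([[v * scale for v in values]], pm.individuals), pm
    )
    assert a["Ed"].iloc[0] == pytest.approx(b["Ed"].iloc[0], rel=1e-9)


# --------------------------------------------------------------- similarity

def test_identical_profiles_give_similarity_one(four_pop_map):
    rng = np.random.default_rng(4)
    profile = rng.lognormal(2, 1, size=50)
    vals = np.tile(profile[:, None], (1, 12))
    x = make_expression(vals, four_pop_map.individuals)
    res = es.ep_similarity(x, four_pop_map, "N1", "S1")
    assert res.estimate == pytest.approx(1.0)


def test_independent_profiles_give_similarity_near_zero(four_pop_map):
    rng = np.random.default_rng(6)
    vals = rng.lognormal(2, 1, size=(5000, 12))
    x = make_expression(vals, four_pop_map.individuals)
    res = es.ep_similarity(x, four_pop_map, "N1", "S2")
    assert abs(res.estimate) < 0.05


def test_pairwise_similarity_matches_hand_mean_of_four_coefficients():
    pm = PopMap(pd.DataFrame({
        "individual": ["a1", "a2", "b1", "b2"],
        "population": ["A", "A", "B", "B"],
        "group": ["north", "north", "south", "south"],
    }))
    vals = np.array([
        [1.0, 2.0, 3.0, 0.5],
        [4.0, 5.0, 1.0, 2.0],
        [2.0, 1.0, 6.0, 7.0],
        [8.0, 3.0, 2.0, 1.0],
    ])
    x = make_expression(vals, pm.individuals)
    logv = np.log2(vals + 1.0)
    expected = np.mean([
        stats.pearsonr(logv[:, i], logv[:, j]).statistic
        for i, j in itertools.product([0, 1], [2, 3])
    ])
    res = es.ep_similarity(x, pm, "A", "B")
    assert res.estimate == pytest.approx(expected)
    assert res.n == 4


def test_similarity_is_symmetric(small_sim):
    x = small_sim.expression
    pm = small_sim.popmap
    ab = es.ep_similarity(x, pm, "N1", "S1").estimate
    ba = es.ep_similarity(x, pm, "S1", "N1").estimate
    assert ab == pytest.approx(ba)


# ---------------------------------------------------------------------- PCA

def test_expression_pca_separates_groups_with_planted_de(small_sim):
    res = es.expression_pca(small_sim.expression, n_components=2)
    grp = dict(zip(small_sim.popmap.table["individual"], small_sim.popmap.table["group"]))
    pc1 = res.coordinates["PC1"]
    north = [pc1[i] for i in pc1.index if grp[i] == "north"]
    south = [pc1[i] for i in pc1.index if grp[i] == "south"]
    assert max(north) < min(south) or max(south) < min(north)


def test_expression_pca_zero_for_equal_individuals(four_pop_map):
    x = make_expression(np.tile([[3.0]], (5, 12)), four_pop_map.individuals)
    res = es.expression_pca(x, n_components=2)
    assert np.allclose(res.coordinates.to_numpy(), 0.0)
    assert es.expression_pca(
        make_expression(np.random.default_rng(0).lognormal(1, 1, (20, 12)),
                        four_pop_map.individuals),
        n_components=3,
    ).explained_variance_ratio.sum() == pytest.approx(1.0)


# --------------------------------------------------------------- dispersion

def test_identical_cv_sets_give_zero_t(four_pop_map):
    rng = np.random.default_rng(12)
    block = rng.lognormal(2, 1, size=(30, 12))
    vals = np.vstack([block, block])  # CGT rows identical to non-CGT rows
    x = make_expression(vals, four_pop_map.individuals)
    flags = pd.Series([True] * 30 + [False] * 30, index=x.transcripts)
    res = es.dispersion_comparison(x, flags)
    assert res.estimate == pytest.approx(0.0)
    assert res.statistic == pytest.approx(0.0)


def test_planted_cv_inflation_is_detected(four_pop_map):
    rng = np.random.default_rng(13)
    n_cgt, n_non = 400, 2000
    base = rng.lognormal(3.0, 0.5, size=(n_cgt + n_non, 1))
    noise = rng.normal(0, 1, size=(n_cgt + n_non, 12))
    sd = 0.25 * np.ones((n_cgt + n_non, 1))
    sd[:n_cgt] *= 1.3  # CV inflation on the CGT set
    vals = base * np.exp(noise * sd)
    x = make_expression(vals, four_pop_map.individuals)
    flags = pd.Series([True] * n_cgt + [False] * n_non, index=x.transcripts)
    res = es.dispersion_comparison(x, flags)
    assert res.pvalue < 0.01
    assert res.metadata["mean_cv_cgt"] > res.metadata["mean_cv_non_cgt"]


def test_low_prevalence_transcripts_are_excluded(four_pop_map):
    vals = np.full((2, 12), 5.0)
    vals[1, :7] = 0.0  # expressed in only 5/12 samples
    x = make_expression(vals + np.random.default_rng(3).uniform(0, 1, (2, 12)) * (vals > 0),
                        four_pop_map.individuals)
    flags = pd.Series([True, False], index=x.transcripts)
    with pytest.raises(ValueError, match="non-empty"):
        es.dispersion_comparison(x, flags)
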