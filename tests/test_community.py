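"""Community-structure statistics: rarefaction, coverage, core filter, CLR,
Bray-Curtis, NMDS, PERMANOVA, alpha diversity."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from rhizopheno import community as cm
from conftest import make_asv_table


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def test_rarefy_forced_and_identity_cases():
    t = make_asv_table([[10, 0, 0], [3, 4, 3]])
    out = cm.rarefy_even_depth(t, depth=5, seed=0)
    assert out.counts.loc["s0"].tolist() == [5, 0, 0]
    t2 = make_asv_table([[3, 4, 3]])
    out2 = cm.rarefy_even_depth(t2, depth=10, seed=0)
    assert out2.counts.loc["s0"].tolist() == [3, 4, 3]


def test_rarefy_hypergeometric_expectation():
    # 1000 independent rows of (50, 50) rarefied to 10: mean first entry ~ 5
    t = make_asv_table(np.tile([50, 50], (1000, 1)))
    out = cm.rarefy_even_depth(t, depth=10, seed=1)
    assert abs(out.counts.iloc[:, 0].mean() - 5.0) < 0.15
    assert (out.counts.sum(axis=1) == 10).all()


def test_rarefy_never_increases_counts_and_drops_shallow():
    t = make_asv_table([[10, 10, 10], [1, 1, 0]])
    with pytest.warns(UserWarning, match="dropping"):
        out = cm.rarefy_even_depth(t, depth=6, seed=2)
    assert list(out.counts.index) == ["s0"]
    assert (out.counts.values <= t.counts.loc[["s0"]].values).all()
    with pytest.raises(ValueError):
        cm.rarefy_even_depth(t, depth=0)


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

def test_coverage_closed_forms():
    t = make_asv_table([[5, 5, 5], [1, 1, 0], [3, 1, 2], [0, 0, 0]])
    cov = cm.estimate_coverage(t)
    assert cov.loc["s0"] == 1.0                       # no singletons
    assert cov.loc["s1"] == 0.0                       # n=2, f1=2, f2=0
    assert np.isclose(cov.loc["s2"], 0.8810, atol=5e-5)
    assert np.isnan(cov.loc["s3"])                    # empty sample


# ---------------------------------------------------------------------------
# Core filter
# ---------------------------------------------------------------------------

def test_core_filter_mean_threshold_and_boundary_prevalence():
    # taxon 0 at 0.4%, below threshold; taxon 1 at 2% in 4/5 replicates
    counts = np.zeros((5, 3), dtype=int)
    counts[:, 2] = 996
    counts[:, 0] = 4        # 0.4% everywhere
    counts[:4, 1] = [20, 20, 20, 20]
    counts[:, 2] -= counts[:, 1]
    t = make_asv_table(counts, plant=["carrot"] * 5)
    out = cm.filter_core_taxa(t, mean_thresh=0.005, prevalence=0.8)
    assert "t0" not in out.taxon_ids
    assert "t1" in out.taxon_ids        # 4/5 = 0.8 boundary inclusive
    assert "t2" in out.taxon_ids


def test_core_filter_matches_brute_force_enumeration():
    rng = np.random.default_rng(4)
    counts = rng.integers(0, 40, size=(10, 6))
    counts[:, 0] = 0                     # absent taxon
    plants = ["carrot"] * 5 + ["lettuce"] * 5
    t = make_asv_table(counts, plant=plants)
    out = cm.filter_core_taxa(t, mean_thresh=0.005, prevalence=0.8)

    rel = counts / counts.sum(axis=1, keepdims=True)
    survivors = []
    for j, taxon in enumerate(t.taxon_ids):
        if rel[:, j].mean() < 0.005:
            continue
        ok = False
        for g in ("carrot", "lettuce"):
            idx = [i for i, p in enumerate(plants) if p == g]
            present = np.mean([counts[i, j] > 0 for i in idx])
            if present >= 0.8:
                ok = True
        if ok:
            survivors.append(taxon)
    assert out.taxon_ids == survivors


# ---------------------------------------------------------------------------
# CLR
# ---------------------------------------------------------------------------

def test_clr_closed_forms_and_scale_invariance():
    t = make_asv_table([[10, 10, 10]])
    assert np.allclose(cm.clr_transform(t).values, 0.0)
    c = 7.0
    row = pd.DataFrame([[np.e * c - 0.5, c - 0.5]])
    out = cm.clr_transform(row, pseudocount=0.5)
    assert np.allclose(out.values, [[0.5, -0.5]], atol=1e-12)
    row2 = pd.DataFrame([[2.0, 6.0, 12.0]])
    a = cm.clr_transform(row2, pseudocount=0.0)
    b = cm.clr_transform(row2 * 10, pseudocount=0.0)
    assert np.allclose(a.values, b.values, atol=1e-12)
    # rows sum to zero
    t2 = make_asv_table([[3, 0, 9], [1, 1, 1]])
    assert np.allclose(cm.clr_transform(t2).sum(axis=1), 0.0, atol=1e-9)


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

def test_bray_curtis_hand_values_and_axioms():
    rel = pd.DataFrame(
        [[0.7, 0.3, 0.0], [0.2, 0.3, 0.5], [0.7, 0.3, 0.0], [0.0, 0.0, 1.0]],
        index=["a", "b", "c", "d"],
    )
    d = cm.bray_curtis_matrix(rel)
    assert np.isclose(d["a", "b"], 0.5, atol=1e-12)
    assert d["a", "c"] == 0.0                       # identical rows
    assert np.isclose(d["a", "d"], 1.0, atol=1e-12)  # disjoint supports
    D = np.asarray(d.data)
    assert np.allclose(D, D.T) and np.all(np.diag(D) == 0)
    assert (D >= 0).all() and (D <= 1 + 1e-12).all()
    with pytest.raises(ValueError):
        cm.bray_curtis_matrix(pd.DataFrame([[-0.1, 1.1]]))


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

def test_nmds_euclidean_configuration_has_low_stress():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(8, 2))
    D = squareform(pdist(X))
    res = cm.nmds_ordinate(DistanceMatrix(D, ids=[f"s{i}" for i in range(8)]),
                           n_starts=10, seed=0)
    assert res.stress < 0.01


def test_nmds_duplicates_coincide_and_determinism():
    X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [2.0, 2.0]])
    D = squareform(pdist(X))
    ids = [f"s{i}" for i in range(5)]
    res = cm.nmds_ordinate(DistanceMatrix(D, ids=ids), n_starts=10, seed=3)
    c0 = res.site_scores.loc["s0"].to_numpy()
    c1 = res.site_scores.loc["s1"].to_numpy()
    assert np.linalg.norm(c0 - c1) < 1e-4
    res2 = cm.nmds_ordinate(DistanceMatrix(D, ids=ids), n_starts=10, seed=3)
    pd.testing.assert_frame_equal(res.site_scores, res2.site_scores)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _toy_distance(n, seed, shift=0.0, groups=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3))
    if shift and groups is not None:
        X[np.asarray(groups) == "a"] += shift
    ids = [f"s{i}" for i in range(n)]
    return DistanceMatrix(squareform(pdist(X)), ids=ids), ids


def test_permanova_single_level_group_gives_zero_r2():
    d, ids = _toy_distance(8, 6)
    meta = pd.DataFrame({"g": ["a"] * 8}, index=ids)
    with pytest.warns(UserWarning, match="aliased"):
        res = cm.permanova(d, meta, terms=["g"], n_perm=99, seed=0)
    assert abs(res.table.loc["g", "R2"]) < 1e-9
    assert res.table.loc["g", "p"] == 1.0


def test_permanova_perfect_separation():
    # two tight groups far apart
    X = np.vstack([np.zeros((4, 2)), 100 + np.zeros((4, 2))])
    X += np.random.default_rng(7).normal(0, 1e-3, X.shape)
    ids = [f"s{i}" for i in range(8)]
    d = DistanceMatrix(squareform(pdist(X)), ids=ids)
    meta = pd.DataFrame({"g": ["a"] * 4 + ["b"] * 4}, index=ids)
    res = cm.permanova(d, meta, terms=["g"], n_perm=999, seed=1)
    assert res.table.loc["g", "R2"] > 0.999
    # only group-preserving permutations tie the observed F
    assert res.table.loc["g", "p"] < 0.05


def test_permanova_matches_exhaustive_enumeration_on_tiny_design():
    groups = ["a"] * 4 + ["b"] * 4
    d, ids = _toy_distance(8, 8, shift=1.2, groups=groups)
    meta = pd.DataFrame({"g": groups}, index=ids)
    res = cm.permanova(d, meta, terms=["g"], n_perm=4999, seed=2)
    f_obs = res.table.loc["g", "F"]
    fs = []
    for comb in itertools.combinations(range(8), 4):
        lab = np.array(["b"] * 8)
        lab[list(comb)] = "a"
        m = pd.DataFrame({"g": lab}, index=ids)
        fs.append(cm.permanova(d, m, terms=["g"], n_perm=99, seed=0)
                  .table.loc["g", "F"])
    p_exact = np.mean(np.asarray(fs) >= f_obs - 1e-9)
    assert abs(res.table.loc["g", "p"] - p_exact) < 0.02


def test_permanova_agrees_with_skbio_single_factor():
    groups = ["a"] * 5 + ["b"] * 5
    d, ids = _toy_distance(10, 9, shift=1.0, groups=groups)
    meta = pd.DataFrame({"g": groups}, index=ids)
    ours = cm.permanova(d, meta, terms=["g"], n_perm=999, seed=3)
    ref = skbio_permanova(d, grouping=list(groups), permutations=999)
    assert np.isclose(ours.table.loc["g", "F"], ref["test statistic"],
                      atol=1e-9)


def test_permanova_r2_partition_sums_to_one():
    groups = ["a", "a", "b", "b", "a", "b", "a", "b", "a", "b"]
    plants = ["x", "y"] * 5
    d, ids = _toy_distance(10, 10, shift=0.8, groups=groups)
    meta = pd.DataFrame({"g": groups, "p": plants,
                         "lat": np.linspace(0, 1, 10)}, index=ids)
    res = cm.permanova(d, meta, terms=["g", "p", "g:p", "lat"],
                       n_perm=199, seed=4)
    r2 = res.table["R2"]
    assert np.isclose(r2.drop("Total").sum(), 1.0, atol=1e-9)
    assert np.isclose(r2.loc["Total"], 1.0)


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def test_alpha_diversity_closed_forms():
    t = make_asv_table([[1, 1, 1, 1], [9, 1, 0, 0], [7, 0, 0, 0]])
    div = cm.alpha_diversity(t)
    assert div.loc["s0", "richness"] == 4
    assert np.isclose(div.loc["s0", "shannon"], np.log(4), atol=1e-12)
    assert np.isclose(div.loc["s0", "evenness"], 1.0, atol=1e-12)
    assert np.isclose(div.loc["s1", "shannon"],
                      -0.9 * np.log(0.9) - 0.1 * np.log(0.1), atol=1e-12)
    assert div.loc["s2", "evenness"] == 0.0
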