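"""Distances, Mantel, ordination, dissimilarity tests, ANOVA and regression."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from menpipe.community_stats import (
    DistanceMatrix,
    dissimilarity_tests,
    euclidean_trait_distance,
    flux_regression,
    group_anova,
    jaccard_distance,
    mantel_table,
    mantel_test,
    pca_ordination,
)
from menpipe.io_formats import CountTable


def _table(counts, **kw):
    counts = np.asarray(counts)
    return CountTable.from_arrays(
        [f"o{i}" for i in range(counts.shape[0])],
        [f"s{j}" for j in range(counts.shape[1])],
        counts,
        **kw,
    )


def _random_dm(rng, n, ids=None):
    x = rng.normal(size=(n, 3))
    d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
    return DistanceMatrix(ids or [f"s{i}" for i in range(n)], d, "euclidean")


def test_jaccard_hand_values():
    # s0 = {o0, o1}, s1 = {o1, o2}: |∩| = 1, |∪| = 3 -> d = 2/3
    t = _table([[3, 0], [1, 2], [0, 5]])
    dm = jaccard_distance(t)
    assert dm.data[0, 1] == pytest.approx(2 / 3, abs=1e-12)


def test_jaccard_empty_samples():
    t = _table([[3, 0, 0], [1, 0, 0]])
    dm = jaccard_distance(t)
    assert dm.data[0, 1] == 1.0  # empty vs non-empty
    assert dm.data[1, 2] == 0.0  # two empty samples are identical


def test_mantel_identical_matrices_r_one():
    dm = _random_dm(np.random.default_rng(0), 6)
    res = mantel_test(dm, dm, permutations=99, seed=1)
    assert res.r == pytest.approx(1.0, abs=1e-12)


def test_mantel_invariant_to_common_relabelling():
    rng = np.random.default_rng(3)
    dx = _random_dm(rng, 7)
    dy = _random_dm(rng, 7)
    r1 = mantel_test(dx, dy, permutations=0, exact=False, seed=0).r
    perm = list(np.random.default_rng(5).permutation(7))
    relabel = [dx.ids[i] for i in perm]
    dx2 = dx.reorder(relabel)
    dy2 = dy.reorder(relabel)
    r2 = mantel_test(dx2, dy2, permutations=0, exact=False, seed=0).r
    assert r1 == pytest.approx(r2, abs=1e-12)


def test_mantel_exact_matches_independent_enumeration():
    rng = np.random.default_rng(7)
    dx = _random_dm(rng, 4)
    dy = _random_dm(rng, 4)
    res = mantel_test(dx, dy, exact=True)
    iu = np.triu_indices(4, k=1)
    x = dx.data[iu]
    count = 0
    for perm in itertools.permutations(range(4)):
        yp = dy.data[np.ix_(perm, perm)][iu]
        if np.corrcoef(x, yp)[0, 1] >= res.r - 1e-12:
            count += 1
    assert res.permutations == 24
    assert res.p == pytest.approx(count / 24, abs=1e-15)


def test_mantel_degenerate_constant_matrix():
    ids = ["a", "b", "c", "d"]
    constant = DistanceMatrix(ids, np.ones((4, 4)) - np.eye(4), "jaccard")
    dy = _random_dm(np.random.default_rng(1), 4, ids)
    res = mantel_test(constant, dy, permutations=9, seed=0)
    assert np.isnan(res.r) and np.isnan(res.p)
    assert res.method == "degenerate"


def test_mantel_seeded_reproducibility():
    rng = np.random.default_rng(9)
    dx = _random_dm(rng, 8)
    dy = _random_dm(rng, 8)
    a = mantel_test(dx, dy, permutations=199, seed=11)
    b = mantel_test(dx, dy, permutations=199, seed=11)
    assert (a.r, a.p) == (b.r, b.p)


def test_mantel_table_layout():
    rng = np.random.default_rng(2)
    t = _table(rng.integers(0, 20, (5, 6)))
    traits = pd.DataFrame(
        {"TN": rng.normal(size=6), "pH": rng.normal(size=6)}, index=t.sample_ids
    )
    out = mantel_table({"prokaryote": jaccard_distance(t)}, traits, permutations=49, seed=0)
    assert list(out.columns) == ["community", "trait", "r", "p"]
    assert len(out) == 2


def test_pca_ordination_matches_svd_variance():
    rng = np.random.default_rng(4)
    t = _table(rng.integers(1, 100, (6, 9)))
    ords = pca_ordination(t)
    assert ords.scores.shape == (9, 2)
    x = t.relative_abundance().to_numpy().T
    xc = x - x.mean(axis=0)
    s = np.linalg.svd(xc, compute_uv=False)
    assert np.allclose(
        ords.explained_variance_ratio, s**2 / (s**2).sum(), atol=1e-10
    )


def test_anosim_disjoint_groups_r_one():
    # two groups of samples with disjoint OTU sets -> maximal separation
    counts = np.zeros((6, 6), dtype=int)
    rng = np.random.default_rng(0)
    counts[:3, :3] = rng.integers(1, 50, (3, 3))
    counts[3:, 3:] = rng.integers(1, 50, (3, 3))
    dm = jaccard_distance(_table(counts))
    out = dissimilarity_tests(dm, ["A"] * 3 + ["B"] * 3, permutations=99, seed=0)
    r = out.set_index("test").loc["ANOSIM", "statistic"]
    assert r == pytest.approx(1.0, abs=1e-12)


def test_dissimilarity_statistics_match_skbio():
    from skbio import DistanceMatrix as SkbioDM
    from skbio.stats.distance import anosim, permanova

    rng = np.random.default_rng(12)
    n = 10
    dm = _random_dm(rng, n)
    labels = ["A"] * 4 + ["B"] * 3 + ["C"] * 3
    out = dissimilarity_tests(dm, labels, permutations=49, seed=0).set_index("test")
    sk_dm = SkbioDM(dm.data, ids=dm.ids)
    sk_anosim = anosim(sk_dm, list(labels), permutations=9)
    sk_permanova = permanova(sk_dm, list(labels), permutations=9)
    assert out.loc["ANOSIM", "statistic"] == pytest.approx(
        sk_anosim["test statistic"], abs=1e-10
    )
    assert out.loc["PERMANOVA", "statistic"] == pytest.approx(
        sk_permanova["test statistic"], abs=1e-10
    )


def test_mrpp_hand_value():
    # 4 points on a line: groups {0,1} and {2,3}
    x = np.array([0.0, 1.0, 10.0, 12.0])
    d = np.abs(x[:, None] - x[None, :])
    dm = DistanceMatrix(["a", "b", "c", "d"], d, "euclidean")
    out = dissimilarity_tests(dm, ["g1", "g1", "g2", "g2"], permutations=23, seed=0)
    delta = out.set_index("test").loc["MRPP", "statistic"]
    # delta = 0.5 * mean(d within g1) + 0.5 * mean(d within g2) = 0.5*1 + 0.5*2
    assert delta == pytest.approx(1.5, abs=1e-12)


def test_dissimilarity_degenerate_distances_give_nan():
    dm = DistanceMatrix(
        ["a", "b", "c", "d"], np.ones((4, 4)) - np.eye(4), "jaccard"
    )
    out = dissimilarity_tests(dm, ["A", "A", "B", "B"], permutations=9, seed=0)
    assert out["statistic"].isna().all()


def test_dissimilarity_reproducible_under_seed():
    dm = _random_dm(np.random.default_rng(6), 9)
    labels = ["A"] * 5 + ["B"] * 4
    a = dissimilarity_tests(dm, labels, permutations=99, seed=3)
    b = dissimilarity_tests(dm, labels, permutations=99, seed=3)
    pd.testing.assert_frame_equal(a, b)


def test_group_anova_hand_computed():
    # groups (1,2,3) and (3,4,5): grand mean 3, SSB = 6, SSW = 4, F = 6/(4/4)
    values = [1, 2, 3, 3, 4, 5]
    groups = ["a", "a", "a", "b", "b", "b"]
    f, p = group_anova(values, groups)
    assert f == pytest.approx(6.0, abs=1e-12)
    assert p == pytest.approx(stats.f.sf(6.0, 1, 4), abs=1e-12)


def test_group_anova_degenerate_equal_constant_groups():
    f, p = group_anova([2.0, 2.0, 2.0, 2.0], ["a", "a", "b", "b"])
    assert (f, p) == (0.0, 1.0)


def test_flux_regression_collinear():
    res = flux_regression([1, 2, 3, 4], [2, 4, 6, 8])
    assert res.r_squared == pytest.approx(1.0, abs=1e-12)
    assert res.slope == pytest.approx(2.0, abs=1e-12)


def test_euclidean_trait_distance_standardizes():
    s = pd.Series([0.0, 10.0, 20.0], index=["a", "b", "c"])
    dm = euclidean_trait_distance(s)
    assert dm.data[0, 2] == pytest.approx(2 * dm.data[0, 1], abs=1e-12)
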