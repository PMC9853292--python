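"""Spearman matrices, RMT machinery and network assembly."""

import numpy as np
import pytest
from scipy import stats

from menpipe.association import (
    CorrelationMatrix,
    ThresholdError,
    build_interdomain_network,
    build_network,
    category_counts,
    chi_square_gof,
    merge_tables,
    spearman_matrix,
    threshold_matrix,
    unfold_spacings,
    _goe_cdf,
    _poisson_cdf,
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


def test_spearman_matches_rank_pearson_oracle():
    rng = np.random.default_rng(11)
    t = _table(rng.integers(0, 100, size=(6, 8)))
    got = spearman_matrix(t)
    rel = t.relative_abundance().to_numpy()
    for i in range(6):
        for j in range(6):
            ri = stats.rankdata(rel[i])
            rj = stats.rankdata(rel[j])
            expected = np.corrcoef(ri, rj)[0, 1]
            assert got.rho[i, j] == pytest.approx(expected, abs=1e-12)


def test_spearman_known_value():
    # ranks (1,2,3,4) vs (1,3,2,4): rho = 1 - 6*2/(4*15) = 0.8
    t = _table([[1, 2, 3, 4], [1, 3, 2, 4], [4, 3, 2, 1], [5, 5, 5, 5]])
    got = spearman_matrix(t)
    # closure keeps ranks except the constant row, which closure makes
    # anti-monotone with the column totals; use raw-rank rows only
    assert got.rho[0, 1] == pytest.approx(0.8, abs=1e-12)
    assert got.rho[0, 2] == pytest.approx(-1.0, abs=1e-12)


def test_spearman_zero_variance_rows_get_zero():
    t = _table([[1, 2, 3, 4], [2, 4, 6, 8], [0, 0, 0, 0], [1, 1, 2, 1]])
    got = spearman_matrix(t)
    # o2 has zero counts -> zero-variance relative abundance -> rho 0
    assert np.all(got.rho[2, [0, 1, 3]] == 0.0)
    assert got.rho[2, 2] == 1.0


def test_spearman_requires_four_samples():
    with pytest.raises(ValueError, match="4 samples"):
        spearman_matrix(_table([[1, 2, 3], [3, 2, 1]]))


def test_correlation_matrix_validation():
    with pytest.raises(ValueError, match="symmetric"):
        CorrelationMatrix(["a", "b"], np.array([[1.0, 0.5], [0.4, 1.0]]), 10)
    with pytest.raises(ValueError, match="diagonal"):
        CorrelationMatrix(["a", "b"], np.array([[0.9, 0.5], [0.5, 1.0]]), 10)


def test_threshold_matrix_keeps_sign_and_diagonal():
    rho = np.array([[1.0, -0.9, 0.3], [-0.9, 1.0, 0.0], [0.3, 0.0, 1.0]])
    m = threshold_matrix(CorrelationMatrix(["a", "b", "c"], rho, 10), 0.5)
    assert m[0, 1] == -0.9
    assert m[0, 2] == 0.0
    assert np.all(np.diag(m) == 1.0)


def test_unfold_spacings_mean_exactly_one():
    rng = np.random.default_rng(0)
    a = rng.standard_normal((80, 80))
    lam = np.linalg.eigvalsh((a + a.T) / 2)
    spacings = unfold_spacings(lam)
    assert spacings is not None
    assert spacings.mean() == pytest.approx(1.0, abs=1e-9)
    assert (spacings >= -1e-12).all()


def test_unfold_spacings_degenerate_spectrum_returns_none():
    assert unfold_spacings(np.ones(50)) is None
    assert unfold_spacings(np.arange(10.0)) is None


def test_chi_square_gof_accepts_own_law_rejects_other():
    rng = np.random.default_rng(1)
    pois = rng.exponential(1.0, 500)
    _, p_own, _ = chi_square_gof(pois, _poisson_cdf)
    _, p_other, _ = chi_square_gof(pois, _goe_cdf)
    assert p_own > 0.05
    assert p_other < 1e-6
    goe = rng.rayleigh(np.sqrt(2 / np.pi), 500)  # Wigner surmise sampler
    _, p_goe, _ = chi_square_gof(goe, _goe_cdf)
    _, p_pois, _ = chi_square_gof(goe, _poisson_cdf)
    assert p_goe > 0.05
    assert p_pois < 1e-6


def test_chi_square_gof_pools_small_expected_counts():
    d = np.random.default_rng(2).exponential(1.0, 60)
    chi2, p, df = chi_square_gof(d, _poisson_cdf)
    # 60 spacings in 30 bins cannot support 29 degrees of freedom once
    # expected counts are pooled to >= 5
    assert df <= 60 / 5
    assert np.isfinite(chi2) and 0 <= p <= 1


def test_build_network_edges_signs_and_categories(toy_table):
    corr = spearman_matrix(toy_table)
    net = build_network(corr, 0.5, toy_table)
    assert net.number_of_edges() >= 1
    for u, v, d in net.edges(data=True):
        assert abs(d["weight"]) >= 0.5
        assert d["sign"] == ("positive" if d["weight"] >= 0 else "negative")
    for n, d in net.nodes(data=True):
        expected = d["guild"] if d["guild"] != "none" else d["kingdom"]
        assert d["category"] == expected


def test_build_network_empty_raises_with_diagnostic():
    t = _table(np.random.default_rng(5).integers(0, 100, (5, 30)))
    corr = spearman_matrix(t)
    with pytest.raises(ThresholdError, match="max off-diagonal"):
        build_network(corr, 0.999, t)


def test_merge_tables_intersects_samples_and_rejects_collisions():
    a = CountTable.from_arrays(["p1", "p2"], ["s1", "s2", "s3"], [[1, 2, 3], [4, 5, 6]])
    b = CountTable.from_arrays(
        ["f1"], ["s2", "s3", "s4"], [[7, 8, 9]], kingdom="fungus"
    )
    merged = merge_tables([a, b])
    assert merged.sample_ids == ["s2", "s3"]
    assert merged.otu_ids == ["p1", "p2", "f1"]
    clash = CountTable.from_arrays(["p1"], ["s2", "s3"], [[1, 1]], kingdom="fungus")
    with pytest.raises(ValueError, match="collide"):
        merge_tables([a, clash])


def test_interdomain_categories_partition_nodes(toy_table):
    net, merged = build_interdomain_network([toy_table], threshold=0.5)
    counts = category_counts(net)
    assert counts.sum() == net.number_of_nodes()
    assert set(counts.index) <= {
        "prokaryote",
        "fungus",
        "cercozoa",
        "methanogen",
        "methanotroph",
    }
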