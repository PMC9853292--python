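"""Modules, Zi/Pi roles, eigengenes and trait correlations."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats

from menpipe.io_formats import CountTable, SampleMetadata
from menpipe.module_traits import (
    ModulePartition,
    classify_role,
    detect_modules,
    eigengene_set,
    eigengene_trait_correlation,
    guild_subnetwork,
    module_eigengene,
    significance_stars,
    zi_pi,
    _benjamini_hochberg,
)


def test_detect_modules_two_cliques(two_cliques):
    part = detect_modules(two_cliques)
    assert part.q == pytest.approx(0.5, abs=1e-12)
    assert sorted(map(sorted, part.modules)) == [[0, 1, 2, 3], [4, 5, 6, 7]]


def test_detect_modules_edgeless_graph():
    part = detect_modules(nx.empty_graph(4))
    assert part.q == 0.0
    assert len(part.modules) == 4


def test_detect_modules_ordering_is_size_descending():
    g = nx.union(
        nx.complete_graph(3),
        nx.relabel_nodes(nx.complete_graph(5), {i: i + 10 for i in range(5)}),
    )
    part = detect_modules(g)
    assert len(part.members(0)) == 5
    assert len(part.members(1)) == 3


def test_zi_pi_brute_force_oracle():
    g = nx.gnp_random_graph(24, 0.2, seed=3)
    part = detect_modules(g)
    roles = zi_pi(g, part)
    for node in g.nodes:
        own = part.assignment[node]
        members = part.members(own)
        k_within = {
            m: sum(1 for nb in g.neighbors(m) if part.assignment[nb] == own)
            for m in members
        }
        ks = np.array(list(k_within.values()), dtype=float)
        zi = (k_within[node] - ks.mean()) / ks.std() if ks.std() > 0 else 0.0
        deg = g.degree(node)
        if deg == 0:
            pi = 0.0
        else:
            per_mod = {}
            for nb in g.neighbors(node):
                per_mod[part.assignment[nb]] = per_mod.get(part.assignment[nb], 0) + 1
            pi = 1 - sum((k / deg) ** 2 for k in per_mod.values())
        assert roles.roles[node].zi == pytest.approx(zi, abs=1e-12)
        assert roles.roles[node].pi == pytest.approx(pi, abs=1e-12)


def test_zi_per_module_mean_zero_sd_one():
    g = nx.gnp_random_graph(30, 0.25, seed=9)
    part = detect_modules(g)
    roles = zi_pi(g, part)
    for members in part.modules:
        z = np.array([roles.roles[n].zi for n in members])
        if z.std() > 0:  # modules with spread in within-degree
            assert z.mean() == pytest.approx(0.0, abs=1e-10)
            assert z.std() == pytest.approx(1.0, abs=1e-10)


def test_classify_role_boundaries_exact():
    assert classify_role(0.25, 0.62) == "peripheral"  # both boundaries excluded
    assert classify_role(0.2500000001, 0.62) == "module hub"
    assert classify_role(0.25, 0.6200000001) == "connector"
    assert classify_role(0.26, 0.63) == "network hub"


def test_zi_pi_requires_full_partition(two_cliques):
    with pytest.raises(ValueError, match="cover"):
        zi_pi(two_cliques, ModulePartition({0: 0}, 0.0))


def _random_table(rng, n_otus=6, n_samples=10):
    return CountTable.from_arrays(
        [f"o{i}" for i in range(n_otus)],
        [f"s{j}" for j in range(n_samples)],
        rng.integers(1, 200, size=(n_otus, n_samples)),
    )


def test_eigengene_identical_profiles_explain_everything():
    # a background OTU keeps the closure from flattening the identical rows
    counts = np.vstack([np.tile([5, 1, 9, 3, 7, 2, 8, 4], (4, 1)), [2, 9, 1, 8, 3, 7, 5, 6]])
    t = CountTable.from_arrays(
        [f"o{i}" for i in range(5)], [f"s{j}" for j in range(8)], counts
    )
    part = ModulePartition(
        {o: (1 if o != "o4" else 2) for o in t.otu_ids}, 0.0
    )
    eig = module_eigengene(t, part, 1)
    assert eig.explained_variance == pytest.approx(1.0, abs=1e-10)
    assert np.linalg.norm(eig.vector) == pytest.approx(1.0, abs=1e-10)


def test_eigengene_sign_convention_on_random_fixtures():
    rng = np.random.default_rng(8)
    for _ in range(100):
        t = _random_table(rng)
        part = ModulePartition(dict.fromkeys(t.otu_ids, 1), 0.0)
        eig = module_eigengene(t, part, 1)
        rel = t.relative_abundance()
        z = rel.sub(rel.mean(axis=1), axis=0).div(rel.std(axis=1, ddof=1), axis=0)
        assert np.dot(eig.vector, z.mean(axis=0)) >= -1e-12


def test_eigengene_matches_eigendecomposition_oracle():
    rng = np.random.default_rng(21)
    t = _random_table(rng, n_otus=8, n_samples=12)
    part = ModulePartition(dict.fromkeys(t.otu_ids, 1), 0.0)
    eig = module_eigengene(t, part, 1)
    rel = t.relative_abundance()
    z = (
        rel.sub(rel.mean(axis=1), axis=0)
        .div(rel.std(axis=1, ddof=1), axis=0)
        .to_numpy()
    )
    w, v = linalg.eigh(z.T @ z)  # independent route: sample-space Gram matrix
    lead = v[:, np.argmax(w)]
    if np.dot(lead, z.mean(axis=0)) < 0:
        lead = -lead
    assert np.allclose(eig.vector.to_numpy(), lead, atol=1e-10)
    assert eig.explained_variance == pytest.approx(
        w.max() / w.sum(), abs=1e-10
    )


def test_eigengene_rejects_tiny_modules():
    rng = np.random.default_rng(4)
    t = _random_table(rng)
    part = ModulePartition({o: (1 if o == "o0" else 2) for o in t.otu_ids}, 0.0)
    with pytest.raises(ValueError, match="fewer than 2"):
        module_eigengene(t, part, 1)


def test_eigengene_set_skips_small_modules():
    rng = np.random.default_rng(5)
    t = _random_table(rng)
    part = ModulePartition({o: (1 if o == "o0" else 2) for o in t.otu_ids}, 0.0)
    es = eigengene_set(t, part)
    assert set(es.eigengenes) == {2}


def test_significance_stars_thresholds():
    assert significance_stars(0.0005) == "***"
    assert significance_stars(0.005) == "**"
    assert significance_stars(0.049) == "*"
    assert significance_stars(0.05) == ""
    assert significance_stars(np.nan) == ""


def test_eigengene_trait_correlation_matches_pearsonr():
    rng = np.random.default_rng(6)
    t = _random_table(rng)
    part = ModulePartition(dict.fromkeys(t.otu_ids, 1), 0.0)
    es = eigengene_set(t, part)
    meta = SampleMetadata(
        pd.DataFrame(
            {"TN": rng.normal(size=10), "pH": rng.normal(size=10)},
            index=t.sample_ids,
        )
    )
    out = eigengene_trait_correlation(es, meta)
    for _, row in out.iterrows():
        r, p = stats.pearsonr(es.eigengenes[1].vector, meta.table[row["trait"]])
        assert row["r"] == pytest.approx(r, abs=1e-12)
        assert row["p"] == pytest.approx(p, abs=1e-12)
        assert row["stars"] == significance_stars(p)


def test_benjamini_hochberg_matches_scipy():
    p = np.array([0.001, 0.02, 0.03, 0.5, 0.04, 0.2])
    adj = _benjamini_hochberg(p)
    expected = stats.false_discovery_control(p, method="bh")
    assert np.allclose(adj, expected, atol=1e-12)


def test_guild_subnetwork_includes_first_neighbours():
    g = nx.path_graph(4)  # 0-1-2-3
    nx.set_node_attributes(g, "none", "guild")
    g.nodes[1]["guild"] = "methanogen"
    sub = guild_subnetwork(g, "methanogen")
    assert set(sub.nodes) == {0, 1, 2}
    assert guild_subnetwork(g, "methanotroph").number_of_nodes() == 0
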