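import itertools

import networkx as nx
import numpy as np
import pytest

from photognn.family_clustering import (
    build_ssn,
    cluster_families,
    mcl_cluster,
    read_family_table,
    reciprocal_best_hits,
    write_family_table,
)
from photognn.genome_io import Genome

from conftest import make_gene, make_hit


class TestSSN:
    def test_edge_requires_passing_evalue(self):
        g = build_ssn([make_hit("a", "b", evalue=1e-60)], 1e-50)
        assert g.has_edge("a", "b")
        g = build_ssn([make_hit("a", "b", evalue=1e-20)], 1e-50)
        assert not g.has_edge("a", "b")

    def test_symmetrization_takes_max_bitscore(self):
        hits = [
            make_hit("a", "b", evalue=1e-60, bitscore=150.0),
            make_hit("b", "a", evalue=1e-80, bitscore=220.0),
        ]
        g = build_ssn(hits, 1e-50)
        assert g.number_of_edges() == 1
        assert g["a"]["b"]["weight"] == 220.0

    def test_self_hits_excluded(self):
        g = build_ssn([make_hit("a", "a", evalue=1e-200)], 1e-50)
        assert g.number_of_edges() == 0

    def test_stricter_threshold_never_adds_edges(self):
        rng = np.random.default_rng(0)
        hits = [
            make_hit(f"p{rng.integers(8)}", f"p{rng.integers(8)}",
                     evalue=10.0 ** -rng.integers(1, 120))
            for _ in range(60)
        ]
        loose = build_ssn(hits, 1e-10)
        strict = build_ssn(hits, 1e-50)
        as_sets = lambda g: {frozenset(e) for e in g.edges()}
        assert as_sets(strict) <= as_sets(loose)


def brute_force_mcl_partition(graph, inflation=2.0, max_iter=200, tol=1e-6):
    """Independent dense-matrix MCL: plain numpy loop, attractor readout."""
    order = sorted(graph.nodes())
    n = len(order)
    idx = {v: i for i, v in enumerate(order)}
    m = np.zeros((n, n))
    for a, b, w in graph.edges(data="weight", default=1.0):
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = w
    loop = np.ones(n)
    for i in range(n):
        if m[i].max() > 0:
            loop[i] = m[i].max()
    m[np.diag_indices(n)] = loop
    m = m / m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        new = np.linalg.matrix_power(m, 2) ** inflation
        new[new < 1e-9] = 0
        new = new / new.sum(axis=0, keepdims=True)
        if np.abs(new - m).max() < tol:
            m = new
            break
        m = new
    clusters = []
    for i in np.flatnonzero(np.diag(m) > 1e-12):
        members = set(np.flatnonzero(m[i] > 1e-12)) | {i}
        for c in clusters:
            if c & members:
                c |= members
                break
        else:
            clusters.append(members)
    assigned = set().union(*clusters) if clusters else set()
    clusters += [{i} for i in range(n) if i not in assigned]
    return {frozenset(order[i] for i in c) for c in clusters}


def partition_as_sets(partition):
    return set(partition.families.values())


class TestMCL:
    def test_disconnected_triangles_stay_separate(self):
        g = nx.Graph()
        for offset in (0, 3):
            nodes = [f"n{offset + i}" for i in range(3)]
            g.add_weighted_edges_from(
                [(a, b, 1.0) for a, b in itertools.combinations(nodes, 2)]
            )
        part = mcl_cluster(g, 1e-10)
        assert partition_as_sets(part) == {
            frozenset({"n0", "n1", "n2"}),
            frozenset({"n3", "n4", "n5"}),
        }

    def test_single_isolated_node(self):
        g = nx.Graph()
        g.add_node("solo")
        part = mcl_cluster(g, 1e-10)
        assert partition_as_sets(part) == {frozenset({"solo"})}

    def test_barbell_splits_at_weak_bridge(self):
        g = nx.Graph()
        left = [f"l{i}" for i in range(4)]
        right = [f"r{i}" for i in range(4)]
        for clique in (left, right):
            g.add_weighted_edges_from(
                (a, b, 10.0) for a, b in itertools.combinations(clique, 2)
            )
        g.add_edge("l0", "r0", weight=0.5)
        part = mcl_cluster(g, 1e-10, inflation=2.0)
        assert partition_as_sets(part) == {frozenset(left), frozenset(right)}

    def test_matches_dense_oracle_on_random_small_graphs(self):
        rng = np.random.default_rng(42)
        for trial in range(12):
            n = int(rng.integers(3, 11))
            g = nx.Graph()
            g.add_nodes_from(f"v{i}" for i in range(n))
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.4:
                        g.add_edge(f"v{i}", f"v{j}", weight=float(rng.uniform(1, 10)))
            ours = partition_as_sets(mcl_cluster(g, 1e-10))
            oracle = brute_force_mcl_partition(g)
            assert ours == oracle, f"trial {trial}"

    def test_never_merges_connected_components(self):
        rng = np.random.default_rng(5)
        g = nx.gnp_random_graph(20, 0.15, seed=3)
        g = nx.relabel_nodes(g, {i: f"v{i}" for i in g.nodes()})
        for a, b in g.edges():
            g[a][b]["weight"] = float(rng.uniform(1, 5))
        part = mcl_cluster(g, 1e-10)
        components = list(nx.connected_components(g))
        for family in part.families.values():
            assert any(family <= comp for comp in components)

    def test_inflation_must_exceed_one(self):
        with pytest.raises(ValueError):
            mcl_cluster(nx.Graph(), 1e-10, inflation=1.0)


class TestFamilyCountMonotonicity:
    def test_family_count_nondecreasing_with_stringency(self, small_collection):
        counts = []
        proteins = set(small_collection.sequences)
        for thr in (1e-10, 1e-50, 1e-100):
            part = cluster_families(small_collection.hits, thr, proteins)
            counts.append(len(part.families))
        assert counts == sorted(counts)


def brute_force_rbh(hits, prots_a, prots_b):
    """Enumerate best hits directly from the score table."""
    def best(queries, subjects):
        out = {}
        for q in queries:
            cands = [h for h in hits if h.query_id == q and h.subject_id in subjects]
            if cands:
                out[q] = min(cands, key=lambda h: (-h.bitscore, h.evalue, h.subject_id)).subject_id
        return out

    fwd = best(prots_a, prots_b)
    rev = best(prots_b, prots_a)
    return {(p, q) for p, q in fwd.items() if rev.get(q) == p}


class TestRBH:
    def _genomes(self):
        ga = Genome("A", [make_gene(1, 100, "+", "a1", "A", protein_id="a1"),
                          make_gene(500, 600, "+", "a2", "A", protein_id="a2")])
        gb = Genome("B", [make_gene(1, 100, "+", "b1", "B", protein_id="b1"),
                          make_gene(500, 600, "+", "b2", "B", protein_id="b2")])
        return ga, gb

    def test_mutual_best_included(self):
        ga, gb = self._genomes()
        hits = [make_hit("a1", "b1", bitscore=300), make_hit("b1", "a1", bitscore=300)]
        assert reciprocal_best_hits(hits, ga, gb) == {("a1", "b1")}

    def test_non_mutual_excluded(self):
        ga, gb = self._genomes()
        hits = [
            make_hit("a1", "b1", bitscore=300),
            make_hit("b1", "a2", bitscore=400),
            make_hit("b1", "a1", bitscore=100),
        ]
        assert reciprocal_best_hits(hits, ga, gb) == set()

    def test_tie_break_matches_brute_force_over_orderings(self):
        ga, gb = self._genomes()
        base_hits = [
            make_hit("a1", "b1", bitscore=200, evalue=1e-50),
            make_hit("a1", "b2", bitscore=200, evalue=1e-50),  # tie: b1 wins
            make_hit("b1", "a1", bitscore=250),
            make_hit("b2", "a2", bitscore=100),
            make_hit("a2", "b2", bitscore=90),
        ]
        expected = brute_force_rbh(base_hits, {"a1", "a2"}, {"b1", "b2"})
        for perm in itertools.permutations(base_hits):
            assert reciprocal_best_hits(list(perm), ga, gb) == expected

    def test_rbh_size_bounded_by_smaller_proteome(self, small_collection):
        genomes = small_collection.genomes[:3]
        for i in range(len(genomes)):
            for j in range(i + 1, len(genomes)):
                rbh = reciprocal_best_hits(small_collection.hits, genomes[i], genomes[j])
                assert len(rbh) <= min(genomes[i].proteome_size, genomes[j].proteome_size)


def test_family_table_round_trip(tmp_path, small_collection):
    proteins = set(small_collection.sequences)
    part = cluster_families(small_collection.hits, 1e-10, proteins)
    path = tmp_path / "families.tsv"
    write_family_table([part], path)
    (reread,) = read_family_table(path)
    assert reread.family_of == part.family_of
    assert set(reread.families.values()) == set(part.families.values())
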