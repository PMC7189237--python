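"""Protein families from sequence-similarity networks, and reciprocal best hits.

The sequence-similarity network (SSN) has one node per protein and an edge
between two proteins whenever some hit between them passes the E-value
threshold; the edge weight is the best (maximum) bitscore among qualifying
hits.  Families are the clusters found by the Markov cluster algorithm (MCL)
on that weighted graph: a column-stochastic transition matrix with self-loops
is alternately squared (expansion) and raised entrywise to the inflation
power with column renormalisation (inflation) until it stops changing, and
clusters are read off the attractor structure.  Stricter thresholds remove
edges, so families can only split, never fuse, as stringency increases.

Reciprocal best hits (RBH) between two genomes — mutually highest-bitscore
partners — serve as the orthology proxy feeding the shared-gene-content
genome distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import sparse

from .genome_io import Genome, SimilarityHit


@dataclass
class ProteinFamilyPartition:
    """Partition of proteins into families at one E-value threshold."""

    evalue_threshold: float
    family_of: dict[str, str]
    families: dict[str, frozenset[str]]
    converged: bool = True

    def __post_init__(self) -> None:
        total = sum(len(m) for m in self.families.values())
        if total != len(self.family_of):
            raise ValueError("families do not partition the protein set")


def threshold_tag(evalue_threshold: float) -> str:
    """Compact tag for a threshold, e.g. 1e-50 -> '1e-50'."""
    return f"{evalue_threshold:.0e}".replace("e-0", "e-").replace("e+0", "e+")


def build_ssn(
    hits: list[SimilarityHit],
    evalue_threshold: float,
    nodes: set[str] | None = None,
) -> nx.Graph:
    """Build the SSN at one threshold.

    Self-hits are dropped; (a,b) and (b,a) collapse to one undirected edge
    with weight = max bitscore over qualifying hits.  ``nodes`` optionally
    adds isolated proteins so singletons survive clustering.
    """
    if evalue_threshold <= 0:
        raise ValueError("evalue_threshold must be > 0")
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    for h in hits:
        if h.query_id == h.subject_id or h.evalue > evalue_threshold:
            continue
        a, b = h.query_id, h.subject_id
        if g.has_edge(a, b):
            if h.bitscore > g[a][b]["weight"]:
                g[a][b]["weight"] = h.bitscore
        else:
            g.add_edge(a, b, weight=h.bitscore)
    return g


def _mcl_matrix(
    m: sparse.csr_matrix,
    inflation: float,
    max_iter: int,
    tol: float,
    prune: float,
) -> tuple[sparse.csr_matrix, bool]:
    """Run the expansion/inflation loop on a column-stochastic matrix."""

    def normalize(mat: sparse.csr_matrix) -> sparse.csr_matrix:
        col_sums = np.asarray(mat.sum(axis=0)).ravel()
        col_sums[col_sums == 0] = 1.0
        d = sparse.diags(1.0 / col_sums)
        return (mat @ d).tocsr()

    m = normalize(m)
    for _ in range(max_iter):
        expanded = (m @ m).tocsr()
        inflated = expanded.copy()
        inflated.data = np.power(inflated.data, inflation)
        inflated.data[inflated.data < prune] = 0.0
        inflated.eliminate_zeros()
        inflated = normalize(inflated)
        diff = abs(inflated - m)
        change = diff.max() if diff.nnz else 0.0
        m = inflated
        if change < tol:
            return m, True
    return m, False


def _clusters_from_attractors(m: sparse.csr_matrix) -> list[set[int]]:
    """Read clusters: attractor rows (nonzero diagonal) span the clusters;
    overlapping attractor supports are merged."""
    n = m.shape[0]
    diag = m.diagonal()
    attractors = np.flatnonzero(diag > 1e-12)
    clusters: list[set[int]] = []
    for a in attractors:
        row = m.getrow(a)
        members = set(row.indices[row.data > 1e-12]) | {int(a)}
        merged = False
        for c in clusters:
            if c & members:
                c |= members
                merged = True
                break
        if merged:
            # merging may chain: re-consolidate
            changed = True
            while changed:
                changed = False
                for i in range(len(clusters)):
                    for j in range(i + 1, len(clusters)):
                        if clusters[i] & clusters[j]:
                            clusters[i] |= clusters.pop(j)
                            changed = True
                            break
                    if changed:
                        break
        else:
            clusters.append(members)
    assigned = set().union(*clusters) if clusters else set()
    for i in range(n):
        if i not in assigned:
            clusters.append({i})
    return clusters


def mcl_cluster(
    graph: nx.Graph,
    evalue_threshold: float,
    inflation: float = 2.0,
    max_iter: int = 100,
    tol: float = 1e-6,
    prune: float = 1e-9,
) -> ProteinFamilyPartition:
    """Markov clustering of the SSN into a protein family partition.

    Self-loop weight per node = max incident edge weight (1.0 for isolated
    nodes), the usual regularisation keeping odd-length walks alive.
    Family ids are ``F{threshold tag}_{index}`` with indices assigned in
    order of each family's smallest protein id over a sorted node ordering,
    so the partition is reproducible.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    order = sorted(graph.nodes())
    tag = threshold_tag(evalue_threshold)
    if not order:
        return ProteinFamilyPartition(evalue_threshold, {}, {})
    index = {n: i for i, n in enumerate(order)}
    rows, cols, data = [], [], []
    loop = np.ones(len(order))
    for a, b, w in graph.edges(data="weight", default=1.0):
        ia, ib = index[a], index[b]
        rows += [ia, ib]
        cols += [ib, ia]
        data += [w, w]
        loop[ia] = max(loop[ia], w)
        loop[ib] = max(loop[ib], w)
    rows += list(range(len(order)))
    cols += list(range(len(order)))
    data += list(loop)
    m = sparse.csr_matrix((data, (rows, cols)), shape=(len(order), len(order)))
    m, converged = _mcl_matrix(m, inflation, max_iter, tol, prune)
    clusters = _clusters_from_attractors(m)
    named = sorted(
        ({order[i] for i in c} for c in clusters), key=lambda c: min(c)
    )
    family_of: dict[str, str] = {}
    families: dict[str, frozenset[str]] = {}
    for i, members in enumerate(named):
        fid = f"F{tag}_{i}"
        families[fid] = frozenset(members)
        for p in members:
            family_of[p] = fid
    return ProteinFamilyPartition(
        evalue_threshold, family_of, families, converged=converged
    )


def cluster_families(
    hits: list[SimilarityHit],
    evalue_threshold: float,
    all_proteins: set[str],
    inflation: float = 2.0,
) -> ProteinFamilyPartition:
    """Convenience: SSN construction + MCL over the full protein universe."""
    ssn = build_ssn(hits, evalue_threshold, nodes=all_proteins)
    return mcl_cluster(ssn, evalue_threshold, inflation=inflation)


def reciprocal_best_hits(
    hits: list[SimilarityHit], genome_a: Genome, genome_b: Genome
) -> set[tuple[str, str]]:
    """Mutually best (highest-bitscore) hit pairs between two genomes.

    Ties on bitscore break by lower E-value, then lexicographic subject id.
    """
    if genome_a.genome_id == genome_b.genome_id:
        raise ValueError("RBH requires two distinct genomes")
    prots_a = {g.protein_id for g in genome_a.genes}
    prots_b = {g.protein_id for g in genome_b.genes}

    def best_hits(queries: set[str], subjects: set[str]) -> dict[str, str]:
        best: dict[str, tuple[float, float, str]] = {}
        for h in hits:
            if h.query_id in queries and h.subject_id in subjects:
                key = (-h.bitscore, h.evalue, h.subject_id)
                if h.query_id not in best or key < best[h.query_id]:
                    best[h.query_id] = key
        return {q: k[2] for q, k in best.items()}

    a_best = best_hits(prots_a, prots_b)
    b_best = best_hits(prots_b, prots_a)
    return {
        (p, q) for p, q in a_best.items() if b_best.get(q) == p
    }


def write_family_table(partitions: list[ProteinFamilyPartition], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tevalue_threshold\tfamily_id\n")
        for part in partitions:
            for pid in sorted(part.family_of):
                fh.write(f"{pid}\t{part.evalue_threshold:g}\t{part.family_of[pid]}\n")


def read_family_table(path) -> list[ProteinFamilyPartition]:
    """Import an externally produced clustering in the TSV dialect above."""
    by_threshold: dict[float, dict[str, str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("protein_id"):
            raise ValueError("missing family table header")
        for line in fh:
            pid, thr, fid = line.rstrip("\n").split("\t")
            by_threshold.setdefault(float(thr), {})[pid] = fid
    out = []
    for thr, family_of in sorted(by_threshold.items()):
        families: dict[str, set[str]] = {}
        for pid, fid in family_of.items():
            families.setdefault(fid, set()).add(pid)
        out.append(
            ProteinFamilyPartition(
                thr, family_of, {f: frozenset(m) for f, m in families.items()}
            )
        )
    return out
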