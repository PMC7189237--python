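"""GO-coherence analysis of conserved neighborhoods.

For each query protein the GO annotation of its conserved neighbors (those
whose adjacency Phylo score passes a cutoff) is compared with the query's own
annotation by a semantic F1: both term sets are expanded to their is_a
ancestor closures, and precision/recall are the overlap fractions of the
neighbor and query closures respectively.  Sweeping the cutoff yields a
coherence curve; a random baseline replaces each neighbor term set by an
equal-size uniform sample from the pool of all annotated terms, averaged
over repeated draws.  Coverage at a cutoff is the number of queries that
still have at least one surviving neighbor.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .dataset_labels import GOAnnotation, ancestor_closure


@dataclass
class GOCoherenceCurve:
    cutoffs: list[float]
    f1_neighbors: list[float | None]
    f1_random: list[float | None]
    coverage: list[int]

    def __post_init__(self) -> None:
        n = len(self.cutoffs)
        if not (len(self.f1_neighbors) == len(self.f1_random) == len(self.coverage) == n):
            raise ValueError("curve fields must have equal length")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("cutoff\tf1_neighbors\tf1_random\tcoverage\n")
            for c, fn, fr, cov in zip(
                self.cutoffs, self.f1_neighbors, self.f1_random, self.coverage
            ):
                fn_s = "NA" if fn is None else f"{fn:.6f}"
                fr_s = "NA" if fr is None else f"{fr:.6f}"
                fh.write(f"{c:g}\t{fn_s}\t{fr_s}\t{cov}\n")


def go_f1(
    query_terms: set[str] | frozenset[str],
    neighbor_terms: set[str] | frozenset[str],
    dag: nx.MultiDiGraph,
) -> float:
    """Semantic F1 between two GO term sets after ancestor closure.

    precision = |closure(Q) ∩ closure(N)| / |closure(N)|,
    recall    = |closure(Q) ∩ closure(N)| / |closure(Q)|.
    """
    cq = ancestor_closure(query_terms, dag)
    cn = ancestor_closure(neighbor_terms, dag)
    if not cq or not cn:
        raise ValueError("term sets must be nonempty after closure")
    overlap = len(cq & cn)
    precision = overlap / len(cn)
    recall = overlap / len(cq)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def coherence_curve(
    queries: list[str],
    neighbor_scores: dict[str, dict[str, float]],
    annotations: GOAnnotation,
    cutoffs: list[float],
    n_random: int = 100,
    seed: int = 0,
) -> GOCoherenceCurve:
    """Mean query-vs-neighborhood GO F1 as a function of Phylo-score cutoff.

    ``neighbor_scores`` maps query -> {neighbor protein/family -> Phylo
    score}; neighbor keys must be annotated in ``annotations`` (unannotated
    neighbors are ignored).  At each cutoff, per query, the union of the
    surviving neighbors' term sets is compared with the query's terms; the
    random baseline draws an equal-size term sample from the pool of all
    annotated terms, ``n_random`` times.
    """
    rng = np.random.default_rng(seed)
    pool = sorted({t for ts in annotations.terms_of.values() for t in ts})
    f1_n: list[float | None] = []
    f1_r: list[float | None] = []
    coverage: list[int] = []
    for cutoff in cutoffs:
        per_query_f1: list[float] = []
        per_query_rand: list[float] = []
        covered = 0
        for q in queries:
            q_terms = annotations.terms_of.get(q)
            if not q_terms:
                continue
            survivors = [
                n
                for n, score in neighbor_scores.get(q, {}).items()
                if score >= cutoff and annotations.terms_of.get(n)
            ]
            if not survivors:
                continue
            covered += 1
            n_terms = set().union(*(annotations.terms_of[n] for n in survivors))
            per_query_f1.append(go_f1(q_terms, n_terms, annotations.dag))
            draws = []
            for _ in range(n_random):
                sample = rng.choice(pool, size=min(len(n_terms), len(pool)), replace=False)
                draws.append(go_f1(q_terms, set(sample.tolist()), annotations.dag))
            per_query_rand.append(float(np.mean(draws)))
        coverage.append(covered)
        f1_n.append(float(np.mean(per_query_f1)) if per_query_f1 else None)
        f1_r.append(float(np.mean(per_query_rand)) if per_query_rand else None)
    return GOCoherenceCurve(list(cutoffs), f1_n, f1_r, coverage)
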