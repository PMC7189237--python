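"""T/F labelling of collection proteins.

Positives are transferred from a curated photosynthetic reference set by
stringent similarity (identity AND query coverage strictly above 80%).
Negative candidates are admitted only if (a) the is_a ancestor closure of
their GO annotations contains no photosynthesis term and (b) they carry at
least one annotation at GO depth >= 3 — the depth of photosynthesis
(GO:0015979) itself — where depth is the shortest is_a path to the namespace
root.  The negative class is then down-sampled to the size of the positive
class.

The GO DAG comes from an OBO file (via ``obonet``); only ``is_a`` edges are
traversed.
"""

from __future__ import annotations

import random
from collections import deque
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import networkx as nx
import obonet

from .genome_io import SimilarityHit


def load_photo_go_terms(path: str | Path | None = None) -> frozenset[str]:
    """The photosynthesis GO id list (one id per line, '#' comments)."""
    if path is None:
        text = (
            resources.files("photognn.data")
            .joinpath("photo_go_terms.txt")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    terms = {
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    }
    return frozenset(terms)


@dataclass
class GOAnnotation:
    """Protein -> GO term sets plus the ontology graph they live in."""

    terms_of: dict[str, frozenset[str]]
    dag: nx.MultiDiGraph  # obonet convention: edges child -> parent

    def __post_init__(self) -> None:
        for pid, terms in self.terms_of.items():
            missing = [t for t in terms if t not in self.dag]
            if missing:
                raise ValueError(
                    f"protein {pid}: annotated terms not in the ontology: {missing}"
                )


def read_obo(path: str | Path) -> nx.MultiDiGraph:
    return obonet.read_obo(str(path))


def read_annotations(path: str | Path, dag: nx.MultiDiGraph) -> GOAnnotation:
    """GAF-like two-column TSV: protein_id <tab> GO id."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            pid, go = line.split("\t")[:2]
            terms.setdefault(pid, set()).add(go)
    return GOAnnotation({p: frozenset(t) for p, t in terms.items()}, dag)


def _is_a_parents(dag: nx.MultiDiGraph, term: str) -> list[str]:
    return [
        parent
        for _, parent, key in dag.out_edges(term, keys=True)
        if key == "is_a"
    ]


def ancestor_closure(terms: set[str] | frozenset[str], dag: nx.MultiDiGraph) -> frozenset[str]:
    """The terms plus every is_a ancestor up to the namespace root."""
    closure: set[str] = set()
    stack = list(terms)
    for t in terms:
        if t not in dag:
            raise KeyError(f"unknown GO term {t}")
    while stack:
        term = stack.pop()
        if term in closure:
            continue
        closure.add(term)
        stack.extend(_is_a_parents(dag, term))
    return frozenset(closure)


def go_depth(term: str, dag: nx.MultiDiGraph) -> int:
    """Shortest is_a path length from the term to its namespace root
    (a term with no is_a parents); root depth is 0."""
    if term not in dag:
        raise KeyError(f"unknown GO term {term}")
    depth = {term: 0}
    queue = deque([term])
    while queue:
        t = queue.popleft()  # BFS pops in nondecreasing depth
        parents = _is_a_parents(dag, t)
        if not parents:
            return depth[t]
        for p in parents:
            if p not in depth:
                depth[p] = depth[t] + 1
                queue.append(p)
    raise ValueError(f"no is_a root reachable from {term} (cycle?)")


def transfer_positive_labels(
    reference_positive_ids: set[str],
    hits: list[SimilarityHit],
    min_identity: float = 80.0,
    min_coverage: float = 80.0,
) -> frozenset[str]:
    """Collection proteins receiving the photosynthetic label.

    A hit transfers the label when its query is a reference positive and
    both percent identity and query coverage are STRICTLY above the cutoffs.
    """
    labeled: set[str] = set()
    for h in hits:
        if h.query_id not in reference_positive_ids:
            continue
        if h.percent_identity > min_identity and h.query_coverage > min_coverage:
            labeled.add(h.subject_id)
    return frozenset(labeled)


def select_negatives(
    candidates: set[str],
    annotations: GOAnnotation,
    photo_terms: frozenset[str],
    min_level: int = 3,
) -> frozenset[str]:
    """Negative candidates with no photosynthetic ancestry and adequate depth."""
    if not photo_terms:
        raise ValueError("photo_terms must be nonempty")
    kept: set[str] = set()
    for pid in candidates:
        terms = annotations.terms_of.get(pid)
        if not terms:
            continue
        closure = ancestor_closure(terms, annotations.dag)
        if closure & photo_terms:
            continue
        if any(go_depth(t, annotations.dag) >= min_level for t in terms):
            kept.add(pid)
    return frozenset(kept)


def balance_sample(
    negative_pool: set[str], n_target: int, seed: int
) -> frozenset[str]:
    """Uniform sample without replacement, reproducible by seed."""
    if n_target > len(negative_pool):
        raise ValueError(
            f"pool of {len(negative_pool)} too small for target {n_target}"
        )
    rng = random.Random(seed)
    return frozenset(rng.sample(sorted(negative_pool), n_target))


def filter_representatives(
    instance_ids: list[str], representatives_path: str | Path
) -> list[str]:
    """Keep only ids present in an externally produced representative list
    (redundancy reduction is delegated to an external clustering tool)."""
    reps = {
        line.strip()
        for line in Path(representatives_path).read_text().splitlines()
        if line.strip()
    }
    return [i for i in instance_ids if i in reps]
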