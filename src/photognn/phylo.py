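"""Genome distances, neighbor-joining trees and the Phylo conservation score.

A conserved gene-neighborhood adjacency is worth more when it is preserved
across distantly related genomes than across near-clones.  The Phylo score
captures this: for a (query family, neighbor family) adjacency observed in a
set of genomes, it is the total branch length of the neighbor-joining tree
built over exactly those genomes, using shared-gene-content distances

    s = |RBH(a, b)| / mean(proteome_a, proteome_b),        d = -ln(s)

(reciprocal best hits as the orthology proxy).  The score is only defined
when the adjacency is observed in at least three genomes; below that it is
ABSENT (downstream it is encoded as 0, "no conservation evidence").
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import numpy as np
from Bio import Phylo
from Bio.Phylo.TreeConstruction import DistanceMatrix as _BioDM
from Bio.Phylo.TreeConstruction import DistanceTreeConstructor

from .genome_io import Genome

#: sentinel for "adjacency observed in fewer than three genomes"
ABSENT = None


@dataclass
class GenomeDistanceMatrix:
    """Symmetric genome-genome distance matrix (units: -ln shared content)."""

    genome_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.genome_ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match genome_ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite (cap s=0 pairs)")
        self._index = {g: i for i, g in enumerate(self.genome_ids)}

    def get(self, a: str, b: str) -> float:
        return float(self.d[self._index[a], self._index[b]])

    def submatrix(self, genome_ids: Iterable[str]) -> "GenomeDistanceMatrix":
        ids = sorted(genome_ids)
        missing = [g for g in ids if g not in self._index]
        if missing:
            raise KeyError(f"genomes missing from distance matrix: {missing}")
        idx = [self._index[g] for g in ids]
        return GenomeDistanceMatrix(ids, self.d[np.ix_(idx, idx)])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("genome_id\t" + "\t".join(self.genome_ids) + "\n")
            for i, g in enumerate(self.genome_ids):
                fh.write(g + "\t" + "\t".join(f"{x:.6g}" for x in self.d[i]) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "GenomeDistanceMatrix":
        with open(path) as fh:
            ids = fh.readline().rstrip("\n").split("\t")[1:]
            rows = [
                [float(x) for x in line.rstrip("\n").split("\t")[1:]] for line in fh
            ]
        return cls(ids, np.array(rows))


def shared_gene_content(
    rbh: set[tuple[str, str]], genome_a: Genome, genome_b: Genome
) -> float:
    """Proportion of shared gene content: RBH count over mean proteome size."""
    if genome_a.proteome_size == 0 or genome_b.proteome_size == 0:
        raise ValueError("proteome sizes must be positive")
    mean_size = 0.5 * (genome_a.proteome_size + genome_b.proteome_size)
    s = len(rbh) / mean_size
    if s > 1:
        raise ValueError(
            f"shared content {s:.3f} > 1: RBH set inconsistent with proteomes"
        )
    return s


def default_dmax(genome_a: Genome, genome_b: Genome) -> float:
    """Distance assigned to a pair sharing nothing: what one shared gene
    would give, -ln(1 / mean proteome size)."""
    return math.log(0.5 * (genome_a.proteome_size + genome_b.proteome_size))


def genome_distance(s: float, d_max: float) -> float:
    """d = -ln(s), capped at d_max; s = 0 maps to d_max."""
    if not 0 <= s <= 1:
        raise ValueError(f"shared content {s} outside [0, 1]")
    if s == 0:
        return d_max
    return min(-math.log(s), d_max)


def distance_matrix(
    genomes: list[Genome],
    rbh_counts: dict[frozenset[str], int],
    d_max: float | None = None,
) -> GenomeDistanceMatrix:
    """Full pairwise matrix from RBH counts keyed by genome-id pairs."""
    ids = sorted(g.genome_id for g in genomes)
    by_id = {g.genome_id: g for g in genomes}
    n = len(ids)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        a, b = by_id[ids[i]], by_id[ids[j]]
        count = rbh_counts.get(frozenset((ids[i], ids[j])), 0)
        s = count / (0.5 * (a.proteome_size + b.proteome_size))
        if s > 1:
            raise ValueError(f"shared content {s:.3f} > 1 for pair {ids[i]},{ids[j]}")
        cap = d_max if d_max is not None else default_dmax(a, b)
        d[i, j] = d[j, i] = genome_distance(s, cap)
    return GenomeDistanceMatrix(ids, d)


@dataclass
class PhyloTree:
    """Unrooted NJ tree over a genome subset with clamped branch lengths."""

    leaf_ids: list[str]
    tree: "Phylo.BaseTree.Tree"

    @property
    def total_branch_length(self) -> float:
        total = 0.0
        for clade in self.tree.find_clades():
            if clade.branch_length:
                total += max(0.0, clade.branch_length)
        return total

    def to_newick(self) -> str:
        buf = io.StringIO()
        Phylo.write(self.tree, buf, "newick")
        return buf.getvalue().strip()


def nj_tree(dm: GenomeDistanceMatrix) -> PhyloTree:
    """Neighbor-joining (Saitou-Nei) tree; needs at least three genomes.

    Leaves are fed in sorted id order so ties in the NJ selection criterion
    resolve deterministically; negative branch lengths are clamped to zero
    when the total length is read.
    """
    ids = sorted(dm.genome_ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least 3 genomes")
    sub = dm.submatrix(ids)
    lower = [[float(sub.d[i, j]) for j in range(i + 1)] for i in range(len(ids))]
    bio_dm = _BioDM(names=ids, matrix=lower)
    tree = DistanceTreeConstructor().nj(bio_dm)
    return PhyloTree(leaf_ids=ids, tree=tree)


@dataclass(frozen=True)
class AdjacencyEvidence:
    """Genomes in which members of two families co-occur in a neighborhood."""

    query_family: str
    neighbor_family: str
    threshold: float
    genomes_observed: frozenset[str]

    def __post_init__(self) -> None:
        if self.query_family == self.neighbor_family:
            raise ValueError("query and neighbor family must differ")


def phylo_score(
    evidence: AdjacencyEvidence, dm: GenomeDistanceMatrix
) -> float | None:
    """Total NJ branch length over the observed genomes, or ABSENT (< 3)."""
    genomes = sorted(evidence.genomes_observed)
    if len(genomes) < 3:
        return ABSENT
    sub = dm.submatrix(genomes)
    return nj_tree(sub).total_branch_length
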