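"""Genome-neighborhood (gene cluster) calling.

Prokaryotic genes that sit close together on the same strand tend to be
co-transcribed; a run of such genes is used here as the operational unit of a
"genome neighborhood".  Two rules define the clusters:

1. consecutive same-strand genes whose intergenic distance is at most
   ``max_gap`` (default 250 bp), or which overlap, are chained into one
   cluster;
2. two adjacent clusters whose strands diverge head-to-head (a ``-`` cluster
   followed by a ``+`` cluster along the coordinate axis, so that their first
   genes face away from each other around a shared upstream region) are merged
   when the gap between those first genes lies within [``min_gap``,
   ``max_gap``] (defaults 200-1000 bp), mirroring divergently transcribed
   operon pairs.

Clusters never span contigs, and merging is a single left-to-right pass (no
cascade).
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import Gene, Genome, intergenic_distance


@dataclass(frozen=True)
class NeighborhoodCluster:
    cluster_id: str
    genome_id: str
    contig_id: str
    member_gene_ids: tuple[str, ...]
    strands: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.member_gene_ids)


def _sorted_contig_genes(genome: Genome) -> dict[str, list[Gene]]:
    contigs = genome.contigs()
    for genes in contigs.values():
        genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
    return contigs


def call_same_strand_clusters(
    genome: Genome, max_gap: int = 250
) -> list[NeighborhoodCluster]:
    """Chain consecutive same-strand genes with gaps <= ``max_gap`` bp.

    Overlapping genes (negative or zero intergenic distance) always chain.
    Every gene ends up in exactly one cluster; singletons are kept.
    """
    clusters: list[NeighborhoodCluster] = []
    contigs = _sorted_contig_genes(genome)
    for contig_id in sorted(contigs):
        genes = contigs[contig_id]
        run: list[Gene] = []
        for gene in genes:
            if run and (
                gene.strand != run[-1].strand
                or intergenic_distance(run[-1], gene) > max_gap
            ):
                clusters.append(_make_cluster(genome.genome_id, contig_id, run, len(clusters)))
                run = []
            run.append(gene)
        if run:
            clusters.append(_make_cluster(genome.genome_id, contig_id, run, len(clusters)))
    return clusters


def _make_cluster(
    genome_id: str, contig_id: str, genes: list[Gene], index: int
) -> NeighborhoodCluster:
    return NeighborhoodCluster(
        cluster_id=f"{genome_id}|{contig_id}|c{index}",
        genome_id=genome_id,
        contig_id=contig_id,
        member_gene_ids=tuple(g.gene_id for g in genes),
        strands=tuple(g.strand for g in genes),
    )


def merge_divergent_clusters(
    clusters: list[NeighborhoodCluster],
    genome: Genome,
    min_gap: int = 200,
    max_gap: int = 1000,
) -> list[NeighborhoodCluster]:
    """Merge head-to-head divergent adjacent cluster pairs.

    Along the coordinate axis this is a ``-`` cluster followed by a ``+``
    cluster; the "first" gene of each cluster transcription-wise is the
    rightmost gene of the ``-`` cluster and the leftmost gene of the ``+``
    cluster, and the gap is measured between their inner boundaries.  One
    pass, left to right; a merged (mixed-strand) cluster is not merged again.
    """
    by_gene = {g.gene_id: g for g in genome.genes}
    out: list[NeighborhoodCluster] = []
    i = 0
    order = sorted(
        clusters, key=lambda c: (c.contig_id, by_gene[c.member_gene_ids[0]].start)
    )
    while i < len(order):
        cur = order[i]
        if i + 1 < len(order):
            nxt = order[i + 1]
            if (
                cur.contig_id == nxt.contig_id
                and set(cur.strands) == {"-"}
                and set(nxt.strands) == {"+"}
            ):
                left_first = by_gene[cur.member_gene_ids[-1]]  # rightmost of the - run
                right_first = by_gene[nxt.member_gene_ids[0]]  # leftmost of the + run
                gap = intergenic_distance(left_first, right_first)
                if min_gap <= gap <= max_gap:
                    merged = NeighborhoodCluster(
                        cluster_id=cur.cluster_id + "+",
                        genome_id=cur.genome_id,
                        contig_id=cur.contig_id,
                        member_gene_ids=cur.member_gene_ids + nxt.member_gene_ids,
                        strands=cur.strands + nxt.strands,
                    )
                    out.append(merged)
                    i += 2
                    continue
        out.append(cur)
        i += 1
    return out


def call_neighborhoods(
    genome: Genome,
    max_gap: int = 250,
    divergent_min_gap: int = 200,
    divergent_max_gap: int = 1000,
) -> list[NeighborhoodCluster]:
    """Full neighborhood calling: same-strand chaining then divergent merge."""
    clusters = call_same_strand_clusters(genome, max_gap=max_gap)
    return merge_divergent_clusters(
        clusters, genome, min_gap=divergent_min_gap, max_gap=divergent_max_gap
    )


def neighbor_pairs(
    clusters: list[NeighborhoodCluster],
    protein_of: dict[str, str] | None = None,
) -> set[frozenset[str]]:
    """All unordered within-cluster gene pairs (the neighborhood relation).

    With ``protein_of`` the pairs are expressed in protein ids instead of
    gene ids.
    """
    pairs: set[frozenset[str]] = set()
    for cluster in clusters:
        ids = cluster.member_gene_ids
        if protein_of is not None:
            ids = tuple(protein_of[g] for g in ids)
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                if ids[a] != ids[b]:
                    pairs.add(frozenset((ids[a], ids[b])))
    return pairs


def write_clusters_tsv(clusters: list[NeighborhoodCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tcontig_id\tcluster_id\tmembers\n")
        for c in clusters:
            fh.write(
                f"{c.genome_id}\t{c.contig_id}\t{c.cluster_id}\t"
                + ",".join(c.member_gene_ids)
                + "\n"
            )
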