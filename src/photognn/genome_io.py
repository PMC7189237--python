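"""Readers for genome annotations, proteomes and all-vs-all similarity tables.

The internal genome model is deliberately small: a :class:`Gene` is a strand-
aware interval on a contig carrying a cross-reference to its protein product,
and a :class:`Genome` is the coordinate-sorted list of protein-coding genes of
one organism.  Coordinates are 1-based inclusive, exactly as GFF3 defines
them, so the intergenic distance between adjacent genes is
``next.start - prev.end - 1`` (the number of bases strictly between them).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

GFF_COLUMNS = 9

#: feature types treated as protein-coding genes
CODING_TYPES = frozenset({"gene", "CDS"})


@dataclass(frozen=True, order=True)
class Gene:
    """A protein-coding gene locus (1-based inclusive coordinates)."""

    contig_id: str
    start: int
    end: int
    strand: str
    gene_id: str
    genome_id: str
    protein_id: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: start {self.start} < 1")
        if self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start + 1


def intergenic_distance(prev: Gene, nxt: Gene) -> int:
    """Bases strictly between two genes on one contig; <= 0 means overlap."""
    return nxt.start - prev.end - 1


@dataclass
class Genome:
    genome_id: str
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes.sort(key=lambda g: (g.contig_id, g.start, g.end, g.gene_id))

    @property
    def proteome_size(self) -> int:
        return len(self.genes)

    def contigs(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes:
            out.setdefault(g.contig_id, []).append(g)
        return out


@dataclass(frozen=True)
class SimilarityHit:
    """One row of a 12-column tabular alignment report."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float
    query_coverage: float = float("nan")

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("E-value must be >= 0")


class GFFError(ValueError):
    pass


def _parse_attributes(text: str) -> dict[str, str]:
    out = {}
    for chunk in text.strip().rstrip(";").split(";"):
        if not chunk:
            continue
        key, _, value = chunk.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gff3(path: str | Path, genome_id: str | None = None) -> list[Gene]:
    """Parse protein-coding gene features from one GFF3 file.

    Features of type ``gene`` or ``CDS`` are accepted; when both describe the
    same locus the ``gene`` record wins.  The protein cross-reference is taken
    from the ``protein_id`` attribute if present, else ``ID``.
    """
    path = Path(path)
    gid = genome_id or path.stem
    genes: dict[str, Gene] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != GFF_COLUMNS:
                raise GFFError(
                    f"{path}:{lineno}: expected {GFF_COLUMNS} tab-separated "
                    f"columns, got {len(fields)}"
                )
            contig, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype not in CODING_TYPES:
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise GFFError(f"{path}:{lineno}: non-integer coordinate") from exc
            attr = _parse_attributes(attrs)
            feature_id = attr.get("ID")
            if feature_id is None:
                raise GFFError(f"{path}:{lineno}: feature has no ID attribute")
            protein_id = attr.get("protein_id", feature_id)
            key = (ftype, feature_id)
            gene = Gene(
                contig_id=contig,
                start=start_i,
                end=end_i,
                strand=strand,
                gene_id=feature_id,
                genome_id=gid,
                protein_id=protein_id,
            )
            # gene features shadow CDS features with the same protein_id
            if protein_id in genes and ftype == "CDS":
                continue
            genes[protein_id] = gene
    return sorted(genes.values(), key=lambda g: (g.contig_id, g.start, g.end, g.gene_id))


def write_gff3(genes: Iterable[Gene], path: str | Path) -> None:
    """Write genes back to GFF3 (inverse of :func:`read_gff3`)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.contig_id, g.start, g.end, g.gene_id)):
            attrs = f"ID={g.gene_id};protein_id={g.protein_id}"
            fh.write(
                f"{g.contig_id}\tphotognn\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def read_fasta_lengths(paths: Sequence[str | Path]) -> dict[str, int]:
    """Protein id -> sequence length over one or more FASTA files."""
    lengths: dict[str, int] = {}
    for path in paths:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in lengths:
                raise ValueError(f"duplicate FASTA record id {rec.id!r}")
            lengths[rec.id] = len(rec.seq)
    return lengths


def read_genome_collection(
    gff_paths: Sequence[str | Path],
    fasta_paths: Sequence[str | Path],
    genome_ids: Sequence[str] | None = None,
) -> list[Genome]:
    """Load a genome collection, validating GFF3/FASTA cross-references.

    Raises if any gene lacks a protein sequence or if a protein_id occurs in
    more than one genome (protein ids are the global keys of the method).
    """
    if genome_ids is not None and len(genome_ids) != len(gff_paths):
        raise ValueError("genome_ids must match gff_paths in length")
    lengths = read_fasta_lengths(fasta_paths)
    genomes: list[Genome] = []
    seen: dict[str, str] = {}
    for i, gff in enumerate(gff_paths):
        gid = genome_ids[i] if genome_ids is not None else Path(gff).stem
        genes = read_gff3(gff, genome_id=gid)
        for g in genes:
            if g.protein_id not in lengths:
                raise ValueError(
                    f"gene {g.gene_id} (genome {gid}): protein "
                    f"{g.protein_id!r} has no FASTA sequence"
                )
            if g.protein_id in seen and seen[g.protein_id] != gid:
                raise ValueError(
                    f"protein_id {g.protein_id!r} occurs in genomes "
                    f"{seen[g.protein_id]!r} and {gid!r}"
                )
            seen[g.protein_id] = gid
        genomes.append(Genome(genome_id=gid, genes=genes))
    return genomes


def read_similarity_table(
    path: str | Path,
    known_proteins: Mapping[str, int] | set[str] | None = None,
) -> list[SimilarityHit]:
    """Parse a 12-column tabular similarity report (qseqid sseqid pident
    length mismatch gapopen qstart qend sstart send evalue bitscore).

    When ``known_proteins`` maps protein ids to sequence lengths, rows whose
    ids are unknown are dropped (a count is logged) and query coverage is
    derived as ``alignment_length / query_length * 100``.
    """
    hits: list[SimilarityHit] = []
    dropped = 0
    lengths = known_proteins if isinstance(known_proteins, Mapping) else None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 columns, got {len(fields)}"
                )
            q, s = fields[0], fields[1]
            try:
                pident = float(fields[2])
                length = int(fields[3])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field") from exc
            if known_proteins is not None and (
                q not in known_proteins or s not in known_proteins
            ):
                dropped += 1
                continue
            coverage = float("nan")
            if lengths is not None and lengths[q] > 0:
                coverage = 100.0 * length / lengths[q]
            hits.append(
                SimilarityHit(
                    query_id=q,
                    subject_id=s,
                    percent_identity=pident,
                    alignment_length=length,
                    evalue=evalue,
                    bitscore=bitscore,
                    query_coverage=coverage,
                )
            )
    if dropped:
        logger.warning("dropped %d similarity rows with unknown protein ids", dropped)
    return hits


def write_similarity_table(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    """Write hits in the 12-column dialect (placeholder alignment coords)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.1f}",
                        str(h.alignment_length),
                        "0",
                        "0",
                        "1",
                        str(h.alignment_length),
                        "1",
                        str(h.alignment_length),
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )
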