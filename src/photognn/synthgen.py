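"""Self-consistent synthetic genome collections with planted neighborhoods.

The generator emulates the data regime the method targets: several
prokaryotic genomes sharing protein families, where "positive"
(photosynthesis-like) families sit inside gene clusters whose composition is
conserved across genomes, while background families get independently
shuffled contexts.  Everything downstream needs — GFF3 annotations, a
protein FASTA, an all-vs-all similarity table, GO annotations with a small
ontology, and T/F labels — is derived from one ground truth so the whole
pipeline is testable without any external data.

Key knobs (defaults are the standard study conditions used throughout the
test-suite):

* ``n_genomes`` 10, ``n_families`` 200, ``n_positive_families`` 20;
* ``conservation_prob`` 0.9 — per genome, the chance that a positive family
  appears with its full planted neighbor cluster (same strand, gaps
  <= 250 bp) rather than scattered;
* ``cluster_size`` 4 — positive families are grouped four at a time into
  planted clusters, so photosynthesis-like genes are each other's conserved
  neighbors (as real photosystem operons are); a fraction of background
  families form weakly conserved housekeeping operons so the negative class
  has realistic, non-degenerate neighborhood structure;
* within-family hits get E-values far below every family threshold,
  between-family noise hits get E-values above them, so the similarity
  network at the configured thresholds recovers the planted families;
* genomes carry increasing numbers of private singleton families so the
  shared-gene-content distance matrix is non-degenerate.

Sequences are random amino-acid strings; the similarity table is generated
from the ground truth rather than from alignment, which keeps the whole
stack aligner-free while remaining format-faithful.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .genome_io import (
    Gene,
    Genome,
    SimilarityHit,
    write_gff3,
    write_similarity_table,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

PHOTO_ROOT_TERM = "GO:0015979"  # photosynthesis, depth 3 in the mini ontology


@dataclass
class SynthConfig:
    n_genomes: int = 10
    n_families: int = 200
    n_positive_families: int = 20
    cluster_size: int = 4  # positive families per planted cluster
    conservation_prob: float = 0.9
    background_operon_frac: float = 0.4
    background_conservation: tuple[float, float] = (0.3, 0.8)
    intergenic_gap: tuple[int, int] = (20, 180)  # within clusters
    spacer_gap: tuple[int, int] = (400, 3000)  # between blocks
    divergent_pair_prob: float = 0.05
    evalue_within_family: tuple[float, float] = (1e-180, 1e-120)
    evalue_between_families: tuple[float, float] = (1e-8, 1e-2)
    noise_hit_rate: float = 0.5  # between-family noise hits per protein
    private_fraction_max: float = 0.4
    go_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.conservation_prob <= 1:
            raise ValueError("conservation_prob must be in [0, 1]")
        if not 0 <= self.go_noise <= 1:
            raise ValueError("go_noise must be in [0, 1]")
        if not 0 <= self.background_operon_frac <= 1:
            raise ValueError("background_operon_frac must be in [0, 1]")
        if self.n_positive_families > self.n_families:
            raise ValueError("n_positive_families exceeds n_families")
        if self.cluster_size > self.n_families:
            raise ValueError("cluster larger than the family universe")


@dataclass
class GroundTruth:
    family_of: dict[str, str]  # protein -> planted family
    planted_adjacencies: set[frozenset]  # family pairs inside planted clusters
    positive_families: list[str]
    neighbor_families: dict[str, list[str]]  # positive family -> its neighbors
    labels: dict[str, str]  # protein -> T/F for query proteins


@dataclass
class SyntheticCollection:
    genomes: list[Genome]
    sequences: dict[str, str]
    hits: list[SimilarityHit]
    annotations: dict[str, frozenset[str]]
    dag: nx.MultiDiGraph
    labels: dict[str, str]
    ground_truth: GroundTruth
    config: SynthConfig | None = None

    @property
    def query_ids(self) -> list[str]:
        return sorted(self.labels)


def make_synthetic_ontology(n_background_terms: int = 40) -> nx.MultiDiGraph:
    """A miniature GO-like is_a DAG (biological_process namespace).

    The photosynthesis term GO:0015979 sits at depth 3 (its real depth) with
    one child at depth 4; ``n_background_terms`` non-photosynthetic terms sit
    at depths 3-4, plus one shallow depth-2 term for depth-filter tests.
    """
    dag = nx.MultiDiGraph()
    root = "GO:0008150"

    def add(term: str, name: str, parents: list[str]) -> None:
        dag.add_node(term, name=name, namespace="biological_process")
        for p in parents:
            dag.add_edge(term, p, key="is_a")

    dag.add_node(root, name="biological_process", namespace="biological_process")
    add("GO:0009987", "cellular process", [root])
    add("GO:0008152", "metabolic process", [root])
    add("GO:0044237", "cellular metabolic process", ["GO:0009987", "GO:0008152"])
    add("GO:0006091", "energy derivation", ["GO:0044237"])
    add(PHOTO_ROOT_TERM, "photosynthesis", ["GO:0044237"])
    add("GO:0019684", "photosynthesis, light reaction", [PHOTO_ROOT_TERM])
    add("GO:9000001", "shallow process", [root])  # depth 1, fails the filter
    for i in range(n_background_terms):
        parent = "GO:0006091" if i % 2 == 0 else "GO:0044237"
        term = f"GO:91000{i:02d}"
        add(term, f"background process {i}", [parent])
        if i % 5 == 0:
            add(f"GO:92000{i:02d}", f"specific background process {i}", [term])
    return dag


def write_obo(dag: nx.MultiDiGraph, path: str | Path) -> None:
    """Serialise the mini ontology in OBO format (obonet-compatible)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go\n\n")
        for term in sorted(dag.nodes):
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {dag.nodes[term].get('name', term)}\n")
            ns = dag.nodes[term].get("namespace", "biological_process")
            fh.write(f"namespace: {ns}\n")
            for _, parent, key in dag.out_edges(term, keys=True):
                if key == "is_a":
                    fh.write(f"is_a: {parent}\n")
            fh.write("\n")


def _random_sequence(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(length))


def _log_uniform(rng: random.Random, lo: float, hi: float) -> float:
    return 10 ** rng.uniform(math.log10(lo), math.log10(hi))


def generate_collection(config: SynthConfig | None = None) -> SyntheticCollection:
    """Generate a full synthetic collection from one seed.

    Layout per genome: each positive family is, with probability
    ``conservation_prob``, laid out as a planted same-strand cluster with its
    dedicated neighbor families (gaps <= 250 bp); otherwise the positive
    gene and its neighbors are scattered as singleton blocks.  Background
    families appear as independently shuffled singleton blocks separated by
    spacer gaps.  Each genome additionally carries private singleton
    families (an increasing count across genomes) so pairwise shared gene
    content, and hence the genome distance matrix, varies.
    """
    cfg = config or SynthConfig()
    rng = random.Random(cfg.seed)

    families = [f"FAM{i:04d}" for i in range(cfg.n_families)]
    positive = families[: cfg.n_positive_families]
    background = families[cfg.n_positive_families :]

    # planted clusters: positive families grouped cluster_size at a time,
    # so cluster-mates are each other's conserved neighbors
    positive_blocks = [
        positive[i : i + cfg.cluster_size]
        for i in range(0, len(positive), cfg.cluster_size)
    ]
    neighbors_of = {
        p: [q for q in block if q != p]
        for block in positive_blocks
        for p in block
    }
    # a fraction of background families live in weakly conserved operon-like
    # blocks of 2-3 (housekeeping clusters); the rest are free singletons
    n_operonic = int(round(cfg.background_operon_frac * len(background)))
    operonic, free_background = background[:n_operonic], background[n_operonic:]
    background_blocks: list[list[str]] = []
    i = 0
    while i < len(operonic):
        size = rng.choice((2, 3))
        background_blocks.append(operonic[i : i + size])
        i += size
    block_conservation = {
        idx: rng.uniform(*cfg.background_conservation)
        for idx in range(len(background_blocks))
    }

    fam_length = {f: rng.randint(80, 300) for f in families}
    fam_seed_seq = {f: _random_sequence(rng, fam_length[f]) for f in families}

    genomes: list[Genome] = []
    sequences: dict[str, str] = {}
    family_of: dict[str, str] = {}
    members: dict[str, list[str]] = {f: [] for f in families}
    planted_adjacencies: set[frozenset] = set()
    for block in positive_blocks:
        for i in range(len(block)):
            for j in range(i + 1, len(block)):
                planted_adjacencies.add(frozenset((block[i], block[j])))

    for gi in range(cfg.n_genomes):
        gid = f"G{gi:03d}"
        blocks: list[list[str]] = []
        for pblock in positive_blocks:
            if rng.random() < cfg.conservation_prob:
                blocks.append(list(pblock))
            else:
                blocks.extend([[p] for p in pblock])
        for idx, bblock in enumerate(background_blocks):
            if rng.random() < block_conservation[idx]:
                blocks.append(list(bblock))
            else:
                blocks.extend([[f] for f in bblock])
        blocks.extend([[f] for f in free_background])
        if cfg.n_genomes > 1:
            n_private = int(
                round(
                    cfg.private_fraction_max
                    * cfg.n_families
                    * gi
                    / (cfg.n_genomes - 1)
                )
            )
        else:
            n_private = 0
        private = [f"PRIV{gi:03d}_{k:03d}" for k in range(n_private)]
        for f in private:
            fam_length[f] = rng.randint(80, 300)
            fam_seed_seq[f] = _random_sequence(rng, fam_length[f])
            members.setdefault(f, [])
        blocks.extend([[f] for f in private])
        rng.shuffle(blocks)

        genes: list[Gene] = []
        pos = 1
        pending_divergent = False
        for block in blocks:
            if pending_divergent:
                strand = "+"
                pending_divergent = False
            else:
                strand = rng.choice("+-")
            for k, fam in enumerate(block):
                length = 3 * fam_length[fam]  # nucleotide span of the CDS
                pid = f"{gid}_{fam}"
                genes.append(
                    Gene(
                        contig_id=f"{gid}_chr",
                        start=pos,
                        end=pos + length - 1,
                        strand=strand,
                        gene_id=f"{pid}_gene",
                        genome_id=gid,
                        protein_id=pid,
                    )
                )
                sequences[pid] = fam_seed_seq[fam]
                family_of[pid] = fam
                members[fam].append(pid)
                pos += length
                if k < len(block) - 1:
                    pos += rng.randint(*cfg.intergenic_gap)
            if (
                len(block) == 1
                and strand == "-"
                and rng.random() < cfg.divergent_pair_prob
            ):
                pos += rng.randint(300, 900)  # divergent-promoter spacing
                pending_divergent = True
            else:
                pos += rng.randint(*cfg.spacer_gap)
                pending_divergent = False
        genomes.append(Genome(genome_id=gid, genes=genes))

    # similarity table: within-family all ordered cross pairs + self hits
    hits: list[SimilarityHit] = []
    for fam, mem in members.items():
        for p in mem:
            hits.append(
                SimilarityHit(
                    query_id=p,
                    subject_id=p,
                    percent_identity=100.0,
                    alignment_length=fam_length[fam],
                    evalue=1e-200,
                    bitscore=2.0 * fam_length[fam] + 50,
                    query_coverage=100.0,
                )
            )
        for a in mem:
            for b in mem:
                if a == b:
                    continue
                hits.append(
                    SimilarityHit(
                        query_id=a,
                        subject_id=b,
                        percent_identity=rng.uniform(85, 99),
                        alignment_length=fam_length[fam],
                        evalue=_log_uniform(rng, *cfg.evalue_within_family),
                        bitscore=2.0 * fam_length[fam] - rng.uniform(0, 10),
                        query_coverage=100.0,
                    )
                )
    # between-family noise
    all_proteins = sorted(sequences)
    n_noise = int(cfg.noise_hit_rate * len(all_proteins))
    for _ in range(n_noise):
        a, b = rng.sample(all_proteins, 2)
        if family_of[a] == family_of[b]:
            continue
        hits.append(
            SimilarityHit(
                query_id=a,
                subject_id=b,
                percent_identity=rng.uniform(20, 35),
                alignment_length=rng.randint(30, 60),
                evalue=_log_uniform(rng, *cfg.evalue_between_families),
                bitscore=rng.uniform(25, 40),
                query_coverage=rng.uniform(20, 60),
            )
        )

    # GO annotations over the mini ontology
    dag = make_synthetic_ontology()
    photo_terms = [PHOTO_ROOT_TERM, "GO:0019684"]
    deep_background = sorted(
        t for t in dag.nodes if t.startswith("GO:91") or t.startswith("GO:92")
    )
    annotations: dict[str, frozenset[str]] = {}
    fam_term: dict[str, str] = {}
    for fam in families + sorted(
        f for f in members if f.startswith("PRIV")
    ):
        if fam in positive:
            fam_term[fam] = photo_terms[rng.randrange(2)]
        else:
            fam_term[fam] = deep_background[
                rng.randrange(len(deep_background))
            ]
    for pid, fam in family_of.items():
        term = fam_term[fam]
        if rng.random() < cfg.go_noise:
            term = deep_background[rng.randrange(len(deep_background))]
        annotations[pid] = frozenset({term})

    # labels: positive-family members are T, background members F
    labels: dict[str, str] = {}
    for fam in positive:
        for pid in members[fam]:
            labels[pid] = "T"
    for fam in background:
        for pid in members[fam]:
            labels[pid] = "F"

    truth = GroundTruth(
        family_of=family_of,
        planted_adjacencies=planted_adjacencies,
        positive_families=list(positive),
        neighbor_families=neighbors_of,
        labels=dict(labels),
    )
    return SyntheticCollection(
        genomes=genomes,
        sequences=sequences,
        hits=hits,
        annotations=annotations,
        dag=dag,
        labels=labels,
        ground_truth=truth,
        config=cfg,
    )


def write_collection(collection: SyntheticCollection, out_dir: str | Path) -> dict:
    """Write the collection in the formats the ingest step consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gff_paths = []
    for genome in collection.genomes:
        path = out / f"{genome.genome_id}.gff3"
        write_gff3(genome.genes, path)
        gff_paths.append(path)
    fasta = out / "proteins.fasta"
    with open(fasta, "w") as fh:
        for pid in sorted(collection.sequences):
            fh.write(f">{pid}\n{collection.sequences[pid]}\n")
    hits_path = out / "hits.tsv"
    write_similarity_table(collection.hits, hits_path)
    anno_path = out / "go_annotations.tsv"
    with open(anno_path, "w") as fh:
        for pid in sorted(collection.annotations):
            for term in sorted(collection.annotations[pid]):
                fh.write(f"{pid}\t{term}\n")
    obo_path = out / "ontology.obo"
    write_obo(collection.dag, obo_path)
    labels_path = out / "labels.tsv"
    with open(labels_path, "w") as fh:
        for pid in sorted(collection.labels):
            fh.write(f"{pid}\t{collection.labels[pid]}\n")
    return {
        "gff": [str(p) for p in gff_paths],
        "fasta": str(fasta),
        "hits": str(hits_path),
        "annotations": str(anno_path),
        "obo": str(obo_path),
        "labels": str(labels_path),
    }


def regenerate_fig1_toy() -> SyntheticCollection:
    """A hard-coded four-genome toy exhibiting threshold-dependent splitting.

    One query family (Q) holds the four query proteins at the loose
    threshold (1e-10) and sheds its most divergent member (genome G1's) at
    the strictest (1e-100).  Neighbor families: c1 is conserved in all four
    genomes at 1e-10 but splits at 1e-50 into a two-genome part (score
    ABSENT) and a three-genome part (scored, "c4"); c2 and c3 hold together
    at every threshold.  Genomes carry different numbers of private genes so
    all pairwise distances are positive and distinct.
    """
    rng = random.Random(1234)
    genome_ids = ["G1", "G2", "G3", "G4"]
    sequences: dict[str, str] = {}
    genomes: list[Genome] = []
    hits: list[SimilarityHit] = []

    # per-genome neighborhood gene content: query Q, then c1 members
    # (genome G2 carries two c1-like paralogs A2a/A2b), then c2 (B), c3 (D)
    c1_members = {
        "G1": ["A1"],
        "G2": ["A2a", "A2b"],
        "G3": ["A3"],
        "G4": ["A4"],
    }
    protein_lengths: dict[str, int] = {}

    def add_protein(pid: str, length: int = 150) -> None:
        sequences[pid] = _random_sequence(rng, length)
        protein_lengths[pid] = length

    for gi, gid in enumerate(genome_ids):
        genes = []
        pos = 1
        block = [f"Q{gi + 1}"] + c1_members[gid] + [f"B{gi + 1}", f"D{gi + 1}"]
        for pid in block:
            add_protein(pid)
            genes.append(
                Gene(
                    contig_id=f"{gid}_chr",
                    start=pos,
                    end=pos + 449,
                    strand="+",
                    gene_id=f"{pid}_gene",
                    genome_id=gid,
                    protein_id=pid,
                )
            )
            pos += 450 + 50
        # private singletons make the genome distances positive and distinct
        for k in range(gi + 1):
            pid = f"{gid}_priv{k}"
            add_protein(pid, 120)
            genes.append(
                Gene(
                    contig_id=f"{gid}_chr",
                    start=pos + 2000,
                    end=pos + 2000 + 359,
                    strand="+",
                    gene_id=f"{pid}_gene",
                    genome_id=gid,
                    protein_id=pid,
                )
            )
            pos += 3000
        genomes.append(Genome(genome_id=gid, genes=genes))

    def pair_hits(a: str, b: str, evalue: float, bitscore: float) -> None:
        for q, s in ((a, b), (b, a)):
            hits.append(
                SimilarityHit(
                    query_id=q,
                    subject_id=s,
                    percent_identity=90.0,
                    alignment_length=protein_lengths[q],
                    evalue=evalue,
                    bitscore=bitscore,
                    query_coverage=100.0,
                )
            )

    # query family: G2-G4 tight, G1 looser (drops out at 1e-100)
    for a, b in (("Q2", "Q3"), ("Q2", "Q4"), ("Q3", "Q4")):
        pair_hits(a, b, 1e-150, 300.0)
    for other in ("Q2", "Q3", "Q4"):
        pair_hits("Q1", other, 1e-60, 180.0)
    # c1: {A1, A2a} tight, {A2b, A3, A4} tight, cross pairs loose
    pair_hits("A1", "A2a", 1e-120, 280.0)
    for a, b in (("A2b", "A3"), ("A2b", "A4"), ("A3", "A4")):
        pair_hits(a, b, 1e-120, 280.0)
    for a in ("A1", "A2a"):
        for b in ("A2b", "A3", "A4"):
            pair_hits(a, b, 1e-30, 120.0)
    # c2 and c3: tight at every threshold
    for fam in (["B1", "B2", "B3", "B4"], ["D1", "D2", "D3", "D4"]):
        for i in range(len(fam)):
            for j in range(i + 1, len(fam)):
                pair_hits(fam[i], fam[j], 1e-150, 300.0)

    family_of = {}
    for pid in sequences:
        if pid.startswith("Q"):
            family_of[pid] = "Q"
        elif pid.startswith("A"):
            family_of[pid] = "c1"
        elif pid.startswith("B"):
            family_of[pid] = "c2"
        elif pid.startswith("D"):
            family_of[pid] = "c3"
        else:
            family_of[pid] = f"priv_{pid}"

    dag = make_synthetic_ontology()
    annotations = {pid: frozenset({PHOTO_ROOT_TERM}) for pid in sequences}
    labels = {f"Q{i}": "T" for i in range(1, 5)}
    truth = GroundTruth(
        family_of=family_of,
        planted_adjacencies={
            frozenset(("Q", "c1")),
            frozenset(("Q", "c2")),
            frozenset(("Q", "c3")),
        },
        positive_families=["Q"],
        neighbor_families={"Q": ["c1", "c2", "c3"]},
        labels=labels,
    )
    return SyntheticCollection(
        genomes=genomes,
        sequences=sequences,
        hits=hits,
        annotations=annotations,
        dag=dag,
        labels=labels,
        ground_truth=truth,
        config=None,
    )
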