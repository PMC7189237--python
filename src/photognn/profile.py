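"""Genome-neighborhood profiles: the query x (threshold, family) feature table.

Each query protein gets one row; each column is a neighbor family at one
E-value threshold, and the value is the Phylo score of the (query family,
neighbor family) adjacency at that threshold, 0 when the adjacency is absent
or conserved in fewer than three genomes.  Columns from different thresholds
are namespaced ``{threshold tag}|{family_id}`` so the per-threshold tables
simply concatenate.  Scores are then discretised to four conservation levels
using the first/third quartiles of the nonzero scores of positive instances:

    level 0 : score = 0          (no conservation evidence)
    level 1 : 0 < score <= Q1    (low)
    level 2 : Q1 < score <= Q3   (intermediate)
    level 3 : score > Q3         (strong)

The quartile cutpoints fitted on the full photosynthetic reference collection
are shipped as ``REFERENCE_Q1``/``REFERENCE_Q3`` for use when no training
data is available to refit them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .family_clustering import ProteinFamilyPartition, threshold_tag
from .neighborhood import NeighborhoodCluster
from .phylo import ABSENT, AdjacencyEvidence, GenomeDistanceMatrix, phylo_score

#: quartile cutpoints fitted on the reference photosynthetic collection
REFERENCE_Q1 = 0.41079
REFERENCE_Q3 = 2.61799

LABELS = ("T", "F", "UNLABELED")


@dataclass
class NeighborhoodProfile:
    """Continuous profile: rows = queries, columns = (threshold, family)."""

    data: pd.DataFrame  # float, >= 0; index = query protein ids
    labels: pd.Series  # values in LABELS, aligned with data.index

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.data.index)
        if (self.data.values < 0).any():
            raise ValueError("profile values must be >= 0")
        bad = set(self.labels.unique()) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels: {bad}")

    @property
    def feature_columns(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class DiscretizedProfile:
    """Profile with values in {0,1,2,3}; the fitted cutpoints ride along."""

    data: pd.DataFrame  # int levels
    labels: pd.Series
    q1: float
    q3: float
    conflicted: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.data.index)
        vals = set(np.unique(self.data.values)) if self.data.size else set()
        if not vals <= {0, 1, 2, 3}:
            raise ValueError(f"levels outside 0..3: {vals}")
        if self.q1 > self.q3:
            raise ValueError("q1 must be <= q3")


def collect_adjacency_evidence(
    clusters_by_genome: dict[str, list[NeighborhoodCluster]],
    protein_of_gene: dict[str, str],
    partition: ProteinFamilyPartition,
) -> dict[frozenset, set[str]]:
    """Family-pair -> genomes where members co-occur in one neighborhood.

    A genome counts once per family pair however many clusters exhibit it.
    """
    observed: dict[frozenset, set[str]] = {}
    for genome_id, clusters in clusters_by_genome.items():
        for cluster in clusters:
            fams = {
                partition.family_of[protein_of_gene[g]]
                for g in cluster.member_gene_ids
                if protein_of_gene[g] in partition.family_of
            }
            fams = sorted(fams)
            for i in range(len(fams)):
                for j in range(i + 1, len(fams)):
                    observed.setdefault(
                        frozenset((fams[i], fams[j])), set()
                    ).add(genome_id)
    return observed


def score_adjacencies(
    evidence: dict[frozenset, set[str]],
    dm: GenomeDistanceMatrix,
    threshold: float,
    min_genomes: int = 3,
) -> dict[frozenset, float]:
    """Phylo-score every family pair with evidence in >= min_genomes genomes."""
    scores: dict[frozenset, float] = {}
    for pair, genomes in evidence.items():
        if len(genomes) < min_genomes:
            continue
        fams = sorted(pair)
        ev = AdjacencyEvidence(
            query_family=fams[0],
            neighbor_family=fams[1],
            threshold=threshold,
            genomes_observed=frozenset(genomes),
        )
        score = phylo_score(ev, dm)
        if score is not ABSENT:
            scores[pair] = score
    return scores


def build_profile(
    queries: list[str],
    partitions: dict[float, ProteinFamilyPartition],
    scores: dict[float, dict[frozenset, float]],
    labels: dict[str, str] | None = None,
) -> NeighborhoodProfile:
    """Assemble the feature table across thresholds.

    The column universe is every neighbor family scored against at least one
    query's family (all-zero columns are dropped); rows for queries whose
    family has no scored neighbor anywhere are all-zero.
    """
    columns: dict[str, dict[str, float]] = {}
    for threshold, partition in partitions.items():
        tag = threshold_tag(threshold)
        thr_scores = scores.get(threshold, {})
        for q in queries:
            if q not in partition.family_of:
                raise KeyError(
                    f"query {q!r} missing from the {tag} family partition"
                )
        for q in queries:
            fam = partition.family_of[q]
            for pair, score in thr_scores.items():
                if fam in pair:
                    (neighbor,) = pair - {fam}
                    col = f"{tag}|{neighbor}"
                    columns.setdefault(col, {})[q] = score
    data = pd.DataFrame(0.0, index=list(queries), columns=sorted(columns))
    for col, values in columns.items():
        for q, v in values.items():
            data.loc[q, col] = v
    label_series = pd.Series("UNLABELED", index=data.index)
    if labels:
        for q, lab in labels.items():
            if q in label_series.index:
                label_series.loc[q] = lab
    return NeighborhoodProfile(data=data, labels=label_series)


def combine_profiles(profiles: list[NeighborhoodProfile]) -> NeighborhoodProfile:
    """Column-wise concatenation of per-threshold profiles (same queries)."""
    if not profiles:
        raise ValueError("no profiles to combine")
    index = profiles[0].data.index
    for p in profiles[1:]:
        if not p.data.index.equals(index):
            raise ValueError("profiles must share the same query set and order")
    data = pd.concat([p.data for p in profiles], axis=1)
    if data.columns.duplicated().any():
        raise ValueError("duplicate feature columns across profiles")
    return NeighborhoodProfile(data=data, labels=profiles[0].labels.copy())


def fit_quartile_cutpoints(
    profile: NeighborhoodProfile, scope: str = "T"
) -> tuple[float, float]:
    """First and third quartiles (linear interpolation) of the nonzero
    scores of ``scope``-labeled instances (positives by default)."""
    rows = profile.data.loc[profile.labels == scope] if scope else profile.data
    values = rows.values.ravel()
    nonzero = values[values > 0]
    if nonzero.size < 4:
        raise ValueError(
            f"need >= 4 nonzero scores in scope to fit quartiles, got {nonzero.size}"
        )
    q1, q3 = np.percentile(nonzero, [25, 75])
    return float(q1), float(q3)


def discretize(
    profile: NeighborhoodProfile, q1: float, q3: float
) -> DiscretizedProfile:
    """Map scores to levels 0-3; boundaries fall in the lower bin."""
    if q1 > q3:
        raise ValueError("q1 must be <= q3")
    v = profile.data.values
    if (v < 0).any():
        raise ValueError("negative Phylo score")
    levels = np.zeros(v.shape, dtype=int)
    levels[(v > 0) & (v <= q1)] = 1
    levels[(v > q1) & (v <= q3)] = 2
    levels[v > q3] = 3
    data = pd.DataFrame(levels, index=profile.data.index, columns=profile.data.columns)
    return DiscretizedProfile(
        data=data, labels=profile.labels.copy(), q1=q1, q3=q3
    )


def discretize_value(v: float, q1: float, q3: float) -> int:
    if v < 0:
        raise ValueError("negative Phylo score")
    if v == 0:
        return 0
    if v <= q1:
        return 1
    if v <= q3:
        return 2
    return 3


def deduplicate(profile: DiscretizedProfile) -> DiscretizedProfile:
    """Collapse instances identical in (feature vector, label).

    The first instance of each group (by index order) is kept.  Instances
    identical in features but conflicting in label are all kept and their
    ids recorded in ``conflicted``.
    """
    key_cols = list(profile.data.columns)
    df = profile.data.copy()
    df["__label__"] = profile.labels
    keep = ~df.duplicated(keep="first")
    feature_dup = profile.data.duplicated(keep=False)
    conflicted: list[str] = []
    if feature_dup.any():
        groups = profile.data[feature_dup].groupby(key_cols, sort=False)
        for _, idx in groups.groups.items():
            labs = set(profile.labels.loc[idx])
            if len(labs) > 1:
                conflicted.extend(list(idx))
                keep.loc[idx] = True  # conflicting rows are all kept
    data = profile.data.loc[keep]
    return DiscretizedProfile(
        data=data,
        labels=profile.labels.loc[keep],
        q1=profile.q1,
        q3=profile.q3,
        conflicted=sorted(conflicted),
    )


def write_arff(
    profile: DiscretizedProfile, path, relation: str = "genome_neighborhood_profile"
) -> None:
    """Write the Weka ARFF dialect: nominal {0,1,2,3} attributes + class {T,F}."""
    if profile.data.empty:
        raise ValueError("refusing to write an empty profile")
    with open(path, "w") as fh:
        fh.write(f"@relation {relation}\n\n")
        for col in profile.data.columns:
            fh.write(f"@attribute '{col}' {{0,1,2,3}}\n")
        fh.write("@attribute class {T,F}\n\n@data\n")
        for qid, row in profile.data.iterrows():
            label = profile.labels.loc[qid]
            label = label if label in ("T", "F") else "?"
            fh.write(",".join(str(int(x)) for x in row) + f",{label}\n")


def read_arff(path) -> DiscretizedProfile:
    """Read back the ARFF dialect written by :func:`write_arff`."""
    columns: list[str] = []
    rows: list[list[int]] = []
    labels: list[str] = []
    in_data = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("%"):
                continue
            low = line.lower()
            if low.startswith("@relation"):
                continue
            if low.startswith("@attribute"):
                name = line.split(None, 2)[1].strip("'\"")
                if name != "class":
                    columns.append(name)
                continue
            if low.startswith("@data"):
                in_data = True
                continue
            if in_data:
                parts = line.split(",")
                rows.append([int(x) for x in parts[:-1]])
                labels.append(parts[-1] if parts[-1] in ("T", "F") else "UNLABELED")
    data = pd.DataFrame(rows, columns=columns)
    data.index = [f"instance_{i}" for i in range(len(rows))]
    return DiscretizedProfile(
        data=data,
        labels=pd.Series(labels, index=data.index),
        q1=REFERENCE_Q1,
        q3=REFERENCE_Q3,
    )


def write_csv(profile: DiscretizedProfile, path) -> None:
    out = profile.data.copy()
    out["class"] = profile.labels
    out.to_csv(path, index_label="query_id")
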