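# Methods

This note documents the models, parameters, numerical choices and
limitations of `photognn`, in the order the pipeline runs.

## Gene model and neighborhood calling

Coordinates are 1-based inclusive as GFF3 defines them, so the intergenic
distance between adjacent genes is `next.start − prev.end − 1` (bases
strictly between them) and `next.start ≤ prev.end` means overlap. Two rules
build the neighborhood clusters:

* **Same-strand chaining** — consecutive same-strand genes with intergenic
  distance ≤ `max_gap` (default 250 bp) or overlapping are chained
  transitively; a strand change or a larger gap breaks the chain. The
  boundary is inclusive: a 250 bp gap chains, 251 bp does not.
* **Divergent merging** — a `−` cluster followed by a `+` cluster along the
  coordinate axis has its two first genes (transcription-wise) facing away
  from each other across a shared upstream region. When the gap between
  their inner boundaries lies in [`min_gap`, `max_gap`] (defaults
  200–1000 bp, both inclusive) the clusters merge, mirroring divergently
  transcribed operon pairs. Merging is one left-to-right pass with no
  cascade: a merged (mixed-strand) cluster is not merged again. Convergent
  (`+` then `−`) pairs never merge.

Neighborhoods never span contigs, and only protein-coding features are
considered. The neighborhood relation used downstream is within-cluster
co-membership (all pairs), not just immediate adjacency. Ties between genes
with equal start are broken by end coordinate then gene id, making cluster
ids deterministic. The three distance constants are configurable but are
treated as fixed protocol constants, not fitted quantities.

## Families: similarity network + Markov clustering

The sequence-similarity network at threshold *t* has an edge (a, b), a ≠ b,
whenever some hit in either direction has E-value ≤ *t*; the edge weight is
the maximum bitscore over qualifying hits. Weighting by bitscore (rather
than −log E or binary) is the default and configurable.

MCL runs on the column-stochastic matrix with per-node self-loops equal to
the node's maximum incident edge weight (1.0 for isolated nodes),
alternating expansion (matrix squaring) and inflation (entrywise power 2.0,
column renormalisation) until the entrywise change falls below 1e-6 or 100
iterations elapse (non-convergence returns the current clustering with a
warning flag; never observed on test inputs). Entries below 1e-9 are
pruned each iteration — a numerical-hygiene tolerance, not a model
parameter. Clusters are read from attractor rows (nonzero diagonal), with
overlapping attractor supports merged; unassigned nodes become singletons.
Family ids are assigned over a sorted node ordering so the partition is
reproducible. MCL never merges disconnected components, so stricter
thresholds can only split families.

Reciprocal best hits (RBH) between two genomes take the highest-bitscore
partner in each direction, ties broken by lower E-value then lexicographic
subject id, giving a deterministic orthology proxy.

## Genome distances, NJ trees, Phylo score

Shared gene content *s* = |RBH| / mean(proteome sizes); distance
*d* = −ln *s*. For *s* = 0 the distance is capped at
`d_max = −ln(1 / mean proteome size)` — the distance one shared gene would
give — keeping the matrix finite without letting empty pairs dominate a
tree; the cap is configurable.

Neighbor-joining (Saitou–Nei) trees are built with Biopython's
`Bio.Phylo.TreeConstruction` over the genomes in which a (query family,
neighbor family) adjacency is observed; leaves are fed in sorted id order
so selection ties resolve deterministically, and negative branch lengths
are clamped to zero before summation (a conservation score must be
non-negative). The Phylo score is the total branch length of that tree,
computed only when the adjacency is observed in ≥ 3 genomes (a genome
counts once regardless of copy number); otherwise the score is ABSENT and
encoded as 0 in the profile — deliberately indistinguishable from "no
evidence". Total branch length is rooting-invariant, so the unrooted NJ
tree is summed directly. The full distance matrix is computed once; each
adjacency restricts it to its observed genome subset. The independent NJ
cross-check in the test-suite uses scikit-bio.

## Profile, discretization, deduplication

Columns are namespaced `{threshold}|{family}`, so per-threshold tables
concatenate without collisions and the combined table's per-threshold
submatrices equal the single-threshold tables. The column universe is
every neighbor family scored for at least one query; all-zero columns are
excluded to keep the table finite and reproducible.

Discretization maps a score *v* to level 0 (*v* = 0), 1 (0 < *v* ≤ Q1), 2
(Q1 < *v* ≤ Q3) or 3 (*v* > Q3): the only reading consistent with two
cutpoints plus a dedicated zero level. Q1/Q3 are the linear-interpolation
(type-7) quartiles of the nonzero scores of positive-labeled instances;
boundaries fall in the lower bin. The reference cutpoints 0.41079 /
2.61799, fitted on the full photosynthetic reference collection, are
shipped as constants for use when no training data is available; they are
reference values, not re-derived here. Inside cross-validation the
cutpoints are always refit on the training fold.

Deduplication collapses instances identical in (feature vector, label),
keeping the first by index order; feature-identical instances with
conflicting labels are all kept and flagged. The operation is idempotent.

## Classifiers and evaluation

* Random forest is the primary classifier (500 trees, √p features);
  categorical naive Bayes stands in for the graphical-model classifier and
  a linear SVM for the SMO-style margin classifier — behavioural parity
  with other toolkits is a non-goal.
* Gain ratio = (H(Y) − H(Y|A)) / H(A), log base 2; constant features score
  0 by convention; ranking ties break by column name. The per-threshold
  composition of a selected feature set is reported.
* PCA treats levels as numeric 0–3 and keeps the smallest component count
  reaching the requested variance fraction (default 0.95); the fitted
  transform is reused on held-out rows.
* Class balancing: instance reweighting equalises per-class weight sums
  while keeping total weight = instance count; SMOTE interpolates between
  a minority row and one of its k = 5 nearest minority neighbours, rate
  100% by default, seeded.
* Nested CV: stratified outer folds (default 10); two inner folds per
  outer training set pick hyperparameters by F1-minor (random-forest grid:
  trees ∈ {100, 500} × depth ∈ {∞, 10}). Cutpoints, feature selection, PCA
  and balancing are fitted inside each training set only, so held-out rows
  never influence any fitted component. Metrics with a zero denominator
  are 0 by convention (degenerate folds only). A Wilcoxon signed-rank
  comparison across outer folds is a thin call into scipy.
* Novel sequences: matches are collection proteins hit at E-value ≤ 1;
  each match's profile row is classified and the majority (unweighted)
  vote decides; an exact tie goes to F (the method favours precision on
  the minority class; configurable) and no match yields NOT_ASSIGNABLE,
  treated as an error for labeled queries in evaluation. The similarity
  baseline transfers the label of the best hit at E-value ≤ 10.

## GO handling

Only `is_a` edges are traversed, both for ancestor closure and for depth;
depth is the shortest is_a path to the namespace root (root = 0), the
convention under which photosynthesis (GO:0015979) sits at level 3.
Negative candidates must have no photosynthesis term in their closure and
at least one annotation at depth ≥ 3. The shipped photosynthesis term list
(`data/photo_go_terms.txt`) is a synthetic stand-in centred on GO:0015979
and its public descendants; users should substitute their curated list.
Redundancy reduction below 25% identity is delegated to an external
clustering tool; the package only consumes its representative-id list.

GO-coherence (the functional-relation analysis) compares a query's terms
with the union of its surviving neighbors' terms — union rather than
per-neighbor averaging because one F1 is reported per query; both sets are
ancestor-closed first. The random baseline replaces the neighbor term set
with an equal-size uniform sample from the pool of all annotated terms,
averaged over `n_random` draws.

## Synthetic data: what it emulates, and what it does not

The generator plants positive families in conserved same-strand clusters
(grouped `cluster_size` = 4 at a time, so photosynthesis-like genes are
each other's neighbors, as in real photosystem operons), present per
genome with probability `conservation_prob`; a fraction (default 0.4) of
background families form weakly conserved housekeeping operons
(per-operon conservation drawn from 0.3–0.8) and the rest are free
singletons, shuffled independently per genome. Without the background
operons every negative row would be all-zero and collapse to a single
instance under deduplication — real negative proteins also live in
(non-photosynthetic) operons. Genomes carry increasing numbers of private
singleton families so the distance matrix is non-degenerate. Within-family
hits get E-values far below all three thresholds and between-family noise
hits E-values above them, so MCL recovers the planted families exactly;
sequences are random amino-acid strings and the similarity table is
generated from ground truth, not alignment.

Consequences: passing tests demonstrate that the pipeline recovers planted
conservation signal under controlled noise; they do not demonstrate
robustness to homology detection errors, horizontal transfer, assembly
fragmentation, paralog-rich families, or annotation bias in real genome
collections. The default study conditions used throughout the test-suite
are 10 genomes, 200 families, 20 positive families, conservation 0.9, five
generator seeds — sizes chosen so a full nested-CV evaluation completes in
minutes on one core while leaving ≥ 3 genomes of evidence for planted
adjacencies under the conservation probability.

## Known limitations

* The profile is family-keyed, so generalisation to a novel query family
  requires that family to share neighbor columns with training families;
  a fully isolated operon cannot be learned from other instances.
* MCL is implemented for desk-scale collections (10³–10⁴ proteins); no
  out-of-core or GPU path.
* ABSENT and "score 0" are indistinguishable downstream by design.
* The divergent-merge rule is a single pass; long alternating strand
  arrangements are not merged transitively.
* Depth conventions differ between ontologies; the shortest-path
  convention is the default and longest-path is not implemented.
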