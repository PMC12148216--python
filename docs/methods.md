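# Methods

This note documents the models, the synthetic study conditions, the
numerical choices and the known limitations of `kgsynergy`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model and I/O

A knowledge graph is a multiset of directed labelled triples
`(head, relation, tail)` over typed entities. The on-disk dialect is a
three-column tab-separated edge list plus a two-column node-type table;
entity identifiers are opaque, case-sensitive strings (real pharmacome
snapshots mix namespaces, so no normalization is attempted). Duplicate
triples are collapsed with their multiplicity retained: embedding training
treats repetition as weight, while entity/edge reporting stays
deduplicated.

## Synergy harmonization and enrichment

Combination-screen exports carry one row per (pair, cell line, assay) with
a ZIP synergy score (the zero-interaction-potency model subsumes Loewe
additivity and Bliss independence, which is why only ZIP drives
labelling; HSA/Bliss/Loewe columns are carried through but unused).
Processing order matters and is fixed:

1. replicates are averaged *within* a (pair, cell line) key — the mean is
   labelled, not the labels averaged;
2. each cell line is classified independently with a symmetric dead band:
   ZIP ≥ +10 synergism, ≤ −10 antagonism, otherwise additive. The ±10
   default is a package choice (configurable): a dead band is required for
   "additive" to be a well-defined class at all, and ±10 sits far enough
   from experimental noise that class counts are stable;
3. a pair survives only if its cell-line labels are unanimous and
   non-additive. Mixed pairs model cell-type-dependent interactions and
   are removed; all-additive pairs carry no interaction signal and would
   otherwise create a tiny, hopelessly imbalanced third class.

Surviving pairs are written into the graph as *reciprocal* edges (both
orientations). Downstream prediction scores both orientations and demands
agreement, so the training signal must be orientation-symmetric too.
Unresolvable drug names are never fuzzily matched; a synonym table can be
supplied explicitly.

## Embedding models and training

All five models are implemented directly in NumPy with hand-derived
gradients (verified against finite differences in the test suite) and a
dense-Adam optimizer. Conventions:

- **Losses.** Margin ranking (margin 1.0) for the distance models TransE,
  TransR, RotatE; pointwise softplus for the bilinear models ComplEx and
  HolE — matching each family's original formulation.
- **Regularization.** L2 weight decay 1e-4 on the parameters touched by
  each batch. The bilinear scores are unbounded in the parameter norm, so
  without decay a large-norm relation vector can dominate every relation
  ranking; 1e-4 is small enough not to disturb the distance models (TransE
  additionally renormalizes entity vectors to unit norm each step).
- **Negative sampling (SLCWA).** Each positive is corrupted k times
  (default 4) by replacing head or tail (fair coin) with a uniform entity;
  the corrupted slot is resampled until it actually differs. Collisions
  with observed triples are permitted by default, as under the stochastic
  local closed-world assumption; a filtered mode resamples them.
- **Constraints.** RotatE stores relation *phases*, so unit modulus holds
  by construction; phases are wrapped to [0, 2π) each step for hygiene.
  TransR projection matrices start near the identity so early training
  behaves like TransE before relation spaces differentiate.
- **Numerics.** Norms carry an additive 1e-12 inside the square root so
  gradients stay finite at exact translation; HolE's circular correlation
  runs via the FFT with the O(d²) double loop kept as an independent test
  oracle; complex quantities are stored as paired real arrays. A NaN batch
  loss aborts with a diagnostic rather than continuing silently.
- **Determinism.** A single integer seed drives initialization, shuffling
  and corruption; identical config + seed reproduces identical parameters
  bit for bit. No early stopping — the epoch count is explicit
  configuration.
- Defaults: dimension 64, 100 epochs, batch 256, Adam lr 1e-2
  (β = 0.9/0.999). No hyperparameter search is built in; grids of one are
  a deliberate reproducibility choice.

Relation ranking scores every relation for a fixed (head, tail), sorts
descending and breaks exact ties by vocabulary order, making rankings
stable across calls and platforms.

## Splitting

Splits are stratified per relation label with floor rounding on the
held-out side; singleton strata and remainders go to train. This makes the
coverage guarantee — every relation occurring anywhere occurs in train —
deterministic rather than probabilistic, at the cost of a ≤1-triple
deviation per stratum from the exact fraction. The two-level 80/20 then
80/20 convention yields 64/16/20 train/validation/test overall. Hold-out
sizing uses the ceil-on-the-held-out-side convention shared with
scikit-learn's splitters, so a 90/10 split of 20 840 pairs is exactly
18 756 / 2 084.

## Evaluation metrics

The per-rank true-prediction percentage uses the number of evaluated pairs
as its denominator: every pair contributes exactly one prediction at every
rank, so counts across ranks 1..|R| sum to the number of pairs. Binary
ROC-AUC is computed as the Mann–Whitney concordance probability with ties
counted one half — algebraically identical to the trapezoidal area, which
serves as the independent oracle in tests. The multiclass ROC-AUC is the
*unweighted* (macro) mean of one-vs-rest binary AUCs over the relation
types present in the truth; types absent from the truth have an undefined
one-vs-rest AUC and are excluded with a warning.

## Pair features and nested CV

Pair feature vectors must be invariant to pair orientation, which is
achieved structurally: per-drug blocks are ordered by the
lexicographically smaller drug, pair-level features (shortest path,
adjacency cosine, Tanimoto) are symmetric functions, and fingerprints
enter as the elementwise OR and AND of the two bit vectors rather than a
concatenation. The adjacency cosine is the cosine of the two drugs'
adjacency indicator vectors, the only KG-native similarity available
before any embedding exists. Disconnected pairs receive the sentinel
(max finite observed distance + 1), keeping the feature finite and
monotone within a feature table. Missing descriptor values are
mean-imputed with a recorded mask.

The nested-CV protocol: stratified 90/10 hold-out; ten inner 90/10 loops
on the training portion, each selecting grid-search hyperparameters by
validation ROC-AUC; ten final instances (one per loop's best parameters)
refit on the full training portion and evaluated on the hold-out. The
embedding-hybrid path — entity-embedding concatenations as features — uses
the same function and report schema unchanged. Default grids are small
and fixed (2–6 points per model); SVM scores come from the decision
function, the others from class probabilities.

## Pair prediction and the mutual filter

Exhaustive prediction covers every unordered drug pair not already linked,
ranking relations in both orientations. "Non-mutual" is read strictly as
rank-1 disagreement between orientations (a laxer top-3 mode exists behind
a flag but is off by default). Pairs whose agreed rank-1 relation is not a
combination relation get a "no combination call" reason code rather than
being forced into a class. Scores are model-native and not comparable
across models; within a model, segregated sets order by
min(forward, reverse) score with a deterministic pair-id tie-break.

## Causal-only pruning

The pipeline is fixed: whitelist filter → isolated sweep → hub removal →
isolated sweep. The default whitelist is {increases, decreases,
causes_no_change} — the three causal labels of the pharmacome schema this
package targets — but it is configuration, not a constant. Hub removal
defaults to node-*type* selection (all Pathology nodes) with an optional
degree threshold, because disease nodes are the dominant super-hubs in
drug-target-mechanism graphs and a universally correct numeric cutoff does
not exist. The disease-retained companion copy is produced in the same run
(pathway tracing needs the disease anchors that embedding must not see),
guaranteeing the two graphs differ only by the hub-removal step.

## Repurposing

Candidates are ranked synergistic partners of per-disease anchor drugs.
Safety is an explicit user-supplied exclusion list — "cytotoxic or severe
side effects" is an editorial judgement, not a computable predicate — and
excluded partners stay in the report with rank preserved so the audit
trail is complete. Pathway evidence pairs simple paths (≤ max_len edges,
default 4 — mechanism chains drug→protein→protein→disease) from anchor and
candidate to the disease that share at least one interior node; sharing a
node rather than the identical path matches how mechanistic convergence
actually appears in curated graphs. Traversal ignores edge direction by
default (recording each step's orientation) because causal chains are
routinely read through both orientations; a strict-direction mode is a
flag. A missing disease node is reported distinctly from an unreachable
one. Verdicts are a total function of (safety, evidence):
excluded / pathway_supported / synergy_only.

## Synthetic study conditions

The generators define the conditions every test runs under:

- **Planted KG** (default 500 entities, 8 relations, 5 000 triples,
  generator dimension 16): entities sit near one of a few cluster centres
  (per-coordinate noise 0.08) and each relation's ground-truth embedding
  maps one ordered centre pair (TransE: centre difference; RotatE: phase
  difference; HolE: normalized centre correlation). The emitted graph is
  exactly the top-scoring `triple_budget` candidates under the ground
  truth, so the relation between two entities is determined by their
  cluster memberships and recovery is well-posed. Relation labels cycle
  through a pharmacome-like vocabulary (causal labels first), so the same
  fixture exercises causal pruning. The planted-recovery benchmark trains
  at dimension 32 for 60 epochs — sized so all five models converge within
  about a minute total while leaving a wide margin over the 3×-uniform
  recovery bar.
- **Synergy tables**: latent class per pair (additive with rate 0.1,
  remainder split evenly), per-cell-line ZIP = class mean ±15/0 +
  N(0, noise_sd = 2), three cell lines. With the ±10 dead band the class
  means sit 2.5σ from the thresholds, so a per-cell-line misclassification
  has probability ≈ 0.006 and filter behaviour is predictable in closed
  form. An `inconsistency_rate` fraction of non-additive pairs get one
  cell line's mean sign-flipped, guaranteeing non-unanimity.
- **Drug tables**: descriptors uniform over drug-like ranges (MW 100–900,
  logP −2–7, TPSA 0–200, HBD 0–10, HBA 0–12, rotatable bonds 0–15) and
  1024-bit fingerprints with ~64 on-bits; planted similar pairs share 90%
  of their on-bits (Tanimoto > 0.6 by construction).

What the synthetic data does *not* emulate: real pharmacome degree
distributions (no super-hubs unless planted), literature curation noise,
assay batch effects, chemically meaningful fingerprints, and the extreme
class imbalance of real combination databases. Passing tests therefore
demonstrate correctness of the algorithms and the recoverability of
planted structure — not real-world predictive performance.

## Known limitations

- Training is CPU NumPy; graphs in the 10⁵–10⁶-triple range train in
  minutes–hours depending on dimension and epochs, but no GPU path exists.
- Only SLCWA training is implemented (no LCWA mode), and no
  hyperparameter-optimization pipeline is bundled.
- Relation ranking between fixed entity pairs is the only link-prediction
  mode; entity ranking (tail prediction) is not exposed.
- The mutual filter necessarily loses pairs whose best relation is not a
  combination relation; on sparse graphs this can be the majority.
- Path-based evidence is bounded by `max_len`; biologically meaningful
  longer chains are invisible to the default configuration.
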