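# Methods

## Model and assumptions

The package rests on one biological premise: proteins that truly
interact tend to participate in similar biological processes, so an
interacting pair annotated to semantically distant GO terms is more
likely a false positive of the detection technology than a real
interaction. Confidence in an edge is therefore a GO semantic
similarity between its endpoints, and the refined network keeps only
edges whose confidence reaches a threshold.

The GO is treated as three independent rooted DAGs (biological
process, cellular component, molecular function), with ancestry
defined by `is_a` and `part_of` edges only. Other relationship types
(`regulates`, `occurs_in`, ...) are dropped on load: they cross
namespaces and do not express the subsumption that information-content
and S-value computations assume.

### Information content

Annotation probabilities are computed per namespace after true-path
propagation: a protein annotated to a term counts for every ancestor
of that term, the counting unit being distinct proteins (not
annotation rows). Then `p(t) = count(t) / N` with `N` the number of
proteins annotated anywhere in the namespace, and `IC(t) = −ln p(t)`
(natural log; IC is in nats). Propagation guarantees `p` is monotone
non-decreasing from descendant to ancestor, `p(root) = 1` and
`IC(root) = 0`, which the metrics rely on. Terms never annotated have
no IC entry and cannot serve as a MICA.

### Term-level metrics and conventions

* **Resnik** returns `IC(MICA)`, which is unbounded; by default it is
  divided by the maximum corpus IC of the namespace so that all five
  metrics share the [0, 1] scale and one filtering threshold is
  meaningful across metrics. The raw value is available
  (`normalize_resnik=False`).
* **Jiang** (`1 − [IC(m)+IC(v)−2·IC(MICA)]`) is arbitrarily negative
  for distant term pairs; it is floored at 0 by default
  (`clamp_nonnegative=False` returns the raw value). Without the
  floor, thresholding at a nonnegative τ would behave identically, but
  exported scores would not sit on the common scale.
* **Rel** multiplies Lin by `1 − p(MICA)`, so it is bounded above by
  Lin pointwise, with equality only when `p(MICA) = 0` — impossible on
  an annotated corpus, hence strictly below Lin in practice.
* **Wang** uses edge contribution factors `is_a = 0.8`,
  `part_of = 0.6` (the convention of the original hybrid method);
  S-values follow the max-over-children recursion and similarity is
  the shared-ancestor S-mass over the two total semantic values.
* Degenerate `0/0` cases (both ICs zero, e.g. root vs root) are
  defined as similarity 0.
* MICA ties (several common ancestors with equal IC) are broken by the
  lexicographically smallest term identifier, making every score
  deterministic.

### Protein-pair aggregation

The term formulas are aggregated over the two proteins' *direct*
(unpropagated) annotation sets in the configured namespace;
propagation influences only the IC corpus. The default aggregation is
best-match average (bma): average the row maxima and the column maxima
of the term-pair similarity matrix and take their mean. A global `max`
aggregation is available. When both proteins carry exactly one term
the two coincide. A protein with no annotation in the namespace scores
0 against everything — this is what makes sparsely annotated
namespaces (MF in particular) filter aggressively.

## Refinement

Edges with score ≥ τ are reserved (boundary edges kept); default
τ = 0.33. Proteins with no surviving edge are removed. Scores are only
ever computed on existing edges — refinement never adds links.
Refinement is idempotent and monotone in τ (higher τ ⇒ subset of edges
and nodes). Identifier matching between network, annotations and gold
standard is exact-string.

## Centrality measures

* **BC** sums, over unordered node pairs excluding the focal protein,
  the fraction of shortest paths passing through it; no normalisation
  constant; disconnected pairs contribute 0. (The summation convention
  is not forced by the definition; this is the prevailing one and is
  used consistently in code and tests.)
* **EC** is the eigenvector of the largest adjacency eigenvalue,
  unit-norm, nonnegative sign convention, computed by dense symmetric
  eigendecomposition with a verified residual
  `‖Av − λv‖ ≤ 1e−10·max(λ, 1)`. On disconnected graphs the global
  dominant eigenvector is used; components outside its eigencomponent
  are numerically zero.
* **NC** sums edge clustering coefficients
  `|N_p ∩ N_u| / min(|N_p|−1, |N_u|−1)`; a denominator ≤ 0 (an
  endpoint of degree 1) contributes 0 rather than raising — degree-1
  nodes are ubiquitous in real PPI networks.
* **SC** is `diag(exp(A))` via eigendecomposition
  (`Σ_j v_pj² e^{λ_j}`), always ≥ 1 (the length-0 closed walk).
* **aveNC** is the mean neighbour degree; isolated nodes score 0.
* Dense eigendecomposition is used throughout: the intended scale is
  10³–10⁴ proteins, where it is exact and fast enough; no sparse
  approximation is implemented.

Rankings sort by descending score with ties broken by ascending
protein identifier, so all rankings are reproducible and
relabel-stable up to that tiebreak.

## Evaluation

Each network variant is evaluated against the gold standard restricted
to its own node set (a protein absent from the refined network can be
neither a true nor a false positive there). Precision is `TP/(TP+FP)`
over the top-k (k = 600 in the standard protocol; smaller k on
desk-scale data). Edge-class portions are computed over the subgraph
induced by the top-k proteins — an interpretation of "interactions
ranking in the top k" that makes the per-method numbers well defined.
ROC curves assign each protein the normalised rank score
`1 − (rank−1)/|P|` (rank 1 → 1.0) and sweep the threshold over [0, 1];
AUC is trapezoidal and, on tie-free rankings, equals the
concordant-pair (Mann–Whitney) statistic — a property the tests check
by brute force. Improvement between two counts is
`100·(refined − original)/original`.

## Synthetic data generator

The generator produces, from a single seed, everything the pipeline
consumes; a fixed seed gives bit-identical output.

* **DAG**: one rooted `branching`-ary tree per namespace
  (default branching 4, depth 3 ⇒ 85 terms each) plus a few
  within-branch `part_of` shortcuts, so both edge types and multiple
  paths occur.
* **Modules**: each depth-2 BP term is a functional module; proteins
  (default 300) are spread evenly across modules and annotated to 1–3
  leaf terms under their module term. CC/MF annotations are random
  leaves — present so all namespaces exercise the code, carrying no
  module signal.
* **True edges** (default 900): with probability
  `annotation_coherence` (0.9) both endpoints come from one module,
  else from two random modules. Endpoints are drawn with Zipf-like
  weights within modules so hubs emerge.
* **False edges** (default 10 % of the network): drawn between
  different *top-level branches*, so the endpoints' only shared BP
  ancestor is the root and their confidence is forced to ~0 under
  every metric. They concentrate on a small set of "sticky bait"
  proteins (default 4 % of proteins ≈ 12 hubs) — uniform spray noise
  at this rate barely moves a degree ranking, whereas promiscuous
  baits are exactly how false positives manifest in real two-hybrid
  screens.
* **Unannotated proteins** (default 5 %) are drawn from the
  below-median-degree pool, weighted toward the least connected —
  modelling study bias: uncharacterised proteins are neither well
  annotated nor well represented in interaction data. Their edges
  score 0 and are filtered.
* **Essential proteins** (default 20 %) are sampled with probability
  increasing in true-interaction degree (`(deg+0.1)^1.5` weights),
  the centrality–lethality premise the ranking step assumes.

At these defaults, refining at τ = 0.33 with Lin/BP removes 100 % of
the planted false edges and retains ≈ 84 % of true edges (losses are
the incoherent cross-module pairs and unannotated endpoints), and the
mean top-50 DC essential count on the refined network is at or above
the noisy network's across seeds.

**What the generator does not emulate:** realistic yeast degree
distributions (no scale-free fit), GO term-size distributions, shallow
or partial annotation depth, evidence-code heterogeneity,
inter-module biological overlap, or false *negatives* (missing true
edges). Passing the recovery tests therefore demonstrates that the
pipeline's machinery is correct and that the method behaves as
designed when its premise holds — not that the premise holds, nor how
strongly, in any particular real interactome.

## Test and script problem sizes

Unit and property tests run on hand-built 3–5-term ontologies, random
DAGs of ≤ 15 terms, random graphs of ≤ 10 nodes, and the default
300-protein bundle; the recovery experiment and the acceptance script
average ten 300-protein seeds, which keeps a full run in seconds while
leaving the planted-signal margins wide.

## Known limitations

* Cross-namespace similarity is out of scope; one namespace per run.
* No synonym/identifier cross-referencing — inputs must share an
  identifier space.
* Raw (unnormalised) Resnik and unclamped Jiang scores are not on
  [0, 1]; thresholds for them must be chosen on their own scale.
* The exact aggregation (bma vs max) and normalisation used with the
  0.33 threshold in the original protocol are underdetermined; both
  are exposed as configuration rather than fixed as the only truth.
* Whether boundary edges scoring exactly τ were kept in the original
  protocol is unknowable; this implementation keeps them.
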