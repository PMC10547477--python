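# Methods

This note documents the models and procedures implemented in `phenofun`,
the parameters that matter, what the synthetic studies do and do not
emulate, and the numerical choices made where the design was open.

## Ontology handling and information content

The GO DAG is held with typed child→parent edges. Annotation closure
("up-propagation") traverses `is_a`, `part_of`, `has_part` and `regulates`
by default; subsumption semantics (descendant counting for IC, ancestry for
semantic similarity and novelty classes) use only `is_a`/`part_of`, because
`has_part` and `regulates` cross or invert specificity. Obsolete terms are
flagged at load, excluded from propagation, and form their own novelty
class; `alt_id`s are remapped to primary identifiers. OBO parsing is
delegated to `obonet`, with dangling-parent and acyclicity checks on top.

Information content is IC(t) = −log p(t), with p(t) the fraction of
annotation records on t or any of its descendants. Two conventions are
deliberate and configurable:

- **Log base.** Natural log by default, so the customary "IC > 5" filter
  means p < e⁻⁵ ≈ 0.0067. A `base` argument switches to bits or any base.
- **Denominator.** N is the per-namespace record count *after*
  up-propagation. This makes p(root) = 1 and IC(root) = 0 exactly, and makes
  IC monotone non-increasing from leaf to root — the property the filter
  relies on. Frequencies can be computed on raw sets via `propagate=False`.

Predicted terms never seen in the reference corpus receive the maximum
observed IC (they are at least as specific as the most specific known term).

## Semantic similarity

A term's semantic-value map assigns S(t) = 1 and
S(a) = max over children c of a on paths toward t of w(c→a)·S(c), traversing
only is_a/part_of. The edge weight is child-count aware:
w = 1/(c + nc(a)) + w₀ with c = 0.67 and w₀ = 0.4 (is_a) / 0.3 (part_of),
where nc(a) is a's direct child count — decay is faster through densely
branched regions. All four constants are configurable, and a classic fixed
preset (0.8/0.6) is provided. Weights ≥ 1 (possible only in degenerate
ontologies) are clamped to 0.999 with a warning.

Term similarity is Σ_shared (S₁(a)+S₂(a)) / (SV₁+SV₂); gene-pair similarity
is the best-match average over the two term sets, 1 for identical sets.
Gene scores are computed on the **directly annotated** term sets — ancestors
enter through the S-maps. Computing them on up-propagated sets would
saturate between-gene similarity and is not done. BP and MF are never mixed;
genes with an empty term set in a namespace are omitted from that
namespace's pairs rather than scored 0.

## Family homology and the fast-and-frugal tree

Domain hits (hmmsearch `--domtblout` or an equivalent 6-column TSV; 1-based
inclusive envelope coordinates; per-domain independent E-values) are
filtered at E < 10⁻³ (strict), and per protein resolved to the pairwise
non-overlapping subset maximizing summed bit score by weighted-interval
scheduling (exact dynamic programming; overlap tolerance 0 residues by
default, configurable). The machine-learning feature matrix holds
−log₁₀ of the best E-value per (protein, family), sparse.

Family→GO association counts, per family and term, the members annotated
with the term after evidence filtering (NAS/ND/TAS/IEA dropped;
keyword-curated IEA records, marked e.g. `IEA:UniProtKB-KW`, kept) and
four-relation ancestor closure; the probability is the member proportion.

The predictor asks at most two questions: any significant resolved hit in
the primary library? — emit the best-bit family's term proportions; else the
same against the fallback library; else nothing. Proportions < 0.1 (strict)
are dropped. Per-family bit-score inclusion thresholds can be supplied as a
table; absent one, the E-value filter is the significance gate.

## Network embedding

Six symmetric, max-normalized, zero-diagonal adjacency layers over a common
gene index feed a multimodal autoencoder: per-layer ReLU encoders (width h)
→ one shared bounded embedding (width d) → per-layer ReLU decoders →
per-layer sigmoid reconstructions; the loss is the sum of per-layer binary
cross-entropies against the adjacency rows. Training uses Adam on
mini-batches of a random 90% of genes; the held-out 10% monitors validation
loss and the weights from the arg-min epoch generate the final embedding for
all genes. The implementation is pure NumPy with manual backpropagation and
is bit-reproducible given the seed.

The embedding activation is configurable {sigmoid, tanh}, default sigmoid
with range (0, 1). (A bounded activation spanning −1..+1 would be tanh; both
are supported, and the documented range here is the sigmoid's.) An optional
random-walk-with-restart + PPMI preprocessing of each layer is available but
off by default.

Scale defaults: the library default is h = d = 256, 500 epochs, batch 128,
Adam lr 10⁻³ — the full-scale configuration for thousands of genes. The
staged pipeline and the test studies run desk-scale (h = 64, d = 32,
300 epochs, batch 32, lr 10⁻²): at n ≈ 200 genes the larger step size and
capacity-to-n ratio are what make the reconstruction objective separate five
planted modules cleanly; with the full-scale settings the optimizer is far
from converged at desk problem sizes.

## One-vs-rest forests

Targets are GO terms — a supplied slim list or terms whose up-propagated
positive count lies in [lo, hi] (library default 50–1000; pipeline fixtures
scale this down proportionally). One random forest per term: 500 trees
(desk-scale runs use 30–100), entropy criterion, min 2 samples to split, no
depth cap. `partial_sampling` is implemented as the bootstrap draw fraction
(`max_samples` in scikit-learn, sampling with replacement) — the standard
forest idiom for subsampling examples. Scores are the forest's positive-class
vote fraction.

Cross-validation is stratified per target label independently (joint
multilabel stratification is not attempted), repeated over seeded trials;
every gene receives exactly one out-of-fold score per trial, and no gene is
scored by a forest that saw it. AUPR is average precision without
interpolation smoothing; the headline number is the macro average over
targets (micro available). With all-equal scores AUPR equals prevalence
exactly, which the label-shuffle null tests rely on.

Grid search evaluates all 12 cells of {10, 25, 50, √n} × {0.5, 0.75, 1.0}
by mean macro AUPR on inner folds only, with √n resolved by floor and
integers clipped to the feature count. Ties break deterministically toward
smaller resolved `max_features`, then larger sampling; scores are compared
at 1e-9 resolution so floating-point noise cannot defeat the tie-break when
several cells saturate on cleanly separable data.

When family features are appended, each target's usable family columns are
restricted to families containing at least one protein annotated with that
target (a per-term column mask); embedding columns are always kept.
Phenotype-presence features can be appended as a third block but are off by
default.

## Combining and filtering predictions

Shared (gene, term) pairs combine as min(p₁ + p₂, 1); single-source rows
pass through at their own probability (the minimal consistent reading — the
downstream score filter governs inclusion either way). The high-confidence
filter applies, in a fixed order so stage counts are comparable across runs:
score > 0.7 (strict) → taxon-constraint ban list (optionally including
descendants of banned terms) → IC > 5 (strict).

Novelty partition against the curated reference (raw, not up-propagated),
with precedence: *obsolete* → *identical* (term annotated to the gene) →
*redundant* (a strict descendant of the prediction is annotated — the
prediction only restates known annotation at lower depth) → *novel-deeper*
(the prediction is a strict descendant of an annotated term) →
*novel-new-subtree* (no ancestry overlap beyond the root). The five classes
are exhaustive and mutually exclusive by construction; ancestry uses
is_a/part_of within the namespace.

## Phenomics

Fitness values are colony sizes relative to the wild-type grid on the same
plate. Benign conditions (≥10 repeats): two-sided Welch t-test of mutant
repeats against wild-type repeats, BH correction **across strains within
each condition** (each condition is an independent screen); a hit needs
adjusted p < 0.05 and |median − 1| ≥ 0.05. The location test is a documented
choice — only the BH correction and the two thresholds are fixed by the
procedure. Stress conditions (4 repeats): phenotype score =
median(condition) / median(mapped control medium); hit iff |score − 1| ≥
0.10, no p-values — the control normalization cancels constitutive growth
defects.

Ternary encoding codes score ≤ 0.9 as −1, ≥ 1.1 as +1 (boundaries
inclusive), else 0; benign entries additionally require adjusted p < 0.05.
Matrix filtering: "methods" mode drops strains >50% missing and conditions
>90% zeros; "fig3" mode drops rows/columns with <4 phenotypes, columns with
>2400, and rows >50% missing (both signs count as phenotypes).

Clustering is PAM — deterministic BUILD seeding plus best-improvement SWAP,
cost provably non-increasing per iteration — on 1 − Pearson distance between
profiles, pairwise-complete with a minimum overlap of 20 shared conditions
(desk-scale configs lower this; pairs below it and zero-variance rows get
distance 1 or the median observed distance, logged). k is chosen by maximum
mean silhouette over 2–12 unless fixed.

## Association and integration networks

PHEPHE is the Pearson correlation of two mutants' phenotype profiles
(continuous scores by default; the ternary matrix can be used instead —
which matrix feeds the network is a genuine degree of freedom and both are
supported). p-values come from the two-sided t-transform with n−2 df, BH
across all pairs computed in the run. Networks keep |r| > 0.7 and adjusted
p < 0.01, retaining the sign. Communities are greedy-modularity (CNM) within
connected components — a deterministic stand-in for GLay-style community
clustering, pluggable. Integration admits a pair iff GO-similarity(BP) > 0.5
and similarity × PHEPHE > 0.5; negatively correlated pairs can never pass
the product gate as specified. The null model permutes the gene labels of
the PHEPHE table (seeded), preserving both marginals.

## Synthetic studies

The generator plants a module structure shared across every data type:
module-specific deep subtrees in a random two-namespace GO DAG (each
non-root term has 1–2 parents, mixed is_a/part_of; every term reaches its
namespace root via is_a); gene annotations sampled from the gene's module
pool with a 10% noise rate; six stochastic-block-model network layers
(within-module edge probability 0.3, between 0.02, per-layer jitter and
sub-seeds); protein families nested within modules with proportions that
follow exactly from the generated annotations; and replicate fitness tables
where module archetypes assign each stress condition an effect in
{−25%, 0, +25%} (nonzero with probability 0.15), benign effects of ±10% are
planted in 10% of strains, noise is multiplicative lognormal (σ = 0.03), and
a strain's constitutive benign defect multiplies its stress plates so the
control normalization cancels it. One global seed expands into fixed named
sub-seeds per generator; outputs are bit-identical given (spec, seed).

What this does *not* emulate: genome-scale corpora (thousands of genes,
tens of thousands of terms), realistic edge-weight and E-value
distributions, annotation biases, plate spatial artifacts, or conditions
with heterogeneous repeat structure. Passing tests therefore demonstrate
correctness of the algorithms and recoverability of planted structure at
desk scale, not expected performance on real corpora — headline performance
numbers on real data depend on the data and are out of scope here.

Problem sizes throughout (100–200 genes, ≤200 terms, ≤26 conditions,
30–100 trees) are the package's desk-scale study conditions; the full-scale
defaults remain on the library functions.

## Numerical choices and degenerate inputs

- Strict vs inclusive comparisons follow the stated rules exactly:
  E < 10⁻³, score > 0.7, IC > 5 and family p < 0.1 strict; ±10% ternary
  bands and the 5%/10% effect thresholds inclusive.
- Hit-resolution ties (equal total bit score) resolve deterministically by
  the DP's take-on-tie rule; tests compare achieved total score against
  exhaustive search.
- Correlation of zero-variance profiles is undefined → distance 1
  (maximally dissimilar), logged.
- BCE uses an epsilon of 1e-12; non-finite losses abort with diagnostics.
- All randomness flows through `numpy.random.Generator` seeded from a single
  integer; scikit-learn forests get derived integer seeds. Two runs with the
  same config and seed produce byte-identical TSV outputs (floats printed at
  %.10g; manifests store content hashes with paths relative to the artifact
  directory).

## Known limitations

- The benign-condition location test (Welch) is a stand-in; rank tests may
  be preferable for heavy-tailed plate effects.
- Greedy modularity can split large sparse communities differently from
  GLay; the community detector is pluggable.
- The grid-search recovery study uses a saturating separable signal: with
  only two informative features among noise, forests with larger
  `max_features` are empirically never worse, so the small-`max_features`
  optimum is realized through the documented tie-break rather than a strict
  performance gap.
- `partial_sampling` draws with replacement (bootstrap); a without-
  replacement variant would require a custom forest implementation.
- The NumPy autoencoder targets desk-scale problems; it has no GPU path and
  no architecture search.
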