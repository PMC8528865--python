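# Methods

## The ontology model

The class hierarchy is a single-rooted tree of *textual* entity classes
(`nero/data/nero_classes.tsv`), rooted at `InformationContentEntity` with
`NamedEntity` carrying the three heavily populated branches
(`AnatomicalPart`, `Chemical`, `Process`) plus a flat layer of further
concepts (`MedicalFinding`, `Organism`, `Measurement`, …). Five **union
classes** encode annotation ambiguity: `GeneOrProtein`,
`AminoAcidOrPeptide`, `QuantityOrMeasurement`, `PublicationOrCitation`,
`MedicalProcedureOrDevice`. Subsumption is reachability over parent links
plus member→union edges, precomputed as a closure at load time; a
brute-force graph search over the same edges is the test oracle.

Choices worth noting:

* **"Most specific" excludes union classes.** A `GeneOrProtein` label is an
  unresolved assignment, not a specific one, so it does not count toward the
  specificity fraction. Because this is a genuine modeling choice, it is
  reversible per call via `unions_specific=True`.
* Class names are case-sensitive identifiers. A small alias table maps
  known variant spellings (e.g. `AminaoAcidOrPeptide`) to canonical names on
  read.
* A handful of classes whose exact placement is reconstructed rather than
  explicitly documented (e.g. the sixth `Process` subclass) are flagged
  `provisional` in the packaged table.
* The hierarchy ships as plain TSV; OWL authoring and description-logic
  reasoning beyond subsumption/union resolution are out of scope.

## Standoff corpus model

Documents are text plus entity mentions (0-based half-open code-point
spans) and event mentions (an action trigger span, ≥ 1 entity arguments,
polarity asserted/negated). On-disk format is the brat dialect
(`T`/`E`/`A` lines), one `.ann` per annotator layer; a flat-TSV fallback
reader and a JSON export exist for other schemata. Surfaces are
cross-checked against spans on read, and `validate_corpus` returns
violations as data rather than raising, so corpora can be triaged.
Overlapping and nested mentions are legal in the model; they are only
flattened at BIO-encoding/evaluation time.

## Composition statistics

Frequency tables rank items by count descending with lexicographic
tie-breaks, making every downstream fit deterministic. Per-class shares are
computed over labels exactly as annotated (`rollup=False`) by default;
`rollup=True` credits mentions to all superclasses, in which case the root
count equals the mention total (a conservation property under test).

Action normalization is a deterministic rule pipeline — case-fold, detect a
leading negation cue (`do not`, `does not`, `did not`, `not`, `no`;
configurable) and canonicalize it to `do not`, lemmatize the head verb by a
packaged irregular-form table plus suffix rules (-ies/-es/-s/-ing/-ed with
consonant undoubling and minimum stem length 3). A rule table was chosen
over a learned lemmatizer for reproducibility; unknown forms pass through
case-folded, and the function is idempotent (property-tested).

Inter-annotator agreement reports, per document pair: exact span+label F1,
relaxed (overlap+label, greedy one-to-one) F1, a pooled micro F1, and
token-level Cohen's κ with `O` for untagged tokens. No single metric is
privileged; κ is computed directly so that perfect agreement on a
degenerate single-class labeling yields 1 rather than 0/0.

## Rank-frequency fitting

The DGBD `f(r) = A (N+1−r)^b / r^a` is fitted by OLS of log count on
`[1, log(N+1−r), log r]` — the standard estimator for this family, giving
closed-form residual diagnostics; discrete MLE is a possible extension. The
Zipf fit constrains b = 0 (the design matrix loses one column), and
`compare_zipf_vs_dgbd` is the nested-model F test of b = 0 with one
numerator degree of freedom (α defaults to 0.05). Zero-count items are
dropped and ranks reindexed 1..N before fitting. Minimum sizes: 3 ranks for
the two-exponent fit, 2 for Zipf, 4 for the comparison (≥ 1 residual df).

One calibration subtlety: when raw count arrays are passed, they are sorted
into rank order by default. If noise is comparable to the spacing between
adjacent expected counts, sorting correlates residuals with rank and
inflates the apparent curvature, so significance calibration
(type-I-error ≈ α) holds for tables whose rank identities are fixed —
`assume_ranked=True` — which is how the calibration simulation is run. On
realistic class tables the spacing is large and the distinction is
immaterial.

## Embeddings and semantic axes

The trainer is a compact word2vec: CBOW (default) or skip-gram with
negative sampling (5 negatives, unigram^0.75 noise distribution),
mini-batched numpy SGD with linearly decayed learning rate (initial 0.025),
logits clipped to ±6, and a fixed RNG seed making training bitwise
deterministic. Mini-batches accumulate scatter updates with `np.add.at`;
with the small vocabularies used here the same row is hit many times per
batch, which is why the learning rate is conservative and logits are
clipped. Defaults `d=300, window=10, epochs=20` mirror the usual
configuration for corpus-scale embedding work; tests and the acceptance
script train smaller spaces (d≈50, window 4, 3 epochs, ~2.5×10⁵ tokens),
which the planted-signal corpora are comfortably within (see below).

A **semantic axis** is the unit-normed mean of v(plus)−v(minus) over an
antonym vocabulary; the four packaged vocabularies are severity (14 pairs),
gender (12), toxicity (3), expense (4). Projection is the cosine of a term
vector with the axis (scale-invariant; dot-product mode behind a flag).
Multiword terms are underscore-joined tokens; an out-of-vocabulary
multiword term falls back to the mean of its in-vocabulary constituents,
and the fallback is recorded on the axis/report. Correlations with
ground-truth attribute tables default to Pearson r with the t-transform
two-sided p; dimensional robustness (pairwise cosine-distance correlation
between two spaces over shared terms) defaults to Spearman ρ, matching how
the two kinds of numbers are conventionally reported.

## NER evaluation protocol

Tokenization is whitespace+punctuation with spans retained (hyphenated
words stay whole). BIO encoding flattens nested mentions to the outermost
(the baseline taggers this protocol serves are flat; inner retention is a
flag) and snaps entity boundaries that fall inside a token outward.
Scoring is exact span+label multiset matching, per class and micro; the
zero-denominator convention is precision = 0 with a `zero_division_hit`
flag on the report. k-fold splits shuffle sorted document ids with a seeded
RNG — stable across platforms — and the dictionary tagger (surface →
majority label, longest case-sensitive left-to-right match) provides an
end-to-end baseline that achieves F1 = 1 on its own unambiguous training
corpus (self-consistency test).

## Synthetic data: what is emulated, what is not

`gen_corpus` builds one-sentence documents (`<entity> <action> <entity> .`)
with surfaces from a packaged pseudo-biomedical lexicon. Planted structure:

* **Class law**: a DGBD(a, b) over the ~40-class inventory under
  `NamedEntity` (defaults a=0.8, b=0.3 — a curved, finite-inventory law of
  the kind annotated class frequencies follow).
* **Composition targets**: defaults 70.4% most-specific and 17.8%
  union-labeled mentions. Category totals (union / leaf / intermediate) are
  planted *exactly* by largest-remainder rounding; classes are assigned to
  ranks so that each category's expected DGBD mass matches its target —
  found by exhaustive subset enumeration (cached) to ~10⁻⁶ — and counts are
  drawn multinomially within category. This keeps the global rank law
  unbiased (the corpus→statistics→fit loop recovers a and b within 3
  Monte-Carlo SE at 10⁵ mentions) while the fractions hit their targets
  exactly. One consequence: the head rank's mass (~0.186) exceeds the
  ambiguity target, so the flagship union class sits at rank 3 rather than
  rank 1 under the default law.
* **Action law**: DGBD over a 20-verb inventory with inflected surfaces and
  negation probability 0.1, chosen so negated actions are common enough to
  appear among the top normalized actions.
* **Disagreement**: a second annotator layer flips labels at one rate and
  grows spans by one adjacent token at another; the grown span still
  overlaps the original, so relaxed matching survives shifts while exact
  matching does not. Expected exact F1 under label flips alone is 1 − q.

Realized tallies (class counts, action counts, fractions) are recorded in
`GroundTruthRecord`, so statistics tests assert integer equality instead of
distributional closeness.

`gen_embedding_direct` plants attributes in the geometry itself: orthonormal
axis directions u_k, pole words at ±u_k, each entity at Σ attr_k·u_k plus an
entity-specific orthogonal filler completing it to unit norm (requires
d ≥ n_axes + n_entities and Σ attr² ≤ 1 per entity), plus isotropic noise.
With zero noise, cosine with the planted axis equals the attribute exactly
(r = 1 to machine precision). `gen_embedding_corpus` emits sentences of one
entity plus context tokens whose plus-vs-minus pole log-odds equal
attribute/mixing (default mixing temperature 0.25, chosen so the pole
probability sweeps ~0.02–0.98 over attributes in [−1, 1] — informative
without hard saturation, which would cap the linear correlation).

What the generators deliberately do **not** emulate: linguistic realism,
multi-sentence discourse, nested mentions, real vocabulary distributions,
polysemy, or annotator biases that correlate across mentions. Passing tests
therefore demonstrate correctness of the machinery on data with known
structure, not performance claims about real corpora.

## Problem sizes and tolerances

* Noiseless rank-law recovery: exponents to 1e−6 (regression on exact log
  values); sampled recovery: mean over 20 seeds within 3 Monte-Carlo SE.
* Type-I calibration: 500 simulations, binomial 3σ band around α = 0.05.
* Planted-axis recovery: r = 1 to 1e−9 at zero noise; mean r nonincreasing
  over noise ∈ {0, 0.1, 0.3, 1}.
* End-to-end embedding loop: 2.5×10⁵-token corpora, d=50, window 4,
  3 epochs; r ≥ 0.9 required on every seed (observed ~0.94–0.96).
* Dimensional robustness: planted d=100 vs d=300 spaces at noise 0.05,
  ρ ≥ 0.9 (observed ~0.999); self-comparison exactly 1; independent random
  spaces within 3 SE of 0 over 100 seeds.
* Statistics-vs-tally equality: exact, over 50 seeded corpora.
* Degenerate inputs raise: empty corpora for fractions (silent zeros mask
  pipeline bugs), < 3 matched terms or zero variance for correlations,
  out-of-vocabulary terms for projections (no silent 0).

## Known limitations

* The word2vec trainer is tuned for small, planted vocabularies; for real
  corpus-scale training its pure-numpy batches would be slow compared to C
  implementations, and it implements no subsampling of frequent words.
* The suffix-rule lemmatizer covers the packaged verb inventory and regular
  inflections only; it is not a general English lemmatizer.
* The flat-TSV corpus reader reconstructs document text only at annotated
  spans (padding elsewhere), which is sufficient for statistics but not for
  re-tokenization of unannotated stretches.
* BIO encoding discards nested mentions (outermost wins); evaluation of
  nested NER requires a different encoding.
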