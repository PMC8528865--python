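# nerotext

Analysis toolkit for **ambiguity-aware named-entity annotation** of
biomedical text: an ontology of *textual* entity classes with union
(ambiguity) classes, standoff corpus I/O and composition statistics,
rank-frequency law fitting, entity-level NER evaluation, and antonym-pair
semantic-axis analysis of word embeddings — with seeded synthetic-data
generators that plant known ground truth for every analysis.

## Who this is for

Text-mining and BioNLP researchers who work with expert-annotated corpora
where mentions cannot always be resolved to a single class. In biomedical
prose, "a mutant hemoglobin α2" may denote a gene or a protein with near
equal probability; forcing annotators to pick one injects noise. The class
hierarchy modeled here instead contains explicit **union classes** such as
`GeneOrProtein` (equivalent to *Gene* ∪ *Protein*) that preserve exactly the
uncertainty present in the text, plus four more: `AminoAcidOrPeptide`,
`QuantityOrMeasurement`, `PublicationOrCitation`, `MedicalProcedureOrDevice`.
Subsumption queries treat a union class as a superclass of each member.

## What it computes

**Corpus composition** (`nero.stats`): class and action frequency tables
with shares and top-*k* mass; the fraction of mentions annotated at the most
specific ontology level; the fraction carrying ambiguity labels; rule-based
action normalization (*binds*, *binding* → *bind*; *does not bind* → *do not
bind*); inter-annotator agreement (span-level F1, exact and relaxed, plus
token-level Cohen's κ).

**Rank-frequency laws** (`nero.rankfit`): class frequencies in corpora are
heavy-tailed; the Discrete Generalized Beta Distribution

```
f(r) = A · (N + 1 − r)^b / r^a ,   r = 1 … N
```

generalizes Zipf's law (b = 0) by letting the tail bend when the class
inventory is finite. Fitting is OLS in log space; a nested-model F test
decides whether the Zipf special case suffices.

**Semantic axes** (`nero.embedding`): a meaning dimension is the unit-normed
mean of antonym difference vectors, v(plus) − v(minus), over a packaged
vocabulary — severity (14 pairs: *harmful/beneficial* … *hazard/routine*),
gender (12), toxicity (3), expense (4). A term's meaning along the axis is
the cosine of its vector with the axis; projections are correlated with
external ground-truth attributes (Pearson r, t-based two-sided p, n).
Embeddings are trained in-package (compact word2vec: CBOW or skip-gram with
negative sampling, deterministic per seed) or loaded from word2vec text
format. Distance correlations across dimensionalities quantify embedding
robustness.

**NER evaluation** (`nero.eval`): BIO encoding, document-level k-fold
splits, exact span+label precision/recall/F1 per class and micro-averaged,
and a dictionary baseline tagger so the train/predict/score loop runs
without external models.

**Synthetic data** (`nero.datasets`): seeded generators for corpora with
planted DGBD class laws, exact specificity/ambiguity fractions, planted
action laws with negation, controlled annotator disagreement; and embedding
spaces (or word2vec training corpora) with attributes planted along the
packaged axes. Generators return the realized tallies so downstream
statistics can be checked for exact integer equality.

## Worked example

```python
from nero import (
    load_ontology, entity_frequencies, specificity_fraction, ambiguity_fraction,
    fit_dgbd, compare_zipf_vs_dgbd, build_axis, correlate_with_groundtruth,
)
from nero.datasets import (
    CorpusGenConfig, PlantedEmbeddingConfig, default_entity_attributes,
    gen_corpus, gen_embedding_direct,
)
from nero.embedding import project_many

onto = load_ontology()
corpus, record = gen_corpus(CorpusGenConfig(n_documents=20_000, seed=1), onto)

freq = entity_frequencies(corpus, onto)
print("most frequent classes:", freq.ranking[:3])
print(f"top class share:       {freq.share(freq.ranking[0]):.3f}")
print(f"specificity fraction:  {specificity_fraction(corpus, onto):.3f}")
print(f"ambiguity fraction:    {ambiguity_fraction(corpus, onto):.3f}")

fit = fit_dgbd(freq)
print(f"DGBD fit: a={fit.a:.3f}, b={fit.b:.3f}, R^2={fit.r_squared:.3f}")
print("Zipf vs DGBD:", compare_zipf_vs_dgbd(freq)["preferred"])

attrs = default_entity_attributes(30, axes=("severity",))
space = gen_embedding_direct(
    PlantedEmbeddingConfig(attributes=attrs, d=100, axes=("severity",),
                           noise=0.5, seed=1)
)
axis = build_axis(space, "severity")
scores = project_many(space, axis, sorted(attrs))
report = correlate_with_groundtruth(
    scores, {t: a["severity"] for t, a in attrs.items()}
)
print(f"severity axis: {axis.pairs_used} antonym pairs, "
      f"r={report.r:.3f} (p={report.p:.2e}, n={report.n})")
```

prints

```
most frequent classes: ['AminoAcid', 'BiologicalProcess', 'GeneOrProtein']
top class share:       0.182
specificity fraction:  0.704
ambiguity fraction:    0.178
DGBD fit: a=0.786, b=0.299, R^2=0.999
Zipf vs DGBD: dgbd
severity axis: 14 antonym pairs, r=0.998 (p=5.41e-35, n=30)
```

The corpus generator planted 70.4% of mentions at the most specific ontology
level, 17.8% with union-class labels, and a DGBD(a=0.8, b=0.3) rank law —
the statistics recover the planted composition exactly and the rank fit
recovers the exponents up to sampling noise. The planted severity axis is
read back from the embedding at r ≈ 1 despite the injected vector noise.

A thin CLI mirrors the library: `nero synth|stats|fitrank|axes|eval|cv`
(see `nero --help`).

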