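"""BIO encoding, entity-level scoring, folds, and the dictionary baseline."""

from collections import Counter

import numpy as np
import pytest

from nero.datasets import CorpusGenConfig, gen_corpus
from nero.eval import (
    BIOSequence,
    DictionaryTagger,
    cross_validate_tagger,
    decode_bio,
    entity_prf,
    kfold_split,
    to_bio,
    to_conll,
)
from nero.io import AnnotatedDocument, Corpus, EntityMention


def doc_with(text, spans):
    ents = [
        EntityMention(f"T{i}", s, e, text[s:e], lab, "A")
        for i, (s, e, lab) in enumerate(spans, start=1)
    ]
    return AnnotatedDocument("d", text, ents)


def corpus_of(docs):
    c = Corpus()
    for d in docs:
        c.add(d)
    return c


def test_to_bio_hand_encoding():
    seq = to_bio(doc_with("p53 binds DNA", [(0, 3, "GeneOrProtein")]))
    assert seq.tokens == ["p53", "binds", "DNA"]
    assert seq.tags == ["B-GeneOrProtein", "O", "O"]


def test_to_bio_no_entities_all_outside():
    seq = to_bio(doc_with("nothing at all", []))
    assert set(seq.tags) == {"O"}


def test_to_bio_multitoken_entity():
    seq = to_bio(doc_with("acute renal failure seen", [(0, 19, "MedicalFinding")]))
    assert seq.tags == ["B-MedicalFinding", "I-MedicalFinding", "I-MedicalFinding", "O"]


def test_nested_entity_flattened_to_outermost():
    seq = to_bio(
        doc_with("growth factor rises", [(0, 13, "Protein"), (7, 13, "Gene")])
    )
    assert seq.tags == ["B-Protein", "I-Protein", "O"]


def test_boundary_snapping_outward():
    # span starts mid-token: the whole token is covered
    seq = to_bio(doc_with("p53 binds", [(1, 3, "Gene")]))
    assert seq.tags == ["B-Gene", "O"]


def test_invalid_bio_sequence_rejected():
    with pytest.raises(ValueError):
        BIOSequence(["a", "b"], [(0, 1), (2, 3)], ["O", "I-Gene"])


def test_bio_round_trip_on_synthetic_corpus(onto):
    corpus, _ = gen_corpus(CorpusGenConfig(n_documents=40, seed=11), onto)
    for doc in corpus.documents.values():
        seq = to_bio(doc)
        decoded = set(decode_bio(seq))
        assert decoded == {(e.start, e.end, e.label) for e in doc.entities}


def test_conll_export_columns():
    out = to_conll(doc_with("p53 binds DNA", [(0, 3, "Gene")]))
    assert out.splitlines()[0] == "p53\tB-Gene"


def test_entity_prf_perfect_prediction(onto):
    corpus, _ = gen_corpus(CorpusGenConfig(n_documents=25, seed=2), onto)
    report = entity_prf(corpus, corpus)
    assert report.micro == {
        "tp": corpus.n_entities(),
        "fp": 0,
        "fn": 0,
        "precision": 1.0,
        "recall": 1.0,
        "f1": 1.0,
    }
    assert all(v["f1"] == 1.0 for v in report.per_class.values())


def test_entity_prf_hand_computed():
    gold = corpus_of(
        [doc_with("aa bb cc dd", [(0, 2, "G"), (3, 5, "G"), (6, 8, "G"), (9, 11, "G")])]
    )
    pred = corpus_of(
        [doc_with("aa bb cc dd", [(0, 2, "G"), (3, 5, "G"), (6, 8, "X")])]
    )
    report = entity_prf(gold, pred)
    assert report.micro["precision"] == pytest.approx(2 / 3)
    assert report.micro["recall"] == pytest.approx(0.5)
    assert report.micro["f1"] == pytest.approx(2 * (2 / 3) * 0.5 / (2 / 3 + 0.5))


def test_entity_prf_empty_prediction_convention():
    gold = corpus_of([doc_with("aa bb", [(0, 2, "G")])])
    pred = corpus_of([doc_with("aa bb", [])])
    report = entity_prf(gold, pred)
    assert report.micro["precision"] == 0.0
    assert report.micro["recall"] == 0.0
    assert report.micro["f1"] == 0.0
    assert report.zero_division_hit


def test_entity_prf_document_mismatch():
    gold = corpus_of([doc_with("aa", [])])
    pred = Corpus()
    pred.add(AnnotatedDocument("other", "aa", []))
    with pytest.raises(ValueError):
        entity_prf(gold, pred)


def _bruteforce_micro(gold_sets, pred_sets):
    tp = fp = fn = 0
    for g, p in zip(gold_sets, pred_sets):
        inter = g & p
        tp += len(inter)
        fp += len(p - g)
        fn += len(g - p)
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f1


def test_entity_prf_equals_bruteforce_oracle_on_random_corpora():
    rng = np.random.default_rng(0)
    labels = ["G", "P", "C"]
    for _ in range(200):
        text = "tok " * 12
        gold_docs, pred_docs, gsets, psets = [], [], [], []
        for doc_i in range(rng.integers(1, 4)):
            spans = sorted({(int(4 * s), int(4 * s + 3)) for s in rng.integers(0, 12, size=rng.integers(0, 5))})
            g = {(s, e, labels[rng.integers(0, 3)]) for s, e in spans}
            spans2 = sorted({(int(4 * s), int(4 * s + 3)) for s in rng.integers(0, 12, size=rng.integers(0, 5))})
            p = {(s, e, labels[rng.integers(0, 3)]) for s, e in spans2}
            gd = doc_with(text, sorted(g))
            pd = doc_with(text, sorted(p))
            gd.id = pd.id = f"d{doc_i}"
            gold_docs.append(gd)
            pred_docs.append(pd)
            gsets.append(g)
            psets.append(p)
        report = entity_prf(corpus_of(gold_docs), corpus_of(pred_docs))
        prec, rec, f1 = _bruteforce_micro(gsets, psets)
        assert report.micro["precision"] == pytest.approx(prec)
        assert report.micro["recall"] == pytest.approx(rec)
        assert report.micro["f1"] == pytest.approx(f1)


def test_adding_correct_prediction_never_decreases_micro_f1():
    text = "aa bb cc dd"
    gold = corpus_of([doc_with(text, [(0, 2, "G"), (3, 5, "P"), (6, 8, "C")])])
    pred_spans = [(0, 2, "G")]
    prev = entity_prf(gold, corpus_of([doc_with(text, pred_spans)])).micro["f1"]
    for extra in [(3, 5, "P"), (6, 8, "C")]:
        pred_spans.append(extra)
        cur = entity_prf(gold, corpus_of([doc_with(text, pred_spans)])).micro["f1"]
        assert cur >= prev
        prev = cur


# ---------------------------------------------------------------------------
# folds


def test_kfold_partition_properties(onto):
    corpus, _ = gen_corpus(CorpusGenConfig(n_documents=100, seed=4), onto)
    folds = kfold_split(corpus, k=10, seed=1)
    tests = [set(t) for _, t in folds]
    assert all(len(t) == 10 for t in tests)
    assert set().union(*tests) == set(corpus.documents)
    for i in range(10):
        for j in range(i + 1, 10):
            assert not tests[i] & tests[j]
    for train, test in folds:
        assert set(train) | set(test) == set(corpus.documents)
        assert not set(train) & set(test)


def test_kfold_deterministic_and_balanced(onto):
    corpus, _ = gen_corpus(CorpusGenConfig(n_documents=10, seed=4), onto)
    f1 = kfold_split(corpus, k=3, seed=9)
    f2 = kfold_split(corpus, k=3, seed=9)
    assert f1 == f2
    sizes = sorted(len(t) for _, t in f1)
    assert sizes == [3, 3, 4]


def test_kfold_k_exceeding_documents(onto):
    corpus, _ = gen_corpus(CorpusGenConfig(n_documents=5, seed=4), onto)
    with pytest.raises(ValueError):
        kfold_split(corpus, k=6)


# ---------------------------------------------------------------------------
# dictionary tagger


def test_tagger_majority_label():
    train = corpus_of([
        doc_with("p53 p53 p53 p53", [(0, 3, "GeneOrProtein"), (4, 7, "GeneOrProtein"),
                                     (8, 11, "GeneOrProtein"), (12, 15, "Gene")]),
    ])
    tagger = DictionaryTagger().fit(train)
    assert tagger.lexicon_["p53"] == "GeneOrProtein"
    test_doc = AnnotatedDocument("t", "p53 rises", [])
    preds = tagger.predict_document(test_doc)
    assert [(p.start, p.end, p.label) for p in preds] == [(0, 3, "GeneOrProtein")]


def test_tagger_unseen_surface_gives_no_prediction():
    tagger = DictionaryTagger().fit(corpus_of([doc_with("p53", [(0, 3, "Gene")])]))
    assert tagger.predict_document(AnnotatedDocument("t", "BRCA1", [])) == []


def test_tagger_longest_match_wins():
    train = corpus_of([
        doc_with("growth factor factor", [(0, 13, "Protein"), (14, 20, "Gene")])
    ])
    tagger = DictionaryTagger().fit(train)
    preds = tagger.predict_document(AnnotatedDocument("t", "growth factor", []))
    assert [(p.start, p.end, p.label) for p in preds] == [(0, 13, "Protein")]


def test_tagger_self_consistency_f1_one(onto):
    """On its own training corpus with unambiguous surfaces, F1 == 1."""
    corpus, _ = gen_corpus(CorpusGenConfig(n_documents=60, seed=8), onto)
    surface_labels = Counter()
    for d in corpus.documents.values():
        for e in d.entities:
            surface_labels[(e.text, e.label)] += 1
    surfaces = Counter(s for s, _ in surface_labels)
    assert all(v == 1 for v in surfaces.values()), "fixture must be unambiguous"
    tagger = DictionaryTagger().fit(corpus)
    report = entity_prf(corpus, tagger.predict(corpus))
    assert report.micro["f1"] == 1.0


def test_cross_validated_tagger_runs(onto):
    corpus, _ = gen_corpus(CorpusGenConfig(n_documents=50, seed=8), onto)
    report = cross_validate_tagger(corpus, k=5, seed=0)
    assert report.n_folds == 5
    assert 0.0 <= report.micro["f1"] <= 1.0
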