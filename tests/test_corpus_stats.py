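"""Composition statistics: frequencies, shares, specificity/ambiguity,
action normalization, agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nero.datasets import CorpusGenConfig, gen_corpus, gen_second_annotator
from nero.io import AnnotatedDocument, Corpus, EntityMention, EventMention
from nero.stats import (
    FrequencyTable,
    action_frequencies,
    ambiguity_fraction,
    entity_frequencies,
    inter_annotator_agreement,
    normalize_action,
    share,
    specificity_fraction,
    top_k_share,
)


def corpus_with_labels(labels):
    corpus = Corpus()
    ents = [
        EntityMention(f"T{i}", 2 * i, 2 * i + 1, "x", lab, "A")
        for i, lab in enumerate(labels)
    ]
    text = "x " * len(labels)
    corpus.add(AnnotatedDocument("d", text, ents))
    return corpus


def test_entity_frequencies_direct(onto):
    corpus = corpus_with_labels(["GeneOrProtein", "GeneOrProtein", "Cell"])
    ft = entity_frequencies(corpus, onto)
    assert ft.counts == {"GeneOrProtein": 2, "Cell": 1} and ft.total == 3
    assert share(ft, "GeneOrProtein") == pytest.approx(2 / 3)
    assert share(ft, "Process") == 0.0


def test_entity_frequencies_rollup_ancestor_closure(onto):
    corpus = corpus_with_labels(["GeneOrProtein", "GeneOrProtein", "Cell"])
    ft = entity_frequencies(corpus, onto, rollup=True)
    assert ft.counts["NamedEntity"] == 3
    assert ft.counts["Chemical"] == 2
    assert ft.counts["AnatomicalPart"] == 1


def test_rollup_root_conservation(small_corpus, onto):
    corpus, record = small_corpus
    ft = entity_frequencies(corpus, onto, rollup=True)
    assert ft.counts[onto.root] == record.n_entities


def test_frequencies_match_generator_tally(small_corpus, onto):
    corpus, record = small_corpus
    ft = entity_frequencies(corpus, onto)
    assert ft.counts == dict(record.class_counts)


def test_share_undefined_on_empty_table():
    with pytest.raises(ValueError):
        FrequencyTable({}).share("a")


def test_specificity_enumeration(onto):
    corpus = corpus_with_labels(["Gene", "GeneOrProtein", "Cell", "Process"])
    assert specificity_fraction(corpus, onto) == pytest.approx(0.5)


def test_specificity_all_leaf_corpus(onto):
    corpus = corpus_with_labels(["Gene", "Cell", "Drug"])
    assert specificity_fraction(corpus, onto) == 1.0


def test_ambiguity_enumeration(onto):
    corpus = corpus_with_labels(["GeneOrProtein", "Gene", "Protein", "Cell"])
    assert ambiguity_fraction(corpus, onto) == pytest.approx(0.25)
    assert ambiguity_fraction(corpus_with_labels(["Gene", "Cell"]), onto) == 0.0


def test_union_complement_contract(small_corpus, onto):
    corpus, _ = small_corpus
    ambi = ambiguity_fraction(corpus, onto)
    non_union = sum(
        1
        for d in corpus.documents.values()
        for e in d.entities
        if not onto.classes[e.label].is_union
    ) / corpus.n_entities()
    assert ambi + non_union == pytest.approx(1.0)


def test_fractions_raise_on_empty_corpus(onto):
    with pytest.raises(ValueError):
        specificity_fraction(Corpus(), onto)
    with pytest.raises(ValueError):
        ambiguity_fraction(Corpus(), onto)


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("binds", "bind"),
        ("binding", "bind"),
        ("bound", "bind"),
        ("Bind", "bind"),
        ("does not bind", "do not bind"),
        ("did not affect", "do not affect"),
        ("do not inhibit", "do not inhibit"),
        ("associated with", "associate with"),
        ("occurs in presence of", "occur in presence of"),
        ("phosphorylates", "phosphorylate"),
        ("mediating", "mediate"),
        ("carries", "carry"),
    ],
)
def test_normalize_action(raw, expected):
    assert normalize_action(raw) == expected


@given(
    st.sampled_from(
        [
            "bind", "binds", "binding", "bound", "does not bind", "inhibits",
            "activated", "not affect", "occurring", "expresses", "lacks",
            "no increase", "triggered", "sing", "bring", "unknownverbiage",
        ]
    )
)
@settings(deadline=None)
def test_normalize_action_idempotent(form):
    once = normalize_action(form)
    assert normalize_action(once) == once


def test_action_frequencies_normalized(onto):
    corpus = Corpus()
    for i, form in enumerate(["binds", "bind", "binding"]):
        text = f"x {form} y"
        corpus.add(
            AnnotatedDocument(
                f"d{i}",
                text,
                [
                    EntityMention("T1", 0, 1, "x", "Gene", "A"),
                    EntityMention("T2", len(text) - 1, len(text), "y", "Gene", "A"),
                ],
                [
                    EventMention(
                        "E1", 2, 2 + len(form), form,
                        (("Arg1", "T1"), ("Arg2", "T2")), "asserted", "A",
                    )
                ],
            )
        )
    assert action_frequencies(corpus, normalized=True).counts == {"bind": 3}
    raw = action_frequencies(corpus, normalized=False)
    assert raw.total == 3 and len(raw.counts) == 3


def test_action_tally_matches_generator(small_corpus):
    corpus, record = small_corpus
    assert action_frequencies(corpus, normalized=True).counts == dict(
        record.action_counts_normalized
    )
    assert action_frequencies(corpus, normalized=False).counts == dict(
        record.action_counts_raw
    )


def test_top_k_share_cases():
    ft = FrequencyTable({"a": 5, "b": 3, "c": 2})
    assert top_k_share(ft, 2) == pytest.approx(0.8)
    assert top_k_share(ft, 99) == 1.0
    assert top_k_share(FrequencyTable({"only": 4}), 1) == 1.0


@given(
    st.dictionaries(
        st.text(alphabet="abcdefg", min_size=1, max_size=3),
        st.integers(min_value=0, max_value=50),
        min_size=1,
    ).filter(lambda d: sum(d.values()) > 0)
)
@settings(deadline=None, max_examples=50)
def test_top_k_share_monotone_and_exhaustive(counts):
    ft = FrequencyTable(counts)
    shares = [ft.top_k_share(k) for k in range(1, len(ft.ranking) + 1)]
    assert all(b >= a - 1e-12 for a, b in zip(shares, shares[1:]))
    assert shares[-1] == pytest.approx(1.0)
    assert sum(ft.share(i) for i in ft.ranking) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# agreement


def test_identical_layers_agree_perfectly(onto):
    corpus, _ = gen_corpus(CorpusGenConfig(n_documents=20, seed=3), onto)
    doubled, _ = gen_second_annotator(corpus, 0.0, 0.0, seed=0, onto=onto)
    report = inter_annotator_agreement(doubled)
    assert report.pooled_f1 == 1.0
    assert report.kappa_token == 1.0
    for scores in report.per_pair.values():
        assert scores["exact"]["f1"] == 1.0
        assert scores["relaxed"]["f1"] == 1.0


def test_disjoint_layers_zero_f1():
    corpus = Corpus()
    corpus.add(
        AnnotatedDocument(
            "d",
            "aa bb",
            [
                EntityMention("T1", 0, 2, "aa", "Gene", "A"),
                EntityMention("T1", 3, 5, "bb", "Cell", "B"),
            ],
        )
    )
    report = inter_annotator_agreement(corpus)
    assert report.pooled_f1 == 0.0


def test_agreement_symmetric_in_f1(onto):
    corpus, _ = gen_corpus(CorpusGenConfig(n_documents=30, seed=5), onto)
    doubled, _ = gen_second_annotator(corpus, 0.2, 0.1, seed=9, onto=onto)
    report = inter_annotator_agreement(doubled)
    for scores in report.per_pair.values():
        ex = scores["exact"]
        # swapping annotators transposes precision and recall; F1 is symmetric
        assert ex["f1"] == pytest.approx(
            2 * ex["recall"] * ex["precision"] / (ex["recall"] + ex["precision"])
            if ex["recall"] + ex["precision"]
            else 0.0
        )


def test_label_flip_rate_sets_expected_f1(onto):
    f1s = []
    for seed in range(10):
        corpus, _ = gen_corpus(CorpusGenConfig(n_documents=200, seed=seed), onto)
        doubled, rec = gen_second_annotator(
            corpus, label_flip_rate=0.1, span_shift_rate=0.0, seed=seed + 100,
            onto=onto,
        )
        report = inter_annotator_agreement(doubled)
        f1s.append(report.pooled_f1)
        # exact realized equality: matches are exactly the unflipped mentions
        assert report.pooled_f1 == pytest.approx(
            1 - rec.n_label_flipped / rec.n_entities
        )
    assert np.mean(f1s) == pytest.approx(0.9, abs=0.02)


def test_agreement_requires_pairs(onto):
    corpus, _ = gen_corpus(CorpusGenConfig(n_documents=5, seed=1), onto)
    with pytest.raises(ValueError):
        inter_annotator_agreement(corpus)
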