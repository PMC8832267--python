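import numpy as np
import pytest

from conftest import make_corpus
from vapenet.classifier import (
    CONJUNCTION,
    PHRASE,
    classify_corpus,
    classify_doc,
    default_ruleset,
    match_pattern,
    summarize_by_item,
)
from vapenet.corpus import dedup_across_items, dedup_across_profiles
from vapenet.synthetic import GeneratorConfig, generate_corpus
from vapenet.textproc import background_vocabulary, preprocess
from vapenet.util import StageError, ValidationError

RS = default_ruleset()
DEVICE, ELIQUID, CANNABIS = RS.scored_classes()
OTHER = RS.fallback_class
BG = background_vocabulary()


def doc_of(text):
    return preprocess(text, RS.text_config)


def test_default_ruleset_structure():
    assert len(RS.classes) == 4
    assert RS.patterns[OTHER] == []
    drip_tip = [p for p in RS.patterns[DEVICE] if p.raw == "drip tip"]
    assert drip_tip[0].kind == PHRASE and drip_tip[0].terms == ("drip", "tip")
    conj = [p for p in RS.patterns[DEVICE] if p.kind == CONJUNCTION]
    assert {tuple(sorted(p.terms)) for p in conj} == {("device", "ecig"), ("device", "vape")}
    # printed duplicates collapse to one pattern each
    assert sum(1 for p in RS.patterns[DEVICE] if p.terms == ("drip",)) == 1


def test_match_literal_and_contiguity():
    thc = next(p for p in RS.patterns[CANNABIS] if p.raw == "THC")
    assert match_pattern(doc_of("best thc cartridge"), thc)
    drip_tip = next(p for p in RS.patterns[DEVICE] if p.raw == "drip tip")
    assert not match_pattern(doc_of("drip coffee tip"), drip_tip)
    assert match_pattern(doc_of("new drip tip review"), drip_tip)


def test_match_conjunction_anywhere():
    conj = next(p for p in RS.patterns[DEVICE] if set(p.terms) == {"ecig", "device"})
    assert match_pattern(doc_of("this device is my favorite ecig"), conj)
    assert not match_pattern(doc_of("this ecig is great"), conj)


def test_whole_lemma_only_no_substrings():
    vc = classify_doc(doc_of("potato salad with modern flavor"), RS)
    assert vc.exclusive_label == OTHER and not vc.matched_classes


def test_tie_break_by_class_order():
    vc = classify_doc(doc_of("thc cartridge"), RS)
    assert vc.matched_classes == {DEVICE, CANNABIS}
    assert vc.hits[DEVICE] == 1 and vc.hits[CANNABIS] == 1
    assert vc.exclusive_label == DEVICE


def test_no_match_falls_back():
    vc = classify_doc(doc_of("morning garden river window"), RS)
    assert vc.exclusive_label == OTHER and vc.matched_classes == set()


def test_phrase_subsumption_keeps_own_class_only():
    vc = classify_doc(doc_of("premium vape juice flavors"), RS)
    assert vc.matched_classes == {ELIQUID}
    vc = classify_doc(doc_of("vape juice and a vape"), RS)
    assert vc.matched_classes == {ELIQUID, DEVICE}  # free-standing "vape" counts


def test_full_lexicon_single_indicator_regression():
    """Every shipped indicator, alone in background text, fires exactly its
    own class."""
    bg_pad = " ".join(BG[:8])
    for cls in RS.scored_classes():
        for raw in RS.raw_indicators[cls]:
            words = " ".join(raw.replace("+", " ").split())
            vc = classify_doc(doc_of(f"{bg_pad} {words} {bg_pad}"), RS)
            assert vc.matched_classes == {cls}, (raw, vc.matched_classes)
            assert vc.exclusive_label == cls


def test_monotonicity_adding_indicator_token():
    """Appending a single-token indicator never removes a matched class."""
    rng = np.random.default_rng(5)
    single_tokens = [
        p.raw for c in RS.scored_classes() for p in RS.patterns[c]
        if p.kind == PHRASE and len(p.terms) == 1
    ]
    for _ in range(40):
        base_words = list(rng.choice(BG, size=6))
        extra = [str(rng.choice(single_tokens)) for _ in range(rng.integers(0, 3))]
        text = " ".join(base_words + extra)
        before = classify_doc(doc_of(text), RS).matched_classes
        appended = text + " " + str(rng.choice(single_tokens))
        after = classify_doc(doc_of(appended), RS).matched_classes
        assert before <= after


def test_exclusive_label_function_of_hits():
    """Shuffling a transcript of single-lemma indicators leaves the label
    unchanged."""
    rng = np.random.default_rng(9)
    words = ["thc", "kush", "dab", "juul", "morning", "garden"]
    base = classify_doc(doc_of(" ".join(words)), RS)
    for _ in range(10):
        rng.shuffle(words)
        shuffled = classify_doc(doc_of(" ".join(words)), RS)
        assert shuffled.hits == base.hits
        assert shuffled.exclusive_label == base.exclusive_label


def test_classify_corpus_requires_fully_deduped():
    corpus = make_corpus({"a": {"p": ["v"]}})
    with pytest.raises(StageError):
        classify_corpus(corpus)


def test_summarize_all_device_item():
    corpus = make_corpus({"a": {"p": [f"v{i}" for i in range(10)]}})
    deduped, _ = dedup_across_profiles(corpus)
    labels = {
        f"v{i}": classify_doc(doc_of("juul review"), RS, video_id=f"v{i}")
        for i in range(10)
    }
    summary = summarize_by_item(deduped, labels, RS)
    assert summary.percentages["a"][DEVICE] == 100.0
    assert summary.percentages["a"][OTHER] == 0.0


def test_summarize_unclassified_video_rejected():
    corpus = make_corpus({"a": {"p": ["v1"]}})
    deduped, _ = dedup_across_profiles(corpus)
    with pytest.raises(ValidationError):
        summarize_by_item(deduped, {}, RS)


def test_summary_percentages_sum_to_100():
    cfg = GeneratorConfig(
        n_items=3, n_profiles=2, results_per_item=40, n_themes=2, videos_per_theme=80,
        item_theme_mixtures=[[1, 0], [0.5, 0.5], [0, 1]],
        class_given_theme=[[0.5, 0.2, 0.2, 0.1], [0.2, 0.5, 0.2, 0.1]],
        indicator_density=0.8, transcript_length=40, seed=3,
    )
    corpus, _ = generate_corpus(cfg)
    profile_deduped, _ = dedup_across_profiles(corpus)
    fully_deduped, _ = dedup_across_items(profile_deduped)
    labels = classify_corpus(fully_deduped, RS)
    summary = summarize_by_item(profile_deduped, labels, RS)
    for item, pcts in summary.percentages.items():
        assert abs(sum(pcts.values()) - 100.0) <= 2.0  # integer rounding slack
        assert sum(summary.counts[item].values()) == len(
            profile_deduped.video_ids_of(item)
        )


def test_class_mix_recovery_matches_generator_expectation():
    """At high density the per-item class mix tracks the generator's
    class_given_theme mixture within 3 binomial SEs."""
    cfg = GeneratorConfig(
        n_items=1, n_profiles=1, results_per_item=300, n_themes=1, videos_per_theme=400,
        item_theme_mixtures=[[1.0]],
        class_given_theme=[[0.5, 0.2, 0.2, 0.1]],
        indicator_density=0.9, transcript_length=60, seed=17,
    )
    corpus, gt = generate_corpus(cfg)
    profile_deduped, _ = dedup_across_profiles(corpus)
    fully_deduped, _ = dedup_across_items(profile_deduped)
    labels = classify_corpus(fully_deduped, RS)
    summary = summarize_by_item(profile_deduped, labels, RS)
    n = 300
    for cls, expected in zip(RS.classes, [0.5, 0.2, 0.2, 0.1]):
        observed = summary.counts[corpus.items[0]][cls] / n
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) <= 3 * se, (cls, observed)
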