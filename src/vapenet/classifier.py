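"""Lexicon rule-based multi-label classification of video text.

Four classes: "e-cigarette device", "e-liquid", "cannabis vaping products"
and the fallback "other e-cigarette videos".  Indicators are shipped as an
editable plain-text rules file (``data/box1.rules``): literal patterns match
as contiguous lemma phrases (a one-word pattern therefore matches whole
lemmas only, so "pot" never fires inside "potato"), and ``a + b``
conjunctions match when every term occurs anywhere in the document.

A matched literal only counts where it has at least one occurrence that is
not strictly inside a longer matched phrase: "vape juice" fires the e-liquid
phrase but not the device indicator "vape", while a free-standing "vape"
elsewhere in the document still counts.  Videos can carry several classes;
for pie-style summaries an exclusive label is derived as the class with the
most distinct matched patterns, ties broken by class order, no match falling
back to "other e-cigarette videos".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .corpus import STAGE_FULLY_DEDUPED, STAGE_PROFILE_DEDUPED, SearchCorpus
from .textproc import LemmaDoc, TextConfig, lemma_phrase, preprocess
from .util import ConfigError, StageError, ValidationError, round_half_up

PHRASE = "phrase"
CONJUNCTION = "conjunction"


@dataclass(frozen=True)
class Pattern:
    kind: str  # PHRASE or CONJUNCTION
    terms: tuple[str, ...]  # lemma sequence (phrase) or lemma set (conjunction)
    raw: str  # source text, for reports

    def __post_init__(self) -> None:
        if not self.terms or any(not t for t in self.terms):
            raise ValidationError(f"empty pattern from {self.raw!r}")


@dataclass
class RuleSet:
    """Ordered classes with their indicator patterns; last class with no
    indicators is the fallback."""

    classes: list[str]
    patterns: dict[str, list[Pattern]]
    raw_indicators: dict[str, list[str]]
    text_config: TextConfig = field(default_factory=TextConfig)

    def __post_init__(self) -> None:
        if len(set(self.classes)) != len(self.classes):
            raise ValidationError("class names must be unique")
        empties = [c for c in self.classes if not self.patterns.get(c)]
        if len(empties) != 1:
            raise ValidationError("exactly one (fallback) class must have no indicators")
        self.fallback_class = empties[0]

    def scored_classes(self) -> list[str]:
        return [c for c in self.classes if c != self.fallback_class]


def _parse_pattern(line: str, config: TextConfig) -> Pattern:
    raw = line.strip().strip('"')
    if "+" in raw:
        terms = tuple(
            lemma_phrase([part.strip()], config)[0] for part in raw.split("+") if part.strip()
        )
        return Pattern(kind=CONJUNCTION, terms=terms, raw=raw)
    return Pattern(kind=PHRASE, terms=lemma_phrase(raw.split(), config), raw=raw)


def load_ruleset(path: str | Path | None = None, config: TextConfig | None = None) -> RuleSet:
    """Parse a rules file; ``None`` loads the packaged default lexicon."""
    config = config or TextConfig()
    if path is None:
        text = resources.files("vapenet.data").joinpath("box1.rules").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    classes: list[str] = []
    patterns: dict[str, list[Pattern]] = {}
    raw_ind: dict[str, list[str]] = {}
    current: str | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1].strip()
            if current in patterns:
                raise ConfigError(f"duplicate class section {current!r}")
            classes.append(current)
            patterns[current] = []
            raw_ind[current] = []
            continue
        if current is None:
            raise ConfigError("indicator pattern before any class section")
        pat = _parse_pattern(line, config)
        if pat.terms in {p.terms for p in patterns[current]}:
            continue  # printed lexicons repeat a few entries; keep one
        patterns[current].append(pat)
        raw_ind[current].append(line.strip().strip('"'))
    return RuleSet(classes=classes, patterns=patterns, raw_indicators=raw_ind, text_config=config)


def default_ruleset(config: TextConfig | None = None) -> RuleSet:
    return load_ruleset(None, config)


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


def _phrase_spans(tokens: tuple[str, ...], terms: tuple[str, ...]) -> list[tuple[int, int]]:
    k = len(terms)
    return [
        (i, i + k) for i in range(len(tokens) - k + 1) if tokens[i : i + k] == terms
    ]


def match_pattern(doc: LemmaDoc, pattern: Pattern) -> bool:
    """Does the pattern match the document at all (no subsumption filtering)?"""
    if pattern.kind == CONJUNCTION:
        present = set(doc.tokens)
        return all(term in present for term in pattern.terms)
    return bool(_phrase_spans(doc.tokens, pattern.terms))


@dataclass
class VideoClassification:
    video_id: str
    matched_classes: set[str]
    hits: dict[str, int]
    exclusive_label: str


def classify_doc(doc: LemmaDoc, ruleset: RuleSet, video_id: str = "") -> VideoClassification:
    """Multi-label classification with longer-phrase subsumption.

    Hits count distinct matched patterns per class.  A literal phrase is
    credited only if at least one of its occurrences is not strictly inside
    an occurrence of a longer matched phrase (of any class); conjunctions
    are position-free and never subsume or get subsumed.
    """
    matched: list[tuple[str, Pattern, list[tuple[int, int]]]] = []
    for cls in ruleset.scored_classes():
        for pat in ruleset.patterns[cls]:
            if pat.kind == CONJUNCTION:
                if match_pattern(doc, pat):
                    matched.append((cls, pat, []))
            else:
                spans = _phrase_spans(doc.tokens, pat.terms)
                if spans:
                    matched.append((cls, pat, spans))
    longer_spans = [
        (s, e) for _, pat, spans in matched if pat.kind == PHRASE for (s, e) in spans
    ]
    hits: dict[str, int] = {c: 0 for c in ruleset.scored_classes()}
    for cls, pat, spans in matched:
        if pat.kind == PHRASE:
            free = any(
                not any(qs <= s and e <= qe and (qe - qs) > (e - s) for qs, qe in longer_spans)
                for s, e in spans
            )
            if not free:
                continue
        hits[cls] += 1
    matched_classes = {c for c, n in hits.items() if n > 0}
    if matched_classes:
        exclusive = max(
            ruleset.scored_classes(),
            key=lambda c: (hits[c], -ruleset.classes.index(c)),
        )
    else:
        exclusive = ruleset.fallback_class
    return VideoClassification(
        video_id=video_id,
        matched_classes=matched_classes,
        hits={c: n for c, n in hits.items() if n > 0},
        exclusive_label=exclusive,
    )


def classify_corpus(
    corpus: SearchCorpus, ruleset: RuleSet | None = None
) -> dict[str, VideoClassification]:
    """Classify every unique video of a fully deduplicated corpus once, from
    title + description + transcript."""
    if corpus.stage != STAGE_FULLY_DEDUPED:
        raise StageError(
            f"classification expects a fully_deduped corpus, got {corpus.stage!r}"
        )
    ruleset = ruleset or default_ruleset()
    out: dict[str, VideoClassification] = {}
    for video_id, rec in corpus.record_index().items():
        doc = preprocess(rec.text(), ruleset.text_config)
        out[video_id] = classify_doc(doc, ruleset, video_id=video_id)
    return out


# ---------------------------------------------------------------------------
# Per-item summaries (pie-chart analogue)
# ---------------------------------------------------------------------------


@dataclass
class ClassificationSummary:
    classes: list[str]
    counts: dict[str, dict[str, int]]  # item -> class -> video count
    percentages: dict[str, dict[str, float]]  # item -> class -> integer percent

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "item": item,
                "class": cls,
                "count": self.counts[item][cls],
                "percent": self.percentages[item][cls],
            }
            for item in self.counts
            for cls in self.classes
        ]
        return pd.DataFrame(rows, columns=["item", "class", "count", "percent"])


def summarize_by_item(
    corpus: SearchCorpus,
    classifications: dict[str, VideoClassification],
    ruleset: RuleSet | None = None,
) -> ClassificationSummary:
    """Percentage of each item's videos per exclusive class.

    The corpus is the profile-deduplicated one, so a video retrieved by
    several items counts toward each of those items' denominators while
    carrying the single classification it received after full dedup.
    Percentages are reported as integers (round-half-up).
    """
    if corpus.stage != STAGE_PROFILE_DEDUPED:
        raise StageError(
            f"summaries expect a profile_deduped corpus, got {corpus.stage!r}"
        )
    ruleset = ruleset or default_ruleset()
    counts: dict[str, dict[str, int]] = {}
    percentages: dict[str, dict[str, float]] = {}
    for item in corpus.items:
        ids = corpus.video_ids_of(item)
        per_class = {c: 0 for c in ruleset.classes}
        for vid in ids:
            if vid not in classifications:
                raise ValidationError(f"video {vid!r} of item {item!r} is unclassified")
            per_class[classifications[vid].exclusive_label] += 1
        counts[item] = per_class
        total = len(ids)
        percentages[item] = {
            c: (round_half_up(100.0 * n / total) if total else 0.0)
            for c, n in per_class.items()
        }
    return ClassificationSummary(
        classes=list(ruleset.classes), counts=counts, percentages=percentages
    )


def write_classification_csv(
    classifications: dict[str, VideoClassification], path: str | Path
) -> None:
    rows = [
        {
            "video_id": vc.video_id,
            "matched_classes": ";".join(sorted(vc.matched_classes)),
            "hits": ";".join(f"{c}={n}" for c, n in sorted(vc.hits.items())),
            "exclusive_label": vc.exclusive_label,
        }
        for vc in sorted(classifications.values(), key=lambda v: v.video_id)
    ]
    pd.DataFrame(rows, columns=["video_id", "matched_classes", "hits", "exclusive_label"]).to_csv(
        path, index=False
    )
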