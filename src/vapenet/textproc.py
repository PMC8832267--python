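"""Deterministic transcript preprocessing.

The pipeline lowercases, strips punctuation (keeping intra-token hyphens and
digits so tokens like ``e-cigarette``, ``v2`` and ``21st`` survive), removes
stop words on surface forms, then lemmatizes each remaining token.  The
default lemmatizer is a small dependency-free suffix-rule stemmer tuned so
the vaping lexicon's conjugations collapse correctly ("vaping" -> "vape",
"mods" -> "mod", "disposables" -> "disposable"); an industrial NLP backend
(e.g. spaCy) can be registered as an alternative backend at run time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable

from .util import ConfigError

_VOWELS = "aeiou"

# Irregular forms that the suffix rules would mangle; all lexicon-relevant.
_LEMMA_EXCEPTIONS = {
    "vaping": "vape",
    "vaped": "vape",
    "vapes": "vape",
    "juuling": "juul",
    "dripping": "drip",
    "dripped": "drip",
    "dabbing": "dab",
    "dabbed": "dab",
    "modding": "mod",
    "modded": "mod",
    "podding": "pod",
    "waxes": "wax",
    "hashes": "hash",
    "ohms": "ohm",
    "pens": "pen",
    "pots": "pot",
    "tips": "tip",
    "bars": "bar",
}

_TOKEN_CLEAN = re.compile(r"[^a-z0-9-]+")


def _load_wordlist(name: str) -> list[str]:
    """Read a packaged one-word-per-line list, ignoring comments and blanks."""
    text = resources.files("vapenet.data").joinpath(name).read_text("utf-8")
    seen: dict[str, None] = {}
    for line in text.splitlines():
        word = line.strip()
        if word and not word.startswith("#"):
            seen.setdefault(word.lower(), None)
    return list(seen)


def default_stopwords() -> frozenset[str]:
    return frozenset(_load_wordlist("stopwords.txt"))


def background_vocabulary() -> list[str]:
    """Packaged background vocabulary used by the synthetic corpus generator;
    disjoint, after lemmatization, from every classifier indicator term."""
    return _load_wordlist("background_vocab.txt")


def _lemma_once(tok: str) -> str:
    if tok in _LEMMA_EXCEPTIONS:
        return _LEMMA_EXCEPTIONS[tok]
    if len(tok) >= 5 and tok.endswith("ies"):
        return tok[:-3] + "y"
    if len(tok) >= 5 and tok.endswith(("ches", "shes", "xes", "sses", "zes")):
        return tok[:-2]
    if len(tok) >= 4 and tok.endswith("s") and not tok.endswith(("ss", "us", "is")):
        return tok[:-1]
    for suffix in ("ing", "ed"):
        if tok.endswith(suffix):
            stem = tok[: -len(suffix)]
            if len(stem) < 3 or not any(c in _VOWELS for c in stem):
                return tok
            if stem[-1] in _VOWELS:  # "bleed", "agreed": not an inflection
                return tok
            if (
                stem[-1] == stem[-2]
                and stem[-1] not in _VOWELS
                and not stem.endswith(("ll", "ss", "zz"))
            ):
                return stem[:-1]
            if stem[-2] in _VOWELS and stem[-1] not in "wxy" and stem[-3] not in _VOWELS:
                return stem + "e"
            return stem
    return tok


def lemmatize_token(token: str) -> str:
    """Rule lemmatizer for a single lowercase token.  Idempotent.

    Ordered rules: exception table; -ies -> -y; -es after sibilants; plural
    -s strip (length guard, never after ss/us/is); -ing and -ed strip with
    consonant undoubling and silent-e restoration ("vaping" -> "vap" ->
    "vape").  Rules are applied until a fixed point is reached, so
    lemmatize(lemmatize(x)) == lemmatize(x) by construction.
    """
    prev, tok = None, token
    while tok != prev:
        prev, tok = tok, _lemma_once(tok)
    return tok


# Registry of lemmatizer backends; callers may register e.g. a spaCy wrapper.
_LEMMATIZERS: dict[str, Callable[[str], str]] = {"rule": lemmatize_token}


def register_lemmatizer(name: str, fn: Callable[[str], str]) -> None:
    _LEMMATIZERS[name] = fn


@dataclass(frozen=True)
class TextConfig:
    """Names the stop list and lemmatizer backend; 'default'/'rule' are packaged."""

    stoplist: str = "default"
    lemmatizer: str = "rule"
    extra_stopwords: frozenset[str] = field(default_factory=frozenset)

    def resolve(self) -> tuple[frozenset[str], Callable[[str], str]]:
        if self.stoplist == "default":
            stops = default_stopwords()
        elif self.stoplist == "none":
            stops = frozenset()
        else:
            raise ConfigError(f"unknown stop list {self.stoplist!r}")
        if self.lemmatizer not in _LEMMATIZERS:
            raise ConfigError(f"unknown lemmatizer backend {self.lemmatizer!r}")
        return stops | self.extra_stopwords, _LEMMATIZERS[self.lemmatizer]


@dataclass(frozen=True)
class LemmaDoc:
    """A preprocessed document: ordered lemmas plus bookkeeping counts."""

    tokens: tuple[str, ...]
    n_raw_tokens: int
    n_removed_stopwords: int


def tokenize(text: str) -> list[str]:
    """Lowercase, strip punctuation except intra-token hyphens/digits, split."""
    cleaned = _TOKEN_CLEAN.sub(" ", text.lower())
    return [t for t in (tok.strip("-") for tok in cleaned.split()) if t]


def preprocess(text: str, config: TextConfig | None = None) -> LemmaDoc:
    """Tokenize, remove stop words (surface forms), lemmatize.  Deterministic."""
    config = config or TextConfig()
    stops, lemmatizer = config.resolve()
    raw = tokenize(text)
    kept = [t for t in raw if t not in stops]
    lemmas = tuple(lemmatizer(t) for t in kept)
    return LemmaDoc(
        tokens=lemmas,
        n_raw_tokens=len(raw),
        n_removed_stopwords=len(raw) - len(kept),
    )


def lemma_phrase(words: Iterable[str], config: TextConfig | None = None) -> tuple[str, ...]:
    """Lemma sequence of a lexicon pattern: tokenized and lemmatized with the
    same backend as documents but with no stop-word removal, so every pattern
    keeps all of its words."""
    config = config or TextConfig()
    _, lemmatizer = config.resolve()
    out: list[str] = []
    for word in words:
        out.extend(lemmatizer(t) for t in tokenize(word))
    return tuple(out)
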