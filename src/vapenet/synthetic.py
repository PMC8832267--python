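"""Seeded synthetic search-result corpora with planted overlap structure.

The generator emulates a search-surveillance collection: a fixed pool of
videos is organized into latent *themes*; each search item has a mixture
over themes, and each (item, profile) result list is drawn by repeatedly
sampling a theme from the item's mixture and then an as-yet-unused video
uniformly from that theme's pool.  Items with similar mixtures therefore
share many videos (the planted co-retrieval structure), profiles draw
independently (personalization between profiles is assumed erased), and
every video carries a ground-truth class whose transcript mixes indicator
phrases from that class's lexicon with background vocabulary at a
configurable density.

Randomness comes from one integer seed: the video pool uses one substream
and each (item, profile) draw uses a substream keyed by its indices, so
adding profiles or items never perturbs previously generated ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classifier import RuleSet, default_ruleset
from .corpus import STAGE_RAW, SearchCorpus, VideoRecord
from .textproc import background_vocabulary
from .util import InfeasibleConfigError, ValidationError

STUDY_ITEMS = [
    "e-cigarette",
    "e-cig",
    "electronic cigarette",
    "e-liquid",
    "ENDS",
    "e-juice",
    "vape",
    "vaping",
    "vape juice",
    "box mods",
    "cigalikes",
    "disposable e-cigs",
    "disposables",
    "disposable vape",
    "pod mods",
    "vape mods",
    "vape pens",
    "vape pods",
]


@dataclass
class GeneratorConfig:
    n_items: int
    n_profiles: int
    results_per_item: int
    n_themes: int
    videos_per_theme: int
    item_theme_mixtures: np.ndarray  # (n_items, n_themes), rows sum to 1
    class_given_theme: np.ndarray  # (n_themes, n_classes), rows sum to 1
    indicator_density: float = 0.3
    transcript_length: int = 160
    seed: int = 0
    item_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.item_theme_mixtures = np.asarray(self.item_theme_mixtures, dtype=float)
        self.class_given_theme = np.asarray(self.class_given_theme, dtype=float)
        self.validate()

    def validate(self) -> None:
        for name in ("n_items", "n_profiles", "results_per_item", "n_themes",
                     "videos_per_theme", "transcript_length"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if not 0.0 <= self.indicator_density <= 1.0:
            raise ValidationError("indicator_density must be in [0, 1]")
        mix, cgt = self.item_theme_mixtures, self.class_given_theme
        if mix.shape != (self.n_items, self.n_themes):
            raise ValidationError("item_theme_mixtures has wrong shape")
        if cgt.shape[0] != self.n_themes:
            raise ValidationError("class_given_theme has wrong shape")
        for name, arr in (("item_theme_mixtures", mix), ("class_given_theme", cgt)):
            if (arr < 0).any() or np.abs(arr.sum(axis=1) - 1.0).max() > 1e-9:
                raise ValidationError(f"rows of {name} must be probability vectors")
        if self.item_labels is not None and len(self.item_labels) != self.n_items:
            raise ValidationError("item_labels length must equal n_items")

    def labels(self) -> list[str]:
        if self.item_labels is not None:
            return list(self.item_labels)
        return [f"item_{i:02d}" for i in range(self.n_items)]


@dataclass
class GroundTruth:
    class_of: dict[str, str]  # video_id -> true class label
    theme_of: dict[str, int]  # video_id -> theme index
    expected_overlap: np.ndarray  # (n_items, n_items) expected shared counts
    profile_duplicates: dict[str, int] = field(default_factory=dict)


def _indicator_surfaces(ruleset: RuleSet) -> dict[str, list[str]]:
    """Class -> insertable surface phrases (conjunctions become one phrase)."""
    out: dict[str, list[str]] = {}
    for cls in ruleset.scored_classes():
        phrases = []
        for raw in ruleset.raw_indicators[cls]:
            words = [w.strip() for w in raw.split("+")] if "+" in raw else raw.split()
            phrases.append(" ".join(w for w in words if w))
        out[cls] = phrases
    return out


def generate_transcript(
    class_label: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
    ruleset: RuleSet | None = None,
    background: list[str] | None = None,
) -> str:
    """A transcript of ``transcript_length`` tokens.  Each position is an
    indicator insertion with probability ``indicator_density`` (multi-word
    indicators enter as contiguous phrases, consuming several positions) and
    a background token otherwise; the fallback class is all background."""
    ruleset = ruleset or default_ruleset()
    background = background or background_vocabulary()
    length = config.transcript_length
    if class_label == ruleset.fallback_class:
        idx = rng.integers(0, len(background), size=length)
        return " ".join(background[i] for i in idx)
    surfaces = [s.split() for s in _indicator_surfaces(ruleset)[class_label]]
    # Calibrate the per-slot insertion probability so the expected *token*
    # fraction coming from the lexicon equals indicator_density even though
    # multi-word phrases contribute several tokens per insertion.
    d = config.indicator_density
    mean_len = sum(len(s) for s in surfaces) / len(surfaces)
    p_insert = d / (mean_len * (1.0 - d) + d) if d < 1.0 else 1.0
    tokens: list[str] = []
    while len(tokens) < length:
        if rng.random() < p_insert:
            tokens.extend(surfaces[rng.integers(0, len(surfaces))])
        else:
            tokens.append(background[rng.integers(0, len(background))])
    return " ".join(tokens[:length])


def _substream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def generate_corpus(
    config: GeneratorConfig, ruleset: RuleSet | None = None
) -> tuple[SearchCorpus, GroundTruth]:
    """Draw the full corpus; identical config + seed give identical output."""
    ruleset = ruleset or default_ruleset()
    background = background_vocabulary()
    classes = ruleset.classes
    K, M = config.n_themes, config.videos_per_theme
    if config.class_given_theme.shape[1] != len(classes):
        raise ValidationError(
            "class_given_theme columns must match the ruleset's class count"
        )
    if config.results_per_item > K * M:
        raise InfeasibleConfigError(
            f"results_per_item={config.results_per_item} exceeds pool size {K * M}"
        )
    supported = (config.item_theme_mixtures > 0) @ np.full(K, M)
    if (supported < config.results_per_item).any():
        raise InfeasibleConfigError(
            "an item's supported themes hold fewer videos than results_per_item"
        )

    # --- video pool (one substream) ---------------------------------------
    pool_rng = _substream(config.seed, 0)
    pool: list[list[VideoRecord]] = []
    class_of: dict[str, str] = {}
    theme_of: dict[str, int] = {}
    for k in range(K):
        theme_videos: list[VideoRecord] = []
        class_idx = pool_rng.choice(len(classes), size=M, p=config.class_given_theme[k])
        for m in range(M):
            vid = f"v{k:02d}_{m:05d}"
            cls = classes[int(class_idx[m])]
            title = " ".join(
                background[i] for i in pool_rng.integers(0, len(background), size=3)
            )
            desc = " ".join(
                background[i] for i in pool_rng.integers(0, len(background), size=8)
            )
            transcript = generate_transcript(cls, config, pool_rng, ruleset, background)
            theme_videos.append(
                VideoRecord(video_id=vid, title=title, description=desc, transcript=transcript)
            )
            class_of[vid] = cls
            theme_of[vid] = k
        pool.append(theme_videos)

    # --- per-(item, profile) draws (independent substreams) ---------------
    labels = config.labels()
    results: dict[str, dict[str, list[VideoRecord]]] = {label: {} for label in labels}
    drawn_per_item: dict[str, list[str]] = {label: [] for label in labels}
    for i, label in enumerate(labels):
        mixture = config.item_theme_mixtures[i]
        for p in range(config.n_profiles):
            rng = _substream(config.seed, 1, i, p)
            remaining = [list(range(M)) for _ in range(K)]
            records: list[VideoRecord] = []
            for _ in range(config.results_per_item):
                avail = np.array([len(r) > 0 for r in remaining], dtype=float)
                probs = mixture * avail
                total = probs.sum()
                if total == 0:
                    raise InfeasibleConfigError(
                        f"item {label!r}: supported themes exhausted"
                    )
                theme = int(rng.choice(K, p=probs / total))
                j = int(rng.integers(0, len(remaining[theme])))
                remaining[theme][j], remaining[theme][-1] = (
                    remaining[theme][-1],
                    remaining[theme][j],
                )
                records.append(pool[theme][remaining[theme].pop()])
            results[label][f"profile_{p:02d}"] = records
            drawn_per_item[label].extend(rec.video_id for rec in records)

    corpus = SearchCorpus(items=labels, results=results, stage=STAGE_RAW)
    gt = GroundTruth(
        class_of=class_of,
        theme_of=theme_of,
        expected_overlap=expected_overlap(config),
        profile_duplicates={
            label: len(ids) - len(set(ids)) for label, ids in drawn_per_item.items()
        },
    )
    return corpus, gt


def expected_overlap(config: GeneratorConfig) -> np.ndarray:
    """Expected shared-video counts between item pairs for one profile.

    P(a given theme-k video is drawn by item i) = r * pi_ik / M (capped at 1,
    exact when no theme is exhausted); independent items give the entry
    E[shared(i, j)] = sum_k M * p_ik * p_jk.  Diagonal is set to 0.
    """
    r, M = config.results_per_item, config.videos_per_theme
    p = np.minimum(r * config.item_theme_mixtures / M, 1.0)  # (n_items, K)
    out = M * (p @ p.T)
    np.fill_diagonal(out, 0.0)
    return out


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    """JSONL sidecar: one object per video, then one 'overlap' object."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for vid in sorted(gt.class_of):
            fh.write(
                json.dumps(
                    {"video_id": vid, "class": gt.class_of[vid], "theme": gt.theme_of[vid]},
                    sort_keys=True,
                )
                + "\n"
            )
        fh.write(
            json.dumps(
                {
                    "expected_overlap": np.round(gt.expected_overlap, 6).tolist(),
                    "profile_duplicates": gt.profile_duplicates,
                },
                sort_keys=True,
            )
            + "\n"
        )


# Class-mix flavors (device, e-liquid, cannabis, other) used per theme group.
_CLASS_FLAVORS = {
    "general": [0.45, 0.20, 0.20, 0.15],
    "liquids": [0.30, 0.37, 0.18, 0.15],
    "mods": [0.55, 0.14, 0.19, 0.12],
    "disposables": [0.57, 0.14, 0.17, 0.12],
    "pods": [0.50, 0.18, 0.20, 0.12],
    "cigalikes": [0.48, 0.16, 0.22, 0.14],
}

# group name -> (members, per-member mass on the shared group theme)
_STUDY_GROUPS = {
    "general": (
        {"e-cigarette": 0.10, "e-cig": 0.10, "electronic cigarette": 0.10,
         "vape": 0.10, "vaping": 0.10, "ENDS": 0.08, "vape pens": 0.04},
        "general",
    ),
    "liquids": (
        {"e-liquid": 0.20, "e-juice": 0.20, "vape juice": 0.20},
        "liquids",
    ),
    "mods": (
        {"box mods": 0.12, "vape mods": 0.12, "pod mods": 0.08},
        "mods",
    ),
    "disposables": (
        {"disposable e-cigs": 0.15, "disposables": 0.15, "disposable vape": 0.13},
        "disposables",
    ),
    "pods": (
        {"vape pods": 0.10, "vape pens": 0.10, "pod mods": 0.06},
        "pods",
    ),
}

# mass each item spreads evenly over the six diffuse "general interest"
# themes (emulating one large, sparsely sampled shared pool)
_STUDY_DIFFUSE_MASS = {
    "e-cigarette": 0.12, "e-cig": 0.14, "electronic cigarette": 0.12,
    "e-liquid": 0.07, "ENDS": 0.10, "e-juice": 0.07, "vape": 0.12,
    "vaping": 0.12, "vape juice": 0.06, "box mods": 0.03, "cigalikes": 0.025,
    "disposable e-cigs": 0.05, "disposables": 0.05, "disposable vape": 0.04,
    "pod mods": 0.03, "vape mods": 0.04, "vape pens": 0.08, "vape pods": 0.04,
}

_STUDY_ITEM_FLAVOR = {
    "e-liquid": "liquids", "e-juice": "liquids", "vape juice": "liquids",
    "box mods": "mods", "vape mods": "mods", "pod mods": "mods",
    "disposable e-cigs": "disposables", "disposables": "disposables",
    "disposable vape": "disposables",
    "vape pods": "pods", "vape pens": "pods",
    "cigalikes": "cigalikes",
}


def study_config(seed: int = 0) -> GeneratorConfig:
    """Default study-scale configuration: 18 search items x 16 profiles x 140
    results each.

    Themes model three kinds of video pools, all of size 400: one private
    theme per item (the niche results only that query surfaces; profiles
    revisit it heavily, producing the strong cross-profile duplication seen
    in repeated searching), one shared theme per group of related items
    (liquids, mods, disposables, pods, and the broad general terms) carrying
    their strong pairwise overlap, and six diffuse themes sampled lightly by
    every item, producing the weak background overlap between unrelated
    items.  Per-theme class mixes keep every item's class percentages in
    realistic ranges with devices dominant.
    """
    n_items = len(STUDY_ITEMS)
    n_diffuse = 6
    group_names = list(_STUDY_GROUPS)
    n_themes = n_items + len(group_names) + n_diffuse
    mixtures = np.zeros((n_items, n_themes))
    flavors: list[str] = []
    for i, item in enumerate(STUDY_ITEMS):  # private themes first
        flavors.append(_STUDY_ITEM_FLAVOR.get(item, "general"))
    for g, name in enumerate(group_names):  # then group themes
        flavors.append(_STUDY_GROUPS[name][1])
        members, _ = _STUDY_GROUPS[name]
        for item, mass in members.items():
            mixtures[STUDY_ITEMS.index(item), n_items + g] = mass
    for _ in range(n_diffuse):  # then diffuse themes
        flavors.append("general")
    for i, item in enumerate(STUDY_ITEMS):
        diffuse = _STUDY_DIFFUSE_MASS[item]
        mixtures[i, n_items + len(group_names):] = diffuse / n_diffuse
        mixtures[i, i] = 1.0 - mixtures[i].sum()  # remainder on private theme
    class_given_theme = np.array([_CLASS_FLAVORS[f] for f in flavors])
    return GeneratorConfig(
        n_items=n_items,
        n_profiles=16,
        results_per_item=140,
        n_themes=n_themes,
        videos_per_theme=400,
        item_theme_mixtures=mixtures,
        class_given_theme=class_given_theme,
        indicator_density=0.3,
        transcript_length=160,
        seed=seed,
        item_labels=list(STUDY_ITEMS),
    )
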