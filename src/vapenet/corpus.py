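"""Search-result corpora: JSONL (de)serialization and two-stage deduplication.

A corpus maps each search item, per viewer profile, to a ranked list of video
records.  Deduplication mirrors how repeated retrievals are collapsed in
search-surveillance studies: first across profiles within each item (a video
two profiles both retrieved for "vape" counts once for "vape"), then across
items (a video retrieved by several items is kept under the earliest item in
the corpus's declared item order).  The profile-deduplicated corpus — not the
fully deduplicated one — feeds network construction, because cross-item
duplicates are exactly the edges of the co-retrieval network; full
deduplication is only for classification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

from .util import SchemaError, StageError, ValidationError, round_half_up

STAGE_RAW = "raw"
STAGE_PROFILE_DEDUPED = "profile_deduped"
STAGE_FULLY_DEDUPED = "fully_deduped"
_STAGES = (STAGE_RAW, STAGE_PROFILE_DEDUPED, STAGE_FULLY_DEDUPED)

_OPTIONAL_FIELDS = ("view_count", "like_count", "dislike_count", "category")


@dataclass(eq=False)
class VideoRecord:
    """One retrieved video.  Records are equal iff their video IDs are equal."""

    video_id: str
    title: str = ""
    description: str = ""
    transcript: str = ""
    view_count: int | None = None
    like_count: int | None = None
    dislike_count: int | None = None
    category: str | None = None

    def __post_init__(self) -> None:
        if not self.video_id:
            raise ValidationError("video_id must be a non-empty string")
        for name in ("view_count", "like_count", "dislike_count"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValidationError(f"{name} must be non-negative")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VideoRecord):
            return NotImplemented
        return self.video_id == other.video_id

    def __hash__(self) -> int:
        return hash(self.video_id)

    def text(self) -> str:
        """Title + description + transcript, the text a classifier sees."""
        return " ".join(p for p in (self.title, self.description, self.transcript) if p)

    def to_json_fields(self) -> dict:
        out = {
            "video_id": self.video_id,
            "title": self.title,
            "description": self.description,
            "transcript": self.transcript,
        }
        for name in _OPTIONAL_FIELDS:
            value = getattr(self, name)
            if value is not None:
                out[name] = value
        return out


@dataclass
class SearchCorpus:
    """item -> profile -> ranked video records, tagged with its dedup stage."""

    items: list[str]
    results: dict[str, dict[str, list[VideoRecord]]]
    stage: str = STAGE_RAW

    def __post_init__(self) -> None:
        if self.stage not in _STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        if len(set(self.items)) != len(self.items):
            raise ValidationError("item labels must be unique")
        for item in self.results:
            if item not in self.items:
                raise ValidationError(f"results for undeclared item {item!r}")

    # -- views ----------------------------------------------------------
    def profiles(self) -> list[str]:
        seen: dict[str, None] = {}
        for item in self.items:
            for profile in self.results.get(item, {}):
                seen.setdefault(profile, None)
        return list(seen)

    def records_of(self, item: str) -> list[VideoRecord]:
        """All records for an item, profile order then rank order."""
        per_profile = self.results.get(item, {})
        return [rec for profile in per_profile for rec in per_profile[profile]]

    def video_ids_of(self, item: str) -> set[str]:
        return {rec.video_id for rec in self.records_of(item)}

    def n_records(self) -> int:
        return sum(len(self.records_of(item)) for item in self.items)

    def iter_records(self):
        for item in self.items:
            per_profile = self.results.get(item, {})
            for profile, records in per_profile.items():
                for rank, rec in enumerate(records, start=1):
                    yield item, profile, rank, rec

    def record_index(self) -> dict[str, VideoRecord]:
        """video_id -> one representative record (first occurrence)."""
        index: dict[str, VideoRecord] = {}
        for _, _, _, rec in self.iter_records():
            index.setdefault(rec.video_id, rec)
        return index


@dataclass
class DedupSummary:
    """Provenance counts for a deduplication pass (or a corpus snapshot)."""

    n_raw: int = 0
    n_after_profile_dedup: int = 0
    n_cross_item_duplicates: int = 0
    n_unique: int = 0
    per_item: dict[str, dict[str, int]] = field(default_factory=dict)

    def unique_fraction_pct(self) -> float:
        """Unique videos as a percentage of the post-profile-dedup count,
        reported to 2 decimals, ties rounded up (5875 -> 4201 gives 71.51)."""
        if self.n_after_profile_dedup == 0:
            return 0.0
        return round_half_up(100.0 * self.n_unique / self.n_after_profile_dedup, 2)

    def check(self) -> None:
        if self.n_after_profile_dedup - self.n_cross_item_duplicates != self.n_unique:
            raise ValidationError("dedup summary counts are inconsistent")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"item": item, "stage": stage, "count": count}
            for item, stages in self.per_item.items()
            for stage, count in stages.items()
        ]
        return pd.DataFrame(rows, columns=["item", "stage", "count"])


# ---------------------------------------------------------------------------
# JSONL dialect: one object per (item, profile, rank), UTF-8.
# ---------------------------------------------------------------------------

_REQUIRED = ("item", "profile", "rank", "video_id")


def write_corpus(corpus: SearchCorpus, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for item, profile, rank, rec in corpus.iter_records():
            obj = {"item": item, "profile": profile, "rank": rank}
            obj.update(rec.to_json_fields())
            fh.write(json.dumps(obj, ensure_ascii=False, sort_keys=True) + "\n")


def load_corpus(path: str | Path, stage: str = STAGE_RAW) -> SearchCorpus:
    """Read the JSONL dialect; malformed lines are reported with line numbers.

    The stage tag is not part of the line objects, so the caller states what
    stage the file holds (default: raw).
    """
    path = Path(path)
    items: list[str] = []
    results: dict[str, dict[str, list[VideoRecord]]] = {}
    pending: dict[tuple[str, str], list[tuple[int, VideoRecord]]] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SchemaError(f"invalid JSON ({exc.msg})", line=lineno) from exc
            for key in _REQUIRED:
                if key not in obj:
                    raise SchemaError(f"missing required field {key!r}", line=lineno)
            item, profile = str(obj["item"]), str(obj["profile"])
            try:
                rec = VideoRecord(
                    video_id=str(obj["video_id"]),
                    title=obj.get("title", ""),
                    description=obj.get("description", ""),
                    transcript=obj.get("transcript", ""),
                    **{k: obj.get(k) for k in _OPTIONAL_FIELDS},
                )
            except ValidationError as exc:
                raise SchemaError(str(exc), line=lineno) from exc
            if item not in results:
                items.append(item)
                results[item] = {}
            results[item].setdefault(profile, [])
            pending.setdefault((item, profile), []).append((int(obj["rank"]), rec))
    for (item, profile), ranked in pending.items():
        ranked.sort(key=lambda pair: pair[0])
        results[item][profile] = [rec for _, rec in ranked]
    return SearchCorpus(items=items, results=results, stage=stage)


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------


def dedup_across_profiles(corpus: SearchCorpus) -> tuple[SearchCorpus, DedupSummary]:
    """Within each item, keep a video's first occurrence (profile order, then
    rank); later retrievals of the same ID by other profiles are duplicates."""
    if corpus.stage != STAGE_RAW:
        raise StageError(f"expected a raw corpus, got stage {corpus.stage!r}")
    new_results: dict[str, dict[str, list[VideoRecord]]] = {}
    summary = DedupSummary()
    for item in corpus.items:
        seen: set[str] = set()
        new_results[item] = {}
        n_raw = 0
        for profile, records in corpus.results.get(item, {}).items():
            kept: list[VideoRecord] = []
            for rec in records:
                n_raw += 1
                if rec.video_id not in seen:
                    seen.add(rec.video_id)
                    kept.append(rec)
            new_results[item][profile] = kept
        summary.per_item[item] = {
            "raw": n_raw,
            "profile_deduped": len(seen),
            "removed": n_raw - len(seen),
        }
        summary.n_raw += n_raw
        summary.n_after_profile_dedup += len(seen)
    summary.n_unique = summary.n_after_profile_dedup
    deduped = SearchCorpus(
        items=list(corpus.items), results=new_results, stage=STAGE_PROFILE_DEDUPED
    )
    return deduped, summary


def dedup_across_items(corpus: SearchCorpus) -> tuple[SearchCorpus, DedupSummary]:
    """Keep each video ID once, under the earliest item in the corpus's item
    order; a video under k items yields k-1 removals.  The input corpus is
    left untouched so the network stage can still see cross-item duplicates.
    """
    if corpus.stage != STAGE_PROFILE_DEDUPED:
        raise StageError(
            f"expected a profile_deduped corpus, got stage {corpus.stage!r}"
        )
    owner: dict[str, str] = {}
    for item in corpus.items:
        for rec in corpus.records_of(item):
            owner.setdefault(rec.video_id, item)
    new_results: dict[str, dict[str, list[VideoRecord]]] = {}
    summary = DedupSummary()
    for item in corpus.items:
        new_results[item] = {}
        n_in = 0
        n_kept = 0
        for profile, records in corpus.results.get(item, {}).items():
            kept = []
            for rec in records:
                n_in += 1
                if owner[rec.video_id] == item:
                    kept.append(rec)
            n_kept += len(kept)
            new_results[item][profile] = kept
        summary.per_item[item] = {
            "profile_deduped": n_in,
            "unique": n_kept,
            "removed": n_in - n_kept,
        }
        summary.n_after_profile_dedup += n_in
        summary.n_raw += n_in
        summary.n_cross_item_duplicates += n_in - n_kept
        summary.n_unique += n_kept
    summary.check()
    deduped = SearchCorpus(
        items=list(corpus.items), results=new_results, stage=STAGE_FULLY_DEDUPED
    )
    return deduped, summary


def corpus_summary(corpus: SearchCorpus) -> DedupSummary:
    """Snapshot counts of a corpus at any stage: per-item and total record
    counts, plus unique-ID counts (n_unique counts distinct IDs corpus-wide)."""
    summary = DedupSummary()
    all_ids: set[str] = set()
    for item in corpus.items:
        records = corpus.records_of(item)
        ids = {rec.video_id for rec in records}
        all_ids.update(ids)
        summary.per_item[item] = {corpus.stage: len(records), "distinct_ids": len(ids)}
        summary.n_raw += len(records)
    summary.n_after_profile_dedup = sum(
        counts["distinct_ids"] for counts in summary.per_item.values()
    )
    summary.n_unique = len(all_ids)
    summary.n_cross_item_duplicates = summary.n_after_profile_dedup - summary.n_unique
    return summary


def write_summary_csv(summary: DedupSummary, path: str | Path) -> None:
    summary.to_frame().to_csv(path, index=False)


def corpora_equal(a: SearchCorpus, b: SearchCorpus) -> bool:
    """Deep equality (all record fields), used for round-trip checks."""
    if a.items != b.items or a.stage != b.stage:
        return False
    rec_fields = [f.name for f in fields(VideoRecord)]
    recs_a, recs_b = list(a.iter_records()), list(b.iter_records())
    if len(recs_a) != len(recs_b):
        return False
    for (ia, pa, ra, reca), (ib, pb, rb, recb) in zip(recs_a, recs_b):
        if (ia, pa, ra) != (ib, pb, rb):
            return False
        if any(getattr(reca, f) != getattr(recb, f) for f in rec_fields):
            return False
    return True
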