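"""One-command orchestration: simulate/ingest -> dedup -> network -> stats ->
centrality -> correlogram -> classify -> summarize, with a reproducible
report bundle.

Every run emits the same six artifacts (GraphML network, Table-1-style stats
CSV with betweenness, correlation matrix CSV plus long form, per-item class
percentage CSV, dedup provenance CSV, and a JSON manifest with a config hash
and per-artifact checksums); identical config + seed reproduce the bundle
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .centrality import betweenness, rank_items
from .classifier import (
    classify_corpus,
    default_ruleset,
    load_ruleset,
    summarize_by_item,
    write_classification_csv,
)
from .corpus import (
    dedup_across_items,
    dedup_across_profiles,
    load_corpus,
    write_corpus,
    write_summary_csv,
)
from .correlogram import correlate_items, render_correlogram_data, write_matrix_csv
from .network import (
    build_bipartite,
    connection_stats,
    export_network,
    format_connection_stats,
    normalize_weights,
    project_items,
)
from .synthetic import GeneratorConfig, generate_corpus, study_config, write_ground_truth
from .textproc import TextConfig
from .util import ValidationError, VapenetError, sha256_file

logger = logging.getLogger("vapenet")


class PipelineStageError(VapenetError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Exactly one of ``corpus_path`` / ``generator`` selects the input."""

    outdir: str | Path = "vapenet_out"
    corpus_path: str | Path | None = None
    generator: GeneratorConfig | None = None
    text: TextConfig = field(default_factory=TextConfig)
    ruleset_path: str | Path | None = None
    bc_use_weights: bool = False
    bc_normalized: bool = True
    alpha: float = 0.05
    exclude_mutual: bool = False
    correction: str | None = None
    write_corpus_artifacts: bool = True

    def __post_init__(self) -> None:
        if (self.corpus_path is None) == (self.generator is None):
            raise ValidationError(
                "exactly one of corpus_path / generator must be set"
            )

    def config_hash(self) -> str:
        def default(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            if isinstance(obj, frozenset):
                return sorted(obj)
            if isinstance(obj, Path):
                return str(obj)
            raise TypeError(type(obj).__name__)

        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)  # bundle location does not change results
        blob = json.dumps(payload, sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()


def config_from_toml(path: str | Path) -> PipelineConfig:
    """TOML config: top-level pipeline keys plus an optional [generator]
    table, either ``preset = "study"`` (with optional seed override) or the
    full generator field set."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    gen = None
    if "generator" in data:
        g = data["generator"]
        if g.get("preset") == "study":
            gen = study_config(seed=int(g.get("seed", 0)))
        else:
            gen = GeneratorConfig(
                n_items=g["n_items"],
                n_profiles=g["n_profiles"],
                results_per_item=g["results_per_item"],
                n_themes=g["n_themes"],
                videos_per_theme=g["videos_per_theme"],
                item_theme_mixtures=np.array(g["item_theme_mixtures"], dtype=float),
                class_given_theme=np.array(g["class_given_theme"], dtype=float),
                indicator_density=g.get("indicator_density", 0.3),
                transcript_length=g.get("transcript_length", 160),
                seed=g.get("seed", 0),
                item_labels=g.get("item_labels"),
            )
    text = TextConfig(
        stoplist=data.get("stoplist", "default"),
        lemmatizer=data.get("lemmatizer", "rule"),
    )
    return PipelineConfig(
        outdir=data.get("outdir", "vapenet_out"),
        corpus_path=data.get("corpus_path"),
        generator=gen,
        text=text,
        ruleset_path=data.get("ruleset"),
        bc_use_weights=data.get("bc_weighted", False),
        bc_normalized=data.get("bc_normalized", True),
        alpha=data.get("alpha", 0.05),
        exclude_mutual=data.get("exclude_mutual", False),
        correction=data.get("correction"),
    )


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute all stages; on failure, partial outputs are removed and the
    error is re-raised tagged with the failing stage's name."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str) -> Path:
        path = outdir / name
        written.append(path)
        return path

    artifacts: dict[str, Path] = {}
    stage = "setup"
    t0 = time.perf_counter()
    try:
        stage = "ingest"
        ground_truth = None
        if config.generator is not None:
            logger.info("simulating corpus (seed=%d)", config.generator.seed)
            raw, ground_truth = generate_corpus(config.generator)
        else:
            raw = load_corpus(config.corpus_path, stage="raw")

        stage = "dedup"
        profile_deduped, _ = dedup_across_profiles(raw)
        fully_deduped, dedup_summary = dedup_across_items(profile_deduped)
        path = emit("dedup_summary.csv")
        write_summary_csv(dedup_summary, path)
        artifacts["dedup_summary"] = path
        if config.write_corpus_artifacts:
            path = emit("corpus_profile_deduped.jsonl")
            write_corpus(profile_deduped, path)
            artifacts["corpus"] = path
            if ground_truth is not None:
                path = emit("ground_truth.jsonl")
                write_ground_truth(ground_truth, path)
                artifacts["ground_truth"] = path

        stage = "network"
        net = normalize_weights(project_items(build_bipartite(profile_deduped)))
        path = emit("net.graphml")
        export_network(net, path, "graphml")
        artifacts["network"] = path

        stage = "centrality"
        bc = betweenness(net, use_weights=config.bc_use_weights,
                         normalized=config.bc_normalized)
        bc_table = rank_items(bc)

        stage = "stats"
        stats = format_connection_stats(connection_stats(net))
        merged = stats.merge(bc_table[["item", "raw_bc", "normalized_bc"]], on="item")
        path = emit("stats.csv")
        merged.to_csv(path, index=False)
        artifacts["stats"] = path

        stage = "correlogram"
        cm = correlate_items(net, alpha=config.alpha,
                             exclude_mutual=config.exclude_mutual,
                             correction=config.correction)
        path = emit("corr.csv")
        write_matrix_csv(cm, path)
        artifacts["correlation_matrix"] = path
        path = emit("corr_long.csv")
        render_correlogram_data(cm).to_csv(path, index=False)
        artifacts["correlation_long"] = path

        stage = "classify"
        ruleset = (
            load_ruleset(config.ruleset_path, config.text)
            if config.ruleset_path
            else default_ruleset(config.text)
        )
        labels = classify_corpus(fully_deduped, ruleset)
        path = emit("labels.csv")
        write_classification_csv(labels, path)
        artifacts["labels"] = path

        stage = "summarize"
        summary = summarize_by_item(profile_deduped, labels, ruleset)
        path = emit("pies.csv")
        summary.to_frame().to_csv(path, index=False)
        artifacts["class_summary"] = path

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "config_hash": config.config_hash(),
            "seed": None if config.generator is None else config.generator.seed,
            "artifacts": {
                name: {"file": p.name, "sha256": sha256_file(p)}
                for name, p in sorted(artifacts.items())
            },
            "artifact_roles": {
                "network": "weighted co-retrieval network over search items",
                "stats": "per-item connection statistics and betweenness centrality",
                "correlation_matrix": "item-pair correlation matrix",
                "correlation_long": "long-form correlations with significance flags",
                "class_summary": "per-item class percentages (exclusive labels)",
                "dedup_summary": "deduplication provenance counts",
                "labels": "per-video multi-label classification",
            },
        }
        path = emit("manifest.json")
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        artifacts["manifest"] = path
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineStageError(stage, exc) from exc
    logger.info("pipeline finished in %.2fs (%d artifacts)",
                time.perf_counter() - t0, len(artifacts))
    return artifacts


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
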