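"""Item-video bipartite graph and its weighted one-mode projection.

The co-retrieval network has one node per search item; the multiplicity of
an item pair is the exact number of videos retrieved by both (computed on
the profile-deduplicated corpus, where cross-item duplicates are still
present — they are precisely the edges).  Multiplicities are optionally
normalized to weights in [0, 1] by dividing by the global maximum, and
per-item connection statistics (total, mean and SD of multiplicity over the
other n-1 items, support-graph degree) summarize each item's connectedness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .corpus import STAGE_PROFILE_DEDUPED, STAGE_FULLY_DEDUPED, SearchCorpus
from .util import ConfigError, DegenerateInputError, StageError, round_half_up


@dataclass
class BipartiteGraph:
    items: list[str]
    videos: set[str]
    videos_of: dict[str, set[str]]  # item -> set of member video IDs

    def n_edges(self) -> int:
        return sum(len(v) for v in self.videos_of.values())


@dataclass
class ItemNetwork:
    """Weighted undirected graph over search items.

    ``multiplicity`` stores only positive entries, keyed by item-label pairs
    in item-order; absent pairs have multiplicity 0 and no support edge.
    """

    items: list[str]
    multiplicity: dict[tuple[str, str], int]
    weights: dict[tuple[str, str], float] = field(default_factory=dict)

    def _key(self, a: str, b: str) -> tuple[str, str]:
        ia, ib = self.items.index(a), self.items.index(b)
        return (a, b) if ia <= ib else (b, a)

    def multiplicity_of(self, a: str, b: str) -> int:
        return self.multiplicity.get(self._key(a, b), 0)

    def weight_of(self, a: str, b: str) -> float:
        return self.weights.get(self._key(a, b), 0.0)

    def neighbors(self, a: str) -> list[str]:
        return [b for b in self.items if b != a and self.multiplicity_of(a, b) > 0]

    def adjacency_matrix(self, use_weights: bool = False) -> np.ndarray:
        """Symmetric items x items matrix of multiplicities (or weights),
        zero diagonal."""
        n = len(self.items)
        out = np.zeros((n, n))
        index = {item: i for i, item in enumerate(self.items)}
        source = self.weights if use_weights else self.multiplicity
        for (a, b), value in source.items():
            out[index[a], index[b]] = value
            out[index[b], index[a]] = value
        return out


def build_bipartite(corpus: SearchCorpus) -> BipartiteGraph:
    """Membership edges (item, video) from a profile-deduplicated corpus.

    A fully deduplicated corpus is rejected: removing cross-item duplicates
    would delete every projection edge.
    """
    if corpus.stage == STAGE_FULLY_DEDUPED:
        raise StageError("a fully_deduped corpus has no cross-item edges left")
    if corpus.stage != STAGE_PROFILE_DEDUPED:
        raise StageError(
            f"expected a profile_deduped corpus, got stage {corpus.stage!r}"
        )
    videos_of = {item: corpus.video_ids_of(item) for item in corpus.items}
    videos = set().union(*videos_of.values()) if videos_of else set()
    return BipartiteGraph(items=list(corpus.items), videos=videos, videos_of=videos_of)


def project_items(bg: BipartiteGraph) -> ItemNetwork:
    """One-mode projection: multiplicity(i, j) = |videos(i) & videos(j)|."""
    multiplicity: dict[tuple[str, str], int] = {}
    for i, a in enumerate(bg.items):
        for b in bg.items[i + 1 :]:
            shared = len(bg.videos_of[a] & bg.videos_of[b])
            if shared > 0:
                multiplicity[(a, b)] = shared
    return ItemNetwork(items=list(bg.items), multiplicity=multiplicity)


def normalize_weights(net: ItemNetwork) -> ItemNetwork:
    """weight = multiplicity / max multiplicity; at least one pair reaches 1."""
    if not net.multiplicity:
        raise DegenerateInputError("no pair shares a video; weights are undefined")
    peak = max(net.multiplicity.values())
    weights = {pair: m / peak for pair, m in net.multiplicity.items()}
    return ItemNetwork(items=list(net.items), multiplicity=dict(net.multiplicity), weights=weights)


def connection_stats(net: ItemNetwork, ddof: int = 0) -> pd.DataFrame:
    """Per item: total shared videos, mean and SD of multiplicity over the
    other n-1 items (non-edges count as 0), and support-graph degree.

    SD uses the population estimator by default (``ddof=0``); pass ``ddof=1``
    for the sample convention.
    """
    if len(net.items) < 2:
        raise DegenerateInputError("connection statistics need at least 2 items")
    A = net.adjacency_matrix()
    n = len(net.items)
    rows = []
    for i, item in enumerate(net.items):
        partners = np.delete(A[i], i)
        rows.append(
            {
                "item": item,
                "total_connections": int(partners.sum()),
                "mean_connections": float(partners.mean()),
                "sd_connections": float(partners.std(ddof=ddof)),
                "degree": int((partners > 0).sum()),
            }
        )
    return pd.DataFrame(rows, columns=["item", "total_connections", "mean_connections",
                                       "sd_connections", "degree"])


def format_connection_stats(stats: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Reporting view: mean/SD rounded half-up to one decimal."""
    out = stats.copy()
    for col in ("mean_connections", "sd_connections"):
        out[col] = out[col].map(lambda x: round_half_up(x, decimals))
    return out


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

FORMATS = ("graphml", "edgelist", "adjacency")


def to_networkx(net: ItemNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(net.items)
    for (a, b), m in sorted(net.multiplicity.items()):
        g.add_edge(a, b, multiplicity=int(m), weight=float(net.weight_of(a, b)))
    return g


def from_networkx(g: nx.Graph, items: list[str] | None = None) -> ItemNetwork:
    items = items if items is not None else sorted(g.nodes)
    net = ItemNetwork(items=items, multiplicity={})
    for a, b, data in g.edges(data=True):
        key = net._key(a, b)
        net.multiplicity[key] = int(data["multiplicity"])
        if "weight" in data:
            net.weights[key] = float(data["weight"])
    return net


def export_network(net: ItemNetwork, path: str | Path, fmt: str = "graphml") -> None:
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(to_networkx(net), path)
    elif fmt == "edgelist":
        rows = [
            {"item_i": a, "item_j": b, "multiplicity": m, "weight": net.weight_of(a, b)}
            for (a, b), m in sorted(net.multiplicity.items())
        ]
        pd.DataFrame(rows, columns=["item_i", "item_j", "multiplicity", "weight"]).to_csv(
            path, index=False
        )
    elif fmt == "adjacency":
        A = net.adjacency_matrix()
        pd.DataFrame(A, index=net.items, columns=net.items).to_csv(path)
    else:
        raise ConfigError(f"unknown export format {fmt!r}; expected one of {FORMATS}")


def import_graphml(path: str | Path, items: list[str] | None = None) -> ItemNetwork:
    return from_networkx(nx.read_graphml(Path(path)), items=items)
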