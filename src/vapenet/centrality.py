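"""Betweenness centrality of the item network, implemented from scratch.

For node v, raw BC sums sigma_st(v)/sigma_st over unordered node pairs
{s, t} with s != t != v, where sigma_st counts shortest s-t paths and
sigma_st(v) those passing through v; endpoints are excluded and pairs in
different components contribute 0.  Normalized BC divides by (n-1)(n-2)/2,
the number of pairs a node could possibly sit between in an undirected
graph, giving values in [0, 1].

The default mode runs breadth-first search on the support graph (an edge
wherever at least one video is shared).  Weighted mode is a sensitivity
analysis: edge distance is 1/weight, so stronger co-retrieval means closer,
and shortest paths come from Dijkstra; scaling all weights by a constant
leaves the result unchanged.  ``betweenness`` is Brandes' dependency
accumulation; ``betweenness_bruteforce`` enumerates all simple paths per
pair and is the small-graph oracle.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass

import pandas as pd

from .network import ItemNetwork
from .util import DegenerateInputError, round_half_up


@dataclass
class CentralityResult:
    items: list[str]
    raw: dict[str, float]
    normalized: dict[str, float]
    weighted: bool
    is_normalized: bool = True

    def value(self, item: str) -> float:
        return self.normalized[item] if self.is_normalized else self.raw[item]


def _distance(net: ItemNetwork, a: str, b: str) -> float:
    # 1/weight if weights were normalized, else 1/multiplicity; the two give
    # identical geodesics (scale invariance).
    w = net.weight_of(a, b) if net.weights else float(net.multiplicity_of(a, b))
    return 1.0 / w


def _normalize(items: list[str], raw: dict[str, float]) -> dict[str, float]:
    n = len(items)
    if n < 3:
        return {v: 0.0 for v in items}
    scale = 2.0 / ((n - 1) * (n - 2))
    return {v: raw[v] * scale for v in items}


def betweenness(
    net: ItemNetwork, use_weights: bool = False, normalized: bool = True
) -> CentralityResult:
    """Exact Brandes accumulation over all sources."""
    items = net.items
    if not items:
        raise DegenerateInputError("empty network")
    bc = {v: 0.0 for v in items}
    adj = {v: net.neighbors(v) for v in items}
    for s in items:
        # single-source shortest paths: sigma counts and predecessor lists
        sigma = {v: 0.0 for v in items}
        dist: dict[str, float] = {}
        preds: dict[str, list[str]] = {v: [] for v in items}
        sigma[s] = 1.0
        order: list[str] = []
        if not use_weights:
            dist[s] = 0.0
            queue = [s]
            while queue:
                v = queue.pop(0)
                order.append(v)
                for w in adj[v]:
                    if w not in dist:
                        dist[w] = dist[v] + 1
                        queue.append(w)
                    if dist[w] == dist[v] + 1:
                        sigma[w] += sigma[v]
                        preds[w].append(v)
        else:
            seen = {s: 0.0}
            done: set[str] = set()
            heap: list[tuple[float, int, str]] = [(0.0, 0, s)]
            counter = itertools.count(1)
            while heap:
                d, _, v = heapq.heappop(heap)
                if v in done:
                    continue
                done.add(v)
                dist[v] = d
                order.append(v)
                for w in adj[v]:
                    dw = d + _distance(net, v, w)
                    if w in done:
                        continue
                    if w not in seen or dw < seen[w] - 1e-9:
                        seen[w] = dw
                        sigma[w] = sigma[v]
                        preds[w] = [v]
                        heapq.heappush(heap, (dw, next(counter), w))
                    elif abs(dw - seen[w]) <= 1e-9:
                        sigma[w] += sigma[v]
                        preds[w].append(v)
        # dependency accumulation, reverse order of discovery
        delta = {v: 0.0 for v in items}
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += (sigma[v] / sigma[w]) * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    raw = {v: bc[v] / 2.0 for v in items}  # each unordered pair counted twice
    return CentralityResult(
        items=list(items),
        raw=raw,
        normalized=_normalize(items, raw),
        weighted=use_weights,
        is_normalized=normalized,
    )


def betweenness_bruteforce(
    net: ItemNetwork, use_weights: bool = False, max_nodes: int = 12
) -> CentralityResult:
    """Oracle: enumerate every simple path per pair, keep the minimal ones,
    count pass-throughs.  Guarded to small graphs."""
    items = net.items
    n = len(items)
    if n > max_nodes:
        raise DegenerateInputError(f"brute force is guarded to n <= {max_nodes}")
    if n == 0:
        raise DegenerateInputError("empty network")
    adj = {v: net.neighbors(v) for v in items}

    def path_length(path: list[str]) -> float:
        if not use_weights:
            return float(len(path) - 1)
        return sum(_distance(net, a, b) for a, b in zip(path, path[1:]))

    def all_simple_paths(s: str, t: str) -> list[list[str]]:
        out: list[list[str]] = []
        stack = [(s, [s])]
        while stack:
            v, path = stack.pop()
            if v == t:
                out.append(path)
                continue
            for w in adj[v]:
                if w not in path:
                    stack.append((w, path + [w]))
        return out

    raw = {v: 0.0 for v in items}
    for s, t in itertools.combinations(items, 2):
        paths = all_simple_paths(s, t)
        if not paths:
            continue
        lengths = [path_length(p) for p in paths]
        best = min(lengths)
        geodesics = [p for p, l in zip(paths, lengths) if abs(l - best) <= 1e-9]
        for v in items:
            if v in (s, t):
                continue
            through = sum(1 for p in geodesics if v in p)
            raw[v] += through / len(geodesics)
    return CentralityResult(
        items=list(items),
        raw=raw,
        normalized=_normalize(items, raw),
        weighted=use_weights,
    )


def rank_items(result: CentralityResult, decimals: int = 5) -> pd.DataFrame:
    """Items sorted by descending BC, ties lexicographic; values reported to
    ``decimals`` places (round-half-up)."""
    rows = sorted(result.items, key=lambda v: (-result.raw[v], v))
    table = [
        {
            "item": v,
            "raw_bc": round_half_up(result.raw[v], decimals),
            "normalized_bc": round_half_up(result.normalized[v], decimals),
            "rank": i + 1,
        }
        for i, v in enumerate(rows)
    ]
    return pd.DataFrame(table, columns=["item", "raw_bc", "normalized_bc", "rank"])
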