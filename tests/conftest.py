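import numpy as np
import pytest

from vapenet.corpus import STAGE_RAW, SearchCorpus, VideoRecord
from vapenet.network import ItemNetwork


def make_corpus(spec: dict[str, dict[str, list[str]]], stage: str = STAGE_RAW) -> SearchCorpus:
    """Build a corpus from {item: {profile: [video ids]}} with stub text."""
    results = {
        item: {
            profile: [VideoRecord(video_id=vid, title=f"t {vid}") for vid in ids]
            for profile, ids in profiles.items()
        }
        for item, profiles in spec.items()
    }
    return SearchCorpus(items=list(spec), results=results, stage=stage)


def make_network(
    items: list[str], multiplicities: dict[tuple[str, str], int]
) -> ItemNetwork:
    net = ItemNetwork(items=list(items), multiplicity={})
    for (a, b), m in multiplicities.items():
        net.multiplicity[net._key(a, b)] = m
    return net


def random_network(rng: np.random.Generator, n: int, p: float = 0.4,
                   max_mult: int = 10) -> ItemNetwork:
    """Erdos-Renyi support graph with random positive multiplicities."""
    items = [f"n{i}" for i in range(n)]
    mult = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                mult[(items[i], items[j])] = int(rng.integers(1, max_mult + 1))
    return make_network(items, mult)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
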