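import numpy as np
import pandas as pd
import pytest

from conftest import make_corpus, make_network, random_network
from vapenet.corpus import dedup_across_items, dedup_across_profiles
from vapenet.network import (
    build_bipartite,
    connection_stats,
    export_network,
    format_connection_stats,
    import_graphml,
    normalize_weights,
    project_items,
)
from vapenet.synthetic import GeneratorConfig, generate_corpus
from vapenet.util import ConfigError, DegenerateInputError, StageError, round_half_up


def deduped(spec):
    corpus, _ = dedup_across_profiles(make_corpus(spec))
    return corpus


def test_bipartite_examples():
    corpus = deduped({"a": {"p": [f"v{i}" for i in range(140)]}})
    bg = build_bipartite(corpus)
    assert bg.n_edges() == 140
    corpus = deduped({"a": {"p": ["x"]}, "b": {"p": ["y"]}})
    bg = build_bipartite(corpus)
    assert bg.videos_of["a"] & bg.videos_of["b"] == set()


def test_bipartite_stage_guards():
    raw = make_corpus({"a": {"p": ["x"]}})
    with pytest.raises(StageError):
        build_bipartite(raw)
    final, _ = dedup_across_items(dedup_across_profiles(raw)[0])
    with pytest.raises(StageError):
        build_bipartite(final)


def test_bipartite_edges_match_profile_dedup_counts():
    corpus = deduped({"a": {"p1": ["x", "y"], "p2": ["y", "z"]}, "b": {"p1": ["x"]}})
    bg = build_bipartite(corpus)
    assert bg.n_edges() == sum(len(corpus.video_ids_of(i)) for i in corpus.items)


def test_projection_examples():
    ids = ["a", "b", "c"]
    net = project_items(build_bipartite(deduped({"i": {"p": ids}, "j": {"p": ids}})))
    assert net.multiplicity_of("i", "j") == 3
    net = project_items(
        build_bipartite(deduped({"i": {"p": ["a"]}, "j": {"p": ["b"]}}))
    )
    assert net.multiplicity == {}


def test_projection_equals_bruteforce_on_random_corpora(rng):
    """Multiplicity equals brute-force pairwise intersection counting."""
    for _ in range(25):
        n_items = int(rng.integers(2, 6))
        universe = [f"v{k}" for k in range(int(rng.integers(5, 30)))]
        spec = {
            f"i{t}": {
                "p": list(rng.choice(universe, size=rng.integers(1, len(universe)),
                                     replace=False))
            }
            for t in range(n_items)
        }
        corpus = deduped(spec)
        net = project_items(build_bipartite(corpus))
        items = corpus.items
        for x in range(n_items):
            for y in range(x + 1, n_items):
                expect = sum(
                    1 for v in set(spec[items[x]]["p"]) if v in spec[items[y]]["p"]
                )
                assert net.multiplicity_of(items[x], items[y]) == expect
                assert net.multiplicity_of(items[y], items[x]) == expect


def test_monotonicity_adding_shared_video():
    spec = {"i": {"p": ["a", "b"]}, "j": {"p": ["b", "c"]}}
    before = project_items(build_bipartite(deduped(spec)))
    spec2 = {"i": {"p": ["a", "b", "new"]}, "j": {"p": ["b", "c", "new"]}}
    after = project_items(build_bipartite(deduped(spec2)))
    assert after.multiplicity_of("i", "j") == before.multiplicity_of("i", "j") + 1


def test_normalize_weights():
    net = make_network(["a", "b", "c"], {("a", "b"): 10, ("b", "c"): 5})
    normed = normalize_weights(net)
    assert normed.weight_of("a", "b") == 1.0
    assert normed.weight_of("b", "c") == 0.5
    all_equal = make_network(["a", "b", "c"], {("a", "b"): 4, ("b", "c"): 4})
    normed = normalize_weights(all_equal)
    assert {w for w in normed.weights.values()} == {1.0}


def test_normalize_empty_network_rejected():
    with pytest.raises(DegenerateInputError):
        normalize_weights(make_network(["a", "b"], {}))


def test_connection_stats_star_fixture():
    """Hub shares 5 videos with each of 3 leaves; leaves share nothing."""
    net = make_network(
        ["h", "l1", "l2", "l3"],
        {("h", "l1"): 5, ("h", "l2"): 5, ("h", "l3"): 5},
    )
    stats = connection_stats(net).set_index("item")
    assert stats.loc["h", "mean_connections"] == pytest.approx(5.0)
    assert stats.loc["h", "total_connections"] == 15
    assert stats.loc["l1", "mean_connections"] == pytest.approx(5 / 3)
    assert stats.loc["l1", "degree"] == 1


def test_connection_stats_table_rounding():
    """Totals of 505 and 82 over 17 partners report as means 29.7 and 4.8."""
    assert round_half_up(505 / 17, 1) == 29.7
    assert round_half_up(82 / 17, 1) == 4.8


def test_connection_stats_population_vs_sample_sd():
    net = make_network(["a", "b", "c"], {("a", "b"): 2, ("a", "c"): 6})
    pop = connection_stats(net, ddof=0).set_index("item")
    samp = connection_stats(net, ddof=1).set_index("item")
    assert pop.loc["a", "sd_connections"] == pytest.approx(2.0)
    assert samp.loc["a", "sd_connections"] == pytest.approx(np.std([2, 6], ddof=1))


def test_conservation_sum_totals(rng):
    net = random_network(rng, 8, p=0.5)
    stats = connection_stats(net)
    assert stats["total_connections"].sum() == 2 * sum(net.multiplicity.values())


def test_format_stats_one_decimal():
    net = make_network(["a", "b", "c"], {("a", "b"): 2, ("a", "c"): 6})
    out = format_connection_stats(connection_stats(net)).set_index("item")
    assert out.loc["b", "mean_connections"] == 1.0  # 2/2


def test_export_graphml_roundtrip(tmp_path, rng):
    net = normalize_weights(random_network(rng, 6, p=0.6))
    path = tmp_path / "net.graphml"
    export_network(net, path, "graphml")
    back = import_graphml(path, items=net.items)
    assert back.multiplicity == net.multiplicity
    for pair, w in net.weights.items():
        assert back.weights[pair] == pytest.approx(w)


def test_export_edgelist_and_adjacency(tmp_path):
    net = normalize_weights(make_network(["a", "b"], {("a", "b"): 3}))
    edge_path = tmp_path / "e.csv"
    export_network(net, edge_path, "edgelist")
    table = pd.read_csv(edge_path)
    assert len(table) == 1 and table.loc[0, "multiplicity"] == 3
    adj_path = tmp_path / "a.csv"
    export_network(net, adj_path, "adjacency")
    A = pd.read_csv(adj_path, index_col=0)
    assert np.allclose(A.values, A.values.T)
    assert np.all(np.diag(A.values) == 0)
    with pytest.raises(ConfigError):
        export_network(net, tmp_path / "x", "nope")


def test_synthetic_18_item_adjacency_symmetric(tmp_path):
    cfg = GeneratorConfig(
        n_items=4, n_profiles=2, results_per_item=30, n_themes=2, videos_per_theme=60,
        item_theme_mixtures=[[1, 0], [0.5, 0.5], [0.2, 0.8], [0, 1]],
        class_given_theme=[[0.4, 0.2, 0.2, 0.2]] * 2, transcript_length=5, seed=1,
    )
    corpus, _ = generate_corpus(cfg)
    net = project_items(build_bipartite(dedup_across_profiles(corpus)[0]))
    A = net.adjacency_matrix()
    assert np.allclose(A, A.T) and np.all(np.diag(A) == 0)
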