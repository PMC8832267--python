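# vapenet

Co-retrieval network analysis of e-cigarette-related search items.

When public-health researchers query a video platform for related terms
(*e-cig*, *vape*, *e-liquid*, *disposables*, ...), the result lists overlap:
the same video is returned by several queries and by several simulated
viewer profiles. `vapenet` turns those overlaps into a weighted network over
the search items, measures which items act as informational gateways, and
classifies the retrieved videos by theme — giving a quantitative picture of
how a set of related queries partitions, or fails to partition, the content
space.

The package is aimed at infodemiology / digital-surveillance researchers who
already hold search-result corpora (or want to prototype against realistic
synthetic ones — no platform access is required; a seeded generator with
planted structure stands in for live data).

## The method

1. **Deduplication.** Raw results (item × profile × rank) are deduplicated
   in two stages: within each item across profiles, then across items (a
   video retrieved by *k* items is kept once, under the earliest item). The
   cross-item duplicates are *not* discarded for network construction — they
   are precisely the network's edges — only for classification.
2. **Co-retrieval network.** From the bipartite item–video membership graph,
   the one-mode projection gives each item pair a multiplicity
   *m(i, j)* = |V(i) ∩ V(j)|, the exact number of shared videos, normalized
   to weights *w = m / max m* ∈ [0, 1]. Per-item connection statistics
   report the total, mean and SD of multiplicity over the other *n* − 1
   items.
3. **Betweenness centrality.** For node *v*,
   *BC(v) = Σ_{s≠t≠v} σ_st(v) / σ_st*, where *σ_st* counts shortest *s–t*
   paths and *σ_st(v)* those through *v*; normalized by 2/((n−1)(n−2)).
   Implemented from scratch with Brandes' accumulation (BFS on the support
   graph by default; Dijkstra with distance 1/*w* as a weighted sensitivity
   mode) and verified against exhaustive path enumeration.
4. **Correlogram.** Pearson *r* between items' adjacency rows, with
   two-sided p-values from *t = r√((m−2)/(1−r²))* and a significance mask at
   α = 0.05.
5. **Rule-based classification.** A shipped, editable lexicon assigns each
   video's title + description + transcript to one or more of four classes
   (*e-cigarette device*, *e-liquid*, *cannabis vaping products*, fallback
   *other e-cigarette videos*) via contiguous lemma-phrase and conjunction
   patterns after deterministic tokenization, stop-word removal, and
   lemmatization; per-item class percentages summarize the mix.

## Worked example

```python
import vapenet as vn

corpus, truth = vn.generate_corpus(vn.study_config(seed=1))
profile_deduped, _ = vn.dedup_across_profiles(corpus)
fully_deduped, dedup = vn.dedup_across_items(profile_deduped)
print(f"{dedup.n_after_profile_dedup} videos after profile dedup; "
      f"{dedup.n_unique} unique ({dedup.unique_fraction_pct()}%)")

net = vn.normalize_weights(vn.project_items(vn.build_bipartite(profile_deduped)))
bc = vn.rank_items(vn.betweenness(net))
print(bc.head(3).to_string(index=False))

labels = vn.classify_corpus(fully_deduped)
summary = vn.summarize_by_item(profile_deduped, labels)
print("disposable e-cigs:", summary.percentages["disposable e-cigs"])
```

prints

```
13615 videos after profile dedup; 10665 unique (78.33%)
             item  raw_bc  normalized_bc  rank
             ENDS 0.19583        0.00144     1
disposable e-cigs 0.19583        0.00144     2
      disposables 0.19583        0.00144     3
disposable e-cigs: {'e-cigarette device': 54.0, 'e-liquid': 14.0, 'cannabis vaping products': 19.0, 'other e-cigarette videos': 12.0}
```

The simulated collection (18 items × 16 profiles × 140 results) retains
78.33% of its videos as unique after cross-item deduplication. Betweenness
is low and nearly flat — the support graph is dense, so almost every item
pair is directly connected — with the umbrella term *ENDS* among the
bridging nodes tied at the top. Of the videos retrieved for *disposable
e-cigs*, 54% feature a specific device, 14% e-liquids, 19% cannabis vaping
products, and 12% none of the lexicon themes.

The same pipeline is scriptable from the shell:

```sh
vapenet run --preset study --seed 1 --outdir out/
vapenet simulate --seed 1 --out sim/          # corpus + ground truth only
vapenet network --corpus sim/corpus.jsonl --out net.graphml --stats stats.csv
vapenet centrality --net net.graphml --out bc.csv
vapenet correlate --net net.graphml --out corr.csv
vapenet classify --corpus sim/corpus.jsonl --out labels.csv --summary pies.csv
```

`run` emits a reproducible bundle — `net.graphml`, `stats.csv`, `corr.csv`,
`corr_long.csv`, `pies.csv`, `dedup_summary.csv`, `labels.csv` and a
`manifest.json` with a config hash and per-artifact checksums; identical
seed and config reproduce it byte for byte.

## Layout

| Module | Role |
| --- | --- |
| `vapenet.synthetic` | seeded corpus generator with planted overlap + labeled transcripts |
| `vapenet.corpus` | JSONL corpus I/O, two-stage deduplication with provenance |
| `vapenet.network` | bipartite build, weighted projection, connection stats, export |
| `vapenet.centrality` | Brandes betweenness + brute-force oracle + ranking |
| `vapenet.correlogram` | adjacency-row Pearson correlations with significance |
| `vapenet.textproc` | tokenizer, stop list, rule lemmatizer |
| `vapenet.classifier` | lexicon rule set, multi-label matching, per-item summaries |
| `vapenet.pipeline` / `vapenet.cli` | orchestration, TOML config, `vapenet` CLI |

See `docs/methods.md` for modeling assumptions, parameter choices, and known
limitations.
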