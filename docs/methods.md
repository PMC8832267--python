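# Methods

## Problem setting

A search-surveillance collection maps each of a set of related search items,
per simulated viewer profile, to a ranked list of video records (ID, title,
description, transcript). Items that surface the same videos are
informationally close; items that never co-retrieve are niches. The package
quantifies this with a weighted co-retrieval network, betweenness
centrality, an item-pair correlogram, and a rule-based thematic
classification of the retrieved videos.

## Deduplication model

Two dedup stages with full provenance counts:

- **Across profiles, within item.** Profiles are treated as exchangeable
  repeat measurements of the same query; the first occurrence (profile
  order, then rank) is kept. Removed count per item = raw − distinct IDs.
- **Across items.** A video under *k* items is kept once under the earliest
  item in the corpus's declared item order, yielding *k* − 1 removals. The
  order is the order items appear in the corpus file. This tie-break is a
  convention — any consistent rule leaves per-item class percentages
  slightly path-dependent — so it is recorded in the summary where
  alternatives can be audited.

The profile-deduplicated corpus feeds the network (cross-item duplicates
*are* the edges); the fully deduplicated corpus feeds classification, so a
shared video carries one label everywhere. Reported percentages use
2-decimal round-half-up; conservation (kept + removed = input, per item and
globally) is asserted by tests.

## Network and statistics

Multiplicity is the exact intersection size of two items' video-ID sets;
weights divide by the global maximum so at least one pair sits at 1.0.
Connection statistics per item take the mean and SD of multiplicity over the
other *n* − 1 items with non-edges as 0. The SD uses the population
estimator by default (`ddof=0`); the sample convention is a parameter, since
either is defensible for a fixed, fully observed network. Table output
rounds half-up to one decimal.

## Betweenness centrality

The default mode is unweighted BFS on the support graph: the definition of
BC used here is the pure shortest-path-count ratio, and the support graph
(an edge wherever ≥ 1 video is shared) is its natural domain. Raw scores
are normalized by 2/((n−1)(n−2)). A weighted mode for sensitivity analysis
maps weight to distance 1/w (stronger co-retrieval = closer) and runs
Dijkstra with tie tolerance 1e−9 on path lengths; multiplying all weights
by a constant provably leaves results unchanged, so normalized weights and
raw multiplicities give identical output. All geodesics are counted exactly
(Brandes' accumulation); no sampling. A brute-force enumerator of all
simple paths per pair (guarded to n ≤ 12) serves as the oracle, and the
networkx implementation as an independent cross-check in tests.

On dense co-retrieval networks BC is small and nearly flat — most pairs are
directly connected, so few geodesics have interior nodes. Values then hinge
on exactly which weak pairs lack an edge, which is sampling noise at the
margins; ranks among near-tied nodes should not be over-interpreted.

## Correlogram

Item *i* is represented by row *i* of the multiplicity adjacency matrix with
the diagonal set to 0; r(i, j) is the Pearson correlation between rows i and
j over all n positions. This is the most direct reading of correlating "the
nodes and the edges linking them"; an `exclude_mutual` switch drops the two
mutual positions (m = n − 2) as a sensitivity. Note the conventions differ
in their invariances: scaling all multiplicities never changes r, but adding
a constant only leaves r unchanged under `exclude_mutual` (the structural
zeros on the diagonal do not shift with the data). p-values use the
t transform with df = m − 2, two-sided; zero-variance rows yield missing
(NaN) correlations, never 0. α defaults to 0.05 with no multiple-testing
correction (the raw-p convention for a single descriptive matrix);
Benjamini–Hochberg is available but off by default.

## Text pipeline

Tokenization lowercases and strips punctuation except intra-token hyphens
and digits ("e-cigarette", "v2", "21st" survive). Stop words (a packaged
~270-word English list) are removed on surface forms *before*
lemmatization, so list membership is checked on the form a reader sees.
The default lemmatizer is a dependency-free ordered-suffix-rule stemmer
(-ies→-y; sibilant -es; plural -s with a length guard; -ing/-ed with
consonant undoubling and silent-e restoration; a small exception table for
lexicon-relevant irregulars such as "vaping"→"vape"). Rules are iterated to
a fixed point, which makes idempotence — lemmatize∘lemmatize = lemmatize — a
structural property rather than a hope; a fuzz test asserts it over 10⁴
random tokens. The lemmatizer is deliberately crude outside the vaping
vocabulary; an industrial NLP backend can be registered at run time, but the
default keeps results hermetic and version-independent.

## Rule-based classifier

Four classes; the fallback class has no indicators by construction.
Patterns live in an editable plain-text rules file: literal patterns match
as contiguous lemma phrases (one-word patterns therefore match whole lemmas
only — "pot" never fires inside "potato"), and `a + b` conjunctions require
all terms anywhere in the document. A matched phrase is credited only where
it has at least one occurrence not strictly inside a longer matched
phrase's occurrence: without this, "vape juice" would always co-fire the
device indicator "vape", making the liquid lexicon unable to label anything
cleanly. Conjunctions are position-free and never subsume or get subsumed.
Hits count distinct matched patterns per class; the exclusive label (needed
for pie-style percentage summaries) is the argmax of hits with ties broken
by class order, which puts the device class first — a deliberate,
documented reading, since multi-label matches must collapse somehow for
percentages that sum to 100. Per-item percentages are integers
(round-half-up) over the item's profile-deduplicated video set.

## Synthetic corpus generator

The generator emulates the *structure* of a search-surveillance collection,
not its content:

- A fixed pool of videos partitioned into themes of equal size M; each item
  has a probability mixture over themes. A result is drawn by sampling a
  theme from the item's mixture (restricted to themes with unused videos
  remaining) and then an unused video uniformly from that theme — i.e.
  without replacement per (item, profile). Items with similar mixtures share
  videos; one-hot items on disjoint themes share none, ever.
- Profiles draw independently (personalization is assumed erased between
  profiles), so cross-profile duplication arises only from shared pools.
- Every pooled video gets a class from its theme's class distribution and a
  transcript of `transcript_length` tokens mixing indicator phrases from its
  class's lexicon with background vocabulary. The per-slot insertion
  probability is calibrated so the expected *token* fraction from the
  lexicon equals `indicator_density` even though multi-word phrases span
  several tokens; the fallback class is all background. The packaged
  background vocabulary is disjoint, after lemmatization, from every word of
  every indicator pattern (a regression test enforces this), so phrase
  fragments can never assemble across insertion boundaries.
- One integer seed; the pool uses one substream and each (item, profile)
  a substream keyed by its indices, so adding profiles or items never
  perturbs earlier draws, and equal seeds give byte-identical corpora.

The analytic overlap oracle uses P(video in theme k drawn by item i) =
r·π_ik/M_k capped at 1 — exact when no theme is exhausted — giving
E[shared(i,j)] = Σ_k M·p_ik·p_jk (the K = 1 case reduces to the
hypergeometric expectation r²/M, e.g. 140²/200 = 98, which Monte-Carlo
tests confirm within 3 SE over 200 seeds).

### Study-scale defaults

`study_config()` fixes what a real collection of this design fixes: 18
search items (the standard vaping-related query list), 16 profiles, 140
results per item per profile. The latent structure is the package's own
modeling choice, built from three kinds of 400-video themes:

- one **private** theme per item (the niche results only that query
  surfaces; each profile draws most of its results here, producing the
  heavy cross-profile duplication repeated searching shows);
- one **group** theme per cluster of related items (liquids; mods;
  disposables; pods; the broad general terms), carrying their strong
  pairwise overlap — related pairs share on the order of 150–200 videos;
- six **diffuse** themes every item samples lightly, emulating one large,
  sparsely drawn shared pool: unrelated pairs share only a handful of
  videos, and the weakest (niche–niche) pairs sit near zero, so a few
  support-graph edges are usually missing and betweenness is small but not
  degenerate.

Per-theme class mixes keep devices dominant (~30–57% per item) with
e-liquid, cannabis and fallback shares in realistic ranges. What the
generator does **not** model: result-rank bias, recommendation feedback,
demographic profile effects, transcript grammar or topic drift, and
non-English content. Passing tests therefore demonstrate correctness of the
pipeline's algorithms and its behavior under known structure — not that any
particular live platform exhibits that structure.

## Problem sizes used in checks

Oracle comparisons run on 30 random graphs (n ≤ 10, both BC modes) and 100
random small corpora for the projection; planted-structure recovery uses
two disjoint 500-video themes, four one-hot items each, 140 results, over
100 seeds; classifier recovery uses four one-class themes at indicator
density 1. The acceptance script's study run is the full 18 × 16 × 140
configuration. These sizes make every check exact or high-powered while
keeping a complete run around half a minute.

## Known limitations

- The rule lemmatizer over- and under-stems outside the target vocabulary
  ("parsing"→"par"); acceptable because matching happens in lemma space on
  both sides (patterns and documents are processed identically).
- Cross-item dedup assignment, and hence per-item class denominators, depend
  on the declared item order (documented convention).
- The unweighted BC default ignores edge strength entirely; the weighted
  mode's 1/w distance is one of several defensible transforms.
- `expected_overlap` is approximate when an item's expected draws exceed a
  theme's pool; generation itself remains exact (it renormalizes over
  unexhausted themes and errors only when an item's supported pool is
  smaller than the requested results).
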