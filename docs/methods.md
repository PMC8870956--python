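# Methods

This note documents the models, conventions and numerical choices behind
`supportnet`, and what the synthetic benchmarks do and do not demonstrate.

## Text preprocessing

Posts are split into sentences by terminal punctuation (`.`, `!`, `?`
runs followed by whitespace), with an abbreviation exception list ("Dr.",
"e.g.", ...). Tokenization lowercases, keeps word characters and internal
apostrophes, merges multi-word units (MWUs) from a lexicon into
underscore-joined tokens by longest match *before* stopword removal (so a
phrase containing a stopword, e.g. "quality of life", survives as one
node), then drops stopwords, purely numeric tokens and single-character
tokens. The packaged stopword list is a standard English function-word
list and the packaged MWU lexicon holds common oncology phrases; both are
overridable by plain-text files. No stemming or lemmatization is applied:
merging inflected variants would change node identity, and keyword tables
in this line of work show surface forms.

## Co-occurrence network

The unit of co-occurrence is the whole sentence. Each unordered pair of
*distinct* word types in a sentence contributes 1 to the pair's edge
weight, so a weight is the number of sentences in which the pair co-occurs.
Whether a pair should instead count within-sentence occurrence
multiplicities is a genuine convention choice; sentence-level binary
incidence keeps weights interpretable and is the default, with
`count_multiplicity=True` available. Words that never co-occur with
another word remain as degree-0 nodes: they count toward n and toward
clustering-coefficient averaging.

## Network diagnostics

All diagnostics use the binarized graph: path length is hop distance, and
the local clustering coefficient is m_i / (k_i(k_i−1)/2) with m_i the edge
count among node i's neighbours; nodes with k_i < 2 contribute 0. ASPL is
computed on the largest connected component only (distances across
components are undefined); `component_coverage` reports the fraction of
nodes that component holds so the restriction is visible. Shortest paths
are computed with scipy's sparse-graph BFS, which bounds memory by the
dense n×n distance matrix — fine for the tens of thousands of nodes this
kind of corpus produces.

The Erdős–Rényi baselines are the closed forms
ASPLr = ln n / (ln 2m − ln n) and CCr = 2m / n(n−1), reported unrounded.
ASPLr is undefined when 2m ≤ n (mean degree ≤ 1). Published summary tables
in this literature sometimes print CCr = m/n(n−1) — half the stated
formula; this package implements the stated formula, so its CCr can differ
from such tables by a factor of 2.

The small-world condition "ASPL ≈ ASPLr and CC ≫ CCr" is made operational
as `aspl ≤ r_aspl·aspl_r` and `cc ≥ r_cc·cc_r` with configurable ratios
defaulting to r_aspl = 2 and r_cc = 10. The defaults are deliberately
loose on the path side and strict on the clustering side: empirical word
networks show CC one to three orders of magnitude above CCr, while ASPL
tracks ASPLr within a small factor.

The power-law exponent γ of p(k) ∝ k^(−γ) is estimated by discrete maximum
likelihood: for a candidate cutoff k_min the likelihood uses the Hurwitz
zeta normalizer ζ(γ, k_min), maximized by bounded scalar search on
γ ∈ (1.01, 20); k_min is chosen by minimizing the Kolmogorov–Smirnov
distance between the empirical and model tail CDFs (candidates are the
observed degree values with at least 10 tail observations, capped at the
100 smallest — cutoffs beyond that would leave heavy-tailed word networks
with negligible tails anyway). A log-log regression estimator is included
for qualitative comparison only; it is biased on unbinned tails and is not
used anywhere in the pipeline. A fit is refused when fewer than 10 nodes
have positive degree or the tail is degenerate (a single distinct degree).

## Module detection

Modularity with resolution λ,
Q(c) = (1/2M) Σ_ij [w_ij − λ ℓ_i ℓ_j / 2M] δ_ij(c), is **maximized**. (Some
descriptions of this pipeline family print "minimizing"; the reported Q
values in the 0.4–0.8 range, where high is good, make maximization
unambiguous.) The optimizer is the classic two-phase Louvain procedure:
greedy local node moves until no positive gain, then aggregation of
modules into super-nodes (internal weight carried as self-loops), repeated
until a pass no longer improves Q; by construction Q is non-decreasing
across passes, and the test suite asserts this at runtime. Louvain is
visit-order dependent, so node order is shuffled by a seeded RNG and the
best of `restarts` (default 10) independent runs is returned; ties resolve
to the earliest restart, making results fully deterministic in
(network, λ, seed, restarts). Module ids are contiguous integers ordered
by descending module size. Edge weights are used by default (an unweighted
switch exists). The default resolution is 1.0.

Modules smaller than `min_module_size` (default 5) words are dropped after
detection; their nodes become unassigned and are excluded from silhouette
and edge-proportion denominators, which mirrors computing those statistics
after small-module removal.

The silhouette of node i is (b−a)/max(a,b) with a the mean distance to its
own module and b the smallest mean distance to another module. The
dissimilarity is unweighted shortest-path hop length on the subgraph
induced by assigned nodes — the most parsimonious graph-native choice,
isolated behind a `distance=` switch (`inverse_weight` uses Dijkstra on
1/w edge lengths). Unreachable pairs get (largest finite distance + 1);
a node alone in its module scores 0 (the usual singleton convention).

Module keywords are the members with the highest within-module strength
(weighted degree over internal edges), ties broken lexicographically. This
is a reproducible stand-in for the qualitative keyword selection an
analyst would do; it is not claimed to match any particular published
keyword table.

## Support quantification

PC_k = (edges internal to module k) / (Σ over modules of internal edges);
between-module edges appear in neither numerator nor denominator, so
Σ_k PC_k = 1 exactly. Category proportions per group are sums of PC_k over
the modules assigned to each category.

Module→category assignment is, in the original workflow, expert reading of
module keywords. The package substitutes a transparent rule — score each
category by the within-module-strength-weighted fraction of members in
that category's seed lexicon, highest score wins, ties and all-zero scores
give "unclassified" — plus a manual override map so real analyses can
encode expert judgment while synthetic benchmarks stay automatic.
Unclassified modules are excluded and the three category proportions are
renormalized to sum to 1. In the rendered percentage table each cell is
rounded to 2 decimals and the row's rounding residual (at most ±0.015) is
absorbed into the largest cell so every printed row sums to exactly
100.00.

The chi-squared comparison is Pearson's test of homogeneity without
continuity correction on the group × category table of within-module
**edge counts** — the same units that underlie PC_k. (Posts or modules
would be defensible alternative count units; edges are the documented
convention here.) The table's category set is the set of categories
supplied; a zero row or column marginal is a degenerate-table error.

## Synthetic corpora

The generator plants: several groups, each with a mixture over the three
categories; per post, 3–6 sentences; per sentence, a category drawn from
the group's mixture and 4–10 tokens drawn from that category's vocabulary
with probability `purity` (default 0.95), otherwise from a shared
background vocabulary. Within-vocabulary frequencies are Zipf-ranked
(exponent 1.0): this yields the heavy-tailed degree distributions and
small-world structure characteristic of real word co-occurrence networks,
which uniform sampling would not. Category assignment is per *sentence*,
not per post, because the co-occurrence window is the sentence — planted
structure must live at the granularity the pipeline can see.

Default sizes are desk scale: 8 groups × 400 posts, category vocabularies
of 400 words plus a 200-word background. The vocabulary size was chosen,
by pilot simulation at the default corpus scale, to keep the network
sparsity in the realistic regime (a few hundred sentences per thousand
word types, CC an order of magnitude or more above CCr): much smaller
vocabularies saturate the set of observed word pairs, which both inflates
density beyond anything seen in real communities and compresses the
edge-proportion statistic toward uniformity. The default per-group
mixtures follow the support profiles reported across eight cancer
communities, as realistic study conditions.

What the synthetic benchmarks show: that the pipeline recovers planted
module structure (ARI ≈ 1 at purity 0.95) and planted mixtures (within
±0.08 at 500 posts), that its statistics match independent oracles, and
that detected networks reproduce the qualitative small-world/scale-free
diagnostics. What they do not show: performance on real language —
synthetic "sentences" have no syntax, no polysemy, no shared vocabulary
between categories beyond the background words, and no user or thread
structure, so real-data category assignment quality depends on lexicon
coverage and expert overrides in a way these benchmarks cannot measure.

## Determinism and degenerate inputs

All randomness flows from integer seeds (numpy Generators and seeded
`random.Random` for visit orders); dictionary iteration never influences
results (orderings are explicit), so equal inputs and seeds give
byte-identical report files — the run log records library versions, the
seed and a config hash, and deliberately no timestamp. Degenerate inputs
raise typed errors rather than returning silently wrong numbers: empty
corpora, all-isolated networks (ASPL), 2m ≤ n (ASPLr), edgeless graphs
(modularity), single-module partitions (silhouette), all-small modules
after filtering, all-unclassified profiles, and contingency tables with a
zero marginal.

## Known limitations

- Sentence splitting is rule-based; unusual abbreviations or ellipses can
  over- or under-split. The splitter is deliberately simple and auditable.
- The category lexicons shipped as defaults are small seed vocabularies;
  real analyses should extend them or use overrides.
- Louvain is a greedy heuristic: on small graphs it attains the exhaustive
  optimum (verified up to 8 nodes), but on large graphs only a good local
  optimum is guaranteed.
- The dense distance matrix in the silhouette computation is O(n²) memory,
  which caps practical module-quality scoring at roughly 30k nodes.
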