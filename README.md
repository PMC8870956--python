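# supportnet

Word co-occurrence network analysis of social support in online health
communities.

Members of disease-specific online communities exchange several kinds of
social support — **informational support** (facts, suggestions, guidance),
**emotional support** (understanding, encouragement, empathy), and
**companionship** (everyday chat not necessarily about health). `supportnet`
quantifies how much of each kind a community exchanges, directly from the
semantic structure of its posts, without hand-coding individual messages. It
is aimed at health-informatics researchers comparing support communication
across patient groups (e.g. cancer types).

## Method

For each group of posts the pipeline:

1. **Builds a word co-occurrence network** G = (V, E): posts are split into
   sentences, tokenized (lowercased; stopwords, punctuation, numerals
   removed; domain phrases such as "side effects" merged into single
   underscore-joined units), and two words are connected if they co-occur in
   at least one sentence; the edge weight w_ij counts co-occurring
   sentences.
2. **Characterizes the network**: average shortest-path length ASPL and mean
   clustering coefficient CC, compared with the Erdős–Rényi baselines
   ASPLr ≈ ln n / (ln 2m − ln n) and CCr ≈ 2m / n(n−1) (small-world check:
   ASPL comparable to ASPLr while CC ≫ CCr), plus the degree-distribution
   power-law exponent γ in p(k) ∝ k^(−γ), fitted by discrete maximum
   likelihood with a Kolmogorov–Smirnov-selected lower cutoff.
3. **Detects word modules** by maximizing resolution-parameterized
   modularity

       Q(c) = (1/2M) Σ_ij [ w_ij − λ ℓ_i ℓ_j / 2M ] δ_ij(c)

   with a seeded, restartable Louvain optimizer (M total edge weight, ℓ_i
   node strength, λ the resolution, default 1.0). Modules with fewer than
   five words are dropped; partition quality is scored by a
   shortest-path-distance silhouette.
4. **Quantifies support**: each module's share of communication mass is its
   edge proportion PC_k = (edges inside module k) / (all within-module
   edges), so Σ_k PC_k = 1. Modules are mapped to the three support
   categories by a transparent lexicon-scoring rule (with manual override
   for expert judgment), and category proportions per group are the PC_k
   sums. Groups are compared with a Pearson chi-squared test of homogeneity
   on the within-module edge counts.

Because real patient-community corpora usually cannot be redistributed, the
package ships a **synthetic corpus generator** with planted category
structure (per-group category mixtures, sentence-level topic purity,
Zipf-distributed vocabularies), so the entire pipeline is testable and
benchmarkable offline against a known ground truth.

## Worked example

```python
from supportnet import (AnalysisConfig, SyntheticConfig, generate_corpus,
                        run_all, truth_lexicon)

config = SyntheticConfig(posts_per_group=150, seed=7)   # 8 groups, planted mixtures
posts, truth = generate_corpus(config)
result = run_all(posts, "out", AnalysisConfig(seed=7, lexicon=truth_lexicon(truth)))
print(result["profile_table"])
chi2, dof, p = result["chi2"]
print(f"chi2={chi2:.1f} df={dof} p={p:.3g}")
```

prints

```
            informational  emotional  companionship
breast              37.46      44.05          18.49
colon               50.65       9.61          39.74
lung                49.35      16.92          33.73
ovarian             34.38      36.64          28.98
pancreatic          53.15      14.81          32.04
prostate            40.93      37.01          22.06
renal               43.24      28.29          28.47
skin                39.85      24.99          35.16
chi2=4586.9 df=14 p=0
```

Each row is one group's support profile in percent (rows sum to 100); the
chi-squared line says the category distribution differs across groups. The
recovered profiles track the planted mixtures (e.g. "breast" was planted
with 40.7 / 40.5 / 18.9). `out/` receives four CSV reports — per-group
network diagnostics, the per-module table (edge share, silhouette,
keywords, category), the module-detection summary, and the support
profiles — plus the chi-squared result and a run log with versions, seed
and config hash; identical inputs and seed reproduce the reports
byte-for-byte.

The same pipeline runs from the shell:

```bash
supportnet simulate --posts-per-group 150 --seed 7 --out-dir sim
supportnet run-all sim/corpus.jsonl --seed 7 --lexicon sim/lexicon.txt --out-dir out
```

Real corpora are read from JSONL or CSV with columns `post_id`, `group`,
`text`.

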