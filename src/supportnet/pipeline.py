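"""End-to-end orchestration: corpus → per-group networks → diagnostics →
modules → support profiles → group comparison, with deterministic report
files.

``run_all`` writes four CSV reports shaped like the analysis's summary
tables — network_summary.csv (per-group network diagnostics),
module_report.csv (per-module edge share / silhouette / keywords),
module_summary.csv (per-group modularity and module counts),
support_profiles.csv (per-group category percentages) — plus
comparison.csv (chi-squared test) and run_log.txt (library versions, seed,
config hash). Outputs contain no timestamps, so identical inputs and seed
reproduce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy

from . import __version__
from .corpus import (
    Post,
    TokenizedSentence,
    default_mwu_lexicon,
    default_stopwords,
    load_wordlist,
    tokenize_posts,
)
from .errors import EmptyInputError, UndefinedStatisticError
from .modules import ModulePartition, ModuleSummary, filter_modules, louvain_partition
from .netstats import NetworkStats, compute_stats
from .network import CooccurrenceNetwork, build_network
from .support import (
    CategoryLexicon,
    SupportProfile,
    category_profile,
    compare_profiles,
    edge_proportions,
    profile_table,
    summarize_modules,
    within_edge_counts,
)

__all__ = ["AnalysisConfig", "GroupResult", "analyze_group", "run_all"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable knobs of the full pipeline."""

    resolution: float = 1.0
    min_module_size: int = 5
    seed: int = 0
    restarts: int = 10
    r_aspl: float = 2.0
    r_cc: float = 10.0
    count_multiplicity: bool = False
    stopwords_path: str | None = None
    mwu_path: str | None = None
    lexicon_path: str | None = None
    lexicon: CategoryLexicon | None = None
    category_overrides: Mapping[str, Mapping[int, str]] | None = None

    def config_hash(self) -> str:
        def _encode(obj):
            if isinstance(obj, (set, frozenset)):
                return sorted(obj)
            return str(obj)

        payload = json.dumps(asdict(self), sort_keys=True, default=_encode)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class GroupResult:
    group: str
    sentences: int
    net: CooccurrenceNetwork
    stats: NetworkStats
    partition: ModulePartition
    filtered: ModulePartition
    summaries: list[ModuleSummary]
    profile: SupportProfile
    mean_silhouette: float


def _resources(config: AnalysisConfig):
    stopwords = (
        frozenset(load_wordlist(config.stopwords_path))
        if config.stopwords_path
        else default_stopwords()
    )
    mwu = (
        tuple(load_wordlist(config.mwu_path)) if config.mwu_path else default_mwu_lexicon()
    )
    if config.lexicon is not None:
        lexicon = config.lexicon
    elif config.lexicon_path:
        lexicon = CategoryLexicon.from_file(config.lexicon_path)
    else:
        lexicon = CategoryLexicon.default()
    return stopwords, mwu, lexicon


def analyze_group(
    sentences: Sequence[TokenizedSentence],
    group: str,
    config: AnalysisConfig,
    lexicon: CategoryLexicon,
) -> GroupResult:
    """Run the per-group pipeline on already-tokenized sentences."""
    net = build_network(sentences, count_multiplicity=config.count_multiplicity)
    stats = compute_stats(net, r_aspl=config.r_aspl, r_cc=config.r_cc)
    partition = louvain_partition(
        net, resolution=config.resolution, seed=config.seed, restarts=config.restarts
    )
    filtered = filter_modules(partition, config.min_module_size, net=net)
    overrides = (config.category_overrides or {}).get(group)
    summaries = summarize_modules(net, filtered, lexicon, overrides)
    pcs = edge_proportions(net, filtered)
    counts = within_edge_counts(net, filtered)
    categories = {s.module_id: s.category for s in summaries}
    profile = category_profile(pcs, categories, counts, group=group)
    sil_values = [s.silhouette for s in summaries if not math.isnan(s.silhouette)]
    mean_sil = sum(sil_values) / len(sil_values) if sil_values else float("nan")
    return GroupResult(
        group=group,
        sentences=len(sentences),
        net=net,
        stats=stats,
        partition=partition,
        filtered=filtered,
        summaries=summaries,
        profile=profile,
        mean_silhouette=mean_sil,
    )


def run_all(
    posts: Sequence[Post],
    out_dir: str | Path,
    config: AnalysisConfig = AnalysisConfig(),
) -> dict:
    """Full analysis of a corpus; returns results and writes the report
    files into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stopwords, mwu, lexicon = _resources(config)
    sentences = tokenize_posts(posts, stopwords, mwu)
    if not sentences:
        raise EmptyInputError("corpus produced no tokenized sentences")

    groups = sorted({p.group for p in posts})
    results: dict[str, GroupResult] = {}
    for group in groups:
        group_sents = [s for s in sentences if s.group == group]
        results[group] = analyze_group(group_sents, group, config, lexicon)

    profiles = [results[g].profile for g in groups]
    table, means = profile_table(profiles)
    try:
        chi2, dof, pval = compare_profiles(profiles)
    except UndefinedStatisticError:
        chi2, dof, pval = float("nan"), 0, float("nan")

    _write_reports(out, results, groups, table, means, (chi2, dof, pval), config)
    return {
        "groups": results,
        "profile_table": table,
        "column_means": means,
        "chi2": (chi2, dof, pval),
    }


def _fmt(x: float, nd: int = 3) -> str:
    return "" if x is None or (isinstance(x, float) and math.isnan(x)) else f"{x:.{nd}f}"


def _write_reports(out, results, groups, table, means, chi2_tuple, config):
    rows = []
    for g in groups:
        r = results[g]
        s = r.stats
        rows.append(
            {
                "group": g,
                "sentences": r.sentences,
                "words": r.net.n,
                "cooccurrence_pairs": r.net.m,
                "aspl": _fmt(s.aspl),
                "aspl_r": _fmt(s.aspl_r),
                "cc": _fmt(s.cc),
                "cc_r": _fmt(s.cc_r, 6),
                "gamma": _fmt(s.gamma),
                "small_world": s.is_small_world,
                "component_coverage": _fmt(s.component_coverage),
            }
        )
    pd.DataFrame(rows).to_csv(out / "network_summary.csv", index=False)

    rows = []
    for g in groups:
        for s in results[g].summaries:
            rows.append(
                {
                    "group": g,
                    "module_id": s.module_id,
                    "pct_of_edges": f"{100 * s.edge_proportion:.2f}",
                    "silhouette": _fmt(s.silhouette),
                    "category": s.category,
                    "selected_keywords": "; ".join(s.top_keywords),
                }
            )
    pd.DataFrame(rows).to_csv(out / "module_report.csv", index=False)

    rows = []
    for g in groups:
        r = results[g]
        rows.append(
            {
                "group": g,
                "modularity": _fmt(r.filtered.modularity_q),
                "cc": _fmt(r.stats.cc),
                "silhouette": _fmt(r.mean_silhouette),
                "num_modules": r.filtered.num_modules,
            }
        )
    pd.DataFrame(rows).to_csv(out / "module_summary.csv", index=False)

    t4 = table.copy()
    t4.index.name = "group"
    t4 = t4.map(lambda v: f"{v:.2f}")
    t4.loc["mean"] = [f"{means[c]:.2f}" for c in t4.columns]
    t4.to_csv(out / "support_profiles.csv")

    chi2, dof, pval = chi2_tuple
    with open(out / "comparison.csv", "w", encoding="utf-8") as fh:
        fh.write("statistic,df,p_value\n")
        fh.write(f"{_fmt(chi2, 4)},{dof},{_fmt(pval, 6) if pval == pval else ''}\n")

    with open(out / "run_log.txt", "w", encoding="utf-8") as fh:
        fh.write(f"supportnet={__version__}\n")
        fh.write(f"networkx={nx.__version__}\n")
        fh.write(f"numpy={np.__version__}\n")
        fh.write(f"scipy={scipy.__version__}\n")
        fh.write(f"pandas={pd.__version__}\n")
        fh.write(f"seed={config.seed}\n")
        fh.write(f"config_hash={config.config_hash()}\n")
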