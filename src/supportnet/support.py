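"""Social-support quantification.

Each detected word module carries a share of the network's communication
mass, measured by the edge proportion

    PC_k = (# edges internal to module C_k) / (Σ_k # edges internal to C_k),

so Σ_k PC_k = 1 (between-module edges are excluded from numerator and
denominator alike). Modules are mapped onto the three-way social-support
taxonomy — informational support (facts, suggestions, guidance), emotional
support (understanding, encouragement, empathy), companionship (everyday
chat) — by a transparent lexicon-scoring rule with manual override, and the
category proportions per disease group are the PC_k sums. Groups are
compared with a Pearson chi-squared test of homogeneity on the underlying
within-module edge counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from importlib import resources
from scipy.stats import chi2_contingency

from .errors import ConfigError, UndefinedStatisticError, UsageError
from .modules import ModulePartition, ModuleSummary, module_silhouette, top_keywords
from .network import CooccurrenceNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "CategoryLexicon",
    "SupportProfile",
    "edge_proportions",
    "within_edge_counts",
    "write_lexicon",
    "assign_categories",
    "summarize_modules",
    "category_profile",
    "profile_table",
    "compare_profiles",
]

CATEGORIES = ("informational", "emotional", "companionship")


@dataclass(frozen=True)
class CategoryLexicon:
    """Seed vocabularies for the three support categories (pairwise disjoint)."""

    informational: frozenset[str]
    emotional: frozenset[str]
    companionship: frozenset[str]

    def __post_init__(self) -> None:
        sets = [self.informational, self.emotional, self.companionship]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = sets[i] & sets[j]
                if overlap:
                    raise ConfigError(
                        f"category word sets overlap: {sorted(overlap)[:5]} ..."
                    )

    def words(self, category: str) -> frozenset[str]:
        return getattr(self, category)

    @classmethod
    def from_file(cls, path: str | Path) -> "CategoryLexicon":
        """Parse a lexicon file: ``[category]`` headers, one word per line,
        '#' comments allowed."""
        sets: dict[str, set[str]] = {c: set() for c in CATEGORIES}
        current: str | None = None
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                current = line[1:-1].strip().lower()
                if current not in sets:
                    raise ConfigError(f"unknown category header [{current}]")
                continue
            if current is None:
                raise ConfigError(f"word {line!r} appears before any [category] header")
            sets[current].add(line.lower())
        return cls(
            informational=frozenset(sets["informational"]),
            emotional=frozenset(sets["emotional"]),
            companionship=frozenset(sets["companionship"]),
        )

    @classmethod
    def default(cls) -> "CategoryLexicon":
        """Packaged seed lexicon following the taxonomy's example topics."""
        with resources.as_file(
            resources.files("supportnet.data").joinpath("support_lexicon.txt")
        ) as path:
            return cls.from_file(path)


@dataclass
class SupportProfile:
    """Per-group proportions over the three support categories, with the
    within-module edge counts they were derived from."""

    group: str
    proportions: dict[str, float]
    edge_counts: dict[str, int]

    def validate(self) -> None:
        total = sum(self.proportions.get(c, 0.0) for c in CATEGORIES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, not 1")
        for c, count in self.edge_counts.items():
            if count < 0 or int(count) != count:
                raise ValueError(f"edge count for {c} is not a non-negative integer")


def write_lexicon(lexicon: CategoryLexicon, path: str | Path) -> None:
    """Write a lexicon in the bracket-header file format."""
    with open(path, "w", encoding="utf-8") as fh:
        for cat in CATEGORIES:
            fh.write(f"[{cat}]\n")
            for word in sorted(lexicon.words(cat)):
                fh.write(word + "\n")


def within_edge_counts(
    net: CooccurrenceNetwork, p: ModulePartition
) -> dict[int, int]:
    """Number of edges internal to each module (endpoints both assigned to
    that module)."""
    counts = {mod: 0 for mod in p.module_members}
    for u, v in net.graph.edges():
        cu = p.assignment.get(u)
        cv = p.assignment.get(v)
        if cu is not None and cu == cv:
            counts[cu] += 1
    return counts


def edge_proportions(
    net: CooccurrenceNetwork, p: ModulePartition
) -> dict[int, float]:
    """PC_k for every module of the (filtered) partition; sums to 1."""
    counts = within_edge_counts(net, p)
    total = sum(counts.values())
    if total == 0:
        raise UndefinedStatisticError(
            "edge proportions undefined: no within-module edges"
        )
    return {mod: c / total for mod, c in counts.items()}


def _module_scores(
    net: CooccurrenceNetwork,
    members: set,
    lexicon: CategoryLexicon,
) -> dict[str, float]:
    sub = net.graph.subgraph(members)
    strength = {node: 0.0 for node in members}
    for u, v, d in sub.edges(data=True):
        w = d.get("weight", 1)
        strength[u] += w
        strength[v] += w
    total = sum(strength.values())
    if total == 0:  # no internal edges: fall back to unweighted membership
        strength = {node: 1.0 for node in members}
        total = float(len(members))
    scores = {}
    for cat in CATEGORIES:
        vocab = lexicon.words(cat)
        scores[cat] = sum(s for node, s in strength.items() if node in vocab) / total
    return scores


def assign_categories(
    net: CooccurrenceNetwork,
    p: ModulePartition,
    lexicon: CategoryLexicon | None = None,
    overrides: Mapping[int, str] | None = None,
) -> dict[int, str]:
    """Assign each module a support category by lexicon scoring.

    A module's score for a category is the within-module-strength-weighted
    fraction of its members found in that category's word set; the highest
    score wins. A tie, or all-zero scores, yields "unclassified". Manual
    ``overrides`` (module id → category) take absolute precedence and are
    logged.
    """
    if lexicon is None:
        lexicon = CategoryLexicon.default()
    overrides = dict(overrides or {})
    members = p.module_members
    for mod, cat in overrides.items():
        if mod not in members:
            raise UsageError(f"override names nonexistent module {mod}")
        if cat not in CATEGORIES + ("unclassified",):
            raise UsageError(f"override category {cat!r} unknown")
        logger.info("module %d category overridden to %s", mod, cat)

    result: dict[int, str] = {}
    for mod, nodes in members.items():
        if mod in overrides:
            result[mod] = overrides[mod]
            continue
        scores = _module_scores(net, nodes, lexicon)
        best = max(scores.values())
        winners = [c for c in CATEGORIES if abs(scores[c] - best) <= 1e-12]
        result[mod] = winners[0] if best > 0 and len(winners) == 1 else "unclassified"
    return result


def summarize_modules(
    net: CooccurrenceNetwork,
    p: ModulePartition,
    lexicon: CategoryLexicon | None = None,
    overrides: Mapping[int, str] | None = None,
    k_keywords: int = 5,
) -> list[ModuleSummary]:
    """Build the per-module report (size, PC_k, silhouette, keywords,
    category), ordered by module id. With a single module the silhouette is
    reported as NaN."""
    pcs = edge_proportions(net, p)
    try:
        sils = module_silhouette(net, p)
    except UndefinedStatisticError:
        sils = {mod: float("nan") for mod in p.module_members}
    cats = assign_categories(net, p, lexicon, overrides)
    summaries = []
    for mod in sorted(p.module_members):
        summaries.append(
            ModuleSummary(
                module_id=mod,
                size=len(p.module_members[mod]),
                edge_proportion=pcs[mod],
                silhouette=sils[mod],
                top_keywords=tuple(top_keywords(net, p, mod, k=k_keywords)),
                category=cats[mod],
            )
        )
    return summaries


def category_profile(
    pcs: Mapping[int, float],
    categories: Mapping[int, str],
    edge_counts: Mapping[int, int] | None = None,
    group: str = "all",
) -> SupportProfile:
    """Aggregate module edge proportions into a per-group support profile.

    Category proportion = Σ PC_k over that category's modules, renormalized
    over the three classified categories (unclassified modules are
    excluded). Within-module edge counts are carried alongside for the
    chi-squared comparison.
    """
    sums = {c: 0.0 for c in CATEGORIES}
    counts = {c: 0 for c in CATEGORIES}
    for mod, pc in pcs.items():
        cat = categories.get(mod, "unclassified")
        if cat in sums:
            sums[cat] += pc
            if edge_counts is not None:
                counts[cat] += int(edge_counts[mod])
    total = sum(sums.values())
    if total == 0:
        raise UndefinedStatisticError(
            "profile undefined: every module is unclassified"
        )
    proportions = {c: sums[c] / total for c in CATEGORIES}
    return SupportProfile(group=group, proportions=proportions, edge_counts=counts)


def profile_table(
    profiles: Sequence[SupportProfile],
) -> tuple[pd.DataFrame, pd.Series]:
    """Render group × category percentages (2 decimals) plus unweighted
    column means across groups.

    Returns (table, means): ``table`` rows are groups and columns the three
    categories in percent; ``means`` holds the column means of the
    *unrounded* percentages.
    """
    if not profiles:
        raise UndefinedStatisticError("profile table needs at least one profile")
    raw = pd.DataFrame(
        {c: [p.proportions.get(c, 0.0) * 100.0 for p in profiles] for c in CATEGORIES},
        index=[p.group for p in profiles],
    )
    means = raw.mean(axis=0)
    rendered = raw.round(2)
    # largest-remainder correction: rounding three cells independently can
    # leave a row summing to 99.99 or 100.01; absorb the residual into the
    # largest cell so every rendered row sums to exactly 100.00
    for group in rendered.index:
        residual = 100.0 - rendered.loc[group].sum()
        if abs(residual) > 1e-9:
            top = raw.loc[group].idxmax()
            rendered.loc[group, top] = round(rendered.loc[group, top] + residual, 2)
    return rendered, means


def compare_profiles(
    profiles: Sequence[SupportProfile],
) -> tuple[float, int, float]:
    """Pearson chi-squared test of homogeneity on the group × category
    within-module edge-count table (no continuity correction).

    Returns (statistic, degrees of freedom, p-value) with
    df = (groups − 1)(categories − 1).
    """
    if len(profiles) < 2:
        raise UndefinedStatisticError("chi-squared comparison needs ≥ 2 groups")
    present = [c for c in CATEGORIES if any(c in p.edge_counts for p in profiles)]
    if len(present) < 2:
        raise UndefinedStatisticError("chi-squared comparison needs ≥ 2 categories")
    table = pd.DataFrame(
        {c: [p.edge_counts.get(c, 0) for p in profiles] for c in present},
        index=[p.group for p in profiles],
    )
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise UndefinedStatisticError(
            "degenerate contingency table: a group or category has zero edges"
        )
    res = chi2_contingency(table.to_numpy(), correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)
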