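"""Network diagnostics: ASPL, clustering, Erdős–Rényi baselines, degree
distribution, power-law exponent, and the small-world check.

All statistics are computed on the unweighted (binarized) graph: path length
is hop distance d_ij and the local clustering coefficient is
m_i / (k_i(k_i-1)/2), where m_i counts edges among the k_i neighbours of
node i. ASPL is restricted to the largest connected component (d_ij is
undefined across components); ``component_coverage`` reports the fraction of
nodes that component contains so the restriction is visible.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.sparse.csgraph import shortest_path
from scipy.special import zeta

from .errors import UndefinedStatisticError
from .network import CooccurrenceNetwork

__all__ = [
    "NetworkStats",
    "PowerLawFit",
    "average_shortest_path_length",
    "clustering_coefficient",
    "er_baselines",
    "degree_distribution",
    "fit_power_law",
    "loglog_regression_gamma",
    "small_world_check",
    "compute_stats",
    "sample_discrete_power_law",
]


@dataclass
class NetworkStats:
    aspl: float
    cc: float
    aspl_r: float
    cc_r: float
    gamma: float | None
    k_min: int | None
    degree_histogram: dict[int, int]
    is_small_world: bool
    component_coverage: float


@dataclass
class PowerLawFit:
    """Discrete maximum-likelihood power-law fit p(k) ∝ k^(-gamma), k ≥ k_min."""

    gamma: float
    k_min: int
    n_tail: int
    ks_distance: float


def _graph(net: CooccurrenceNetwork | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, CooccurrenceNetwork) else net


def average_shortest_path_length(net: CooccurrenceNetwork | nx.Graph) -> float:
    """Mean hop distance over all unordered node pairs of the largest
    connected component."""
    g = _graph(net)
    if g.number_of_nodes() == 0:
        raise UndefinedStatisticError("ASPL undefined for an empty graph")
    component = max(nx.connected_components(g), key=len)
    if len(component) < 2:
        raise UndefinedStatisticError(
            "ASPL undefined: largest component has fewer than 2 nodes"
        )
    sub = g.subgraph(component)
    adj = nx.to_scipy_sparse_array(sub, nodelist=sorted(component, key=str), format="csr")
    dists = shortest_path(adj, method="D", directed=False, unweighted=True)
    k = dists.shape[0]
    return float(dists.sum() / (k * (k - 1)))


def clustering_coefficient(net: CooccurrenceNetwork | nx.Graph) -> float:
    """Mean local clustering coefficient over all nodes; nodes with degree
    < 2 contribute 0."""
    g = _graph(net)
    if g.number_of_nodes() == 0:
        raise UndefinedStatisticError("CC undefined for an empty graph")
    return nx.average_clustering(g, count_zeros=True)


def er_baselines(n: int, m: int) -> tuple[float, float]:
    """Erdős–Rényi baselines for a graph with n nodes and m edges.

    ASPLr = ln(n) / (ln(2m) - ln(n)) and CCr = 2m / (n(n-1)), both returned
    unrounded.
    """
    if n < 2 or m < 1:
        raise UndefinedStatisticError(f"ER baselines need n ≥ 2 and m ≥ 1 (got n={n}, m={m})")
    if 2 * m <= n:
        raise UndefinedStatisticError(
            f"ASPLr undefined for 2m ≤ n (mean degree ≤ 1; n={n}, m={m})"
        )
    aspl_r = math.log(n) / (math.log(2 * m) - math.log(n))
    cc_r = 2 * m / (n * (n - 1))
    return aspl_r, cc_r


def degree_distribution(net: CooccurrenceNetwork | nx.Graph) -> dict[int, int]:
    """Histogram degree k → node count; counts sum to n. Divide by n for p(k)."""
    g = _graph(net)
    if g.number_of_nodes() == 0:
        raise UndefinedStatisticError("degree distribution undefined for an empty graph")
    return dict(Counter(d for _, d in g.degree()))


def _expand(degree_histogram: Mapping[int, int] | Iterable[int]) -> np.ndarray:
    if isinstance(degree_histogram, Mapping):
        degrees = np.repeat(
            np.fromiter(degree_histogram.keys(), dtype=np.int64),
            np.fromiter(degree_histogram.values(), dtype=np.int64),
        )
    else:
        degrees = np.asarray(list(degree_histogram), dtype=np.int64)
    return degrees


def _mle_gamma(tail: np.ndarray, k_min: int) -> float:
    log_sum = float(np.log(tail).sum())
    n = tail.size

    def nll(g: float) -> float:
        return g * log_sum + n * math.log(zeta(g, k_min))

    res = minimize_scalar(nll, bounds=(1.01, 20.0), method="bounded")
    return float(res.x)

def _ks_distance(tail: np.ndarray, gamma: float, k_min: int) -> float:
    ks = np.unique(tail)
    z0 = zeta(gamma, k_min)
    model_cdf = 1.0 - zeta(gamma, ks + 1) / z0
    emp_cdf = np.searchsorted(np.sort(tail), ks, side="right") / tail.size
    return float(np.abs(emp_cdf - model_cdf).max())


def fit_power_law(
    degree_histogram: Mapping[int, int] | Iterable[int],
    k_min: int | None = None,
    min_tail: int = 10,
    max_candidates: int = 100,
) -> PowerLawFit:
    """Fit p(k) ∝ k^(-gamma) to a degree sample by discrete maximum
    likelihood, selecting the lower cutoff k_min by Kolmogorov–Smirnov
    minimization (Clauset-style) unless a fixed ``k_min`` is given.

    Requires at least ``min_tail`` observations at or above the cutoff and at
    least two distinct degree values there; otherwise the fit is undefined.
    """
    degrees = _expand(degree_histogram)
    degrees = degrees[degrees >= 1]
    if degrees.size < min_tail:
        raise UndefinedStatisticError(
            f"power-law fit needs ≥ {min_tail} nodes with degree ≥ 1"
        )

    if k_min is not None:
        candidates = [int(k_min)]
    else:
        uniq = np.unique(degrees)
        candidates = [
            int(k) for k in uniq if (degrees >= k).sum() >= min_tail
        ][:max_candidates]
    if not candidates:
        raise UndefinedStatisticError("no admissible k_min with a large enough tail")

    best: PowerLawFit | None = None
    for cand in candidates:
        tail = degrees[degrees >= cand]
        if tail.size < min_tail or np.unique(tail).size < 2:
            continue
        gamma = _mle_gamma(tail, cand)
        dist = _ks_distance(tail, gamma, cand)
        if best is None or dist < best.ks_distance:
            best = PowerLawFit(gamma=gamma, k_min=cand, n_tail=int(tail.size), ks_distance=dist)
    if best is None:
        raise UndefinedStatisticError(
            "power-law fit undefined: degenerate degree sample (all degrees equal)"
        )
    return best


def loglog_regression_gamma(degree_histogram: Mapping[int, int]) -> float:
    """Slope-based exponent estimate from a least-squares fit of
    log p(k) on log k. Provided for comparison only; the MLE fit is the
    supported estimator."""
    ks = np.array(sorted(k for k in degree_histogram if k >= 1), dtype=float)
    if ks.size < 2:
        raise UndefinedStatisticError("log-log regression needs ≥ 2 distinct degrees")
    counts = np.array([degree_histogram[int(k)] for k in ks], dtype=float)
    p = counts / counts.sum()
    slope = np.polyfit(np.log(ks), np.log(p), 1)[0]
    return float(-slope)


def small_world_check(
    stats: "NetworkStats",
    r_aspl: float = 2.0,
    r_cc: float = 10.0,
) -> bool:
    """Small-world test: ASPL comparable to the random baseline
    (aspl ≤ r_aspl × aspl_r) while CC greatly exceeds it
    (cc ≥ r_cc × cc_r)."""
    for value in (stats.aspl, stats.aspl_r, stats.cc, stats.cc_r):
        if value is None or not math.isfinite(value):
            return False
    return stats.aspl <= r_aspl * stats.aspl_r and stats.cc >= r_cc * stats.cc_r


def compute_stats(
    net: CooccurrenceNetwork,
    r_aspl: float = 2.0,
    r_cc: float = 10.0,
    fit_gamma: bool = True,
) -> NetworkStats:
    """Compute the full diagnostic bundle for one network.

    The power-law exponent is set to None when the degree sample is too
    small or degenerate for a defined fit.
    """
    g = net.graph
    hist = degree_distribution(net)
    aspl = average_shortest_path_length(net)
    cc = clustering_coefficient(net)
    aspl_r, cc_r = er_baselines(net.n, net.m)
    gamma: float | None = None
    k_min: int | None = None
    if fit_gamma:
        try:
            fit = fit_power_law(hist)
            gamma, k_min = fit.gamma, fit.k_min
        except UndefinedStatisticError:
            pass
    component = max(nx.connected_components(g), key=len)
    stats = NetworkStats(
        aspl=aspl,
        cc=cc,
        aspl_r=aspl_r,
        cc_r=cc_r,
        gamma=gamma,
        k_min=k_min,
        degree_histogram=hist,
        is_small_world=False,
        component_coverage=len(component) / net.n,
    )
    stats.is_small_world = small_world_check(stats, r_aspl=r_aspl, r_cc=r_cc)
    return stats


def sample_discrete_power_law(
    gamma: float,
    k_min: int,
    size: int,
    rng: np.random.Generator,
    k_max: int = 10**6,
) -> np.ndarray:
    """Draw ``size`` integers from p(k) ∝ k^(-gamma), k_min ≤ k ≤ k_max,
    by inverse-CDF sampling (k_max truncation mass is negligible for the
    exponents of interest, gamma > 2)."""
    ks = np.arange(k_min, k_max + 1, dtype=np.float64)
    pmf = ks ** (-gamma)
    cdf = np.cumsum(pmf)
    cdf /= cdf[-1]
    u = rng.random(size)
    return (np.searchsorted(cdf, u, side="left") + k_min).astype(np.int64)
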