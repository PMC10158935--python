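"""Network topology statistics and the degree-preserving null model.

A scale-free check (log-log OLS of the degree frequency), average shortest
path length over connected pairs, and an empirical test of the real
network's path length against degree-preserving rewired replicas
(double-edge swaps that keep every node's degree — and, for bipartite
regulatory networks, its class partners — exactly fixed).
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .datatypes import RegulatoryNetwork


def _as_graph(net) -> nx.Graph:
    return net.graph if isinstance(net, RegulatoryNetwork) else net


def fit_power_law(degree_sequence) -> tuple[float, float]:
    """OLS of log10 P(k) on log10 k over degrees with nonzero frequency.

    Returns (slope, R²). Requires ≥3 distinct positive degrees.
    """
    deg = np.asarray(degree_sequence, dtype=int)
    if deg.size == 0:
        raise ValueError("empty degree sequence")
    ks, counts = np.unique(deg[deg > 0], return_counts=True)
    if ks.size < 3:
        raise ValueError("need ≥3 distinct positive degrees for a power-law fit")
    freq = counts / counts.sum()
    res = stats.linregress(np.log10(ks), np.log10(freq))
    return float(res.slope), float(res.rvalue**2)


def average_path_length(net) -> float:
    """Mean unweighted shortest-path distance over connected node pairs.

    Pairs in different components are excluded from the mean.
    """
    g = _as_graph(net)
    if g.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes")
    total = 0
    n_pairs = 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for d in dists.values():
            if d > 0:
                total += d
                n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no connected node pair")
    return total / n_pairs


def degree_preserving_randomize(net, n_swaps: int, seed: int = 0):
    """Rewire by repeated double-edge swaps, keeping every degree fixed.

    Each attempt picks two edges (a–b, c–d) and proposes (a–d, c–b);
    attempts creating self-loops, parallel edges or — when node classes are
    present — edges within a class pair not seen in the original bipartition
    are skipped. ``n_swaps`` counts attempts. Edge attributes are dropped
    (the null model is purely topological); node attributes are kept.
    Returns the same type as the input.
    """
    is_net = isinstance(net, RegulatoryNetwork)
    g_in = _as_graph(net)
    if g_in.number_of_edges() < 2:
        raise ValueError("need at least 2 edges to swap")
    classes = nx.get_node_attributes(g_in, "cls")
    bipartite = bool(classes) and is_net and net.polarity in ("negative", "positive")

    g = nx.Graph()
    g.add_nodes_from(g_in.nodes(data=True))
    g.add_edges_from(g_in.edges())
    edges = list(g.edges())
    rng = np.random.default_rng(seed)

    reg_cls = "miRNA" if (is_net and net.polarity == "negative") else "lncRNA"

    def part(v):  # regulator side (miRNA, or lncRNA in ceRNA nets) vs target side
        return classes.get(v) == reg_cls

    for _ in range(n_swaps):
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if bipartite:
            # orient both edges with the regulator-side endpoint first
            if not part(a):
                a, b = b, a
            if not part(c):
                c, d = d, c
        elif rng.integers(2):
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        if g.has_edge(a, d) or g.has_edge(c, b):
            continue
        g.remove_edge(*edges[i])
        g.remove_edge(*edges[j])
        g.add_edge(a, d)
        g.add_edge(c, b)
        edges[i], edges[j] = (a, d), (c, b)

    if is_net:
        return RegulatoryNetwork(g, net.polarity)
    return g


@dataclass
class TopologySummary:
    """Degree statistics plus the rewired-null path-length comparison."""

    degree_sequence: list[int]
    powerlaw_slope: float | None
    powerlaw_r2: float | None
    apl_real: float
    apl_null: list[float]
    empirical_p: float
    direction: str  # "larger" | "smaller" than the null mean
    n_random: int
    seed: int

    def __post_init__(self):
        if not (0 < self.empirical_p <= 1):
            raise ValueError("empirical p must be in (0, 1]")
        if len(self.apl_null) != self.n_random:
            raise ValueError("apl_null length must equal n_random")

    def to_dict(self) -> dict:
        return {
            "powerlaw_slope": self.powerlaw_slope,
            "powerlaw_r2": self.powerlaw_r2,
            "apl_real": self.apl_real,
            "apl_null_mean": float(np.mean(self.apl_null)),
            "apl_null_sd": float(np.std(self.apl_null)),
            "empirical_p": self.empirical_p,
            "direction": self.direction,
            "n_random": self.n_random,
            "seed": self.seed,
        }


def apl_null_test(
    net, n_random: int = 1000, n_swaps_factor: int = 10, seed: int = 0
) -> TopologySummary:
    """Compare the real APL with degree-preserving rewired replicas.

    Each replica uses ``n_swaps_factor × |E|`` attempted swaps. The
    empirical two-sided p is (1 + #{|apl_null − mean| ≥ |apl_real − mean|})
    / (n_random + 1), which can never reach 0; the direction of the real
    network relative to the null mean is reported separately.
    """
    g = _as_graph(net)
    apl_real = average_path_length(net)
    n_swaps = n_swaps_factor * g.number_of_edges()
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_random)
    apl_null = [
        average_path_length(degree_preserving_randomize(net, n_swaps, int(s)))
        for s in sub_seeds
    ]
    null = np.asarray(apl_null)
    center = null.mean()
    extreme = int(np.sum(np.abs(null - center) >= abs(apl_real - center)))
    p = (1 + extreme) / (n_random + 1)
    degrees = sorted((d for _, d in g.degree()), reverse=True)
    try:
        slope, r2 = fit_power_law(degrees)
    except ValueError:
        slope, r2 = None, None
    return TopologySummary(
        degree_sequence=degrees,
        powerlaw_slope=slope,
        powerlaw_r2=r2,
        apl_real=apl_real,
        apl_null=[float(a) for a in apl_null],
        empirical_p=p,
        direction="larger" if apl_real >= center else "smaller",
        n_random=n_random,
        seed=seed,
    )
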