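"""Comorbidity network construction, topology summaries, and
degree-distribution model comparison.

Networks are built from the significant pair results only: nodes are
conditions with at least one significant edge (isolated catalog conditions
can be included by flag), annotated with display name, body-system category
and prevalence count; edges carry the adjusted p-value.

Topology follows the standard graph-level measures: edge density,
global transitivity (closed triplets over connected triplets; a mean-local
variant is available), and Freeman graph-level centralization of degree and
betweenness, each normalized by its star-graph maximum so that all four
summaries live in [0, 1].

The degree-distribution comparison asks whether the network looks
scale-free: discrete power-law and exponential (geometric-tail) models are
fitted by maximum likelihood to degrees >= xmin, with xmin chosen by
Kolmogorov-Smirnov minimization for the power law and shared by both fits,
and compared with a Vuong-style normalized log-likelihood-ratio test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .cohort import ConditionCatalog

__all__ = [
    "ComorbidityNetwork",
    "TopologySummary",
    "DegreeFitResult",
    "build_network",
    "topology",
    "degree_centralization",
    "betweenness_centralization",
    "fit_degree_distribution",
    "compare_degree_models",
    "write_graphml",
    "write_edge_list",
    "degree_table",
    "topology_report",
]


@dataclass
class ComorbidityNetwork:
    """A comorbidity network wrapping a networkx graph.

    Undirected edges are stored canonically (lexicographic endpoint order);
    node attributes: name, category, prevalence_count.
    """

    graph: nx.Graph
    directed: bool

    def __post_init__(self) -> None:
        if self.directed != self.graph.is_directed():
            raise ValueError("directed flag does not match the graph type")
        if any(u == v for u, v in self.graph.edges()):
            raise ValueError("self-loops are not allowed")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set:
        if self.directed:
            return set(self.graph.edges())
        return {tuple(sorted(e)) for e in self.graph.edges()}

    def degrees(self) -> np.ndarray:
        return np.array([d for _, d in self.graph.degree()], dtype=int)


def build_network(
    results: list,
    catalog: ConditionCatalog,
    include_isolates: bool = False,
) -> ComorbidityNetwork:
    """Assemble the network from significant pair results.

    Accepts undirected (PairResult) or directed (DirectedPairResult) inputs,
    never a mixture.
    """
    kinds = {hasattr(r, "source") for r in results}
    if len(kinds) > 1:
        raise ValueError("cannot mix directed and undirected pair results")
    directed = bool(results) and hasattr(results[0], "source")

    G: nx.Graph = nx.DiGraph() if directed else nx.Graph()
    for r in results:
        if not r.significant:
            continue
        if directed:
            u, v = r.source, r.target
        else:
            u, v = sorted((r.condition_y, r.condition_z))
        G.add_edge(u, v, p_adjusted=r.p_adjusted)
    if include_isolates:
        for cid in catalog.condition_ids:
            G.add_node(cid)
    for node in G.nodes:
        G.nodes[node]["name"] = catalog.name(node)
        G.nodes[node]["category"] = catalog.category(node)
        G.nodes[node]["prevalence_count"] = catalog.count(node)
    return ComorbidityNetwork(graph=G, directed=directed)


@dataclass(frozen=True)
class TopologySummary:
    """Graph-level topology measures, all dimensionless in [0, 1].

    Values other than density are NaN when the graph has fewer than three
    nodes (the measures are undefined there).
    """

    edge_density: float
    clustering_coefficient: float
    betweenness_centralization: float
    degree_centralization: float


def degree_centralization(G: nx.Graph) -> float:
    """Freeman degree centralization, normalized by the star-graph maximum."""
    n = G.number_of_nodes()
    if n < 3:
        return float("nan")
    degrees = np.array([d for _, d in G.degree()], dtype=float)
    num = float((degrees.max() - degrees).sum())
    return num / ((n - 1) * (n - 2))


def betweenness_centralization(G: nx.Graph) -> float:
    """Freeman betweenness centralization (unnormalized node scores)."""
    n = G.number_of_nodes()
    if n < 3:
        return float("nan")
    b = np.array(
        list(nx.betweenness_centrality(G, normalized=False).values()), dtype=float
    )
    num = float((b.max() - b).sum())
    denom = (n - 1) ** 2 * (n - 2) / 2.0
    return num / denom


def topology(network: ComorbidityNetwork, clustering: str = "global") -> TopologySummary:
    """Topology summary of an undirected comorbidity network."""
    if network.directed:
        raise ValueError("topology summary is defined for undirected networks")
    G = network.graph
    n = G.number_of_nodes()
    density = float(nx.density(G)) if n >= 2 else 0.0
    if n < 3:
        return TopologySummary(density, float("nan"), float("nan"), float("nan"))
    if clustering == "global":
        cc = float(nx.transitivity(G))
    elif clustering == "mean_local":
        cc = float(nx.average_clustering(G))
    else:
        raise ValueError(f"unknown clustering variant {clustering!r}")
    return TopologySummary(
        edge_density=density,
        clustering_coefficient=cc,
        betweenness_centralization=betweenness_centralization(G),
        degree_centralization=degree_centralization(G),
    )


# ---------------------------------------------------------------------------
# degree-distribution model comparison (discrete MLE, KS xmin, Vuong test)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DegreeFitResult:
    xmin: int
    powerlaw_alpha: float
    exponential_rate: float
    loglik_ratio: float
    p_value: float
    preferred: str  # power_law | exponential | inconclusive


def _pl_loglik(alpha: float, k: np.ndarray, xmin: int) -> float:
    return float(-len(k) * np.log(special.zeta(alpha, xmin)) - alpha * np.log(k).sum())


def _fit_powerlaw_alpha(k: np.ndarray, xmin: int) -> float:
    res = optimize.minimize_scalar(
        lambda a: -_pl_loglik(a, k, xmin), bounds=(1.01, 8.0), method="bounded"
    )
    return float(res.x)


def _pl_logpmf(k: np.ndarray, alpha: float, xmin: int) -> np.ndarray:
    return -alpha * np.log(k) - np.log(special.zeta(alpha, xmin))


def _exp_rate_mle(k: np.ndarray, xmin: int) -> float:
    # discrete exponential p(k) = (1 - e^-lam) e^{-lam (k - xmin)}, k >= xmin
    mean_excess = float(k.mean()) - xmin
    if mean_excess <= 0:
        return np.inf
    return float(np.log(1.0 + 1.0 / mean_excess))


def _exp_logpmf(k: np.ndarray, lam: float, xmin: int) -> np.ndarray:
    return np.log1p(-np.exp(-lam)) - lam * (k - xmin)


def _pl_cdf(ks: np.ndarray, alpha: float, xmin: int) -> np.ndarray:
    return 1.0 - special.zeta(alpha, ks + 1) / special.zeta(alpha, xmin)


def _ks_distance(tail: np.ndarray, alpha: float, xmin: int) -> float:
    ks_vals = np.arange(xmin, tail.max() + 1)
    model_cdf = _pl_cdf(ks_vals, alpha, xmin)
    emp_cdf = np.searchsorted(np.sort(tail), ks_vals, side="right") / len(tail)
    return float(np.abs(emp_cdf - model_cdf).max())


def _vuong_decision(li: np.ndarray, alpha: float) -> tuple:
    """Normalized LR decision from pointwise log-likelihood ratios.

    Returns (R, p, preferred): identical log-likelihoods give p = 1 and
    'inconclusive'; otherwise the two-sided normal p on R/(sd*sqrt(n)).
    """
    R = float(li.sum())
    sd = float(li.std(ddof=0))
    n = len(li)
    if np.isclose(R, 0.0, atol=1e-12):
        p_value = 1.0
    elif sd == 0.0:
        p_value = 0.0
    else:
        z = R / (sd * np.sqrt(n))
        p_value = float(2 * stats.norm.sf(abs(z)))
    if p_value < alpha and R > 0:
        preferred = "power_law"
    elif p_value < alpha and R < 0:
        preferred = "exponential"
    else:
        preferred = "inconclusive"
    return R, p_value, preferred


def compare_degree_models(degrees: np.ndarray, alpha: float = 0.05) -> DegreeFitResult:
    """Power-law vs exponential comparison on a degree sequence.

    xmin is chosen by KS minimization for the discrete power law over
    candidate values that retain at least two thirds of the positive-degree
    observations (and never fewer than 10): on small networks the
    likelihood-ratio comparison needs most of the distribution, so the KS
    step may trim the head but not discard the bulk.  The exponential fit
    shares that xmin.  The Vuong statistic normalizes the pointwise
    log-likelihood-ratio sum; its two-sided normal p-value decides
    ``preferred`` (inconclusive when p >= alpha or the ratio is zero).
    """
    k_all = np.sort(np.asarray(degrees, dtype=int))  # order-invariant fits
    k_all = k_all[k_all >= 1]
    if len(k_all) < 10:
        raise ValueError("need at least 10 nodes with degree >= 1")
    if np.ptp(k_all) == 0:
        raise ValueError("degenerate degree sequence: all degrees equal")

    min_tail = max(10, int(np.ceil(2 * len(k_all) / 3)))
    candidates = np.unique(k_all)
    best = None
    for xmin in candidates:
        tail = k_all[k_all >= xmin]
        if len(tail) < min_tail:
            break
        a = _fit_powerlaw_alpha(tail, int(xmin))
        d = _ks_distance(tail, a, int(xmin))
        if best is None or d < best[0]:
            best = (d, int(xmin), a)
    if best is None:
        raise ValueError("no admissible xmin with at least 10 tail points")
    _, xmin, pl_alpha = best
    tail = k_all[k_all >= xmin]
    if np.ptp(tail) == 0:
        raise ValueError("degenerate degree tail: all degrees equal above xmin")

    lam = _exp_rate_mle(tail, xmin)
    li = _pl_logpmf(tail, pl_alpha, xmin) - _exp_logpmf(tail, lam, xmin)
    R, p_value, preferred = _vuong_decision(li, alpha)
    return DegreeFitResult(
        xmin=xmin,
        powerlaw_alpha=pl_alpha,
        exponential_rate=lam,
        loglik_ratio=R,
        p_value=p_value,
        preferred=preferred,
    )


def fit_degree_distribution(
    network: ComorbidityNetwork, alpha: float = 0.05
) -> DegreeFitResult:
    """Degree-distribution model comparison for a network's degree sequence."""
    return compare_degree_models(network.degrees(), alpha=alpha)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_graphml(network: ComorbidityNetwork, path) -> None:
    nx.write_graphml(network.graph, path)


def write_edge_list(network: ComorbidityNetwork, path) -> None:
    rows = []
    for u, v, data in network.graph.edges(data=True):
        if not network.directed:
            u, v = sorted((u, v))
        rows.append(
            {
                "source" if network.directed else "condition_y": u,
                "target" if network.directed else "condition_z": v,
                "p_adjusted": data.get("p_adjusted", float("nan")),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def degree_table(network: ComorbidityNetwork, path=None) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {"condition_id": n, "degree": d}
            for n, d in network.graph.degree()
        ],
        columns=["condition_id", "degree"],
    ).sort_values("condition_id", ignore_index=True)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def topology_report(network: ComorbidityNetwork, path=None) -> dict:
    summary = topology(network)
    report = {
        "n_nodes": network.n_nodes,
        "n_edges": network.n_edges,
        **asdict(summary),
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2, allow_nan=True)
    return report
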