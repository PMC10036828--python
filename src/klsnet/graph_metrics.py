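"""Weighted graph-theoretical characterization of thresholded KLS networks.

A dense similarity matrix is pruned to a target sparsity S (fraction of the
R(R-1)/2 strongest possible edges retained, weights kept), swept over a
range of S, and summarized per metric by the area under the metric-vs-S
curve. Normalized metrics (gamma, lambda, sigma) compare the network
against degree-preserving rewired nulls.

Weighted conventions (the common toolbox choices, fixed here explicitly):

* ``Cp``  — Onnela weighted clustering (weights rescaled by the maximum),
  averaged over nodes; nodes with degree < 2 contribute 0.
* ``Lp``  — characteristic path length with edge length 1/w, averaged over
  pairs with finite distance (fragmented graphs at sparse thresholds).
* ``Eglobal`` — mean of 1/d_ij over all ordered pairs (0 for disconnected).
* ``Elocal``  — mean over nodes of the global efficiency of the subgraph
  induced by the node's neighbours.
* ``Q``   — modularity of the greedy-modularity partition.
* ``Ar``  — weighted degree-assortativity coefficient.
* ``Hr``  — hierarchy exponent beta from log Cp(i) ~ -beta log k(i) over
  nodes with binary degree k > 1 and positive clustering.
* ``Sr``  — synchronizability lambda_2/lambda_max of the binarized
  Laplacian spectrum.
* ``Dc``  — nodal strength (sum of incident weights).
* ``Bc``  — nodal betweenness with edge length 1/w (pair counts, unnormalized).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "ThresholdedNetwork",
    "GlobalMetrics",
    "NodalMetrics",
    "MetricCurve",
    "apply_sparsity_threshold",
    "compute_global_metrics",
    "compute_nodal_metrics",
    "random_rewire",
    "auc_over_thresholds",
    "default_sparsities",
    "sweep_thresholds",
    "GLOBAL_METRIC_NAMES",
]

logger = logging.getLogger(__name__)

GLOBAL_METRIC_NAMES = (
    "Ar", "Q", "Hr", "Eglobal", "Elocal", "Cp", "Lp", "Sr", "lambda", "gamma", "sigma",
)


def default_sparsities(lo: float = 0.02, hi: float = 0.50, step: float = 0.01) -> np.ndarray:
    """The default sweep 0.02..0.50 in steps of 0.01 (49 points)."""
    n = int(round((hi - lo) / step)) + 1
    return np.round(np.linspace(lo, hi, n), 10)


@dataclass
class ThresholdedNetwork:
    """A sparsity-thresholded weighted network."""

    weights: np.ndarray
    sparsity: float
    gamma_threshold: float
    region_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not self.region_ids:
            self.region_ids = list(range(1, self.weights.shape[0] + 1))

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    def graph(self) -> nx.Graph:
        """networkx view with 'weight' and 'length' (=1/weight) attributes."""
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        iu, ju = np.nonzero(np.triu(self.weights, k=1))
        for i, j in zip(iu, ju):
            w = float(self.weights[i, j])
            g.add_edge(int(i), int(j), weight=w, length=1.0 / w)
        return g


def apply_sparsity_threshold(net, S: float) -> ThresholdedNetwork:
    """Retain the round(S * R(R-1)/2) strongest off-diagonal weights.

    Weights are ranked by absolute value; retained entries keep their
    original values (weighted, not binarized). Ties at the cutoff are broken
    deterministically by (|weight| desc, i asc, j asc).

    ``net`` may be a :class:`~klsnet.kls_network.ConnectivityMatrix` or a
    bare symmetric array.
    """
    if hasattr(net, "weights"):
        w = np.asarray(net.weights, dtype=float)
        region_ids = list(getattr(net, "region_ids", []))
    else:
        w = np.asarray(net, dtype=float)
        region_ids = []
    if not 0 < S <= 1:
        raise ValueError("sparsity S must lie in (0, 1]")
    r = w.shape[0]
    iu, ju = np.triu_indices(r, k=1)
    vals = np.abs(w[iu, ju])
    n_keep = int(round(S * r * (r - 1) / 2))
    if n_keep == 0:
        raise ValueError(f"S={S} retains zero edges on {r} nodes")
    order = np.lexsort((ju, iu, -vals))  # |weight| desc, then i asc, j asc
    keep = order[:n_keep]
    out = np.zeros_like(w)
    out[iu[keep], ju[keep]] = np.abs(w[iu[keep], ju[keep]])
    out = out + out.T
    gamma_threshold = float(vals[keep].min())
    return ThresholdedNetwork(
        weights=out, sparsity=float(S), gamma_threshold=gamma_threshold, region_ids=region_ids
    )


# ---------------------------------------------------------------------------
# individual metric implementations


def _finite_pair_distances(g: nx.Graph, n: int) -> np.ndarray:
    """Upper-triangle vector of pairwise shortest-path lengths (inf if none)."""
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for src, lengths in nx.shortest_path_length(g, weight="length"):
        for dst, val in lengths.items():
            d[src, dst] = val
    iu, ju = np.triu_indices(n, k=1)
    return d[iu, ju]


def characteristic_path_length(g: nx.Graph, n: int) -> float:
    """Mean shortest-path length over pairs with a connecting path."""
    d = _finite_pair_distances(g, n)
    finite = d[np.isfinite(d)]
    if finite.size == 0:
        raise ValueError("network has no connected node pair")
    if finite.size < d.size:
        logger.debug("Lp over %d/%d finite pairs (fragmented graph)", finite.size, d.size)
    return float(finite.mean())


def global_efficiency(g: nx.Graph, n: int) -> float:
    d = _finite_pair_distances(g, n)
    if d.size == 0:
        return 0.0
    inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return float(inv.mean())


def local_efficiency(g: nx.Graph) -> float:
    effs = []
    for node in g:
        nbrs = list(g[node])
        if len(nbrs) < 2:
            effs.append(0.0)
            continue
        sub = g.subgraph(nbrs)
        effs.append(global_efficiency(sub_relabel(sub), len(nbrs)))
    return float(np.mean(effs)) if effs else 0.0


def sub_relabel(g: nx.Graph) -> nx.Graph:
    """Relabel nodes to 0..n-1 so distance-matrix helpers can index arrays."""
    return nx.convert_node_labels_to_integers(g, ordering="sorted")


def hierarchy_exponent(g: nx.Graph) -> float:
    """beta from log Cp(i) = a - beta log k(i) over nodes with k>1, Cp>0."""
    clus = nx.clustering(g, weight="weight")
    ks, cs = [], []
    for node, c in clus.items():
        k = g.degree(node)
        if k > 1 and c > 0:
            ks.append(math.log(k))
            cs.append(math.log(c))
    if len(ks) < 2 or np.ptp(ks) == 0:
        return float("nan")
    slope = np.polyfit(ks, cs, 1)[0]
    return float(-slope)


def synchronizability(weights: np.ndarray) -> float:
    """lambda_2 / lambda_max of the binarized combinatorial Laplacian."""
    a = (weights > 0).astype(float)
    lap = np.diag(a.sum(axis=1)) - a
    ev = np.linalg.eigvalsh(lap)
    if ev[-1] <= 0:
        return float("nan")
    return float(ev[1] / ev[-1])


def modularity_greedy(g: nx.Graph) -> float:
    if g.number_of_edges() == 0:
        return float("nan")
    comms = nx.community.greedy_modularity_communities(g, weight="weight")
    return float(nx.community.modularity(g, comms, weight="weight"))


def assortativity(g: nx.Graph) -> float:
    if g.number_of_edges() < 2:
        return float("nan")
    with np.errstate(invalid="ignore", divide="ignore"):
        return float(nx.degree_assortativity_coefficient(g, weight="weight"))


def _raw_global(tnet: ThresholdedNetwork) -> dict[str, float]:
    g = tnet.graph()
    n = tnet.n_nodes
    return {
        "Ar": assortativity(g),
        "Q": modularity_greedy(g),
        "Hr": hierarchy_exponent(g),
        "Eglobal": global_efficiency(g, n),
        "Elocal": local_efficiency(g),
        "Cp": float(nx.average_clustering(g, weight="weight", count_zeros=True)),
        "Lp": characteristic_path_length(g, n),
        "Sr": synchronizability(tnet.weights),
    }


@dataclass
class GlobalMetrics:
    """The 11 global metrics plus the null-model components behind them."""

    ar: float
    q: float
    hr: float
    e_global: float
    e_local: float
    cp: float
    lp: float
    sr: float
    lambda_: float
    gamma_: float
    sigma: float
    cp_rand: float
    lp_rand: float
    null_stats: dict[str, tuple[float, float]] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {
            "Ar": self.ar, "Q": self.q, "Hr": self.hr,
            "Eglobal": self.e_global, "Elocal": self.e_local,
            "Cp": self.cp, "Lp": self.lp, "Sr": self.sr,
            "lambda": self.lambda_, "gamma": self.gamma_, "sigma": self.sigma,
        }

    def zscore(self, name: str) -> float:
        """(metric - mean_null) / sd_null for a metric tracked in null_stats."""
        mu, sd = self.null_stats[name]
        raw = self.as_dict()[name]
        return (raw - mu) / sd if sd > 0 else float("nan")


@dataclass
class NodalMetrics:
    """Per-node strength (Dc) and weighted betweenness (Bc)."""

    dc: np.ndarray
    bc: np.ndarray
    region_ids: list[int] = field(default_factory=list)


def random_rewire(tnet: ThresholdedNetwork, seed: int, swap_factor: int = 10) -> ThresholdedNetwork:
    """Degree-preserving null: double-edge swaps plus weight permutation.

    Topology is rewired by at least ``swap_factor * n_edges`` attempted
    double-edge swaps (binary degree sequence preserved exactly); the
    original weights are then randomly permuted onto the surviving edges.
    Graphs with no valid swap are returned unchanged (logged).
    """
    m = tnet.n_edges
    g = nx.from_numpy_array((tnet.weights > 0).astype(int))
    if m >= 2 and g.number_of_nodes() >= 4:
        try:
            nx.double_edge_swap(g, nswap=swap_factor * m, max_tries=100 * swap_factor * m, seed=seed)
        except nx.NetworkXException as exc:  # no swap possible / tries exhausted
            logger.info("double-edge swap unavailable (%s); topology unchanged", exc)
    else:
        logger.info("too few edges (%d) to rewire; topology unchanged", m)
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(tnet.n_nodes, k=1)
    weights_pool = tnet.weights[iu, ju]
    weights_pool = weights_pool[weights_pool > 0]
    out = np.zeros_like(tnet.weights)
    edges = sorted((min(u, v), max(u, v)) for u, v in g.edges())
    perm = rng.permutation(len(edges))
    for (u, v), k in zip(edges, perm):
        out[u, v] = out[v, u] = weights_pool[k]
    return ThresholdedNetwork(
        weights=out,
        sparsity=tnet.sparsity,
        gamma_threshold=tnet.gamma_threshold,
        region_ids=list(tnet.region_ids),
    )


def compute_global_metrics(
    tnet: ThresholdedNetwork,
    n_rand: int = 100,
    seed: int = 0,
    null_metrics: tuple[str, ...] = (),
) -> GlobalMetrics:
    """All 11 global metrics, with lambda/gamma/sigma from rewired nulls.

    ``Cp_rand`` and ``Lp_rand`` are means over ``n_rand`` degree-preserving
    nulls (per-null seeds derived from ``seed`` by fixed offsets). Any raw
    metric named in ``null_metrics`` additionally gets its null mean/sd
    recorded so a z-scored summary can be formed.
    """
    if tnet.n_edges == 0:
        raise ValueError("empty network: no edges after thresholding")
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    raw = _raw_global(tnet)
    extra = tuple(m for m in null_metrics if m not in ("Cp", "Lp"))
    null_vals: dict[str, list[float]] = {m: [] for m in ("Cp", "Lp") + extra}
    for k in range(n_rand):
        null = random_rewire(tnet, seed=seed + 1000 * k + 1)
        gnull = null.graph()
        null_vals["Cp"].append(float(nx.average_clustering(gnull, weight="weight", count_zeros=True)))
        null_vals["Lp"].append(characteristic_path_length(gnull, null.n_nodes))
        for mname in extra:
            if mname == "Ar":
                null_vals[mname].append(assortativity(gnull))
            elif mname == "Hr":
                null_vals[mname].append(hierarchy_exponent(gnull))
            elif mname == "Sr":
                null_vals[mname].append(synchronizability(null.weights))
            elif mname == "Q":
                null_vals[mname].append(modularity_greedy(gnull))
            elif mname == "Eglobal":
                null_vals[mname].append(global_efficiency(gnull, null.n_nodes))
            elif mname == "Elocal":
                null_vals[mname].append(local_efficiency(gnull))
            else:
                raise ValueError(f"cannot compute null distribution for {mname!r}")
    cp_rand = float(np.mean(null_vals["Cp"]))
    lp_rand = float(np.mean(null_vals["Lp"]))
    lam = raw["Lp"] / lp_rand if lp_rand > 0 else float("nan")
    gam = raw["Cp"] / cp_rand if cp_rand > 0 else float("nan")
    sigma = gam / lam if lam and np.isfinite(lam) and lam != 0 else float("nan")
    null_stats = {
        m: (float(np.nanmean(v)), float(np.nanstd(v, ddof=1)) if len(v) > 1 else float("nan"))
        for m, v in null_vals.items()
    }
    return GlobalMetrics(
        ar=raw["Ar"], q=raw["Q"], hr=raw["Hr"], e_global=raw["Eglobal"],
        e_local=raw["Elocal"], cp=raw["Cp"], lp=raw["Lp"], sr=raw["Sr"],
        lambda_=lam, gamma_=gam, sigma=sigma, cp_rand=cp_rand, lp_rand=lp_rand,
        null_stats=null_stats,
    )


def compute_nodal_metrics(tnet: ThresholdedNetwork) -> NodalMetrics:
    """Nodal strength Dc(i) = sum_j W_ij and betweenness with length 1/W."""
    if tnet.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    g = tnet.graph()
    dc = tnet.weights.sum(axis=1)
    bc_map = nx.betweenness_centrality(g, weight="length", normalized=False)
    bc = np.array([bc_map[i] for i in range(tnet.n_nodes)])
    return NodalMetrics(dc=dc, bc=bc, region_ids=list(tnet.region_ids))


def auc_over_thresholds(values, sparsities) -> float:
    """Mean-height AUC: trapezoidal integral divided by the sweep range."""
    v = np.asarray(values, dtype=float)
    s = np.asarray(sparsities, dtype=float)
    if v.shape != s.shape:
        raise ValueError("values and sparsities must have equal length")
    if v.size < 2:
        raise ValueError("need at least 2 sweep points")
    return float(np.trapezoid(v, s) / (s[-1] - s[0]))


@dataclass
class MetricCurve:
    """One metric across the sparsity sweep plus its AUC summary."""

    sparsities: np.ndarray
    values: np.ndarray
    auc: float

    @classmethod
    def from_values(cls, sparsities, values) -> "MetricCurve":
        s = np.asarray(sparsities, dtype=float)
        v = np.asarray(values, dtype=float)
        return cls(sparsities=s, values=v, auc=auc_over_thresholds(v, s))


def sweep_thresholds(
    net,
    sparsities=None,
    n_rand: int = 100,
    seed: int = 0,
    null_metrics: tuple[str, ...] = (),
) -> tuple[dict[str, MetricCurve], dict[str, np.ndarray]]:
    """Evaluate all global and nodal metrics across the sparsity sweep.

    Returns ``(global_curves, nodal)`` where ``global_curves`` maps each of
    the 11 metric names to a :class:`MetricCurve` and ``nodal`` holds
    ``Dc``/``Bc`` arrays of shape (n_sparsities, R) plus AUC vectors
    ``Dc_auc``/``Bc_auc`` of length R.
    """
    if sparsities is None:
        sparsities = default_sparsities()
    sparsities = np.asarray(sparsities, dtype=float)
    glob = {name: [] for name in GLOBAL_METRIC_NAMES}
    dc_rows, bc_rows = [], []
    for k, s in enumerate(sparsities):
        tnet = apply_sparsity_threshold(net, float(s))
        gm = compute_global_metrics(tnet, n_rand=n_rand, seed=seed + 37 * k, null_metrics=null_metrics)
        for name, val in gm.as_dict().items():
            glob[name].append(val)
        nm = compute_nodal_metrics(tnet)
        dc_rows.append(nm.dc)
        bc_rows.append(nm.bc)
    curves = {name: MetricCurve.from_values(sparsities, vals) for name, vals in glob.items()}
    dc = np.vstack(dc_rows)
    bc = np.vstack(bc_rows)
    nodal = {
        "Dc": dc,
        "Bc": bc,
        "Dc_auc": np.array([auc_over_thresholds(dc[:, i], sparsities) for i in range(dc.shape[1])]),
        "Bc_auc": np.array([auc_over_thresholds(bc[:, i], sparsities) for i in range(bc.shape[1])]),
    }
    return curves, nodal
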