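"""Graph metrics on signed weighted thresholded networks.

Five metrics are computed per scan:

* **degree centrality** — weighted sum of the signed edge weights incident
  to a node (a magnitude option sums |w| instead);
* **clustering coefficient** — fraction of realised edges among a node's
  neighbours, on the binary support;
* **betweenness centrality** — fraction of shortest hop paths between other
  node pairs passing through the node, normalised by (n-1)(n-2)/2 unordered
  pairs;
* **global efficiency** — mean reciprocal hop distance over unordered node
  pairs, with 1/inf = 0 for unreachable pairs;
* **mean shortest path length** — mean hop distance over *connected*
  unordered pairs (unreachable pairs are excluded and counted; a graph with
  no connected pair yields 0 with a warning).

Shortest paths are hop counts ("smallest number of links"), never
weight-derived, so negative edge weights never enter a distance; weights
influence the topology only through thresholding, and the values only
through degree centrality.

The per-scan summary is the node average of each nodal metric (global
efficiency and mean shortest path length are already graph-level).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import ThresholdedGraph
from .core import ValidationError, get_logger

logger = get_logger(__name__)

METRIC_NAMES: tuple[str, ...] = (
    "degree_centrality",
    "clustering_coefficient",
    "betweenness_centrality",
    "global_efficiency",
    "mean_shortest_path_length",
)


@dataclass
class NodalMetricVector:
    """Per-node values of one metric."""

    metric: str
    values: np.ndarray
    node_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.node_labels):
            raise ValidationError("nodal vector length must equal node count")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"nodal metric {self.metric} has non-finite values")

    @property
    def mean(self) -> float:
        return float(self.values.mean())


@dataclass
class ScanMetricRecord:
    """The five scan-wise scalars for one (subject, session, condition, network)."""

    subject: str
    session: str
    condition: str
    network: str
    degree_centrality: float
    clustering_coefficient: float
    betweenness_centrality: float
    global_efficiency: float
    mean_shortest_path_length: float
    n_nodes: int = 0
    n_edges: int = 0
    n_disconnected_pairs: int = 0

    def metric_values(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def degree_centrality(G: ThresholdedGraph, absolute: bool = False) -> NodalMetricVector:
    """Weighted degree: sum of signed edge weights at each node.

    With ``absolute=True`` magnitudes are summed instead — useful when
    positive and negative edges should both count as connectivity strength.
    """
    W = np.abs(G.weights) if absolute else G.weights
    return NodalMetricVector("degree_centrality", W.sum(axis=1), list(G.node_labels))


def clustering_coefficient(G: ThresholdedGraph) -> NodalMetricVector:
    """Binary clustering: realised / possible edges among each node's neighbours.

    Nodes with fewer than two neighbours get 0.
    """
    A = G.support.astype(float)
    k = A.sum(axis=1)
    triangles = np.diag(A @ A @ A) / 2.0
    possible = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        cc = np.where(possible > 0, triangles / np.where(possible > 0, possible, 1.0), 0.0)
    return NodalMetricVector("clustering_coefficient", cc, list(G.node_labels))


def shortest_hop_distances(G: ThresholdedGraph) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs hop distances and shortest-path counts on the binary support.

    Returns ``(D, sigma)``: ``D[i, j]`` is the minimum number of links
    between i and j (0 on the diagonal, ``inf`` for unreachable pairs) and
    ``sigma[i, j]`` the number of distinct shortest hop paths (0 when
    unreachable, 1 on the diagonal).  Computed by simultaneous level-by-level
    expansion: paths of length k to t sum the path counts of t's neighbours
    at length k-1.
    """
    A = G.support.astype(float)
    n = G.n_nodes
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    sigma = np.eye(n)
    for k in range(1, n):
        at_prev = D == (k - 1)
        if not at_prev.any():
            break
        counts = (sigma * at_prev) @ A
        new = (counts > 0) & np.isinf(D)
        if not new.any():
            break
        D[new] = k
        sigma[new] = counts[new]
    return D, sigma


def betweenness_centrality(G: ThresholdedGraph) -> NodalMetricVector:
    """Fraction of shortest hop paths between other pairs passing through a node.

    For node v:  sum over unordered pairs {s, t} (s, t != v) of
    sigma_st(v) / sigma_st, divided by (n-1)(n-2)/2.  Unreachable pairs
    (sigma_st = 0) contribute nothing.  A path "passes through" v when
    d(s, v) + d(v, t) = d(s, t), in which case sigma_st(v) =
    sigma_sv * sigma_vt.
    """
    n = G.n_nodes
    if n < 3:
        return NodalMetricVector(
            "betweenness_centrality", np.zeros(n), list(G.node_labels)
        )
    D, sigma = shortest_hop_distances(G)
    B = np.zeros(n)
    safe_sigma = np.where(sigma > 0, sigma, 1.0)
    for v in range(n):
        on_path = (D[:, v][:, None] + D[v, :][None, :]) == D
        contrib = np.where(
            on_path & (sigma > 0),
            np.outer(sigma[:, v], sigma[v, :]) / safe_sigma,
            0.0,
        )
        contrib[v, :] = 0.0
        contrib[:, v] = 0.0
        np.fill_diagonal(contrib, 0.0)
        B[v] = contrib.sum() / 2.0  # ordered pairs counted twice
    B /= (n - 1) * (n - 2) / 2.0
    return NodalMetricVector("betweenness_centrality", B, list(G.node_labels))


def global_efficiency(G: ThresholdedGraph) -> float:
    """Mean reciprocal hop distance over unordered pairs (1/inf = 0)."""
    n = G.n_nodes
    if n < 2:
        raise ValidationError("global efficiency needs at least 2 nodes")
    D, _ = shortest_hop_distances(G)
    iu, ju = np.triu_indices(n, k=1)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D[iu, ju]
    inv[np.isinf(D[iu, ju])] = 0.0
    return float(inv.mean())


def mean_shortest_path_length(G: ThresholdedGraph) -> tuple[float, int]:
    """Mean hop distance over connected unordered pairs.

    Returns ``(mean, n_disconnected_pairs)``.  When no pair is connected the
    mean is reported as 0 and a warning is logged.
    """
    n = G.n_nodes
    if n < 2:
        raise ValidationError("mean shortest path length needs at least 2 nodes")
    D, _ = shortest_hop_distances(G)
    iu, ju = np.triu_indices(n, k=1)
    d = D[iu, ju]
    connected = np.isfinite(d)
    n_excluded = int((~connected).sum())
    if not connected.any():
        logger.warning(
            "graph %s has no connected node pair; mean shortest path set to 0",
            (G.subject, G.session, G.condition, G.network),
        )
        return 0.0, n_excluded
    return float(d[connected].mean()), n_excluded


def scan_summary(G: ThresholdedGraph, absolute_degree: bool = False) -> ScanMetricRecord:
    """Node-averaged nodal metrics plus the two graph-level metrics for one scan."""
    mspl, n_disc = mean_shortest_path_length(G)
    return ScanMetricRecord(
        subject=G.subject,
        session=G.session,
        condition=G.condition,
        network=G.network,
        degree_centrality=degree_centrality(G, absolute=absolute_degree).mean,
        clustering_coefficient=clustering_coefficient(G).mean,
        betweenness_centrality=betweenness_centrality(G).mean,
        global_efficiency=global_efficiency(G),
        mean_shortest_path_length=mspl,
        n_nodes=G.n_nodes,
        n_edges=G.n_edges,
        n_disconnected_pairs=n_disc,
    )
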