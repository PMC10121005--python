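"""Topology-based centrality measures and deterministic protein rankings.

Six measures used for essential-protein prediction:

* BC — betweenness: fraction of shortest paths through a protein, summed
  over unordered pairs excluding the protein itself, unnormalised.
* DC — degree.
* EC — eigenvector: component of the principal eigenvector of the
  adjacency matrix (unit norm, nonnegative sign convention).
* NC — neighbourhood: sum of edge clustering coefficients
  ``|Np ∩ Nu| / min(|Np|-1, |Nu|-1)`` over the protein's edges; a
  degenerate denominator (<= 0) contributes 0.
* SC — subgraph: weighted count of closed walks, the diagonal of the
  adjacency-matrix exponential, computed by symmetric eigendecomposition.
* aveNC — average neighbour degree.

Rankings sort by descending score, ties broken by ascending identifier,
so every ranking is deterministic and relabel-stable up to the tiebreak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .network import PpiNetwork

METHODS = ("BC", "DC", "EC", "NC", "SC", "aveNC")

#: Relative residual tolerance for the eigenvector-centrality check.
_EIG_RTOL = 1e-10


@dataclass(frozen=True)
class CentralityResult:
    """Scores and the deterministic ranking for one method."""

    method: str
    scores: dict[str, float]
    ranking: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.ranking:
            order = sorted(self.scores, key=lambda p: (-self.scores[p], p))
            object.__setattr__(self, "ranking", order)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (p, self.method, self.scores[p], i + 1)
            for i, p in enumerate(self.ranking)
        ]
        return pd.DataFrame(rows, columns=["protein", "method", "score", "rank"])


def rank(result: CentralityResult, k: int = 600) -> list[str]:
    """First min(k, |P|) proteins of the ranking."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return result.ranking[:k]


def betweenness(net: PpiNetwork) -> CentralityResult:
    """BC over unordered pairs, endpoint-excluding, unnormalised."""
    scores = nx.betweenness_centrality(net.graph, normalized=False)
    return CentralityResult("BC", {p: float(s) for p, s in scores.items()})


def degree(net: PpiNetwork) -> CentralityResult:
    return CentralityResult("DC", {p: float(net.degree(p)) for p in net.nodes})


def _adjacency(net: PpiNetwork) -> tuple[np.ndarray, list[str]]:
    nodes = net.nodes
    a = nx.to_numpy_array(net.graph, nodelist=nodes, dtype=float)
    return a, nodes


def eigenvector(net: PpiNetwork) -> CentralityResult:
    """Principal eigenvector of the adjacency matrix.

    Unit Euclidean norm; sign fixed so the dominant entries are
    nonnegative.  On disconnected graphs the eigenvector of the global
    largest eigenvalue is used, so components outside the dominant
    eigencomponent carry (numerically) zero weight.
    """
    if net.n_edges == 0:
        raise ValueError("eigenvector centrality is undefined on an edgeless network")
    a, nodes = _adjacency(net)
    w, v = np.linalg.eigh(a)
    lam = w[-1]
    vec = v[:, -1]
    resid = np.linalg.norm(a @ vec - lam * vec)
    if resid > _EIG_RTOL * max(abs(lam), 1.0):
        raise ArithmeticError(f"eigenvector residual {resid:.3e} above tolerance")
    if vec[np.argmax(np.abs(vec))] < 0:
        vec = -vec
    vec = np.where(np.abs(vec) < 1e-12, 0.0, vec)
    vec = vec / np.linalg.norm(vec)
    return CentralityResult("EC", {p: float(x) for p, x in zip(nodes, vec)})


def edge_clustering_coefficient(net: PpiNetwork, p: str, u: str) -> float:
    """ECC of the edge p-u; 0 when min(deg-1) <= 0."""
    np_, nu = net.neighbors(p), net.neighbors(u)
    denom = min(len(np_) - 1, len(nu) - 1)
    if denom <= 0:
        return 0.0
    return len(np_ & nu) / denom


def neighborhood(net: PpiNetwork) -> CentralityResult:
    """NC: per-protein sum of edge clustering coefficients."""
    scores = {
        p: sum(edge_clustering_coefficient(net, p, u) for u in net.neighbors(p))
        for p in net.nodes
    }
    return CentralityResult("NC", scores)


def subgraph(net: PpiNetwork) -> CentralityResult:
    """SC: diagonal of exp(A) via symmetric eigendecomposition.

    SC(p) = sum_j v_pj^2 exp(lambda_j) >= 1 always (the length-0 walk).
    """
    a, nodes = _adjacency(net)
    w, v = np.linalg.eigh(a)
    diag = (v ** 2) @ np.exp(w)
    return CentralityResult("SC", {p: float(x) for p, x in zip(nodes, diag)})


def ave_neighbor(net: PpiNetwork) -> CentralityResult:
    """aveNC: mean degree of a protein's neighbours; isolated nodes get 0."""
    scores = {}
    for p in net.nodes:
        nbrs = net.neighbors(p)
        scores[p] = (
            sum(net.degree(u) for u in nbrs) / len(nbrs) if nbrs else 0.0
        )
    return CentralityResult("aveNC", scores)


_DISPATCH = {
    "BC": betweenness,
    "DC": degree,
    "EC": eigenvector,
    "NC": neighborhood,
    "SC": subgraph,
    "aveNC": ave_neighbor,
}


def compute(net: PpiNetwork, method: str) -> CentralityResult:
    """Compute one centrality by its short name (BC/DC/EC/NC/SC/aveNC)."""
    try:
        fn = _DISPATCH[method]
    except KeyError:
        raise ValueError(f"unknown centrality method {method!r}; choose from {METHODS}")
    return fn(net)


def compute_all(net: PpiNetwork, methods=METHODS) -> dict[str, CentralityResult]:
    return {m: compute(net, m) for m in methods}
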