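"""PPI networks, per-edge confidence scores and threshold refinement.

A PPI network is an undirected simple graph of protein identifiers.  The
refinement step scores every existing edge with a semantic-similarity
confidence value and keeps only the edges whose score reaches the
threshold (0.33 by default throughout the package); proteins left
without any interaction are dropped, so the refined "GO-PPI" network is
both sparser and smaller than the input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .ontology import AnnotationCorpus, GoDag
from .semsim import SemanticSimilarity, SemSimConfig

logger = logging.getLogger(__name__)


class EdgeListFormatError(ValueError):
    """Malformed edge-list input."""


def _canon(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


class PpiNetwork:
    """Undirected simple graph of proteins (no self-loops, no multi-edges)."""

    def __init__(self, edges=(), nodes=()):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a, b in edges:
            if a == b:
                logger.warning("self-loop %s-%s dropped", a, b)
                continue
            g.add_edge(a, b)
        self._g = g

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> list[str]:
        return sorted(self._g.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {_canon(a, b) for a, b in self._g.edges}

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def neighbors(self, p: str) -> set[str]:
        return set(self._g.neighbors(p))

    def degree(self, p: str) -> int:
        return self._g.degree[p]

    def has_edge(self, a: str, b: str) -> bool:
        return self._g.has_edge(a, b)

    def subgraph_of(self, nodes) -> "PpiNetwork":
        sub = self._g.subgraph(nodes)
        return PpiNetwork(edges=sub.edges, nodes=sub.nodes)

    def write_edge_list(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for a, b in sorted(self.edges):
                fh.write(f"{a}\t{b}\n")

    def __eq__(self, other) -> bool:
        if not isinstance(other, PpiNetwork):
            return NotImplemented
        return set(self._g.nodes) == set(other._g.nodes) and self.edges == other.edges

    def __repr__(self) -> str:
        return f"PpiNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


def read_edge_list(path) -> PpiNetwork:
    """Read a two-column whitespace-delimited edge list.

    Lines starting with ``#`` are ignored; self-loops are dropped with a
    warning; duplicate pairs collapse.  A line with a field count other
    than two is a format error naming the line number.
    """
    edges = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise EdgeListFormatError(
                    f"{path}: line {lineno}: expected 2 fields, found {len(fields)}"
                )
            edges.append((fields[0], fields[1]))
    if not edges:
        raise EdgeListFormatError(f"{path}: no edges found")
    return PpiNetwork(edges=edges)


@dataclass(frozen=True)
class EdgeScoreTable:
    """Confidence score per (unordered) edge, with its provenance."""

    scores: dict[tuple[str, str], float]
    metric: str
    namespace: str

    def __getitem__(self, pair) -> float:
        return self.scores[_canon(*pair)]

    def __contains__(self, pair) -> bool:
        return _canon(*pair) in self.scores

    def __len__(self) -> int:
        return len(self.scores)

    def items(self):
        return self.scores.items()

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, b, s) for (a, b), s in sorted(self.scores.items())]
        return pd.DataFrame(rows, columns=["protein_a", "protein_b", "score"])


def score_edges(
    net: PpiNetwork,
    corpus: AnnotationCorpus,
    dag: GoDag,
    config: SemSimConfig | None = None,
) -> EdgeScoreTable:
    """Score every edge of ``net`` (edges only, never all pairs).

    Edges with an unannotated endpoint score 0.
    """
    config = config or SemSimConfig()
    scorer = SemanticSimilarity(dag, corpus, config)
    scores = {
        _canon(a, b): scorer.protein_sim(a, b) for a, b in sorted(net.edges)
    }
    return EdgeScoreTable(scores=scores, metric=config.metric, namespace=config.namespace)


@dataclass(frozen=True)
class RefinementReport:
    """Tally of one refinement pass (reserved/filtered edges, node counts)."""

    threshold: float
    n_reserved: int
    n_filtered: int
    n_proteins: int
    n_essential: int | None = None

    @property
    def essential_portion(self) -> float | None:
        if self.n_essential is None or self.n_proteins == 0:
            return None
        return self.n_essential / self.n_proteins

    def to_frame(self) -> pd.DataFrame:
        portion = self.essential_portion
        return pd.DataFrame(
            [
                {
                    "threshold": self.threshold,
                    "reserved": self.n_reserved,
                    "filtered": self.n_filtered,
                    "proteins": self.n_proteins,
                    "essential": self.n_essential,
                    "essential_portion": None if portion is None else round(portion, 4),
                }
            ]
        )


def refine(
    net: PpiNetwork,
    scores: EdgeScoreTable,
    threshold: float = 0.33,
    essential=None,
) -> tuple[PpiNetwork, RefinementReport]:
    """Keep edges whose confidence score is >= threshold.

    Nodes left without any incident edge are removed.  When a
    gold-standard essential set is supplied, the report carries the
    essential-protein portion of the surviving network.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    missing = net.edges - set(scores.scores)
    if missing:
        raise KeyError(f"{len(missing)} edges have no confidence score, e.g. {min(missing)}")
    reserved = [e for e in net.edges if scores[e] >= threshold]
    refined = PpiNetwork(edges=reserved)
    n_ess = None
    if essential is not None:
        n_ess = len(set(refined.nodes) & set(essential))
    report = RefinementReport(
        threshold=threshold,
        n_reserved=len(reserved),
        n_filtered=net.n_edges - len(reserved),
        n_proteins=refined.n_nodes,
        n_essential=n_ess,
    )
    return refined, report


def density(net: PpiNetwork) -> float:
    """Graph density 2|E| / (|P| (|P|-1))."""
    if net.n_nodes < 2:
        raise ValueError("density needs at least 2 nodes")
    return density_from_counts(net.n_nodes, net.n_edges)


def density_from_counts(n_proteins: int, n_edges: int) -> float:
    """Density from node/edge counts alone (e.g. published network sizes)."""
    if n_proteins < 2:
        raise ValueError("density needs at least 2 nodes")
    return 2.0 * n_edges / (n_proteins * (n_proteins - 1))
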