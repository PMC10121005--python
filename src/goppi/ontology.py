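"""Gene Ontology DAG, annotation corpora and information content.

The Gene Ontology is three rooted directed acyclic graphs (biological
process, cellular component, molecular function).  This module loads the
DAG from OBO text, loads a protein -> term annotation corpus from GAF 2.x,
propagates annotations up the DAG (true-path rule), and turns propagated
term frequencies into information content ``IC(t) = -ln p(t)``, the
quantity every IC-based semantic-similarity metric is built on.

Only ``is_a`` and ``part_of`` relationships define ancestry; all other
relationship types are dropped on load.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

#: Short namespace codes used throughout the package.
NAMESPACES = ("BP", "CC", "MF")

_NAMESPACE_CODE = {
    "biological_process": "BP",
    "cellular_component": "CC",
    "molecular_function": "MF",
}
_NAMESPACE_LONG = {v: k for k, v in _NAMESPACE_CODE.items()}

#: GAF aspect column -> namespace code.
_ASPECT_CODE = {"P": "BP", "C": "CC", "F": "MF"}

#: Relationship types that define ancestry.
RELATIONS = ("is_a", "part_of")


class OntologyError(ValueError):
    """Malformed ontology input (cycles, missing namespaces, bad roots)."""


class AnnotationError(ValueError):
    """Unusable annotation input (no valid rows, empty namespace)."""


@dataclass(frozen=True)
class GoDag:
    """A Gene Ontology DAG restricted to is_a/part_of ancestry.

    Parameters
    ----------
    namespace_of
        Term identifier -> namespace code (``BP``/``CC``/``MF``).
    parents
        Term -> set of ``(parent_term, relation)`` pairs.  Roots have an
        empty set.
    roots
        Namespace code -> root term of that namespace.
    alt_ids
        Secondary identifier -> primary term identifier.
    """

    namespace_of: dict[str, str]
    parents: dict[str, frozenset[tuple[str, str]]]
    roots: dict[str, str]
    alt_ids: dict[str, str] = field(default_factory=dict)
    _ancestor_cache: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.namespace_of)
        for child, rels in self.parents.items():
            for parent, _ in rels:
                g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise OntologyError(f"ontology graph has a cycle through {cyc[0][0]!r}")
        for ns, root in self.roots.items():
            if self.namespace_of.get(root) != ns:
                raise OntologyError(f"root {root!r} is not a term of namespace {ns}")

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.namespace_of)

    def __contains__(self, term: str) -> bool:
        return term in self.namespace_of

    def primary(self, term: str) -> str | None:
        """Resolve an identifier to its primary term, or None if unknown."""
        if term in self.namespace_of:
            return term
        return self.alt_ids.get(term)

    def children_of(self, term: str) -> set[tuple[str, str]]:
        """Set of (child, relation) pairs pointing at ``term``."""
        return {
            (child, rel)
            for child, rels in self.parents.items()
            for parent, rel in rels
            if parent == term
        }

    def ancestors(self, term: str, include_self: bool = True) -> frozenset[str]:
        """Ancestor closure of ``term`` over is_a/part_of (memoised).

        By convention every term is its own ancestor, which is the
        convention the common-ancestor set of the similarity metrics uses.
        """
        if term not in self.namespace_of:
            raise KeyError(f"unknown term {term!r}")
        cached = self._ancestor_cache.get(term)
        if cached is None:
            out: set[str] = {term}
            for parent, _ in self.parents[term]:
                out |= self.ancestors(parent)
            cached = frozenset(out)
            self._ancestor_cache[term] = cached
        return cached if include_self else cached - {term}

    def common_ancestors(self, t1: str, t2: str) -> frozenset[str]:
        return self.ancestors(t1) & self.ancestors(t2)


def _find_roots(namespace_of: dict[str, str], parents: dict[str, frozenset]) -> dict[str, str]:
    roots: dict[str, str] = {}
    for term, ns in namespace_of.items():
        if not parents[term]:
            if ns in roots:
                raise OntologyError(
                    f"namespace {ns} has multiple roots: {roots[ns]!r} and {term!r}"
                )
            roots[ns] = term
    return roots


def build_dag(
    namespace_of: dict[str, str],
    parent_edges: dict[str, set[tuple[str, str]]],
    alt_ids: dict[str, str] | None = None,
) -> GoDag:
    """Assemble a validated :class:`GoDag` from plain dictionaries."""
    parents = {t: frozenset(parent_edges.get(t, set())) for t in namespace_of}
    roots = _find_roots(namespace_of, parents)
    return GoDag(
        namespace_of=dict(namespace_of),
        parents=parents,
        roots=roots,
        alt_ids=dict(alt_ids or {}),
    )


def load_obo(path) -> GoDag:
    """Load a GO DAG from an OBO 1.2/1.4 file.

    Obsolete terms are skipped, only is_a/part_of edges are retained, and
    cross-namespace edges are dropped so that every term's ancestry stays
    inside its own subontology.  ``alt_id`` identifiers map to their
    primary term.
    """
    graph = obonet.read_obo(path, ignore_obsolete=True)

    namespace_of: dict[str, str] = {}
    alt_ids: dict[str, str] = {}
    for term, data in graph.nodes(data=True):
        ns = data.get("namespace")
        if ns not in _NAMESPACE_CODE:
            logger.warning("term %s has no recognised namespace; skipped", term)
            continue
        namespace_of[term] = _NAMESPACE_CODE[ns]
        for alt in data.get("alt_id", []):
            alt_ids[alt] = term

    parent_edges: dict[str, set[tuple[str, str]]] = {t: set() for t in namespace_of}
    for child, parent, relation in graph.edges(keys=True):
        if relation not in RELATIONS:
            continue
        if child not in namespace_of or parent not in namespace_of:
            continue
        if namespace_of[child] != namespace_of[parent]:
            continue
        parent_edges[child].add((parent, relation))

    return build_dag(namespace_of, parent_edges, alt_ids)


@dataclass
class AnnotationCorpus:
    """Protein -> GO term assignments, partitioned by namespace.

    ``annotations[ns][protein]`` is the set of *direct* (unpropagated)
    terms for that protein.  Propagation happens only when frequencies are
    counted, in :func:`propagate_and_score`.
    """

    annotations: dict[str, dict[str, set[str]]]
    evidence_filter: frozenset[str] = frozenset()

    def proteins(self, namespace: str) -> set[str]:
        return set(self.annotations.get(namespace, {}))

    def terms_of(self, protein: str, namespace: str) -> frozenset[str]:
        """Direct annotation set; empty for unannotated proteins."""
        return frozenset(self.annotations.get(namespace, {}).get(protein, ()))

    def add(self, protein: str, term: str, namespace: str) -> None:
        self.annotations.setdefault(namespace, {}).setdefault(protein, set()).add(term)


def load_annotations(path, dag: GoDag, evidence_filter=()) -> AnnotationCorpus:
    """Read a GAF 2.1/2.2 file into an :class:`AnnotationCorpus`.

    Rows are skipped (with a logged warning where informative) when the
    qualifier contains NOT, the evidence code is filtered, the term cannot
    be resolved in the DAG, or the line is malformed.
    """
    evidence_filter = frozenset(evidence_filter)
    corpus = AnnotationCorpus(annotations={}, evidence_filter=evidence_filter)
    n_rows = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) < 15:
                logger.warning("GAF line %d: %d fields (<15); skipped", lineno, len(fields))
                continue
            protein = fields[1]
            qualifier = fields[3]
            go_id = fields[4]
            evidence = fields[6]
            if "NOT" in qualifier.split("|"):
                continue
            if evidence in evidence_filter:
                continue
            term = dag.primary(go_id)
            if term is None:
                logger.warning(
                    "GAF line %d: term %s absent/obsolete in ontology; skipped", lineno, go_id
                )
                continue
            corpus.add(protein, term, dag.namespace_of[term])
            n_rows += 1
    if n_rows == 0:
        raise AnnotationError(f"no usable annotation rows in {path!r}")
    return corpus


@dataclass(frozen=True)
class ICTable:
    """Propagated term frequencies and information content, one namespace.

    ``p`` is the fraction of corpus proteins annotated (after propagation)
    to the term or any of its descendants; ``ic = -ln p`` in natural-log
    units.  Terms never annotated have no entry.
    """

    namespace: str
    n_proteins: int
    count: dict[str, int]
    p: dict[str, float]
    ic: dict[str, float]

    def __contains__(self, term: str) -> bool:
        return term in self.ic

    @property
    def max_ic(self) -> float:
        return max(self.ic.values())

    def to_frame(self) -> pd.DataFrame:
        """Tabular export (term, namespace, count, p, ic)."""
        rows = [
            (t, self.namespace, self.count[t], self.p[t], self.ic[t])
            for t in sorted(self.ic)
        ]
        return pd.DataFrame(rows, columns=["term", "namespace", "count", "p", "ic"])


def propagate_and_score(corpus: AnnotationCorpus, dag: GoDag, namespace: str) -> ICTable:
    """Propagate annotations up the DAG and compute p(t) and IC(t).

    Each protein's direct annotations are extended to all ancestors
    (true-path rule); the counting unit is distinct proteins.  The
    namespace root ends with p = 1 and IC = 0.
    """
    if namespace not in NAMESPACES:
        raise ValueError(f"unknown namespace {namespace!r}")
    by_protein = corpus.annotations.get(namespace, {})
    annotated = {p for p, ts in by_protein.items() if ts}
    if not annotated:
        raise AnnotationError(f"no proteins annotated in namespace {namespace}")

    count: dict[str, int] = {}
    for protein in annotated:
        closure: set[str] = set()
        for term in by_protein[protein]:
            closure |= dag.ancestors(term)
        for term in closure:
            count[term] = count.get(term, 0) + 1

    n = len(annotated)
    p = {t: c / n for t, c in count.items()}
    ic = {t: -math.log(pt) for t, pt in p.items()}
    return ICTable(namespace=namespace, n_proteins=n, count=count, p=p, ic=ic)


def mica(t1: str, t2: str, dag: GoDag, ic: ICTable) -> tuple[str, float]:
    """Most informative common ancestor of two same-namespace terms.

    Each term counts as its own ancestor.  Ancestors without an IC entry
    (never annotated in the corpus) are not eligible.  Ties on IC are
    broken by the lexicographically smallest term identifier.
    """
    ns1, ns2 = dag.namespace_of.get(t1), dag.namespace_of.get(t2)
    if ns1 is None or ns2 is None:
        raise KeyError(f"unknown term {t1 if ns1 is None else t2!r}")
    if ns1 != ns2:
        raise ValueError(f"terms {t1} ({ns1}) and {t2} ({ns2}) are in different namespaces")
    candidates = [t for t in dag.common_ancestors(t1, t2) if t in ic]
    if not candidates:
        raise ValueError(f"no common ancestor of {t1} and {t2} has an IC entry")
    best = min(candidates, key=lambda t: (-ic.ic[t], t))
    return best, ic.ic[best]
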