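"""Self-contained synthetic fixtures for the whole pipeline.

Generates, from one seed, a small GO-style DAG per namespace, an
annotation corpus, a PPI network with a planted fraction of false
positive edges, and a planted essential-protein set:

* Each namespace DAG is a rooted tree (configurable branching and depth)
  plus a few within-branch ``part_of`` shortcut edges.
* Proteins belong to functional modules, one module per depth-2 BP term;
  a protein's BP annotations are leaves under its module term, so
  module-mates share an informative ancestor.
* True interactions connect module-mates with probability
  ``annotation_coherence`` (else two random modules); endpoint choice is
  degree-biased so hubs emerge.
* Planted false edges emulate "sticky" high-throughput baits: a small
  set of noise-hub proteins collects the spurious links, each to a
  partner whose module sits under a different top-level branch — the
  pair's only shared BP ancestor is the root, which forces their
  confidence score to ~0 under every metric.
* Essential proteins are sampled with probability increasing in
  true-interaction degree, emulating the centrality-lethality rule.

The emitted files round-trip through the package's own readers, so every
stage of the pipeline is testable without external downloads.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .evaluation import GoldStandard
from .network import PpiNetwork
from .ontology import AnnotationCorpus, GoDag, build_dag

_NS_PREFIX = {"BP": 1, "CC": 2, "MF": 3}
_NS_LONG = {"BP": "biological_process", "CC": "cellular_component", "MF": "molecular_function"}
_NS_ASPECT = {"BP": "P", "CC": "C", "MF": "F"}
_NS_QUALIFIER = {"BP": "involved_in", "CC": "part_of", "MF": "enables"}


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters; a fixed seed gives bit-identical output."""

    seed: int = 0
    branching: int = 4
    depth: int = 3
    n_proteins: int = 300
    n_true_edges: int = 900
    false_edge_fraction: float = 0.10
    essential_fraction: float = 0.20
    annotation_coherence: float = 0.90
    unannotated_fraction: float = 0.05
    max_terms_per_protein: int = 3
    n_shortcuts: int = 4
    noise_hub_fraction: float = 0.04

    def __post_init__(self):
        for name in ("false_edge_fraction", "essential_fraction",
                     "annotation_coherence", "unannotated_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.false_edge_fraction >= 1.0:
            raise ValueError("false_edge_fraction must be < 1")
        if self.depth < 2 or self.branching < 2:
            raise ValueError("need depth >= 2 and branching >= 2")

    @property
    def n_false_edges(self) -> int:
        f = self.false_edge_fraction
        return round(f / (1.0 - f) * self.n_true_edges)

    @property
    def n_terms_per_namespace(self) -> int:
        b, d = self.branching, self.depth
        return (b ** (d + 1) - 1) // (b - 1)


@dataclass
class SyntheticBundle:
    """Everything one generate() call produced, planted truth included."""

    spec: SyntheticSpec
    dag: GoDag
    corpus: AnnotationCorpus
    network: PpiNetwork
    gold: GoldStandard
    true_edges: frozenset[tuple[str, str]]
    false_edges: frozenset[tuple[str, str]]
    module_of: dict[str, str] = field(default_factory=dict)


def _term_id(ns: str, index: int) -> str:
    return f"GO:{_NS_PREFIX[ns]}{index:06d}"


def _build_namespace_tree(spec: SyntheticSpec, ns: str, rng: np.random.Generator):
    """Rooted b-ary tree of the given depth plus within-branch part_of shortcuts.

    Returns (namespace_of, parent_edges, levels) where levels[d] lists the
    terms at depth d.
    """
    b, d = spec.branching, spec.depth
    namespace_of: dict[str, str] = {}
    parent_edges: dict[str, set[tuple[str, str]]] = {}
    levels: list[list[str]] = []
    idx = 0
    for level in range(d + 1):
        terms = []
        for j in range(b ** level):
            t = _term_id(ns, idx)
            idx += 1
            namespace_of[t] = ns
            parent_edges[t] = set()
            if level > 0:
                parent = levels[level - 1][j // b]
                parent_edges[t].add((parent, "is_a"))
            terms.append(t)
        levels.append(terms)
    # part_of shortcuts from deep terms to another ancestor in the SAME
    # top-level branch, so cross-branch pairs still share only the root
    if d >= 3 and spec.n_shortcuts > 0:
        for _ in range(spec.n_shortcuts):
            leaf = levels[3][int(rng.integers(len(levels[3])))]
            branch = levels[3].index(leaf) // (b ** 2)
            # depth-2 terms of the same branch
            candidates = levels[2][branch * b:(branch + 1) * b]
            target = candidates[int(rng.integers(len(candidates)))]
            current_parents = {p for p, _ in parent_edges[leaf]}
            if target not in current_parents and target != leaf:
                parent_edges[leaf].add((target, "part_of"))
    return namespace_of, parent_edges, levels


def generate(spec: SyntheticSpec | None = None) -> SyntheticBundle:
    """Generate a full fixture bundle from the spec (deterministic in seed)."""
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)

    namespace_of: dict[str, str] = {}
    parent_edges: dict[str, set[tuple[str, str]]] = {}
    levels_by_ns: dict[str, list[list[str]]] = {}
    for ns in ("BP", "CC", "MF"):
        ns_of, p_edges, levels = _build_namespace_tree(spec, ns, rng)
        namespace_of.update(ns_of)
        parent_edges.update(p_edges)
        levels_by_ns[ns] = levels
    dag = build_dag(namespace_of, parent_edges)

    proteins = [f"P{i:04d}" for i in range(spec.n_proteins)]
    module_terms = levels_by_ns["BP"][2]          # depth-2 BP terms
    n_modules = len(module_terms)
    branch_of_module = {m: i // spec.branching for i, m in enumerate(module_terms)}
    assignment = rng.permutation(spec.n_proteins) % n_modules
    module_of = {p: module_terms[assignment[i]] for i, p in enumerate(proteins)}
    members: dict[str, list[str]] = {m: [] for m in module_terms}
    for p in proteins:
        members[module_of[p]].append(p)

    # degree-biased endpoint weights inside each module (Zipf-ish)
    weight_of: dict[str, float] = {}
    for m, ps in members.items():
        for r, p in enumerate(ps):
            weight_of[p] = (1.0 + r) ** -0.8

    max_pairs = spec.n_proteins * (spec.n_proteins - 1) // 2
    if spec.n_true_edges + spec.n_false_edges > max_pairs:
        raise ValueError("spec asks for more edges than protein pairs exist")

    def weighted_pick(ps: list[str], size: int) -> list[str]:
        w = np.array([weight_of[p] for p in ps])
        return [str(x) for x in rng.choice(ps, size=size, replace=False, p=w / w.sum())]

    true_edges: set[tuple[str, str]] = set()
    module_sizes = np.array([len(members[m]) for m in module_terms], dtype=float)
    attempts = 0
    while len(true_edges) < spec.n_true_edges and attempts < 50 * spec.n_true_edges:
        attempts += 1
        if rng.random() < spec.annotation_coherence:
            m = module_terms[int(rng.choice(n_modules, p=module_sizes / module_sizes.sum()))]
            if len(members[m]) < 2:
                continue
            a, b = weighted_pick(members[m], 2)
        else:
            mi, mj = rng.choice(n_modules, size=2, replace=False)
            if not members[module_terms[mi]] or not members[module_terms[mj]]:
                continue
            a = weighted_pick(members[module_terms[mi]], 1)[0]
            b = weighted_pick(members[module_terms[mj]], 1)[0]
        e = (a, b) if a < b else (b, a)
        if a != b and e not in true_edges:
            true_edges.add(e)
    if len(true_edges) < spec.n_true_edges:
        raise ValueError("could not place the requested number of true edges")

    # study bias: poorly connected proteins are the poorly annotated ones
    true_deg: dict[str, int] = {p: 0 for p in proteins}
    for a, b in true_edges:
        true_deg[a] += 1
        true_deg[b] += 1
    n_unann = round(spec.unannotated_fraction * spec.n_proteins)
    med = float(np.median([true_deg[p] for p in proteins]))
    candidates = [p for p in proteins if true_deg[p] <= med]
    w_un = np.array([1.0 / (1.0 + true_deg[p]) ** 2 for p in candidates])
    unannotated = {
        str(p)
        for p in rng.choice(candidates, size=min(n_unann, len(candidates)),
                            replace=False, p=w_un / w_un.sum())
    }

    # annotations: BP leaves under the module term; random CC/MF leaves
    corpus = AnnotationCorpus(annotations={})
    bp_leaf_children: dict[str, list[str]] = {m: [] for m in module_terms}
    for leaf in levels_by_ns["BP"][spec.depth]:
        for parent, _ in dag.parents[leaf]:
            if parent in bp_leaf_children:
                bp_leaf_children[parent].append(leaf)
    for p in proteins:
        if p in unannotated:
            continue
        leaves = bp_leaf_children[module_of[p]]
        k = int(rng.integers(1, spec.max_terms_per_protein + 1))
        for t in rng.choice(leaves, size=min(k, len(leaves)), replace=False):
            corpus.add(p, str(t), "BP")
        for ns in ("CC", "MF"):
            pool = levels_by_ns[ns][spec.depth]
            k2 = int(rng.integers(1, 3))
            for t in rng.choice(pool, size=k2, replace=False):
                corpus.add(p, str(t), ns)

    # sticky-bait noise: a few hub proteins collect the spurious links
    false_edges: set[tuple[str, str]] = set()
    n_hubs = max(3, round(spec.noise_hub_fraction * spec.n_proteins))
    noise_hubs = [str(p) for p in rng.choice(proteins, size=n_hubs, replace=False)]
    attempts = 0
    while len(false_edges) < spec.n_false_edges and attempts < 100 * (spec.n_false_edges + 1):
        attempts += 1
        a = noise_hubs[int(rng.integers(n_hubs))]
        mj = module_terms[int(rng.integers(n_modules))]
        if branch_of_module[module_of[a]] == branch_of_module[mj]:
            continue
        if not members[mj]:
            continue
        b = str(rng.choice(members[mj]))
        e = (a, b) if a < b else (b, a)
        if a != b and e not in true_edges and e not in false_edges:
            false_edges.add(e)
    if len(false_edges) < spec.n_false_edges:
        raise ValueError("could not place the requested number of false edges")

    network = PpiNetwork(edges=sorted(true_edges | false_edges))

    # essentiality: degree in the TRUE interaction graph drives the draw
    true_net = PpiNetwork(edges=sorted(true_edges), nodes=proteins)
    deg = np.array([true_net.degree(p) for p in proteins], dtype=float)
    w = (deg + 0.1) ** 1.5
    n_ess = round(spec.essential_fraction * spec.n_proteins)
    essential = rng.choice(proteins, size=n_ess, replace=False, p=w / w.sum())
    gold = GoldStandard(essential=frozenset(str(p) for p in essential))

    return SyntheticBundle(
        spec=spec,
        dag=dag,
        corpus=corpus,
        network=network,
        gold=gold,
        true_edges=frozenset(true_edges),
        false_edges=frozenset(false_edges),
        module_of=module_of,
    )


def _write_obo(bundle: SyntheticBundle, path: Path) -> None:
    dag = bundle.dag
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        fh.write(f"remark: synthetic fixture, seed={bundle.spec.seed}\n")
        fh.write("ontology: goppi-synthetic\n")
        for term in sorted(dag.terms):
            ns = dag.namespace_of[term]
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: synthetic {_NS_LONG[ns]} term {term[-6:]}\n")
            fh.write(f"namespace: {_NS_LONG[ns]}\n")
            for parent, rel in sorted(dag.parents[term]):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")


def _write_gaf(bundle: SyntheticBundle, path: Path) -> None:
    seed = bundle.spec.seed
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("!gaf-version: 2.2\n")
        fh.write(f"!generated-by: goppi synthetic fixture, seed={seed}\n")
        for ns in ("BP", "CC", "MF"):
            by_protein = bundle.corpus.annotations.get(ns, {})
            for protein in sorted(by_protein):
                for term in sorted(by_protein[protein]):
                    row = [
                        "GOPPI", protein, protein, _NS_QUALIFIER[ns], term,
                        "GO_REF:0000001", "IDA", "", _NS_ASPECT[ns], "", "",
                        "protein", "taxon:4932", "20200910", "GOPPI", "", "",
                    ]
                    fh.write("\t".join(row) + "\n")


def write_fixture(bundle: SyntheticBundle, directory) -> dict[str, Path]:
    """Write OBO/GAF/edge-list/gold/false-edge files plus a JSON manifest.

    Every file parses back through the package's own readers.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "obo": directory / "go.obo",
        "gaf": directory / "annotations.gaf",
        "edges": directory / "network.edges",
        "gold": directory / "essential.txt",
        "false_edges": directory / "false_edges.txt",
        "manifest": directory / "manifest.json",
    }
    seed = bundle.spec.seed
    _write_obo(bundle, paths["obo"])
    _write_gaf(bundle, paths["gaf"])
    with open(paths["edges"], "w", encoding="utf-8") as fh:
        fh.write(f"# goppi synthetic network, seed={seed}\n")
        for a, b in sorted(bundle.network.edges):
            fh.write(f"{a}\t{b}\n")
    with open(paths["gold"], "w", encoding="utf-8") as fh:
        fh.write(f"# goppi synthetic essential proteins, seed={seed}\n")
        for p in sorted(bundle.gold.essential):
            fh.write(p + "\n")
    with open(paths["false_edges"], "w", encoding="utf-8") as fh:
        fh.write(f"# goppi planted false edges, seed={seed}\n")
        for a, b in sorted(bundle.false_edges):
            fh.write(f"{a}\t{b}\n")
    manifest = {
        "spec": asdict(bundle.spec),
        "n_terms": len(bundle.dag.terms),
        "n_proteins": bundle.network.n_nodes,
        "n_edges": bundle.network.n_edges,
        "n_true_edges": len(bundle.true_edges),
        "n_false_edges": len(bundle.false_edges),
        "n_essential": len(bundle.gold.essential),
    }
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
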