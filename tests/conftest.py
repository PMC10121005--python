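"""Shared fixtures: hand-built toy ontologies/corpora and synthetic bundles."""

import math
import random

import pytest

from goppi.ontology import AnnotationCorpus, GoDag, build_dag, propagate_and_score
from goppi.synthetic import SyntheticSpec, generate

LN2 = math.log(2.0)
LN4 = math.log(4.0)


@pytest.fixture(scope="session")
def fork_dag() -> GoDag:
    """Three BP terms: one root with two is_a children."""
    ns = {"T:root": "BP", "T:c1": "BP", "T:c2": "BP"}
    parents = {
        "T:c1": {("T:root", "is_a")},
        "T:c2": {("T:root", "is_a")},
    }
    return build_dag(ns, parents)


@pytest.fixture(scope="session")
def fork_corpus() -> AnnotationCorpus:
    """Four proteins: two on c1, one on c2, one on the root.

    Hand counts after propagation: p(c1)=0.5, p(c2)=0.25, p(root)=1, so
    ic(c1)=ln 2, ic(c2)=ln 4, ic(root)=0.
    """
    corpus = AnnotationCorpus(annotations={})
    corpus.add("P1", "T:c1", "BP")
    corpus.add("P2", "T:c1", "BP")
    corpus.add("P3", "T:c2", "BP")
    corpus.add("P4", "T:root", "BP")
    return corpus


@pytest.fixture(scope="session")
def fork_ic(fork_corpus, fork_dag):
    return propagate_and_score(fork_corpus, fork_dag, "BP")


@pytest.fixture(scope="session")
def chain_dag() -> GoDag:
    """BP chain root <- a <- b (is_a edges)."""
    ns = {"T:root": "BP", "T:a": "BP", "T:b": "BP"}
    parents = {
        "T:a": {("T:root", "is_a")},
        "T:b": {("T:a", "is_a")},
    }
    return build_dag(ns, parents)


@pytest.fixture(scope="session")
def chain_corpus() -> AnnotationCorpus:
    """Corpus making ic(a)=ln 2 and ic(b)=ln 4 on the chain."""
    corpus = AnnotationCorpus(annotations={})
    corpus.add("P1", "T:b", "BP")
    corpus.add("P2", "T:a", "BP")
    corpus.add("P3", "T:root", "BP")
    corpus.add("P4", "T:root", "BP")
    return corpus


@pytest.fixture(scope="session")
def chain_ic(chain_corpus, chain_dag):
    return propagate_and_score(chain_corpus, chain_dag, "BP")


@pytest.fixture(scope="session")
def diamond_dag() -> GoDag:
    """BP diamond a <- {b, c} <- d, all is_a."""
    ns = {t: "BP" for t in ("T:a", "T:b", "T:c", "T:d")}
    parents = {
        "T:b": {("T:a", "is_a")},
        "T:c": {("T:a", "is_a")},
        "T:d": {("T:b", "is_a"), ("T:c", "is_a")},
    }
    return build_dag(ns, parents)


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic bundle (seed 7), shared read-only across tests."""
    return generate(SyntheticSpec(seed=7))


def make_random_dag(rng: random.Random, n_terms: int, ns: str = "BP") -> GoDag:
    """Random rooted DAG: term i picks 1-2 parents among terms < i."""
    terms = [f"T:{i:02d}" for i in range(n_terms)]
    namespace_of = {t: ns for t in terms}
    parents = {}
    for i in range(1, n_terms):
        k = rng.choice([1, 1, 2])
        chosen = rng.sample(terms[:i], min(k, i))
        parents[terms[i]] = {
            (p, rng.choice(["is_a", "part_of"])) for p in chosen
        }
    return build_dag(namespace_of, parents)


def make_random_corpus(rng: random.Random, dag: GoDag, n_proteins: int) -> AnnotationCorpus:
    """Random corpus: every protein gets 1-3 random terms."""
    corpus = AnnotationCorpus(annotations={})
    terms = sorted(dag.terms)
    for i in range(n_proteins):
        for t in rng.sample(terms, rng.randint(1, min(3, len(terms)))):
            corpus.add(f"P{i}", t, dag.namespace_of[t])
    return corpus
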