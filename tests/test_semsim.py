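"""Five similarity metrics vs hand values and brute-force oracles."""

import itertools
import math
import random

import pytest

from goppi.ontology import propagate_and_score
from goppi.semsim import (
    ConfigError,
    SemanticSimilarity,
    SemSimConfig,
    protein_similarity,
    sim_jiang,
    sim_lin,
    sim_rel,
    sim_resnik,
    sim_wang,
    wang_profile,
)

from conftest import LN2, make_random_corpus, make_random_dag


# ---------------------------------------------------------------- oracles

def _brute_common_ancestor_max_ic(t1, t2, dag, table):
    """Direct max over every common ancestor with an IC entry."""
    best = None
    for t in sorted(dag.ancestors(t1) & dag.ancestors(t2)):
        if t in table and (best is None or table.ic[t] > table.ic[best]):
            best = t
    return table.ic[best]


def _brute_svalue(t, u, dag, weights):
    """Max over all directed paths t -> u of the edge-weight product."""
    if u == t:
        return 1.0
    best = 0.0
    stack = [(t, 1.0)]
    while stack:
        node, prod = stack.pop()
        for parent, rel in dag.parents[node]:
            p = prod * weights[rel]
            if parent == u:
                best = max(best, p)
            stack.append((parent, p))
    return best


def _brute_wang(t1, t2, dag, weights):
    anc1, anc2 = dag.ancestors(t1), dag.ancestors(t2)
    sv1 = sum(_brute_svalue(t1, u, dag, weights) for u in anc1)
    sv2 = sum(_brute_svalue(t2, u, dag, weights) for u in anc2)
    shared = anc1 & anc2
    num = sum(
        _brute_svalue(t1, u, dag, weights) + _brute_svalue(t2, u, dag, weights)
        for u in shared
    )
    return num / (sv1 + sv2)


# ----------------------------------------------------------- hand values

class TestResnik:
    def test_siblings_under_root_zero(self, fork_dag, fork_ic):
        assert sim_resnik("T:c1", "T:c2", fork_ic, fork_dag) == 0.0

    def test_self_unnormalized_is_own_ic(self, fork_dag, fork_ic):
        assert sim_resnik("T:c1", "T:c1", fork_ic, fork_dag, normalize=False) == (
            pytest.approx(0.6931, abs=1e-4)
        )

    def test_self_on_max_ic_term_normalized_is_one(self, fork_dag, fork_ic):
        assert sim_resnik("T:c2", "T:c2", fork_ic, fork_dag, normalize=True) == 1.0


class TestLin:
    def test_self_similarity_one(self, fork_dag, fork_ic):
        assert sim_lin("T:c1", "T:c1", fork_ic, fork_dag) == 1.0

    def test_siblings_zero(self, fork_dag, fork_ic):
        assert sim_lin("T:c1", "T:c2", fork_ic, fork_dag) == 0.0

    def test_chain_hand_value(self, chain_dag, chain_ic):
        assert sim_lin("T:a", "T:b", chain_ic, chain_dag) == pytest.approx(
            2 * 0.6931 / 2.0794, abs=1e-4
        )

    def test_zero_over_zero_defined_as_zero(self, chain_dag, chain_ic):
        assert sim_lin("T:root", "T:root", chain_ic, chain_dag) == 0.0


class TestJiang:
    def test_self_similarity_one(self, fork_dag, fork_ic):
        assert sim_jiang("T:c1", "T:c1", fork_ic, fork_dag) == 1.0

    def test_siblings_clamped_to_zero(self, fork_dag, fork_ic):
        raw = sim_jiang("T:c1", "T:c2", fork_ic, fork_dag, clamp=False)
        assert raw == pytest.approx(1 - 2.0794, abs=1e-4)
        assert sim_jiang("T:c1", "T:c2", fork_ic, fork_dag, clamp=True) == 0.0

    def test_chain_hand_value(self, chain_dag, chain_ic):
        assert sim_jiang("T:a", "T:b", chain_ic, chain_dag) == pytest.approx(
            0.3069, abs=1e-4
        )


class TestRel:
    def test_siblings_zero(self, fork_dag, fork_ic):
        assert sim_rel("T:c1", "T:c2", fork_ic, fork_dag) == 0.0

    def test_self_equals_one_minus_p(self, fork_dag, fork_ic):
        assert sim_rel("T:c1", "T:c1", fork_ic, fork_dag) == pytest.approx(0.5)
        assert sim_rel("T:c2", "T:c2", fork_ic, fork_dag) == pytest.approx(0.75)

    def test_never_exceeds_lin(self, fork_dag, fork_ic):
        for t1, t2 in itertools.combinations_with_replacement(
            ["T:root", "T:c1", "T:c2"], 2
        ):
            assert sim_rel(t1, t2, fork_ic, fork_dag) <= sim_lin(
                t1, t2, fork_ic, fork_dag
            ) + 1e-12


class TestWang:
    def test_root_profile_base_case(self, chain_dag):
        prof = wang_profile("T:root", chain_dag)
        assert prof.svalues == {"T:root": 1.0}
        assert prof.sv == 1.0

    def test_chain_profile_hand_value(self, chain_dag):
        prof = wang_profile("T:a", chain_dag)
        assert prof.svalues == {"T:a": 1.0, "T:root": 0.8}
        assert prof.sv == pytest.approx(1.8)

    def test_chain_similarity_hand_value(self, chain_dag):
        # profiles {a:1, root:0.8} and {root:1}; shared = {root}
        assert sim_wang("T:root", "T:a", chain_dag) == pytest.approx(1.8 / 2.8)

    def test_diamond_max_rule(self, diamond_dag):
        prof = wang_profile("T:d", diamond_dag)
        assert prof.svalues["T:a"] == pytest.approx(0.64)

    def test_self_similarity_one(self, diamond_dag):
        for t in diamond_dag.terms:
            assert sim_wang(t, t, diamond_dag) == 1.0

    def test_part_of_weight_used(self):
        from goppi.ontology import build_dag

        dag = build_dag(
            {"T:r": "BP", "T:x": "BP"}, {"T:x": {("T:r", "part_of")}}
        )
        prof = wang_profile("T:x", dag)
        assert prof.svalues["T:r"] == pytest.approx(0.6)


# ------------------------------------------------- brute-force agreement

def test_all_metrics_agree_with_brute_force_on_random_dags():
    """Exhaustive agreement on random DAGs of <= 15 terms."""
    rng = random.Random(2024)
    weights = {"is_a": 0.8, "part_of": 0.6}
    for _ in range(15):
        dag = make_random_dag(rng, rng.randint(4, 15))
        corpus = make_random_corpus(rng, dag, rng.randint(3, 10))
        table = propagate_and_score(corpus, dag, "BP")
        scored = sorted(t for t in dag.terms if t in table)
        for t1, t2 in itertools.combinations_with_replacement(scored, 2):
            m = _brute_common_ancestor_max_ic(t1, t2, dag, table)
            assert sim_resnik(t1, t2, table, dag, normalize=False) == pytest.approx(m)
            denom = table.ic[t1] + table.ic[t2]
            expect_lin = 2 * m / denom if denom else 0.0
            assert sim_lin(t1, t2, table, dag) == pytest.approx(expect_lin)
            assert sim_jiang(t1, t2, table, dag, clamp=False) == pytest.approx(
                1 - (denom - 2 * m)
            )
            assert sim_wang(t1, t2, dag, weights) == pytest.approx(
                _brute_wang(t1, t2, dag, weights)
            )


def test_bounded_metrics_stay_in_unit_interval_and_symmetric():
    rng = random.Random(5)
    cfgs = [SemSimConfig(metric=m) for m in ("resnik", "lin", "jiang", "rel", "wang")]
    for _ in range(5):
        dag = make_random_dag(rng, rng.randint(5, 12))
        corpus = make_random_corpus(rng, dag, rng.randint(3, 8))
        scorers = [SemanticSimilarity(dag, corpus, cfg) for cfg in cfgs]
        scored = sorted(t for t in dag.terms if t in scorers[0].ic)
        for t1, t2 in itertools.combinations(scored, 2):
            for scorer in scorers:
                v = scorer.term_sim(t1, t2)
                assert 0.0 <= v <= 1.0 + 1e-12
                assert v == scorer.term_sim(t2, t1)


# ------------------------------------------------------------ aggregation

class TestProteinSimilarity:
    def test_unannotated_protein_scores_zero(self, fork_dag, fork_corpus):
        assert protein_similarity("P1", "P:none", fork_corpus, fork_dag) == 0.0

    def test_identical_single_term_scores_one(self, fork_dag, fork_corpus):
        # P1 and P2 both annotated to c1 only
        for metric in ("lin", "jiang", "wang"):
            cfg = SemSimConfig(metric=metric)
            assert protein_similarity("P1", "P2", fork_corpus, fork_dag, cfg) == 1.0

    def test_bma_hand_value(self, fork_dag, fork_corpus):
        """T1={c1}, T2={c1,c2} under Lin: bma = (1 + 0.5)/2."""
        corpus2 = type(fork_corpus)(annotations={})
        for p, t in [("A", "T:c1"), ("B", "T:c1"), ("B", "T:c2"),
                     ("P1", "T:c1"), ("P2", "T:c1"), ("P3", "T:c2"), ("P4", "T:root")]:
            corpus2.add(p, t, "BP")
        cfg = SemSimConfig(metric="lin", aggregation="bma")
        assert protein_similarity("A", "B", corpus2, fork_dag, cfg) == pytest.approx(0.75)
        cfg_max = SemSimConfig(metric="lin", aggregation="max")
        assert protein_similarity("A", "B", corpus2, fork_dag, cfg_max) == 1.0

    def test_symmetric(self, bundle):
        scorer = SemanticSimilarity(bundle.dag, bundle.corpus, SemSimConfig())
        pairs = sorted(bundle.network.edges)[:25]
        for a, b in pairs:
            assert scorer.protein_sim(a, b) == scorer.protein_sim(b, a)

    def test_bma_equals_max_for_single_term_proteins(self):
        rng = random.Random(11)
        dag = make_random_dag(rng, 10)
        corpus = make_random_corpus(rng, dag, 0)
        terms = sorted(dag.terms)
        corpus.add("A", terms[3], "BP")
        corpus.add("B", terms[7], "BP")
        corpus.add("C", terms[1], "BP")
        for metric in ("lin", "wang", "jiang"):
            bma = SemanticSimilarity(dag, corpus, SemSimConfig(metric=metric))
            mx = SemanticSimilarity(
                dag, corpus, SemSimConfig(metric=metric, aggregation="max")
            )
            assert bma.protein_sim("A", "B") == mx.protein_sim("A", "B")

    def test_unknown_metric_rejected(self):
        with pytest.raises(ConfigError):
            SemSimConfig(metric="cosine")

    def test_wang_weights_validated(self):
        with pytest.raises(ConfigError):
            SemSimConfig(wang_weights={"is_a": 1.0, "part_of": 0.6})
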