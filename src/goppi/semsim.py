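"""GO semantic-similarity metrics and protein-pair confidence scores.

Five term-level metrics are implemented: four information-content based
(Resnik, Lin, Jiang, Rel) built on the most informative common ancestor
(MICA), and the hybrid Wang metric built on semantic contributions of
shared ancestors.  Term-level scores are aggregated over the two
proteins' direct annotation sets (best-match average by default) into a
single confidence score per protein pair, which the network module uses
to filter unreliable interactions.

Conventions (all configurable):

* Resnik is normalised by the maximum corpus IC of the namespace so it is
  comparable to the other metrics on [0, 1].
* Jiang (``1 - [IC(m) + IC(v) - 2 IC(MICA)]``) can be arbitrarily
  negative on distant terms and is clamped at 0 by default.
* Wang edge contribution factors default to 0.8 (is_a) / 0.6 (part_of).
* A protein unannotated in the configured namespace scores 0 against
  everything.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .ontology import AnnotationCorpus, GoDag, ICTable, NAMESPACES, mica

METRICS = ("resnik", "lin", "jiang", "rel", "wang")
AGGREGATIONS = ("bma", "max")

DEFAULT_WANG_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


class ConfigError(ValueError):
    """Invalid semantic-similarity configuration."""


@dataclass(frozen=True)
class SemSimConfig:
    """Configuration of one (metric, namespace) scoring run."""

    metric: str = "lin"
    namespace: str = "BP"
    aggregation: str = "bma"
    wang_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WANG_WEIGHTS)
    )
    normalize_resnik: bool = True
    clamp_nonnegative: bool = True

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ConfigError(f"unknown metric {self.metric!r}; choose from {METRICS}")
        if self.namespace not in NAMESPACES:
            raise ConfigError(
                f"unknown namespace {self.namespace!r}; choose from {NAMESPACES}"
            )
        if self.aggregation not in AGGREGATIONS:
            raise ConfigError(
                f"unknown aggregation {self.aggregation!r}; choose from {AGGREGATIONS}"
            )
        for rel, w in self.wang_weights.items():
            if not 0.0 < w < 1.0:
                raise ConfigError(
                    f"wang weight for {rel!r} must lie strictly in (0, 1), got {w}"
                )


def sim_resnik(t1: str, t2: str, ic: ICTable, dag: GoDag, normalize: bool = True) -> float:
    """Resnik similarity: IC of the MICA, optionally / max corpus IC."""
    _, m = mica(t1, t2, dag, ic)
    if normalize:
        top = ic.max_ic
        return m / top if top > 0 else 0.0
    return m


def sim_lin(t1: str, t2: str, ic: ICTable, dag: GoDag) -> float:
    """Lin similarity: 2 IC(MICA) / (IC(t1) + IC(t2)); 0 on a 0/0."""
    _, m = mica(t1, t2, dag, ic)
    denom = ic.ic[t1] + ic.ic[t2]
    if denom == 0.0:
        return 0.0
    return 2.0 * m / denom


def sim_jiang(t1: str, t2: str, ic: ICTable, dag: GoDag, clamp: bool = True) -> float:
    """Jiang similarity: 1 minus the IC distance to the MICA."""
    _, m = mica(t1, t2, dag, ic)
    raw = 1.0 - (ic.ic[t1] + ic.ic[t2] - 2.0 * m)
    return max(0.0, raw) if clamp else raw


def sim_rel(t1: str, t2: str, ic: ICTable, dag: GoDag) -> float:
    """Rel similarity: Lin weighted by (1 - p(MICA)), so a MICA common to
    the whole corpus contributes nothing even when ICs align."""
    term, m = mica(t1, t2, dag, ic)
    denom = ic.ic[t1] + ic.ic[t2]
    if denom == 0.0:
        return 0.0
    return 2.0 * m * (1.0 - ic.p[term]) / denom


@dataclass(frozen=True)
class WangProfile:
    """S-values of a term's ancestor closure and their sum SV."""

    term: str
    svalues: dict[str, float]
    sv: float


def wang_profile(
    t: str, dag: GoDag, wang_weights: dict[str, float] | None = None
) -> WangProfile:
    """Semantic profile of a term under the Wang metric.

    S(t) = 1 at the term itself; each ancestor u gets the maximum over
    its in-closure children u' of w_e * S(u'), where w_e is the
    contribution factor of the u' -> u edge.  SV is the sum of S-values.
    """
    weights = dict(DEFAULT_WANG_WEIGHTS if wang_weights is None else wang_weights)
    closure = dag.ancestors(t)
    # children of u inside the closure, with edge relation
    in_children: dict[str, list[tuple[str, str]]] = {u: [] for u in closure}
    for child in closure:
        for parent, rel in dag.parents[child]:
            if parent in closure:
                in_children[parent].append((child, rel))

    svalues: dict[str, float] = {}

    def s(u: str) -> float:
        if u in svalues:
            return svalues[u]
        if u == t:
            val = 1.0
        else:
            val = max(weights[rel] * s(child) for child, rel in in_children[u])
        svalues[u] = val
        return val

    for u in closure:
        s(u)
    return WangProfile(term=t, svalues=svalues, sv=sum(svalues.values()))


def sim_wang(
    t1: str, t2: str, dag: GoDag, wang_weights: dict[str, float] | None = None
) -> float:
    """Wang similarity: shared-ancestor S-values over total semantic values."""
    if dag.namespace_of[t1] != dag.namespace_of[t2]:
        raise ValueError(f"terms {t1} and {t2} are in different namespaces")
    p1 = wang_profile(t1, dag, wang_weights)
    p2 = wang_profile(t2, dag, wang_weights)
    shared = set(p1.svalues) & set(p2.svalues)
    num = sum(p1.svalues[u] + p2.svalues[u] for u in shared)
    return num / (p1.sv + p2.sv)


class SemanticSimilarity:
    """Protein-pair confidence scorer for one (metric, namespace) setting.

    Holds the DAG, the annotation corpus, the propagated IC table and a
    term-pair cache, so scoring every edge of a network only evaluates
    each distinct term pair once.
    """

    def __init__(
        self,
        dag: GoDag,
        corpus: AnnotationCorpus,
        config: SemSimConfig | None = None,
        ic: ICTable | None = None,
    ):
        from .ontology import propagate_and_score

        self.config = config or SemSimConfig()
        self.dag = dag
        self.corpus = corpus
        self.ic = ic if ic is not None else propagate_and_score(
            corpus, dag, self.config.namespace
        )
        self._term_cache: dict[tuple[str, str], float] = {}
        self._profile_cache: dict[str, WangProfile] = {}

    def _profile(self, t: str) -> WangProfile:
        prof = self._profile_cache.get(t)
        if prof is None:
            prof = wang_profile(t, self.dag, self.config.wang_weights)
            self._profile_cache[t] = prof
        return prof

    def term_sim(self, t1: str, t2: str) -> float:
        """Term-level similarity under the configured metric."""
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        cached = self._term_cache.get(key)
        if cached is not None:
            return cached
        cfg = self.config
        if cfg.metric == "resnik":
            val = sim_resnik(t1, t2, self.ic, self.dag, normalize=cfg.normalize_resnik)
        elif cfg.metric == "lin":
            val = sim_lin(t1, t2, self.ic, self.dag)
        elif cfg.metric == "jiang":
            val = sim_jiang(t1, t2, self.ic, self.dag, clamp=cfg.clamp_nonnegative)
        elif cfg.metric == "rel":
            val = sim_rel(t1, t2, self.ic, self.dag)
        elif cfg.metric == "wang":
            p1, p2 = self._profile(t1), self._profile(t2)
            shared = set(p1.svalues) & set(p2.svalues)
            val = sum(p1.svalues[u] + p2.svalues[u] for u in shared) / (p1.sv + p2.sv)
        else:  # pragma: no cover - guarded by SemSimConfig
            raise ConfigError(f"unknown metric {cfg.metric!r}")
        self._term_cache[key] = val
        return val

    def protein_sim(self, p1: str, p2: str) -> float:
        """Aggregate term-level similarity over two proteins' annotations.

        Uses the direct (unpropagated) annotation sets of the configured
        namespace.  If either protein is unannotated there, the pair's
        confidence is 0 — the behaviour that makes sparsely annotated
        namespaces filter aggressively.
        """
        ns = self.config.namespace
        terms1 = sorted(self.corpus.terms_of(p1, ns))
        terms2 = sorted(self.corpus.terms_of(p2, ns))
        if not terms1 or not terms2:
            return 0.0
        matrix = [[self.term_sim(a, b) for b in terms2] for a in terms1]
        if self.config.aggregation == "max":
            return max(max(row) for row in matrix)
        row_best = [max(row) for row in matrix]
        col_best = [max(matrix[i][j] for i in range(len(terms1))) for j in range(len(terms2))]
        return 0.5 * (
            sum(row_best) / len(row_best) + sum(col_best) / len(col_best)
        )


def protein_similarity(
    p1: str,
    p2: str,
    corpus: AnnotationCorpus,
    dag: GoDag,
    config: SemSimConfig | None = None,
    ic: ICTable | None = None,
) -> float:
    """One-shot protein-pair confidence score (see :class:`SemanticSimilarity`)."""
    return SemanticSimilarity(dag, corpus, config, ic=ic).protein_sim(p1, p2)
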