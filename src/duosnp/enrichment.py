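"""Hypergeometric GO-term over-representation with Bonferroni adjustment.

Given a study set of genes (e.g. the unigenes of one SNP category) and a
gene-to-term annotation map whose annotated genes form the background
universe, each term is tested with the upper tail of the hypergeometric
distribution: the probability of drawing at least k term-annotated genes in
a study sample of size n from a universe of N genes of which K carry the
term.  Raw p-values are Bonferroni-adjusted over the number of terms
actually tested (terms present in the study set — configurable to all
annotated terms), and a term is enriched when the adjusted p falls below
alpha (default 0.01).

No ontology-graph propagation is performed; annotations are taken as given.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Sequence, Set

from scipy import stats as sps


@dataclass
class AnnotationMap:
    """Bidirectional gene/term annotation views over an annotated universe."""

    gene2terms: Dict[str, Set[str]]
    term2genes: Dict[str, Set[str]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.term2genes:
            for gene, terms in self.gene2terms.items():
                for term in terms:
                    self.term2genes.setdefault(term, set()).add(gene)
        else:
            # check mutual consistency of the supplied views
            derived: Dict[str, Set[str]] = {}
            for gene, terms in self.gene2terms.items():
                for term in terms:
                    derived.setdefault(term, set()).add(gene)
            if derived != self.term2genes:
                raise ValueError("gene->terms and term->genes views disagree")

    @property
    def universe(self) -> Set[str]:
        """The annotated background gene set."""
        return set(self.gene2terms)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple]) -> "AnnotationMap":
        g2t: Dict[str, Set[str]] = {}
        for gene, term in pairs:
            g2t.setdefault(gene, set()).add(term)
        return cls(gene2terms=g2t)


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # study genes carrying the term
    n: int  # study genes in the universe
    K: int  # background genes carrying the term
    N: int  # universe size
    p_raw: float
    p_adj: float
    enriched: bool


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    k successes observed among n draws, without replacement, from a
    population of N containing K successes.  Returns a probability in
    (0, 1]; k = 0 gives exactly 1.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValueError(
            f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def enrich(
    study_set: Iterable[str],
    annotation: AnnotationMap,
    alpha: float = 0.01,
    tested_terms: str = "study",
) -> list:
    """Test every candidate term for over-representation in the study set.

    ``tested_terms`` selects the Bonferroni family: ``"study"`` (default)
    counts only terms with at least one study gene, ``"all"`` counts every
    annotated term.  Results are sorted by adjusted p, ties broken by term
    id.  An empty study-universe intersection yields an empty list.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    universe = annotation.universe
    study = set(study_set) & universe
    n, N = len(study), len(universe)
    if n == 0:
        import logging
        logging.getLogger(__name__).warning(
            "study set has no overlap with the annotated universe")
        return []
    counts = {}
    for term, genes in annotation.term2genes.items():
        k = len(genes & study)
        if k >= 1 or tested_terms == "all":
            counts[term] = (k, len(genes))
    m = len(counts) if tested_terms == "all" else sum(
        1 for k, _ in counts.values() if k >= 1)
    results = []
    for term, (k, K) in counts.items():
        p_raw = hypergeom_upper_tail(k, K, n, N)
        p_adj = min(1.0, p_raw * m)
        results.append(EnrichmentResult(
            term=term, k=k, n=n, K=K, N=N,
            p_raw=p_raw, p_adj=p_adj, enriched=p_adj < alpha))
    results.sort(key=lambda r: (r.p_adj, r.p_raw, r.term))
    return results
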