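"""Module co-similarity: Jaccard on genes, Cohen's kappa on enriched terms.

Two modules are compositionally similar when their gene sets share members
(Jaccard index) and functionally similar when their enriched-annotation
profiles agree (Cohen's kappa over a common term universe).  Pairs passing
both thresholds become edges of the module meta-network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

from scipy.stats import linregress

from gilnet.enrichment import EnrichedTerm
from gilnet.link_communities import LinkCommunityModule

__all__ = [
    "ModulePairScore",
    "MetaNetwork",
    "jaccard",
    "kappa",
    "pairwise_scores",
    "similarity_correlation",
    "build_meta_network",
]


@dataclass
class ModulePairScore:
    module_a: str
    module_b: str
    jaccard: float
    kappa: float | None  # None when either module has no enriched terms
    same_gil: bool


@dataclass
class MetaNetwork:
    """Module-level network: nodes are modules, edges are similar pairs."""

    edges: list[ModulePairScore] = field(default_factory=list)
    kappa_min: float = 0.5
    jaccard_min: float = 0.3

    @property
    def nodes(self) -> set[str]:
        return {m for e in self.edges for m in (e.module_a, e.module_b)}

    def summary(self) -> dict:
        n_edges = len(self.edges)
        same = sum(1 for e in self.edges if e.same_gil)
        return {
            "nodes": len(self.nodes),
            "edges": n_edges,
            "same_gil_edges": same,
            "cross_gil_edges": n_edges - same,
            "same_gil_percent": round(100 * same / n_edges) if n_edges else 0,
        }


def jaccard(a: set, b: set) -> float:
    """|a & b| / |a | b| — 0 for disjoint sets, 1 for identical ones."""
    if not a or not b:
        raise ValueError("Jaccard index of an empty set is undefined")
    return len(a & b) / len(a | b)


def kappa(terms_a: set, terms_b: set, universe: set) -> float:
    """Cohen's kappa of two binary term-presence vectors over a universe.

    P_o is the fraction of terms on which the modules agree (both present
    or both absent), P_e the agreement expected from the marginal
    frequencies; kappa = (P_o - P_e) / (1 - P_e), defined as 1 when the
    vectors are identical and P_e = 1.
    """
    if len(universe) < 2:
        raise ValueError("term universe must contain at least 2 terms")
    if not terms_a <= universe or not terms_b <= universe:
        raise ValueError("term sets must be subsets of the universe")
    N = len(universe)
    n11 = len(terms_a & terms_b)
    n10 = len(terms_a - terms_b)
    n01 = len(terms_b - terms_a)
    n00 = N - n11 - n10 - n01
    p_o = (n11 + n00) / N
    p_e = ((n11 + n10) * (n11 + n01) + (n01 + n00) * (n10 + n00)) / N**2
    if p_e == 1.0:
        return 1.0 if terms_a == terms_b else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def pairwise_scores(
    modules: list[LinkCommunityModule],
    enriched: dict[str, list[EnrichedTerm]],
    size_min: int = 30,
    universe: set | None = None,
) -> list[ModulePairScore]:
    """All unordered pair scores among modules with >= ``size_min`` genes.

    Kappa is computed on enriched-term sets only; the default term
    universe is the union of terms enriched in at least one module of the
    collection (so kappa is comparable across pairs).  Modules with no
    enriched terms get kappa None and are excluded from kappa-based edges
    downstream but keep their Jaccard score.
    """
    qualifying = [m for m in modules if m.size >= size_min]
    if len(qualifying) < 2:
        warnings.warn("fewer than 2 modules meet the size threshold", stacklevel=2)
        return []
    term_sets = {
        m.module_name: {t.term_id for t in enriched.get(m.module_name, [])}
        for m in qualifying
    }
    if universe is None:
        universe = set()
        for terms in enriched.values():
            universe |= {t.term_id for t in terms}
    scores = []
    for a, b in combinations(qualifying, 2):
        ta, tb = term_sets[a.module_name], term_sets[b.module_name]
        if ta and tb and len(universe) >= 2:
            k = kappa(ta, tb, universe | ta | tb)
        else:
            k = None
        scores.append(
            ModulePairScore(
                a.module_name,
                b.module_name,
                jaccard(a.genes, b.genes),
                k,
                a.gil_id == b.gil_id,
            )
        )
    return scores


def similarity_correlation(scores: list[ModulePairScore]) -> tuple[float, float]:
    """OLS of Jaccard on kappa over pairs with defined kappa: (R^2, slope p)."""
    pts = [(s.kappa, s.jaccard) for s in scores if s.kappa is not None]
    if len(pts) < 3:
        raise ValueError("need at least 3 pairs with defined kappa")
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    if max(xs) == min(xs):
        raise ValueError("kappa has zero variance; correlation undefined")
    fit = linregress(xs, ys)
    return float(fit.rvalue**2), float(fit.pvalue)


def build_meta_network(
    scores: list[ModulePairScore], kappa_min: float = 0.5, jaccard_min: float = 0.3
) -> MetaNetwork:
    """Keep pairs with kappa >= kappa_min AND Jaccard >= jaccard_min (inclusive)."""
    edges = [
        s
        for s in scores
        if s.kappa is not None and s.kappa >= kappa_min and s.jaccard >= jaccard_min
    ]
    return MetaNetwork(edges, kappa_min, jaccard_min)
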