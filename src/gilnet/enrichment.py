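"""Fisher's exact over-representation of annotation terms in module gene sets.

Each (module, term) pair is scored with a one-sided Fisher exact test of
the 2x2 table (in module / not) x (has term / not) over a gene background;
terms with raw p below the cutoff (default 0.01) are reported.  A
Benjamini-Hochberg column is emitted for information but the cutoff is on
the raw p, matching the classical DAVID-style procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom

__all__ = ["AnnotationTable", "EnrichedTerm", "fisher_enrichment", "load_annotations"]

TERM_SOURCES = ("GO", "InterPro", "KEGG", "phenotype")


@dataclass
class AnnotationTable:
    """Flat gene -> term annotations from GO / InterPro / KEGG / phenotype sources."""

    genes_by_term: dict[str, set[str]]
    term_source: dict[str, str] = field(default_factory=dict)
    term_label: dict[str, str] = field(default_factory=dict)

    def annotated_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.genes_by_term.values():
            out |= genes
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AnnotationTable":
        genes_by_term: dict[str, set[str]] = {}
        source: dict[str, str] = {}
        label: dict[str, str] = {}
        for row in df.itertuples(index=False):
            genes_by_term.setdefault(row.term_id, set()).add(row.gene_id)
            if hasattr(row, "source"):
                source[row.term_id] = row.source
            if hasattr(row, "label"):
                label[row.term_id] = row.label
        return cls(genes_by_term, source, label)


def load_annotations(path) -> AnnotationTable:
    """Read an annotation TSV with columns gene_id, term_id[, source, label]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "term_id"} <= set(df.columns):
        raise ValueError("annotation table needs columns gene_id and term_id")
    return AnnotationTable.from_frame(df)


@dataclass
class EnrichedTerm:
    """One over-represented term in one module."""

    module_name: str
    term_id: str
    k: int  # module genes with the term
    n: int  # module size
    K: int  # background genes with the term
    N: int  # background size
    p: float
    source: str = ""
    label: str = ""
    bh_q: float | None = None

    def __post_init__(self) -> None:
        if self.k > min(self.n, self.K):
            raise ValueError("inconsistent contingency counts")


def fisher_enrichment(
    module_genes: set[str],
    ann: AnnotationTable,
    background: set[str],
    alpha: float = 0.01,
    module_name: str = "",
) -> list[EnrichedTerm]:
    """One-sided Fisher enrichment of every term hit by the module.

    The p-value for a term with K annotated background genes, module size
    n over background N and k in-module hits is the hypergeometric upper
    tail P(X >= k).  Terms with p < ``alpha`` are returned sorted by
    ascending p (ties by term id).
    """
    offenders = module_genes - background
    if offenders:
        raise ValueError(f"module genes absent from background: {sorted(offenders)[:5]}")
    if not background:
        raise ValueError("empty background")
    N = len(background)
    n = len(module_genes)
    scored: list[EnrichedTerm] = []
    for term_id, term_genes in ann.genes_by_term.items():
        bg_term = term_genes & background
        k = len(term_genes & module_genes)
        if k == 0:
            continue
        K = len(bg_term)
        p = float(hypergeom.sf(k - 1, N, K, n))
        scored.append(
            EnrichedTerm(
                module_name,
                term_id,
                k,
                n,
                K,
                N,
                min(p, 1.0),
                source=ann.term_source.get(term_id, ""),
                label=ann.term_label.get(term_id, ""),
            )
        )
    scored.sort(key=lambda t: (t.p, t.term_id))
    # BH across all scored terms of this module; informational only
    m = len(scored)
    running_min = 1.0
    for rank in range(m, 0, -1):
        t = scored[rank - 1]
        running_min = min(running_min, t.p * m / rank)
        t.bh_q = min(running_min, 1.0)
    return [t for t in scored if t.p < alpha]
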