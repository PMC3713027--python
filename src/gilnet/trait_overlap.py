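"""Genetic-feature integration: QTL/GWAS intervals, module-trait overlap.

QTLs and GWAS SNP linkage windows are mapped to genomic intervals
(1-based, inclusive), genes overlapping a feature inherit its trait, each
module is scored against each trait with a one-sided Fisher exact test
over a gene background, edges are highlighted by how many distinct
features their endpoints hit, and known SNPs near trait-overlapping
module genes are nominated as candidate biomarkers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pyranges as pr
from scipy.stats import hypergeom

from gilnet.link_communities import LinkCommunityModule

__all__ = [
    "GeneLocus",
    "GeneticFeature",
    "TraitOverlapResult",
    "read_gene_loci",
    "prepare_features",
    "assign_genes_to_features",
    "module_trait_fisher",
    "filter_edges_by_trait",
    "biomarker_snps",
]


@dataclass
class GeneLocus:
    """A gene's genomic interval, 1-based inclusive."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")


@dataclass
class GeneticFeature:
    """A trait-tagged genomic interval: a QTL or a SNP LD window."""

    feature_id: str
    type: str  # QTL | GWAS_SNP
    trait: str
    label: str  # genetic map or study label
    chromosome: str
    start: int
    end: int
    p: float | None = None  # source p-value for GWAS SNPs

    def __post_init__(self) -> None:
        if self.type not in ("QTL", "GWAS_SNP"):
            raise ValueError(f"unknown feature type {self.type!r}")
        if self.start > self.end:
            raise ValueError(f"{self.feature_id}: start > end")


@dataclass
class TraitOverlapResult:
    """Module x trait contingency with Fisher p and the features hit."""

    module_name: str
    trait: str
    feature_types: tuple
    overlapping_genes: dict[str, set[str]]  # gene -> distinct feature ids hit
    a: int  # module genes overlapping the trait
    b: int  # module genes not overlapping
    c: int  # background (non-module) genes overlapping
    d: int  # remaining background genes
    p: float
    features_hit: set[str] = field(default_factory=set)


def read_gene_loci(path) -> list[GeneLocus]:
    """Read gene coordinates from GFF3 (gene features) or BED.

    BED (0-based half-open) is converted to 1-based inclusive on read.
    """
    path = str(path)
    if path.endswith((".bed", ".bed.txt")):
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        return [
            GeneLocus(str(r[3]), str(r[0]), int(r[1]) + 1, int(r[2]),
                      str(r[5]) if len(r) > 5 else "+")
            for r in df.itertuples(index=False)
        ]
    gr = pr.read_gff3(path).df
    genes = gr[gr["Feature"] == "gene"] if "Feature" in gr else gr
    out = []
    for row in genes.itertuples(index=False):
        gene_id = getattr(row, "ID", None) or getattr(row, "gene_id", None)
        out.append(
            GeneLocus(str(gene_id), str(row.Chromosome), int(row.Start) + 1,
                      int(row.End), str(getattr(row, "Strand", "+")))
        )
    return out


def _clamp(start: int, end: int, chrom_len: int, rec: str) -> tuple[int, int]:
    length = end - start
    if start < 1:
        start, end = 1, min(chrom_len, 1 + length)
    if end > chrom_len:
        end = chrom_len
        start = max(1, end - length)
    return start, end


def prepare_features(
    qtls: pd.DataFrame,
    snps: pd.DataFrame,
    genome: dict[str, int],
    qtl_enlarge_below: int = 5,
    qtl_enlarged_size: int = 2_000_000,
    snp_window: int = 300_000,
    snp_p_max: float = 1e-4,
    *,
    snp_window_per_side: bool = False,
) -> list[GeneticFeature]:
    """Turn QTL and GWAS SNP tables into trait-tagged intervals.

    QTLs shorter than ``qtl_enlarge_below`` bp (single-marker placements)
    are replaced by a ``qtl_enlarged_size`` interval centred on the
    original midpoint and clamped to the chromosome.  SNPs with
    p <= ``snp_p_max`` become their LD window: total span ``snp_window``
    centred on the position (or +/- ``snp_window`` per side with
    ``snp_window_per_side``); other SNPs are dropped.

    ``qtls`` columns: feature_id (optional), trait, map_label (optional),
    chrom, start, end.  ``snps`` columns: snp_id, trait, chrom, pos, p.
    """
    features: list[GeneticFeature] = []
    clamped = 0
    for i, row in enumerate(qtls.itertuples(index=False)):
        chrom = str(row.chrom)
        if chrom not in genome:
            raise ValueError(f"QTL record {getattr(row, 'feature_id', i)!r}: unknown chromosome {chrom!r}")
        start, end = int(row.start), int(row.end)
        if end - start + 1 < qtl_enlarge_below:
            mid = (start + end) // 2
            start = mid - qtl_enlarged_size // 2 + 1
            end = mid + qtl_enlarged_size // 2
        new = _clamp(start, end, genome[chrom], str(i))
        clamped += new != (start, end)
        start, end = new
        features.append(
            GeneticFeature(
                str(getattr(row, "feature_id", f"QTL{i:05d}")),
                "QTL",
                str(row.trait),
                str(getattr(row, "map_label", "")),
                chrom,
                start,
                end,
            )
        )
    for i, row in enumerate(snps.itertuples(index=False)):
        p = float(row.p)
        if p > snp_p_max:
            continue
        chrom = str(row.chrom)
        if chrom not in genome:
            raise ValueError(f"SNP record {row.snp_id!r}: unknown chromosome {chrom!r}")
        pos = int(row.pos)
        if snp_window_per_side:
            start, end = pos - snp_window, pos + snp_window
        else:
            start, end = pos - snp_window // 2 + 1, pos + snp_window // 2
        new = _clamp(start, end, genome[chrom], str(row.snp_id))
        clamped += new != (start, end)
        start, end = new
        features.append(
            GeneticFeature(str(row.snp_id), "GWAS_SNP", str(row.trait),
                           str(getattr(row, "label", "")), chrom, start, end, p)
        )
    if clamped:
        warnings.warn(f"{clamped} feature intervals clamped to chromosome bounds", stacklevel=2)
    return features


def assign_genes_to_features(
    genes: list[GeneLocus], features: list[GeneticFeature]
) -> pd.DataFrame:
    """Assign traits to genes by >= 1 bp interval overlap.

    Returns one row per overlapping (gene, feature) pair with columns
    gene_id, trait, feature_id, type.
    """
    empty = pd.DataFrame(columns=["gene_id", "trait", "feature_id", "type"])
    if not genes or not features:
        return empty
    gene_gr = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": [g.chromosome for g in genes],
                "Start": [g.start - 1 for g in genes],  # to 0-based half-open
                "End": [g.end for g in genes],
                "gene_id": [g.gene_id for g in genes],
            }
        )
    )
    feat_gr = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": [f.chromosome for f in features],
                "Start": [f.start - 1 for f in features],
                "End": [f.end for f in features],
                "feature_id": [f.feature_id for f in features],
                "trait": [f.trait for f in features],
                "type": [f.type for f in features],
            }
        )
    )
    joined = gene_gr.join(feat_gr).df
    if joined.empty:
        return empty
    out = joined[["gene_id", "trait", "feature_id", "type"]].reset_index(drop=True)
    return out.sort_values(["gene_id", "feature_id"]).reset_index(drop=True)


def _overlapping_genes(
    genes: set[str],
    trait: str,
    assignments: pd.DataFrame,
    feature_types: tuple,
    min_features: int,
) -> dict[str, set[str]]:
    sub = assignments[
        (assignments["trait"] == trait) & assignments["type"].isin(feature_types)
    ]
    hits: dict[str, set[str]] = {}
    for gene, feat in zip(sub["gene_id"], sub["feature_id"]):
        if gene in genes:
            hits.setdefault(gene, set()).add(feat)
    return {g: f for g, f in hits.items() if len(f) >= min_features}


def module_trait_fisher(
    module: LinkCommunityModule,
    trait: str,
    assignments: pd.DataFrame,
    background: set[str],
    feature_types: tuple = ("QTL", "GWAS_SNP"),
    min_features: int = 1,
) -> TraitOverlapResult:
    """One-sided Fisher test of module genes against trait-overlapping genes.

    A gene "overlaps" the trait when it is assigned at least
    ``min_features`` distinct features of the allowed types.  The 2x2
    table crosses module membership with trait overlap over the
    background gene set; p is the hypergeometric upper tail.
    """
    offenders = module.genes - background
    if offenders:
        raise ValueError(f"module genes absent from background: {sorted(offenders)[:5]}")
    if trait not in set(assignments["trait"]):
        warnings.warn(f"trait {trait!r} has no gene assignments", stacklevel=2)
    module_hits = _overlapping_genes(module.genes, trait, assignments, feature_types, min_features)
    bg_hits = _overlapping_genes(background, trait, assignments, feature_types, min_features)
    a = len(module_hits)
    b = module.size - a
    K = len(bg_hits)
    c = K - a
    N = len(background)
    d = N - a - b - c
    p = 1.0 if a == 0 else float(min(hypergeom.sf(a - 1, N, K, a + b), 1.0))
    features_hit = set()
    for f in module_hits.values():
        features_hit |= f
    return TraitOverlapResult(
        module.module_name, trait, feature_types, module_hits, a, b, c, d, p, features_hit
    )


def filter_edges_by_trait(
    module: LinkCommunityModule,
    trait: str,
    assignments: pd.DataFrame,
    feature_types: tuple = ("QTL", "GWAS_SNP"),
    min_features: int = 1,
) -> tuple[list, list]:
    """Partition module edges into (highlighted, other).

    An edge is highlighted when the union of its two endpoints' assigned
    features for the trait contains >= ``min_features`` distinct features
    — the red-arc rule of the genome view.
    """
    hits = _overlapping_genes(module.genes, trait, assignments, feature_types, 1)
    highlighted, other = [], []
    for edge in module.edges:
        a, b = edge
        union = hits.get(a, set()) | hits.get(b, set())
        (highlighted if len(union) >= min_features else other).append(edge)
    return highlighted, other


def biomarker_snps(
    module: LinkCommunityModule,
    trait: str,
    assignments: pd.DataFrame,
    snp_positions: pd.DataFrame,
    genes: list[GeneLocus],
    window: int = 50_000,
    feature_types: tuple = ("QTL", "GWAS_SNP"),
) -> pd.DataFrame:
    """Known SNPs within ``window`` bp of any trait-overlapping module gene.

    ``snp_positions`` columns: snp_id, chrom, pos.  Distance is 0 for a
    SNP inside the gene interval.  The result is deduplicated and sorted
    by chromosome then position.
    """
    if snp_positions["snp_id"].duplicated().any():
        raise ValueError("snp_positions must have unique snp ids")
    hits = _overlapping_genes(module.genes, trait, assignments, feature_types, 1)
    loci = [g for g in genes if g.gene_id in hits]
    keep_rows = []
    for chrom, group in snp_positions.groupby("chrom"):
        spans = [(g.start, g.end) for g in loci if g.chromosome == str(chrom)]
        if not spans:
            continue
        pos = group["pos"].to_numpy()
        mask = np.zeros(len(pos), dtype=bool)
        for start, end in spans:
            mask |= (pos >= start - window) & (pos <= end + window)
        keep_rows.append(group[mask])
    if not keep_rows:
        return snp_positions.iloc[0:0]
    out = pd.concat(keep_rows).drop_duplicates("snp_id")
    return out.sort_values(["chrom", "pos"]).reset_index(drop=True)
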