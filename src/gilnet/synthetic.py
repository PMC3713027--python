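"""Deterministic synthetic fixtures: compendia, toy genomes, annotations.

The generator emulates the study design the pipeline targets: a sample
compendium composed of condition groups, each with its own planted
co-expression modules (a gene correlates with its module partners only in
its home group, so an un-partitioned analysis dilutes the signal), and a
toy genome in which selected planted modules are congruent with planted
trait intervals while other features fall at random.

All randomness descends from one root seed through named
``numpy.random.SeedSequence`` children, so each stage is independently
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gilnet.enrichment import AnnotationTable
from gilnet.expression_io import ExpressionMatrix, ProbeGeneMap
from gilnet.link_communities import LinkCommunityModule
from gilnet.rmt_network import GILNetwork
from gilnet.trait_overlap import GeneLocus

__all__ = [
    "CompendiumTruth",
    "GenomeTruth",
    "GenomeData",
    "generate_compendium",
    "add_probe_artifacts",
    "generate_genome",
    "generate_annotations",
    "evaluate_recovery",
    "count_planted_edges",
]


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Counter-split generator: one root seed, a stable key per stage."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


@dataclass
class CompendiumTruth:
    """Ground truth of a generated compendium."""

    sample_group: dict[str, int]  # sample id -> condition group
    module_genes: dict[tuple[int, int], list[str]]  # (group, module idx) -> genes
    loading: float
    noise_sd: float
    rho: float
    seed: int

    def groups(self) -> list[int]:
        return sorted({g for g, _ in self.module_genes})

    def planted_pairs(self, group: int | None = None) -> set[tuple[str, str]]:
        """All within-module unordered gene pairs (optionally one group's)."""
        pairs: set[tuple[str, str]] = set()
        for (g, _), genes in self.module_genes.items():
            if group is not None and g != group:
                continue
            for i in range(len(genes)):
                for j in range(i + 1, len(genes)):
                    a, b = sorted((genes[i], genes[j]))
                    pairs.add((a, b))
        return pairs


@dataclass
class GenomeTruth:
    """Ground truth of a generated toy genome."""

    gene_loci: list[GeneLocus]
    targeted: dict[str, tuple[int, int]]  # trait -> (group, module idx) it covers
    random_traits: list[str]
    marker_ids: list[str]
    seed: int


def generate_compendium(
    n_groups: int = 4,
    samples_per_group: int = 40,
    n_genes: int = 800,
    modules_per_group: int = 5,
    module_size: int = 25,
    rho: float = 0.95,
    noise_sd: float = 0.1,
    seed: int = 0,
    group_effect_sd: float = 1.0,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.0,
    shared_modules: int = 2,
) -> tuple[ExpressionMatrix, CompendiumTruth]:
    """Simulate a log2-intensity compendium with group-specific modules.

    Within a gene's home group, module genes follow a single latent
    factor per module: value = baseline + loading*z(sample) + noise, with
    loading chosen so the expected pairwise Pearson correlation is
    ``rho`` (loading^2 / (loading^2 + noise_sd^2) = rho).  Outside the
    home group — and for non-module genes everywhere — values are
    independent noise around the gene's baseline plus a per-(group, gene)
    condition offset that separates the groups.

    The first ``shared_modules`` modules of every group reuse the same
    gene sets (with group-independent latent factors), emulating the
    recurrence of co-expression modules across condition groups; the
    remaining modules are group-private.  Modules within a group are
    always disjoint.
    """
    if modules_per_group * module_size > n_genes:
        raise ValueError("modules do not fit: modules_per_group * module_size > n_genes")
    if not 0.0 < rho < 1.0:
        raise ValueError("rho must be in (0, 1)")
    shared_modules = min(shared_modules, modules_per_group)
    loading = noise_sd * math.sqrt(rho / (1.0 - rho))
    gene_ids = [f"GENE{i:04d}" for i in range(n_genes)]
    sample_ids = [
        f"S{g:02d}_{s:03d}" for g in range(n_groups) for s in range(samples_per_group)
    ]
    n_samples = n_groups * samples_per_group

    baseline = baseline_mean + baseline_sd * _rng(seed, 0).standard_normal(n_genes)
    group_shift = group_effect_sd * _rng(seed, 1).standard_normal((n_groups, n_genes))
    shared_idx = _rng(seed, 3).choice(
        n_genes, size=shared_modules * module_size, replace=False
    )
    values = np.empty((n_samples, n_genes))
    module_genes: dict[tuple[int, int], list[str]] = {}
    sample_group: dict[str, int] = {}
    for g in range(n_groups):
        row_idx = np.arange(g * samples_per_group, (g + 1) * samples_per_group)
        rng_g = _rng(seed, 2, g)
        noise = noise_sd * rng_g.standard_normal((samples_per_group, n_genes))
        values[row_idx] = baseline[None, :] + group_shift[g][None, :] + noise
        n_private = modules_per_group - shared_modules
        pool = np.setdiff1d(np.arange(n_genes), shared_idx)
        # draw each group's private modules from its own slice of the pool
        # when it fits, so private modules are disjoint across groups too
        need = n_private * module_size
        if need * n_groups <= len(pool):
            pool = pool[g * (len(pool) // n_groups) : (g + 1) * (len(pool) // n_groups)]
        chosen = rng_g.choice(pool, size=need, replace=False)
        for j in range(modules_per_group):
            if j < shared_modules:
                idx = shared_idx[j * module_size : (j + 1) * module_size]
            else:
                jp = j - shared_modules
                idx = chosen[jp * module_size : (jp + 1) * module_size]
            module_genes[(g, j)] = sorted(gene_ids[i] for i in idx)
            z = rng_g.standard_normal(samples_per_group)
            values[np.ix_(row_idx, idx)] += loading * z[:, None]
        for s in range(samples_per_group):
            sample_group[sample_ids[g * samples_per_group + s]] = g
    matrix = ExpressionMatrix(sample_ids, list(gene_ids), values)
    truth = CompendiumTruth(sample_group, module_genes, loading, noise_sd, rho, seed)
    return matrix, truth


def add_probe_artifacts(
    m: ExpressionMatrix,
    n_ambiguous: int = 0,
    n_control: int = 0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ProbeGeneMap]:
    """Re-label columns as probesets and plant ambiguous/control probes.

    Every original column becomes a single-locus probe ``<gene>_at``.
    ``n_ambiguous`` extra probes each map to two loci and ``n_control``
    probes get the AFFX prefix; both carry independent noise so the
    filtering step has real columns to drop.
    """
    rng = _rng(seed, 10)
    probe_ids = [f"{g}_at" for g in m.probe_ids]
    mapping = {p: [g] for p, g in zip(probe_ids, m.probe_ids)}
    extra_cols = []
    genes = list(m.probe_ids)
    for i in range(n_ambiguous):
        pid = f"AMBIG{i:04d}_s_at"
        pair = rng.choice(len(genes), size=2, replace=False)
        mapping[pid] = [genes[pair[0]], genes[pair[1]]]
        probe_ids.append(pid)
        extra_cols.append(8.0 + rng.standard_normal(m.n_samples))
    for i in range(n_control):
        pid = f"AFFX-CTRL{i:04d}_at"
        mapping[pid] = []
        probe_ids.append(pid)
        extra_cols.append(6.0 + rng.standard_normal(m.n_samples))
    values = m.values if not extra_cols else np.column_stack([m.values] + extra_cols)
    return (
        ExpressionMatrix(list(m.sample_ids), probe_ids, values, dict(m.metadata)),
        ProbeGeneMap(mapping),
    )


@dataclass
class GenomeData:
    """In-memory toy genome plus writers for the standard on-disk formats."""

    genes: list[GeneLocus]
    qtl_table: pd.DataFrame  # trait, map_label, chrom, start, end
    gwas_table: pd.DataFrame  # snp_id, trait, chrom, pos, p
    markers: pd.DataFrame  # snp_id, chrom, pos
    chrom_sizes: dict[str, int]
    truth: GenomeTruth = field(repr=False, default=None)

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes_gff3": outdir / "genes.gff3",
            "qtl_tsv": outdir / "qtl.tsv",
            "gwas_tsv": outdir / "gwas_snps.tsv",
            "markers_vcf": outdir / "markers.vcf",
        }
        with open(paths["genes_gff3"], "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom, size in self.chrom_sizes.items():
                fh.write(f"##sequence-region {chrom} 1 {size}\n")
            for g in sorted(self.genes, key=lambda x: (x.chromosome, x.start)):
                fh.write(
                    f"{g.chromosome}\tgilnet\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}\n"
                )
        self.qtl_table.to_csv(paths["qtl_tsv"], sep="\t", index=False)
        self.gwas_table.to_csv(paths["gwas_tsv"], sep="\t", index=False)
        with open(paths["markers_vcf"], "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for chrom, size in self.chrom_sizes.items():
                fh.write(f"##contig=<ID={chrom},length={size}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for row in self.markers.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.pos}\t{row.snp_id}\tA\tG\t.\tPASS\t.\n")
        return paths


def generate_genome(
    truth: CompendiumTruth,
    chrom_count: int = 4,
    chrom_len: int = 3_000_000,
    targeted_modules: list[tuple[int, int]] | None = None,
    n_random_features: int = 20,
    n_snp_markers: int = 500,
    seed: int = 0,
    gene_length: int = 2_000,
    random_feature_len: int = 150_000,
) -> tuple[GenomeData, GenomeTruth]:
    """Place genes on a toy genome and plant trait features.

    Genes occupy evenly spaced non-overlapping slots; each targeted
    planted module gets a contiguous run of slots on one chromosome with
    a QTL spanning the run (covering 100% of the module's genes) and two
    significant GWAS SNPs inside it.  ``n_random_features`` additional
    QTLs with unrelated traits are placed uniformly at random.
    """
    rng = _rng(seed, 20)
    gene_ids = sorted({g for genes in truth.module_genes.values() for g in genes})
    all_genes = sorted(
        {f"GENE{i:04d}" for i in range(_infer_n_genes(truth))} | set(gene_ids)
    )
    n_genes = len(all_genes)
    per_chrom = math.ceil(n_genes / chrom_count)
    spacing = chrom_len // (per_chrom + 1)
    if spacing <= gene_length:
        raise ValueError("genes do not fit on the chromosomes without overlap")
    chroms = [f"chr{c + 1}" for c in range(chrom_count)]
    slots = [
        (chroms[c], s)
        for c in range(chrom_count)
        for s in range(per_chrom)
        if c * per_chrom + s < n_genes
    ]

    if targeted_modules is None:
        # default: one group-private module per group (the last one; lower
        # indices may hold gene sets shared across groups)
        last = max(j for _, j in truth.module_genes)
        targeted_modules = [(g, last) for g in truth.groups()]
    seen_sets: list[set] = []
    for key in targeted_modules:
        genes = set(truth.module_genes[key])
        if any(genes & s for s in seen_sets):
            raise ValueError("targeted modules must have disjoint gene sets")
        seen_sets.append(genes)
    # reserve one contiguous run of slots per targeted module
    assignment: dict[str, tuple[str, int]] = {}
    used: set[tuple[str, int]] = set()
    targeted_runs: dict[tuple[int, int], list[tuple[str, int]]] = {}
    slot_set = set(slots)
    for t, key in enumerate(targeted_modules):
        genes = truth.module_genes[key]
        chrom = chroms[t % chrom_count]
        run_starts = [
            s
            for s in range(per_chrom - len(genes) + 1)
            if all(
                (chrom, s + i) not in used and (chrom, s + i) in slot_set
                for i in range(len(genes))
            )
        ]
        start = int(rng.choice(run_starts))
        run = [(chrom, start + i) for i in range(len(genes))]
        used |= set(run)
        targeted_runs[key] = run
        for gene, slot in zip(rng.permutation(genes), run):
            assignment[gene] = slot
    free_slots = [s for s in slots if s not in used]
    remaining = [g for g in all_genes if g not in assignment]
    for gene, slot in zip(remaining, rng.permutation(np.arange(len(free_slots)))):
        assignment[gene] = free_slots[slot]

    loci = []
    for gene, (chrom, s) in assignment.items():
        start = (s + 1) * spacing
        loci.append(GeneLocus(gene, chrom, start, start + gene_length - 1))
    loci.sort(key=lambda g: (g.chromosome, g.start))

    qtl_rows, gwas_rows, targeted = [], [], {}
    for key, run in targeted_runs.items():
        trait = f"planted_trait_g{key[0]}m{key[1]}"
        targeted[trait] = key
        chrom = run[0][0]
        lo = (run[0][1] + 1) * spacing
        hi = (run[-1][1] + 1) * spacing + gene_length - 1
        qtl_rows.append((trait, "planted_map", chrom, lo, hi))
        for frac in (1.0 / 3.0, 2.0 / 3.0):
            pos = int(lo + frac * (hi - lo))
            gwas_rows.append((f"gwas_{trait}_{len(gwas_rows)}", trait, chrom, pos, 1e-6))
    random_traits = []
    for i in range(n_random_features):
        trait = f"random_trait_{i:03d}"
        random_traits.append(trait)
        chrom = chroms[int(rng.integers(chrom_count))]
        start = int(rng.integers(1, chrom_len - random_feature_len))
        qtl_rows.append((trait, "random_map", chrom, start, start + random_feature_len - 1))

    marker_pos = np.sort(rng.integers(1, chrom_len, size=n_snp_markers))
    marker_chrom = rng.integers(chrom_count, size=n_snp_markers)
    markers = pd.DataFrame(
        {
            "snp_id": [f"marker{i:05d}" for i in range(n_snp_markers)],
            "chrom": [chroms[c] for c in marker_chrom],
            "pos": marker_pos,
        }
    ).sort_values(["chrom", "pos"]).reset_index(drop=True)

    qtl_table = pd.DataFrame(qtl_rows, columns=["trait", "map_label", "chrom", "start", "end"])
    gwas_table = pd.DataFrame(gwas_rows, columns=["snp_id", "trait", "chrom", "pos", "p"])
    genome_truth = GenomeTruth(loci, targeted, random_traits, list(markers["snp_id"]), seed)
    data = GenomeData(loci, qtl_table, gwas_table, markers,
                      {c: chrom_len for c in chroms}, genome_truth)
    return data, genome_truth


def _infer_n_genes(truth: CompendiumTruth) -> int:
    top = max(int(g[4:]) for genes in truth.module_genes.values() for g in genes)
    return top + 1


def generate_annotations(
    truth: CompendiumTruth,
    coverage: float = 0.8,
    n_background_terms: int = 20,
    genes_per_background_term: int = 30,
    seed: int = 0,
) -> AnnotationTable:
    """Annotation table with one term per planted module plus noise terms.

    Each planted module's term annotates ``coverage`` of its genes plus a
    few random bystanders; background terms annotate random gene sets.
    """
    rng = _rng(seed, 30)
    all_genes = [f"GENE{i:04d}" for i in range(_infer_n_genes(truth))]
    genes_by_term: dict[str, set[str]] = {}
    source: dict[str, str] = {}
    for (g, j), genes in sorted(truth.module_genes.items()):
        term = f"TERM:G{g}M{j}"
        n_hit = max(2, int(round(coverage * len(genes))))
        hit = set(rng.choice(genes, size=n_hit, replace=False))
        hit |= set(rng.choice(all_genes, size=3, replace=False))
        genes_by_term[term] = hit
        source[term] = "GO"
    for i in range(n_background_terms):
        term = f"TERM:BG{i:03d}"
        genes_by_term[term] = set(
            rng.choice(all_genes, size=genes_per_background_term, replace=False)
        )
        source[term] = "GO"
    return AnnotationTable(genes_by_term, source)


def evaluate_recovery(
    discovered: list[LinkCommunityModule],
    truth: CompendiumTruth,
    group_to_gil: dict[int, str] | None = None,
) -> dict:
    """Best-match Jaccard between each planted module and discovered modules.

    With ``group_to_gil`` the search is restricted to the GIL built from
    the planted module's home group; otherwise all discovered modules are
    candidates.  Returns per-planted-module scores and their mean.
    """
    per_module = {}
    for key, genes in sorted(truth.module_genes.items()):
        planted = set(genes)
        candidates = discovered
        if group_to_gil is not None:
            gil = group_to_gil.get(key[0])
            candidates = [m for m in discovered if m.gil_id == gil]
        best = 0.0
        for mod in candidates:
            j = len(planted & mod.genes) / len(planted | mod.genes)
            best = max(best, j)
        per_module["g{}m{}".format(*key)] = best
    mean = sum(per_module.values()) / len(per_module) if per_module else 0.0
    return {"per_module": per_module, "mean_best_jaccard": mean}


def count_planted_edges(networks: list[GILNetwork], truth: CompendiumTruth) -> int:
    """Distinct planted within-module gene pairs present in any network."""
    planted = truth.planted_pairs()
    found: set[tuple[str, str]] = set()
    for net in networks:
        found |= net.edge_set & planted
    return len(found)
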