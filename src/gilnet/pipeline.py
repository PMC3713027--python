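"""End-to-end orchestration: preprocess -> cluster -> per-group GILs ->
modules -> enrichment -> similarity -> traits -> collection summary.

Per-group failures (too few arrays, no RMT threshold) are recorded as
rows of the collection summary without aborting the other groups, so the
summary table mirrors a mixed collection of constructed and failed
networks.
"""

from __future__ import annotations

import dataclasses
import json
import statistics
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from gilnet import (
    enrichment as enr,
    expression_io as eio,
    link_communities as lc,
    module_similarity as msim,
    rmt_network as rmt,
    sample_clustering as sc,
    trait_overlap as tov,
)

__all__ = ["RunConfig", "RunResult", "gil_id_for_cluster", "run_from_objects",
           "run_pipeline", "summarize_collection"]


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run (serialized with the outputs)."""

    # inputs (optional for in-memory runs)
    matrix: str | None = None
    probe_map: str | None = None
    genes_gff3: str | None = None
    qtl: str | None = None
    gwas: str | None = None
    annotations: str | None = None
    out_dir: str | None = None
    # stage parameters
    seed: int = 0
    k: int | str = "auto"
    restarts: int = 10
    min_arrays: int = 25
    control_prefix: str = "AFFX"
    log2: bool = False
    t_start: float = 0.5
    t_step: float = 0.01
    refine_step: float = 0.001
    rmt_p: float = 0.001
    min_eigenvalues: int = 100
    min_module_edges: int = 2
    collection_tag: str = "SYNv1.0"
    enrichment_alpha: float = 0.01
    size_min: int = 30
    kappa_min: float = 0.5
    jaccard_min: float = 0.3
    qtl_enlarge_below: int = 5
    qtl_enlarged_size: int = 2_000_000
    snp_window: int = 300_000
    snp_p_max: float = 1e-4
    biomarker_window: int = 50_000

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**yaml.safe_load(text))


@dataclass
class RunResult:
    """All in-memory products of one pipeline run."""

    config: RunConfig
    qc: eio.QCReport
    assignment: sc.ClusterAssignment
    manifest: sc.GroupManifest
    networks: dict[str, rmt.GILNetwork] = field(default_factory=dict)
    scans: dict[str, rmt.RMTScanResult] = field(default_factory=dict)
    modules: list[lc.LinkCommunityModule] = field(default_factory=list)
    table: pd.DataFrame | None = None  # per-GIL collection summary
    enriched: dict[str, list[enr.EnrichedTerm]] = field(default_factory=dict)
    scores: list[msim.ModulePairScore] = field(default_factory=list)
    meta: msim.MetaNetwork | None = None
    correlation: tuple[float, float] | None = None  # (R^2, p) of J ~ kappa
    assignments: pd.DataFrame | None = None  # gene-trait table
    trait_results: list[tov.TraitOverlapResult] = field(default_factory=list)

    def modules_by_gil(self) -> dict[str, list[lc.LinkCommunityModule]]:
        out: dict[str, list[lc.LinkCommunityModule]] = {}
        for m in self.modules:
            out.setdefault(m.gil_id, []).append(m)
        return out


def gil_id_for_cluster(cluster: int) -> str:
    """GILs are numbered G0001.. by ascending cluster index, failures included."""
    return f"G{cluster + 1:04d}"


def _preprocess(matrix, probe_map, config) -> tuple[eio.ExpressionMatrix, eio.QCReport]:
    m, report = eio.filter_probesets(matrix, probe_map, (config.control_prefix,))
    if m.n_samples >= 4:
        outliers = eio.detect_outlier_samples(m)
        report.outlier_samples = outliers.outlier_samples
        report.outlier_flags = outliers.outlier_flags
        m = eio.remove_samples(m, outliers.outlier_samples)
    m = eio.quantile_normalize(m)
    return m, report


def run_from_objects(
    matrix: eio.ExpressionMatrix,
    probe_map: eio.ProbeGeneMap,
    config: RunConfig | None = None,
    genes: list[tov.GeneLocus] | None = None,
    qtl_table: pd.DataFrame | None = None,
    gwas_table: pd.DataFrame | None = None,
    chrom_sizes: dict[str, int] | None = None,
    annotations: enr.AnnotationTable | None = None,
) -> RunResult:
    """Run the full pipeline on in-memory inputs."""
    config = config or RunConfig()
    pre, qc = _preprocess(matrix, probe_map, config)
    k = sc.rule_of_thumb_k(pre.n_samples) if config.k == "auto" else int(config.k)
    assignment = sc.kmeans_cluster(pre, k, seed=config.seed, restarts=config.restarts)
    _, manifest = sc.partition_compendium(pre, assignment, min_size=config.min_arrays)
    result = RunResult(config, qc, assignment, manifest)

    rows = []
    for cluster in range(k):
        gil_id = gil_id_for_cluster(cluster)
        info = manifest.groups[cluster]
        n_input = len(info["members"])
        row = {
            "gil_id": gil_id, "input_arrays": n_input, "outlier_arrays": 0,
            "edges": None, "nodes": None, "threshold": None, "avg_degree": None,
            "modules": None, "status": None,
        }
        if info["status"] == "too_few_arrays":
            row["status"] = "failed: too few arrays"
            rows.append(row)
            continue
        group = pre.subset_samples(info["members"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            group = eio.quantile_normalize(group)
            if group.n_samples >= 4:
                out = eio.detect_outlier_samples(group)
                row["outlier_arrays"] = len(out.outlier_samples)
                group = eio.remove_samples(group, out.outlier_samples)
            sim = rmt.correlation_matrix(group)
            scan = rmt.find_rmt_threshold(
                sim, config.t_start, config.t_step, config.refine_step, config.rmt_p,
                min_eigenvalues=config.min_eigenvalues,
            )
            result.scans[gil_id] = scan
            if not scan.success:
                row["status"] = (
                    "failed: RMT could not find threshold"
                    if scan.failure == "no_threshold_found"
                    else "failed: too few genes for RMT"
                )
                rows.append(row)
                continue
            net = rmt.build_network(sim, scan.threshold, probe_map, gil_id)
        net.sample_ids = list(group.sample_ids)
        result.networks[gil_id] = net
        modules = lc.detect_link_communities(net, min_edges=config.min_module_edges)
        named = lc.name_modules(config.collection_tag, gil_id, modules)
        result.modules.extend(named)
        summary = rmt.network_summary(net)
        row.update(
            edges=summary["edges"], nodes=summary["nodes"],
            threshold=scan.threshold, avg_degree=summary["avg_degree"],
            modules=len(named), status="constructed",
        )
        rows.append(row)
    result.table = pd.DataFrame(rows)

    if annotations is not None and result.modules:
        background = annotations.annotated_genes()
        for mod in result.modules:
            mod_bg = mod.genes & background
            if len(mod_bg) < 1:
                result.enriched[mod.module_name] = []
                continue
            result.enriched[mod.module_name] = enr.fisher_enrichment(
                mod_bg, annotations, background, config.enrichment_alpha, mod.module_name
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result.scores = msim.pairwise_scores(
                result.modules, result.enriched, size_min=config.size_min
            )
        if result.scores:
            try:
                result.correlation = msim.similarity_correlation(result.scores)
            except ValueError:
                result.correlation = None
            result.meta = msim.build_meta_network(
                result.scores, config.kappa_min, config.jaccard_min
            )

    if genes is not None and chrom_sizes is not None and result.modules:
        qtl_table = qtl_table if qtl_table is not None else pd.DataFrame(
            columns=["trait", "map_label", "chrom", "start", "end"])
        gwas_table = gwas_table if gwas_table is not None else pd.DataFrame(
            columns=["snp_id", "trait", "chrom", "pos", "p"])
        features = tov.prepare_features(
            qtl_table, gwas_table, chrom_sizes,
            config.qtl_enlarge_below, config.qtl_enlarged_size,
            config.snp_window, config.snp_p_max,
        )
        result.assignments = tov.assign_genes_to_features(genes, features)
        background = set()
        for net in result.networks.values():
            background |= net.nodes
        traits = sorted(set(result.assignments["trait"]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for mod in result.modules:
                for trait in traits:
                    res = tov.module_trait_fisher(
                        mod, trait, result.assignments, background
                    )
                    if res.a > 0:
                        result.trait_results.append(res)
    return result


def run_pipeline(config: RunConfig) -> RunResult:
    """Run from files per config and write per-stage outputs to out_dir."""
    if config.matrix is None or config.probe_map is None:
        raise ValueError("config must provide matrix and probe_map paths")
    matrix = eio.load_expression_matrix(config.matrix, log2=config.log2)
    probe_map = eio.load_probe_gene_map(config.probe_map)
    genes = tov.read_gene_loci(config.genes_gff3) if config.genes_gff3 else None
    qtl = pd.read_csv(config.qtl, sep="\t") if config.qtl else None
    gwas = pd.read_csv(config.gwas, sep="\t") if config.gwas else None
    ann = enr.load_annotations(config.annotations) if config.annotations else None
    chrom_sizes = None
    if genes is not None:
        chrom_sizes = {}
        for g in genes:
            chrom_sizes[g.chromosome] = max(chrom_sizes.get(g.chromosome, 0), g.end + 5_000_000)
    result = run_from_objects(matrix, probe_map, config, genes, qtl, gwas, chrom_sizes, ann)
    if config.out_dir:
        write_outputs(result, config.out_dir)
    return result


def write_outputs(result: RunResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yml").write_text(result.config.to_yaml())
    (out / "qc_report.json").write_text(result.qc.to_json())
    (out / "manifest.json").write_text(result.manifest.to_json())
    result.table.to_csv(out / "summary.tsv", sep="\t", index=False)
    for gil_id, net in sorted(result.networks.items()):
        net.write_edge_tsv(out / f"{gil_id}_edges.tsv")
    for gil_id, scan in sorted(result.scans.items()):
        pd.DataFrame(scan.scan).to_csv(out / f"{gil_id}_rmt_scan.tsv", sep="\t", index=False)
    with open(out / "modules.tsv", "w") as fh:
        fh.write("module_name\tgene_id\n")
        for mod in result.modules:
            for gene in sorted(mod.genes):
                fh.write(f"{mod.module_name}\t{gene}\n")
    if result.enriched:
        rows = [
            {
                "module_name": t.module_name, "term_id": t.term_id, "source": t.source,
                "k": t.k, "n": t.n, "K": t.K, "N": t.N, "p": t.p, "bh_q": t.bh_q,
            }
            for terms in result.enriched.values()
            for t in terms
        ]
        pd.DataFrame(rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)
    if result.scores:
        pd.DataFrame(
            [
                {
                    "module_a": s.module_a, "module_b": s.module_b,
                    "jaccard": s.jaccard, "kappa": s.kappa, "same_gil": s.same_gil,
                }
                for s in result.scores
            ]
        ).to_csv(out / "module_scores.tsv", sep="\t", index=False)
    if result.trait_results:
        pd.DataFrame(
            [
                {
                    "module_name": r.module_name, "trait": r.trait,
                    "a": r.a, "b": r.b, "c": r.c, "d": r.d, "p": r.p,
                    "features_hit": len(r.features_hit),
                }
                for r in result.trait_results
            ]
        ).to_csv(out / "trait_overlap.tsv", sep="\t", index=False)
    summary = summarize_collection(result)
    (out / "collection_summary.json").write_text(json.dumps(summary, indent=2))


def _median(values: list[float]) -> float:
    """Midpoint-of-sorted-values median."""
    return float(statistics.median(sorted(values)))


def summarize_collection(run: "RunResult | str | Path") -> dict:
    """Collection-wide arithmetic: module and input-array means/medians,
    node/edge redundancy fractions.

    Means are reported to 1 decimal; medians are the midpoint of the
    sorted values; fractions whole percents.  Accepts a RunResult or a
    run directory containing summary.tsv.
    """
    if isinstance(run, pd.DataFrame):
        table = run
        networks = {}
    elif isinstance(run, (str, Path)):
        table = pd.read_csv(Path(run) / "summary.tsv", sep="\t")
        networks = {}
    else:
        table = run.table
        networks = run.networks
    if table is None or table.empty:
        raise ValueError("empty run: nothing to summarize")
    built = table[table["status"] == "constructed"]
    out = {
        "n_groups": int(len(table)),
        "n_constructed": int(len(built)),
        "n_failed": int(len(table) - len(built)),
        "total_edges": int(built["edges"].sum()) if len(built) else 0,
        "total_modules": int(built["modules"].sum()) if len(built) else 0,
        "mean_modules_per_gil": round(float(built["modules"].mean()), 1) if len(built) else None,
        "median_modules_per_gil": _median(list(built["modules"])) if len(built) else None,
        "mean_input_arrays": round(float(table["input_arrays"].mean()), 1),
        "median_input_arrays": _median(list(table["input_arrays"])),
    }
    if networks:
        out["redundancy"] = rmt.collection_summary(list(networks.values()))
    return out
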