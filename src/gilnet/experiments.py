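"""Seeded validation experiments used by the test suite and the
acceptance script: statistical calibration of the RMT criterion, planted
module recovery, null calibration of the trait test, and the dilution
comparison between a pooled network and the per-group collection.
"""

from __future__ import annotations

import warnings
from collections import Counter

import numpy as np
import pandas as pd

from gilnet import pipeline as pl
from gilnet import rmt_network as rmt
from gilnet import synthetic as syn
from gilnet import trait_overlap as tov
from gilnet.expression_io import quantile_normalize
from gilnet.link_communities import LinkCommunityModule
from gilnet.rmt_network import (
    _poisson_chi_square,
    nnsd_chi_square,
    nnsd_critical_value,
)

__all__ = [
    "rmt_spacing_calibration",
    "planted_block_scan",
    "null_trait_calibration",
    "end_to_end_recovery",
    "dilution_experiment",
]


def rmt_spacing_calibration(
    seed: int = 0, n_replicates: int = 100, n_spacings: int = 2000, goe_size: int = 500
) -> dict:
    """Acceptance/rejection rates of the NNSD Poisson test on known inputs.

    Poisson-side: iid Exponential(1) spacings must be accepted; GOE-side:
    eigenvalues of a dense Gaussian orthogonal ensemble matrix show level
    repulsion and must be rejected.
    """
    crit = nnsd_critical_value()
    accept = reject = 0
    for i in range(n_replicates):
        rng = np.random.default_rng((seed * 100_003 + i) % 2**31)
        spacings = rng.exponential(1.0, n_spacings)
        if _poisson_chi_square(spacings / spacings.mean()) <= crit:
            accept += 1
        A = rng.standard_normal((goe_size, goe_size))
        if nnsd_chi_square(np.linalg.eigvalsh((A + A.T) / np.sqrt(2.0))) > crit:
            reject += 1
    return {
        "exponential_accept_rate": accept / n_replicates,
        "goe_reject_rate": reject / n_replicates,
        "n_replicates": n_replicates,
    }


def planted_block_scan(
    seed: int = 0,
    n_blocks: int = 20,
    block_size: int = 30,
    n_samples: int = 25,
    n_noise_genes: int = 200,
    rho: float = 0.95,
) -> dict:
    """Threshold scan on a block-structured correlation matrix.

    ``n_blocks`` latent-factor blocks with within-block correlation ~ rho
    sit among ``n_noise_genes`` uncorrelated genes whose sample
    correlations supply the random background the RMT criterion needs at
    the scan start (with no random component the matrix is modular from
    the first candidate).  The scan should land strictly between the
    start of the grid and rho, and the resulting network should keep
    nearly all within-block pairs as edges.
    """
    m, truth = syn.generate_compendium(
        n_groups=1,
        samples_per_group=n_samples,
        n_genes=n_blocks * block_size + n_noise_genes,
        modules_per_group=n_blocks,
        module_size=block_size,
        rho=rho,
        seed=seed,
        shared_modules=0,
    )
    sim = rmt.correlation_matrix(m)
    scan = rmt.find_rmt_threshold(sim)
    out = {"threshold": scan.threshold, "failure": scan.failure,
           "edge_recall": 0.0, "n_planted_pairs": len(truth.planted_pairs())}
    if scan.success:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = rmt.build_network(sim, scan.threshold, None, "BLOCK")
        planted = truth.planted_pairs()
        out["edge_recall"] = len(net.edge_set & planted) / len(planted)
    return out


def _chain_modules(truth: syn.CompendiumTruth) -> list[LinkCommunityModule]:
    """Planted gene sets as modules (chain edges; only gene sets matter here)."""
    mods = []
    for (g, j), genes in sorted(truth.module_genes.items()):
        edges = [tuple(sorted((genes[i], genes[i + 1]))) for i in range(len(genes) - 1)]
        mods.append(LinkCommunityModule(f"planted_g{g}m{j}", edges, f"G{g + 1:04d}"))
    return mods


def null_trait_calibration(seed: int = 0, n_replicates: int = 200) -> dict:
    """Type-I calibration of the module-trait Fisher test.

    Genes are placed on the toy genome with no planted congruence; each
    replicate scatters 5-15 random 150-kb features and scores every
    planted module against the resulting trait assignment.  The fraction
    of (module, replicate) tests with p < 0.05 estimates the empirical
    size of the nominal-0.05 test (slightly conservative, as exact tests
    on discrete tables are).
    """
    m, truth = syn.generate_compendium(seed=seed)
    genome, _ = syn.generate_genome(truth, seed=seed, targeted_modules=[], n_random_features=0)
    background = {g.gene_id for g in genome.genes}
    modules = _chain_modules(truth)
    chrom_sizes = genome.chrom_sizes
    empty_snps = pd.DataFrame(columns=["snp_id", "trait", "chrom", "pos", "p"])
    n_sig = n_tot = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_replicates):
            rng = np.random.default_rng((seed * 100_019 + i) % 2**31)
            rows = []
            for _ in range(int(rng.integers(5, 16))):
                chrom = f"chr{1 + rng.integers(len(chrom_sizes))}"
                start = int(rng.integers(1, chrom_sizes[chrom] - 150_000))
                rows.append(("nulltrait", "m", chrom, start, start + 150_000 - 1))
            qtl = pd.DataFrame(rows, columns=["trait", "map_label", "chrom", "start", "end"])
            features = tov.prepare_features(qtl, empty_snps, chrom_sizes)
            assignments = tov.assign_genes_to_features(genome.genes, features)
            for mod in modules:
                res = tov.module_trait_fisher(mod, "nulltrait", assignments, background)
                n_sig += res.p < 0.05
                n_tot += 1
    return {"fraction_significant": n_sig / n_tot, "n_tests": n_tot}


def match_groups_to_gils(truth: syn.CompendiumTruth, result: pl.RunResult) -> dict[int, str]:
    """Planted group -> GIL id, by majority vote over sample membership."""
    out = {}
    for g in truth.groups():
        samples = [s for s, grp in truth.sample_group.items() if grp == g]
        votes = Counter(
            result.assignment.assignment[s]
            for s in samples
            if s in result.assignment.assignment
        )
        out[g] = pl.gil_id_for_cluster(votes.most_common(1)[0][0])
    return out


def end_to_end_recovery(seed: int = 0) -> dict:
    """Full pipeline on the default fixture; recovery + trait congruence.

    The compendium has 4 condition groups x 40 samples, 800 genes, 5
    planted modules of 25 genes per group at rho = 0.95; k is set to the
    known group count (the run validates recovery, not model selection).
    The threshold scan starts at 0.45: at this fixture's noise level the
    GOE-to-Poisson transition lies near |r| = 0.5, and the scan must
    begin inside the random phase for the transition to be observable.
    Reports the mean best-match Jaccard between planted and discovered
    modules, whether each planted-trait module attains the smallest
    module-trait p in its GIL, and collection/meta summaries.
    """
    m, truth = syn.generate_compendium(seed=seed)
    probes, probe_map = syn.add_probe_artifacts(m, n_ambiguous=20, n_control=5, seed=seed)
    genome, genome_truth = syn.generate_genome(truth, seed=seed)
    annotations = syn.generate_annotations(truth, seed=seed)
    config = pl.RunConfig(seed=seed, k=len(truth.groups()), size_min=20, t_start=0.45)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = pl.run_from_objects(
            probes, probe_map, config, genome.genes, genome.qtl_table,
            genome.gwas_table, genome.chrom_sizes, annotations,
        )
    group_to_gil = match_groups_to_gils(truth, result)
    recovery = syn.evaluate_recovery(result.modules, truth, group_to_gil)

    planted_top = {}
    planted_p = {}
    for trait, (g, j) in sorted(genome_truth.targeted.items()):
        gil = group_to_gil[g]
        in_gil = [
            r for r in result.trait_results
            if r.trait == trait and r.module_name.split("_")[1] == gil
        ]
        if not in_gil:
            planted_top[trait] = False
            continue
        best = min(in_gil, key=lambda r: r.p)
        planted_genes = set(truth.module_genes[(g, j)])
        best_mod = next(mm for mm in result.modules if mm.module_name == best.module_name)
        overlap = len(planted_genes & best_mod.genes) / len(planted_genes | best_mod.genes)
        planted_top[trait] = overlap >= 0.5
        planted_p[trait] = best.p
    n_built = int((result.table["status"] == "constructed").sum())
    return {
        "result": result,
        "truth": truth,
        "group_to_gil": group_to_gil,
        "mean_best_jaccard": recovery["mean_best_jaccard"],
        "per_module_jaccard": recovery["per_module"],
        "planted_trait_is_top": planted_top,
        "planted_trait_p": planted_p,
        "n_constructed": n_built,
        "n_groups": int(len(result.table)),
    }


def dilution_experiment(seed: int = 0, n_seeds: int = 10) -> dict:
    """Pooled-versus-partitioned recovery of planted co-expression pairs.

    For each replicate the per-group networks' union of planted
    within-module pairs is compared with the single network built from
    the un-partitioned compendium: pooling across conditions dilutes
    group-specific correlation, so the global network recovers fewer
    planted pairs.  Both arms use the same scan configuration (start
    0.45, inside the fixture's random phase; see end_to_end_recovery).
    """
    t_start = 0.45
    per_seed = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_seeds):
            s = (seed * 7919 + i) % 2**31
            m, truth = syn.generate_compendium(seed=s)
            union_nets = []
            for g in truth.groups():
                members = [x for x, grp in truth.sample_group.items() if grp == g]
                sub = quantile_normalize(m.subset_samples(members))
                sim = rmt.correlation_matrix(sub)
                scan = rmt.find_rmt_threshold(sim, t_start=t_start)
                if scan.success:
                    union_nets.append(rmt.build_network(sim, scan.threshold, None, f"G{g}"))
            union_count = syn.count_planted_edges(union_nets, truth)
            gsim = rmt.correlation_matrix(quantile_normalize(m))
            gscan = rmt.find_rmt_threshold(gsim, t_start=t_start)
            global_count = 0
            if gscan.success:
                gnet = rmt.build_network(gsim, gscan.threshold, None, "GLOBAL")
                global_count = syn.count_planted_edges([gnet], truth)
            per_seed.append({"union": union_count, "global": global_count})
    return {
        "per_seed": per_seed,
        "all_strictly_fewer": all(d["global"] < d["union"] for d in per_seed),
    }
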