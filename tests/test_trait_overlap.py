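from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from gilnet import synthetic as syn
from gilnet.link_communities import LinkCommunityModule
from gilnet.trait_overlap import (
    GeneLocus,
    assign_genes_to_features,
    biomarker_snps,
    filter_edges_by_trait,
    module_trait_fisher,
    prepare_features,
)

GENOME = {"chr1": 20_000_000, "chr2": 20_000_000}
EMPTY_SNPS = pd.DataFrame(columns=["snp_id", "trait", "chrom", "pos", "p"])
EMPTY_QTL = pd.DataFrame(columns=["trait", "map_label", "chrom", "start", "end"])


def qtl_frame(rows):
    return pd.DataFrame(rows, columns=["trait", "map_label", "chrom", "start", "end"])


def snp_frame(rows):
    return pd.DataFrame(rows, columns=["snp_id", "trait", "chrom", "pos", "p"])


class TestPrepareFeatures:
    def test_tiny_qtl_enlarged_to_2mb_centred(self):
        qtl = qtl_frame([("t", "m", "chr1", 4_999_999, 5_000_001)])  # 3 bp, mid 5 Mb
        (feat,) = prepare_features(qtl, EMPTY_SNPS, GENOME)
        assert (feat.start, feat.end) == (4_000_001, 6_000_000)
        assert feat.end - feat.start + 1 == 2_000_000

    def test_large_qtl_unchanged(self):
        qtl = qtl_frame([("t", "m", "chr1", 1_000_000, 6_000_000)])
        (feat,) = prepare_features(qtl, EMPTY_SNPS, GENOME)
        assert (feat.start, feat.end) == (1_000_000, 6_000_000)

    def test_snp_window_total_span_300kb(self):
        snps = snp_frame([("s1", "t", "chr1", 1_000_000, 1e-6)])
        (feat,) = prepare_features(EMPTY_QTL, snps, GENOME)
        assert (feat.start, feat.end) == (850_001, 1_150_000)
        assert feat.end - feat.start + 1 == 300_000

    def test_insignificant_snp_dropped(self):
        snps = snp_frame([("s1", "t", "chr1", 1_000_000, 0.5)])
        assert prepare_features(EMPTY_QTL, snps, GENOME) == []

    def test_unknown_chromosome_names_record(self):
        snps = snp_frame([("sBAD", "t", "chrX", 100, 1e-6)])
        with pytest.raises(ValueError, match="sBAD"):
            prepare_features(EMPTY_QTL, snps, GENOME)

    def test_enlargement_clamped_at_chromosome_start(self):
        qtl = qtl_frame([("t", "m", "chr1", 100, 101)])
        with pytest.warns(UserWarning, match="clamped"):
            (feat,) = prepare_features(qtl, EMPTY_SNPS, GENOME)
        assert feat.start == 1
        assert feat.end - feat.start + 1 == 2_000_000


class TestAssignment:
    def _features(self, start, end):
        qtl = qtl_frame([("trait1", "m", "chr1", start, end)])
        return prepare_features(qtl, EMPTY_SNPS, GENOME, qtl_enlarge_below=0)

    def test_one_bp_overlap_is_assigned(self):
        genes = [GeneLocus("g1", "chr1", 100, 200)]
        out = assign_genes_to_features(genes, self._features(200, 300))
        assert list(out["gene_id"]) == ["g1"]

    def test_adjacent_but_disjoint_not_assigned(self):
        genes = [GeneLocus("g1", "chr1", 100, 200)]
        out = assign_genes_to_features(genes, self._features(201, 300))
        assert out.empty

    def test_swapping_roles_gives_same_pairs(self):
        rng = np.random.default_rng(0)
        genes = [
            GeneLocus(f"g{i}", "chr1", int(s), int(s) + 500)
            for i, s in enumerate(rng.integers(1, 100_000, 30))
        ]
        starts = rng.integers(1, 100_000, 10)
        feats = prepare_features(
            qtl_frame([("t", "m", "chr1", int(s), int(s) + 800) for s in starts]),
            EMPTY_SNPS, GENOME, qtl_enlarge_below=0,
        )
        out = assign_genes_to_features(genes, feats)
        # role-swapped: treat features as "genes" and genes as "features"
        swapped_genes = [GeneLocus(f.feature_id, f.chromosome, f.start, f.end) for f in feats]
        swapped_feats = prepare_features(
            qtl_frame([("t", "m", g.chromosome, g.start, g.end) for g in genes]),
            EMPTY_SNPS, GENOME, qtl_enlarge_below=0,
        )
        out2 = assign_genes_to_features(swapped_genes, swapped_feats)
        pairs = {(g, f) for g, f in zip(out["gene_id"], out["feature_id"])}
        idx = {f"QTL{i:05d}": g.gene_id for i, g in enumerate(genes)}
        pairs2 = {(idx[f], g) for g, f in zip(out2["gene_id"], out2["feature_id"])}
        assert pairs == pairs2

    def test_planted_qtl_covers_its_module(self, default_fixture):
        _, truth = default_fixture
        genome, gtruth = syn.generate_genome(truth, seed=11)
        feats = prepare_features(genome.qtl_table, genome.gwas_table, genome.chrom_sizes)
        out = assign_genes_to_features(genome.genes, feats)
        for trait, key in gtruth.targeted.items():
            assigned = set(out[out["trait"] == trait]["gene_id"])
            planted = set(truth.module_genes[key])
            assert len(planted & assigned) / len(planted) >= 0.8


def hypergeom_tail(k, N, K, n):
    total = Fraction(0)
    for x in range(k, min(n, K) + 1):
        total += Fraction(comb(K, x) * comb(N - K, n - x), comb(N, n))
    return float(total)


def chain_module(name, genes, gil="G0001"):
    gene_list = sorted(genes)
    edges = [tuple(sorted((gene_list[i], gene_list[i + 1]))) for i in range(len(gene_list) - 1)]
    return LinkCommunityModule(name, edges, gil)


def assignment_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "trait", "feature_id", "type"])


class TestModuleTraitFisher:
    def test_no_overlap_gives_p_one(self):
        mod = chain_module("m", {"g1", "g2", "g3"})
        asn = assignment_frame([("x1", "t", "q1", "QTL")])
        res = module_trait_fisher(mod, "t", asn, {"g1", "g2", "g3", "x1"})
        assert res.a == 0 and res.p == 1.0

    def test_matches_direct_tail_sum(self):
        background = {f"g{i}" for i in range(1000)}
        trait_genes = [f"g{i}" for i in range(30)]
        module_genes = {f"g{i}" for i in range(10)} | {f"g{i}" for i in range(500, 515)}
        mod = chain_module("m", module_genes)
        asn = assignment_frame([(g, "t", "q1", "QTL") for g in trait_genes])
        res = module_trait_fisher(mod, "t", asn, background)
        assert (res.a, res.a + res.b) == (10, 25)
        assert res.p == pytest.approx(hypergeom_tail(10, 1000, 30, 25), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_fixtures_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(100, 2000))
        background = {f"g{i}" for i in range(N)}
        mod_genes = set(rng.choice(sorted(background), int(rng.integers(5, 40)), replace=False))
        trait_genes = set(rng.choice(sorted(background), int(rng.integers(10, N // 3)), replace=False))
        mod = chain_module("m", mod_genes)
        asn = assignment_frame([(g, "t", "q1", "QTL") for g in sorted(trait_genes)])
        res = module_trait_fisher(mod, "t", asn, background)
        k = len(mod_genes & trait_genes)
        expect = 1.0 if k == 0 else hypergeom_tail(k, N, len(trait_genes), len(mod_genes))
        assert res.p == pytest.approx(expect, abs=1e-12)

    def test_min_features_requires_distinct_features(self):
        mod = chain_module("m", {"g1", "g2"})
        asn = assignment_frame(
            [("g1", "t", "q1", "QTL"), ("g1", "t", "q2", "QTL"), ("g2", "t", "q1", "QTL")]
        )
        res = module_trait_fisher(mod, "t", asn, {"g1", "g2", "g3"}, min_features=2)
        assert res.a == 1  # only g1 hits two distinct features


class TestEdgeFilter:
    def _setup(self):
        mod = chain_module("m", {"a", "b", "c", "d"})
        asn = assignment_frame(
            [("a", "t", "q1", "QTL"), ("c", "t", "q2", "QTL"), ("c", "t", "q3", "QTL")]
        )
        return mod, asn

    def test_single_feature_highlights_edge(self):
        mod, asn = self._setup()
        hi, _ = filter_edges_by_trait(mod, "t", asn, min_features=1)
        assert ("a", "b") in hi

    def test_min_features_three_drops_edge(self):
        mod, asn = self._setup()
        hi, lo = filter_edges_by_trait(mod, "t", asn, min_features=3)
        assert ("a", "b") not in hi

    def test_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(15)]
        edges = set()
        while len(edges) < 20:
            a, b = rng.choice(15, 2, replace=False)
            edges.add(tuple(sorted((genes[a], genes[b]))))
        mod = LinkCommunityModule("m", sorted(edges), "G0001")
        rows = []
        for g in genes:
            for q in range(int(rng.integers(0, 4))):
                rows.append((g, "t", f"q{rng.integers(0, 6)}", "QTL"))
        asn = assignment_frame(sorted(set(rows)))
        for mf in (1, 2, 3):
            hi, lo = filter_edges_by_trait(mod, "t", asn, min_features=mf)
            feats = {}
            for g, _, f, _ in asn.itertuples(index=False):
                feats.setdefault(g, set()).add(f)
            expect = {e for e in mod.edges
                      if len(feats.get(e[0], set()) | feats.get(e[1], set())) >= mf}
            assert set(hi) == expect
            assert set(hi) | set(lo) == set(mod.edges)

    def test_monotone_in_min_features(self):
        mod, asn = self._setup()
        counts = [len(filter_edges_by_trait(mod, "t", asn, min_features=mf)[0])
                  for mf in (1, 2, 3, 4)]
        assert counts == sorted(counts, reverse=True)


class TestBiomarkers:
    def _setup(self):
        genes = [GeneLocus("gA", "chr1", 1_000_000, 1_002_000)]
        mod = chain_module("m", {"gA", "gB"})
        asn = assignment_frame([("gA", "t", "q1", "QTL")])
        return genes, mod, asn

    def test_boundary_inclusion(self):
        genes, mod, asn = self._setup()
        snps = pd.DataFrame(
            {"snp_id": ["near", "far"], "chrom": ["chr1", "chr1"],
             "pos": [1_000_000 - 49_999, 1_000_000 - 50_001]}
        )
        out = biomarker_snps(mod, "t", asn, snps, genes, window=50_000)
        assert list(out["snp_id"]) == ["near"]

    def test_snp_inside_gene_included(self):
        genes, mod, asn = self._setup()
        snps = pd.DataFrame({"snp_id": ["inside"], "chrom": ["chr1"], "pos": [1_001_000]})
        out = biomarker_snps(mod, "t", asn, snps, genes)
        assert list(out["snp_id"]) == ["inside"]

    def test_planted_markers_recovered_exactly(self):
        rng = np.random.default_rng(4)
        genes = [GeneLocus("gA", "chr1", 5_000_000, 5_002_000)]
        mod = chain_module("m", {"gA", "gB"})
        asn = assignment_frame([("gA", "t", "q1", "QTL")])
        pos = rng.integers(4_700_000, 5_300_000, 100)
        snps = pd.DataFrame(
            {"snp_id": [f"s{i}" for i in range(100)], "chrom": "chr1", "pos": pos}
        )
        out = biomarker_snps(mod, "t", asn, snps, genes, window=50_000)
        expect = {f"s{i}" for i, p in enumerate(pos)
                  if 5_000_000 - 50_000 <= p <= 5_002_000 + 50_000}
        assert set(out["snp_id"]) == expect

    def test_duplicate_snp_ids_rejected(self):
        genes, mod, asn = self._setup()
        snps = pd.DataFrame({"snp_id": ["s", "s"], "chrom": ["chr1", "chr1"],
                             "pos": [1, 2]})
        with pytest.raises(ValueError):
            biomarker_snps(mod, "t", asn, snps, genes)
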