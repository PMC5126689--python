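"""Nearest-gene pairing, orientation classification, co-expression contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lincsig.io_formats import ExpressionMatrix, GenomicFeature
from lincsig.neighbor_coexpr import (
    classify_orientation,
    fc_concordance,
    h2h_enrichment,
    nearest_coding_gene,
    neighbor_pairs,
    pair_nulls,
    pairwise_spearman,
)
from lincsig.synthdata import SimulationTruth, gen_annotation, gen_fpkm_cohort


def _feat(fid, start, end, strand, biotype="protein_coding", chrom="chr1"):
    return GenomicFeature(fid, chrom, start, end, strand, biotype)


class TestClassifyOrientation:
    def test_divergent_is_h2h(self):
        # linc on '-', gene on '+' to its right: 5' ends face across the gap
        linc = _feat("L", 1000, 2000, "-", "lincRNA")
        gene = _feat("G", 3000, 5000, "+")
        assert classify_orientation(linc, gene) == "H2H"

    def test_same_strand_is_h2t(self):
        assert classify_orientation(
            _feat("L", 1000, 2000, "+", "lincRNA"), _feat("G", 3000, 5000, "+")
        ) == "H2T"

    def test_convergent_is_t2t(self):
        # linc '+' left of gene '-': 3' ends adjacent
        linc = _feat("L", 1000, 2000, "+", "lincRNA")
        gene = _feat("G", 3000, 5000, "-")
        assert classify_orientation(linc, gene) == "T2T"

    def test_symmetric_under_swap_for_h2h_and_t2t(self):
        linc = _feat("L", 1000, 2000, "-", "lincRNA")
        gene = _feat("G", 3000, 5000, "+")
        assert classify_orientation(linc, gene) == classify_orientation(gene, linc)
        linc2 = _feat("L2", 1000, 2000, "+", "lincRNA")
        gene2 = _feat("G2", 3000, 5000, "-")
        assert classify_orientation(linc2, gene2) == classify_orientation(gene2, linc2)

    def test_invariant_under_reflection(self):
        """Mirroring the locus (reverse coordinates + flip both strands)
        preserves the orientation class; flipping strands alone exchanges
        divergent and convergent geometry."""
        flip = {"+": "-", "-": "+"}
        L = 10_000
        for s1 in "+-":
            for s2 in "+-":
                a = _feat("A", 1000, 2000, s1, "lincRNA")
                b = _feat("B", 3000, 5000, s2)
                ra = _feat("A", L - 2000, L - 1000, flip[s1], "lincRNA")
                rb = _feat("B", L - 5000, L - 3000, flip[s2])
                assert classify_orientation(a, b) == classify_orientation(ra, rb)
        # strand flip alone swaps H2H and T2T
        a = _feat("A", 1000, 2000, "-", "lincRNA")
        b = _feat("B", 3000, 5000, "+")
        fa = _feat("A", 1000, 2000, "+", "lincRNA")
        fb = _feat("B", 3000, 5000, "-")
        assert classify_orientation(a, b) == "H2H"
        assert classify_orientation(fa, fb) == "T2T"

    def test_different_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            classify_orientation(
                _feat("L", 0, 10, "+", "lincRNA"), _feat("G", 0, 10, "+", chrom="chr2")
            )


class TestNearestCodingGene:
    GENES = {
        "near": _feat("near", 10_000, 12_000, "+"),  # gap 1220 from linc end
        "far": _feat("far", 15_000, 20_000, "+"),
        "other_chrom": _feat("other_chrom", 0, 1000, "+", chrom="chr9"),
        "not_coding": GenomicFeature("not_coding", "chr1", 8_800, 8_900, "+", "lincRNA"),
    }
    LINC = _feat("L", 5_000, 8_780, "-", "lincRNA")

    def test_minimal_gap_chosen(self):
        pair = nearest_coding_gene(self.LINC, self.GENES)
        assert pair.gene_id == "near" and pair.distance == 1220

    def test_overlap_gives_distance_zero(self):
        genes = dict(self.GENES, overlapping=_feat("overlapping", 8_000, 9_000, "+"))
        pair = nearest_coding_gene(self.LINC, genes)
        assert pair.gene_id == "overlapping" and pair.distance == 0

    def test_equidistant_tie_lower_coordinate_flagged(self):
        linc = _feat("L", 10_000, 11_000, "+", "lincRNA")
        genes = {
            "left": _feat("left", 8_000, 9_500, "+"),
            "right": _feat("right", 11_500, 13_000, "+"),
        }
        pair = nearest_coding_gene(linc, genes)
        assert pair.gene_id == "left" and pair.ambiguous

    def test_no_gene_on_chromosome_warns_none(self):
        with pytest.warns(UserWarning):
            assert nearest_coding_gene(self.LINC, {"g": self.GENES["other_chrom"]}) is None

    def test_matches_bruteforce_min_scan(self):
        catalog, _ = gen_annotation(25, 40, seed=13)
        lincs = {f: g for f, g in catalog.items() if g.biotype == "lincRNA"}
        genes = {f: g for f, g in catalog.items() if g.biotype == "protein_coding"}
        for pair in neighbor_pairs(lincs, genes):
            linc = lincs[pair.linc_id]
            gaps = {
                gid: linc.gap_to(g)
                for gid, g in genes.items()
                if g.chrom == linc.chrom
            }
            assert pair.distance == min(gaps.values())
            assert gaps[pair.gene_id] == pair.distance

    def test_designated_partner_recovered_from_generator(self, small_annotation):
        catalog, truth_pairs = small_annotation
        lincs = {f: g for f, g in catalog.items() if g.biotype == "lincRNA"}
        genes = {f: g for f, g in catalog.items() if g.biotype == "protein_coding"}
        got = {p.linc_id: p.gene_id for p in neighbor_pairs(lincs, genes)}
        want = dict(zip(truth_pairs["linc_id"], truth_pairs["gene_id"]))
        assert got == want


class TestFCConcordance:
    def test_perfect_line_r2_one(self):
        x = np.array([1.0, -2.0, 0.5, 3.0])
        slope, r2, _ = fc_concordance(x, x)
        assert slope == pytest.approx(1.0) and r2 == pytest.approx(1.0)

    def test_null_r2_small(self):
        rng = np.random.default_rng(0)
        hits = 0
        for s in range(20):
            y = np.random.default_rng(s).normal(size=85)
            x = np.random.default_rng(100 + s).normal(size=85)
            _, r2, _ = fc_concordance(y, x)
            hits += r2 < 0.1
        assert hits >= 19  # ~95% of null fits explain <10% of variance

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fc_concordance([1.0, 2.0, 3.0], [0.5, 0.5, 0.5])


class TestPairNulls:
    def test_random_mode_exact_count_and_determinism(self, small_annotation):
        catalog, _ = small_annotation
        lincs = {f: g for f, g in catalog.items() if g.biotype == "lincRNA"}
        genes = {f: g for f, g in catalog.items() if g.biotype == "protein_coding"}
        a = pair_nulls(lincs, genes, "random", n_random=1000, seed=4)
        b = pair_nulls(lincs, genes, "random", n_random=1000, seed=4)
        assert len(a) == 1000 and a == b

    def test_non_neighbor_pairs_respect_gap(self, small_annotation):
        catalog, _ = small_annotation
        lincs = {f: g for f, g in catalog.items() if g.biotype == "lincRNA"}
        genes = {f: g for f, g in catalog.items() if g.biotype == "protein_coding"}
        pairs = pair_nulls(lincs, genes, "non_neighbor", seed=1)
        assert len(pairs) == len(lincs)
        for lid, gid in pairs:
            gap = lincs[lid].gap_to(genes[gid])
            assert gap is None or gap > 1_000_000

    def test_all_genes_nearby_warns_empty(self):
        lincs = {"L": _feat("L", 1000, 2000, "+", "lincRNA")}
        genes = {"G": _feat("G", 3000, 4000, "+")}
        with pytest.warns(UserWarning):
            assert pair_nulls(lincs, genes, "non_neighbor", seed=0) == []


class TestH2HEnrichment:
    def test_zero_hits_p_one(self):
        assert h2h_enrichment(0, 37, 0.3) == 1.0

    def test_all_hits_small_n_closed_form(self):
        assert h2h_enrichment(3, 3, 0.5) == pytest.approx(0.125)

    def test_cohort_scale_marginal_regime(self):
        # 14 H2H of 37 pairs against a 27% global rate: marginal significance
        p = h2h_enrichment(14, 37, 0.27)
        assert 0.01 < p < 0.2

    def test_matches_binomial_tail_sum(self):
        from math import comb

        k, n, p0 = 5, 12, 0.3
        tail = sum(comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(k, n + 1))
        assert h2h_enrichment(k, n, p0) == pytest.approx(tail)


class TestPairwiseSpearman:
    def _matrix(self, rows):
        df = pd.DataFrame(rows)
        df.columns = [f"s{i}" for i in range(df.shape[1])]
        return df

    def test_perfect_monotone(self):
        df = self._matrix({0: [1, 2, 3, 4, 5]}).T
        df = pd.DataFrame(
            [[1, 2, 3, 4, 5], [10, 20, 30, 40, 50]], index=["L", "G"],
            columns=[f"s{i}" for i in range(5)],
        )
        assert pairwise_spearman(df, [("L", "G")]).iloc[0] == pytest.approx(1.0)

    def test_exact_reversal(self):
        df = pd.DataFrame(
            [[1, 2, 3, 4, 5], [5, 4, 3, 2, 1]], index=["L", "G"],
            columns=[f"s{i}" for i in range(5)],
        )
        assert pairwise_spearman(df, [("L", "G")]).iloc[0] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        df = pd.DataFrame([x, y], index=["L", "G"], columns=[f"s{i}" for i in range(5)])
        rho = pairwise_spearman(df, [("L", "G")]).iloc[0]
        oracle = stats.pearsonr(stats.rankdata(x), stats.rankdata(y)).statistic
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_flagged_nan(self):
        df = pd.DataFrame(
            [[1, 1, 1, 1], [1, 2, 3, 4]], index=["L", "G"],
            columns=[f"s{i}" for i in range(4)],
        )
        assert np.isnan(pairwise_spearman(df, [("L", "G")]).iloc[0])


class TestPlantedCorrelationShift:
    def test_neighbor_rho_exceeds_random_pairs(self, small_annotation):
        """Planted shared-factor pairs separate cleanly from random pairs."""
        catalog, pairs = small_annotation
        h2h = pairs[pairs["orientation"] == "H2H"]
        truth = SimulationTruth(
            rho_pairs=list(zip(h2h["linc_id"], h2h["gene_id"])), neighbor_rho=0.6
        )
        matrix, sheet = gen_fpkm_cohort(catalog, 85, truth, seed=17)
        adjacent = sheet.samples_of("adjacent")
        rho_nb = pairwise_spearman(matrix, truth.rho_pairs, samples=adjacent)
        lincs = {f: g for f, g in catalog.items() if g.biotype == "lincRNA"}
        genes = {f: g for f, g in catalog.items() if g.biotype == "protein_coding"}
        rnd = pair_nulls(lincs, genes, "random", n_random=500, seed=3)
        rnd = [p for p in rnd if p not in set(truth.rho_pairs)]
        rho_rand = pairwise_spearman(matrix, rnd, samples=adjacent)
        assert np.median(rho_nb) > np.quantile(rho_rand.dropna(), 0.95)
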