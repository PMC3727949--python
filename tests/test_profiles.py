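"""Gene constraint averaging, window meta-profiles, depth, and filters."""

from __future__ import annotations

import numpy as np
import pytest

from bgscan.io import Consequence, GeneRecord, GerpTrack, VariantSite
from bgscan.profiles import (
    FilterConfig,
    WindowProfile,
    assign_quantile_bins,
    build_window_profile,
    depth_of_depression,
    distance_to_nearest_gene,
    filter_mask,
    gene_average_gerp,
    passes_neutral_filter,
    proximal_distal_test,
    select_distal_noncoding_snps,
)
from conftest import build_table
from oracles import count_window_contributions


def _site(gerp=None, cons=Consequence.NONCODING):
    return VariantSite(
        chrom="1", pos0=100, ref="A", alt="G",
        genotypes=np.array([0, 1], dtype=np.int8), gerp=gerp, consequence=cons,
    )


class TestNeutralFilter:
    def test_gerp_above_threshold_fails(self):
        cfg = FilterConfig(exclude_gerp_gt=1.0)
        assert not passes_neutral_filter(_site(gerp=1.5), cfg)

    def test_gerp_below_threshold_passes(self):
        cfg = FilterConfig(exclude_gerp_gt=1.0)
        assert passes_neutral_filter(_site(gerp=0.2), cfg)

    def test_annotated_functional_fails_even_without_gerp(self):
        cfg = FilterConfig(exclude_annotated_functional=True)
        assert not passes_neutral_filter(
            _site(gerp=None, cons=Consequence.NONSYNONYMOUS), cfg
        )
        assert not passes_neutral_filter(
            _site(gerp=None, cons=Consequence.SYNONYMOUS), cfg
        )

    def test_absent_gerp_passes_threshold(self):
        cfg = FilterConfig(exclude_gerp_gt=1.0)
        assert passes_neutral_filter(_site(gerp=None), cfg)

    def test_invalid_hwe_level_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(exclude_hwe_p_lt=1.5)

    def test_vectorized_mask_matches_scalar(self, make_table):
        rows = [
            ("1", 10, [0, 1, 0, 0], 1.5, Consequence.NONCODING, "A"),
            ("1", 20, [0, 1, 0, 0], 0.2, Consequence.NONCODING, "A"),
            ("1", 30, [0, 1, 0, 0], None, Consequence.NONSYNONYMOUS, "A"),
            ("1", 40, [0, 1, 0, 0], 0.0, Consequence.NONCODING, "A"),
        ]
        t = make_table(rows)
        cfg = FilterConfig(
            exclude_annotated_functional=True,
            exclude_gerp_gt=1.0,
            exclude_gerp_exact_zero=True,
        )
        mask = filter_mask(t, cfg)
        expected = []
        for i in range(t.n_sites):
            s = t.site(i)
            ok = passes_neutral_filter(s, cfg)
            if cfg.exclude_gerp_exact_zero and s.gerp == 0.0:
                ok = False
            expected.append(ok)
        assert mask.tolist() == expected

    def test_singleton_exclusion_scoped(self, make_table):
        # singleton within POPA, doubleton globally
        t = make_table([("1", 10, [1, 0, 1, 0], None, Consequence.NONCODING, "A")])
        cfg = FilterConfig(exclude_singletons=True)
        assert filter_mask(t, cfg, population="POPA").tolist() == [False]
        assert filter_mask(t, cfg, population=None).tolist() == [True]

    def test_hwe_filter(self, make_table):
        # all-het site: most extreme HWE departure available at n=4
        t = make_table([
            ("1", 10, [1, 1, 1, 1], None, Consequence.NONCODING, "A"),
            ("1", 20, [0, 1, 1, 2], None, Consequence.NONCODING, "A"),
        ])
        from bgscan.profiles import hwe_exact_test
        p0 = hwe_exact_test(0, 4, 0)
        cfg = FilterConfig(exclude_hwe_p_lt=p0 + 1e-9)
        assert filter_mask(t, cfg).tolist() == [False, True]


class TestGeneAverageGerp:
    def test_mean_includes_zero_scores(self):
        gene = GeneRecord("g", "1", 0, 3, ((0, 3),))
        track = GerpTrack.from_intervals(
            [("1", 0, 1, 2.0), ("1", 1, 2, 4.0), ("1", 2, 3, 0.0)]
        )
        assert gene_average_gerp(gene, track) == pytest.approx(2.0)

    def test_constant_score(self):
        gene = GeneRecord("g", "1", 100, 400, ((100, 200), (300, 400)))
        track = GerpTrack.from_intervals([("1", 0, 1000, 5.8)])
        assert gene_average_gerp(gene, track) == pytest.approx(5.8)

    def test_uncovered_bases_excluded_from_denominator(self):
        gene = GeneRecord("g", "1", 0, 10, ((0, 10),))
        track = GerpTrack.from_intervals([("1", 0, 5, 2.0)])  # half covered
        assert gene_average_gerp(gene, track) == pytest.approx(2.0)

    def test_no_overlap_returns_none_with_warning(self, caplog):
        gene = GeneRecord("g", "1", 0, 10, ((0, 10),))
        track = GerpTrack.from_intervals([("2", 0, 5, 2.0)])
        with caplog.at_level("WARNING", logger="bgscan"):
            assert gene_average_gerp(gene, track) is None
        assert "g" in caplog.text


class TestQuantileBins:
    def test_eight_values_four_bins(self):
        values = {f"g{i}": float(i) for i in range(1, 9)}
        bins = assign_quantile_bins(values, 4)
        sizes = [sum(1 for b in bins.values() if b == k) for k in range(4)]
        assert sizes == [2, 2, 2, 2]
        assert bins["g8"] == 3 and bins["g1"] == 0

    def test_ten_bins_on_1000_genes(self):
        rng = np.random.default_rng(0)
        values = {f"g{i:04d}": float(v) for i, v in enumerate(rng.normal(size=1000))}
        bins = assign_quantile_bins(values, 10)
        sizes = np.bincount(list(bins.values()))
        assert sizes.tolist() == [100] * 10

    def test_all_equal_is_deterministic(self, caplog):
        values = {f"g{i}": 1.0 for i in range(6)}
        with caplog.at_level("WARNING", logger="bgscan"):
            b1 = assign_quantile_bins(values, 3)
            b2 = assign_quantile_bins(values, 3)
        assert b1 == b2
        assert "equal" in caplog.text

    def test_fewer_values_than_bins_rejected(self):
        with pytest.raises(ValueError):
            assign_quantile_bins({"a": 1.0, "b": 2.0}, 3)


def _profile_table(rows, panel=None):
    from bgscan.io import PopulationPanel

    panel = panel or PopulationPanel.from_mapping(
        {"A1": "POPA", "A2": "POPA", "B1": "POPB", "B2": "POPB"}
    )
    return build_table(rows, panel), panel


class TestWindowProfile:
    def test_single_snp_placement(self):
        gene = GeneRecord("g", "1", 1_000_000, 1_010_000, ((1_000_000, 1_010_000),))
        # one SNP 5 kb downstream of the gene end, MAF 0.25 (2 alt of 8)
        t, _ = _profile_table(
            [("1", 1_015_000, [1, 1, 0, 0], None, Consequence.NONCODING, "A")]
        )
        prof = build_window_profile(t, [gene], 10_000, 100)
        assert prof.count_down[0] == 1
        assert prof.mean_down[0] == pytest.approx(0.25)
        assert prof.count_down[1:].sum() == 0 and prof.count_up.sum() == 0

    def test_snp_beyond_span_ignored(self):
        gene = GeneRecord("g", "1", 0, 10_000, ((0, 10_000),))
        t, _ = _profile_table(
            [("1", 10_000 + 1_200_000, [1, 0, 0, 0], None, Consequence.NONCODING, "A")]
        )
        with pytest.raises(ValueError, match="no site contributed"):
            build_window_profile(t, [gene], 10_000, 100)

    def test_site_in_gene_body_excluded(self):
        gene = GeneRecord("g", "1", 1000, 2000, ((1000, 2000),))
        t, _ = _profile_table(
            [
                ("1", 1500, [1, 0, 0, 0], None, Consequence.NONCODING, "A"),
                ("1", 500, [1, 0, 0, 0], None, Consequence.NONCODING, "A"),
            ]
        )
        prof = build_window_profile(t, [gene], 100, 10)
        assert prof.total_contributions == 1  # only the upstream site

    def test_snp_counts_stack_across_anchors(self):
        g1 = GeneRecord("g1", "1", 0, 1000, ((0, 1000),))
        g2 = GeneRecord("g2", "1", 20_000, 21_000, ((20_000, 21_000),))
        # site at 10,500: downstream of g1, upstream of g2, inside both spans
        t, _ = _profile_table(
            [("1", 10_500, [1, 0, 0, 0], None, Consequence.NONCODING, "A")]
        )
        prof = build_window_profile(t, [g1, g2], 1_000, 15)
        assert prof.total_contributions == 2
        assert prof.count_down[9] == 1  # offset 9,500 from g1 end
        assert prof.count_up[9] == 1  # offset 9,499 from g2 start

    def test_contribution_conservation(self, small_ds):
        genes = small_ds.genes[:6]
        prof = build_window_profile(small_ds.table, genes, 10_000, 100)
        expected = count_window_contributions(small_ds.table, genes, 10_000, 100)
        assert prof.total_contributions == expected

    def test_population_scope_uses_population_maf(self):
        # site segregates only in POPA
        gene = GeneRecord("g", "1", 0, 1000, ((0, 1000),))
        t, _ = _profile_table(
            [("1", 1500, [1, 1, 0, 0], None, Consequence.NONCODING, "A")]
        )
        prof_a = build_window_profile(t, [gene], 1000, 5, population="POPA")
        assert prof_a.mean_down[0] == pytest.approx(0.5)
        with pytest.raises(ValueError):
            build_window_profile(t, [gene], 1000, 5, population="POPB")


class TestDepth:
    def _uniform_profile(self, mean_val, central=None):
        n, w = 100, 10_000
        means = np.full(n, mean_val)
        if central is not None:
            means[:5] = central
        counts = np.ones(n, dtype=np.int64)
        return WindowProfile("gene", w, n, None, means.copy(), counts.copy(),
                             means.copy(), counts.copy(), 1)

    def test_depth_arithmetic(self):
        prof = self._uniform_profile(0.10, central=0.04)
        stat = depth_of_depression(prof)
        assert stat.distal_mean_maf == pytest.approx(0.10)
        assert stat.central_min_maf == pytest.approx(0.04)
        assert stat.depth == pytest.approx(0.06)

    def test_flat_profile_zero_depth(self):
        stat = depth_of_depression(self._uniform_profile(0.08))
        assert stat.depth == pytest.approx(0.0)

    def test_empty_central_region_raises(self):
        prof = self._uniform_profile(0.1)
        prof.count_up[:5] = 0
        prof.count_down[:5] = 0
        with pytest.raises(ValueError, match="central"):
            depth_of_depression(prof)

    def test_empty_distal_flank_raises(self):
        prof = self._uniform_profile(0.1)
        prof.count_up[50:] = 0
        with pytest.raises(ValueError, match="upstream"):
            depth_of_depression(prof)

    def test_mirror_symmetry(self, small_ds):
        """Reversing the genome leaves the depth unchanged."""
        t = small_ds.table
        genes = small_ds.genes[:6]
        L = 10**9
        from bgscan.sites import SiteTable

        mt = SiteTable(
            t.chrom,
            L - 1 - t.pos0,
            t.ref,
            t.alt,
            t.geno,
            t.gerp,
            t.cons,
            t.ancestral,
            t.panel,
        )
        mg = [
            GeneRecord(
                g.gene_id,
                g.chrom,
                L - g.span_end,
                L - g.span_start,
                tuple((L - e, L - s) for s, e in g.coding_intervals),
            )
            for g in genes
        ]
        p1 = build_window_profile(t, genes, 10_000, 100)
        p2 = build_window_profile(mt, mg, 10_000, 100)
        d1 = depth_of_depression(p1)
        d2 = depth_of_depression(p2)
        assert d1.depth == pytest.approx(d2.depth, abs=1e-12)
        assert d1.distal_mean_maf == pytest.approx(d2.distal_mean_maf, abs=1e-12)


class TestDistalSelection:
    def _setup(self):
        genes = [GeneRecord("g", "1", 1_000_000, 1_010_000, ((1_000_000, 1_010_000),))]
        rows = [
            ("1", 1_010_000 + 250_000, [1, 0, 0, 0], 3.0, Consequence.NONCODING, "A"),
            ("1", 1_010_000 + 150_000, [1, 0, 0, 0], 3.0, Consequence.NONCODING, "A"),
            ("1", 1_000_000 - 250_000, [1, 0, 0, 0], 0.0, Consequence.NONCODING, "A"),
        ]
        t, _ = _profile_table(rows)
        return t, genes

    def test_distance_threshold(self):
        t, genes = self._setup()
        idx = select_distal_noncoding_snps(t, genes, 200_000)
        pos = set(t.pos0[idx].tolist())
        assert 1_010_000 + 250_000 - 0 in {p for p in pos} or (1_260_000 in pos)
        assert 1_160_000 not in pos  # 150 kb away: dropped

    def test_gerp_zero_dropped_when_binning(self):
        t, genes = self._setup()
        idx = select_distal_noncoding_snps(
            t, genes, 200_000, exclude_gerp_exact_zero=True
        )
        assert all(t.gerp[i] != 0 for i in idx)
        assert len(idx) == 1

    def test_distance_to_nearest_gene(self):
        t, genes = self._setup()
        d = distance_to_nearest_gene(t, genes)
        # sites sorted by position: 750000, 1160000, 1260000; distance is
        # measured to the nearest gene base (first base 1,000,000, last
        # base 1,009,999)
        assert d.tolist() == [250_000, 150_001, 250_001]


class TestProximalDistal:
    def _table_around(self, focal_pos, prox_mafs, dist_mafs):
        rows = []
        # MAF via genotype counts out of 8 alleles: use alt counts 1..4
        def geno_for(maf):
            alt = int(round(maf * 8))
            g = [0, 0, 0, 0]
            for k in range(alt):
                g[k % 4] += 1
            return g

        rows.append(("1", focal_pos, [1, 0, 0, 0], 5.0, Consequence.NONCODING, "A"))
        for i, m in enumerate(prox_mafs):
            rows.append(("1", focal_pos + 10 * (i + 1), geno_for(m), None,
                         Consequence.NONCODING, "A"))
        for i, m in enumerate(dist_mafs):
            rows.append(("1", focal_pos + 6000 + 10 * i, geno_for(m), None,
                         Consequence.NONCODING, "A"))
        t, _ = _profile_table(rows)
        return t

    def test_low_proximal_vs_high_distal(self):
        t = self._table_around(5_000_000, [0.125, 0.125], [0.25, 0.375, 0.5])
        p = proximal_distal_test(t, [("1", 5_000_000)])
        from oracles import mwu_exact_p

        prox = [0.125, 0.125]
        dist = [0.25, 0.375, 0.5]
        assert p == pytest.approx(mwu_exact_p(prox, dist), abs=1e-9)

    def test_identical_regions_p_one(self):
        t = self._table_around(5_000_000, [0.25, 0.25], [0.25, 0.25])
        assert proximal_distal_test(t, [("1", 5_000_000)]) == 1.0

    def test_clear_separation_significant(self):
        rng = np.random.default_rng(0)
        prox = [0.125] * 10
        dist = [0.375] * 10
        t = self._table_around(5_000_000, prox, dist)
        assert proximal_distal_test(t, [("1", 5_000_000)]) < 0.01

    def test_focal_site_excluded(self):
        # only the focal site in the proximal region -> error
        t = self._table_around(5_000_000, [], [0.25, 0.25])
        with pytest.raises(ValueError, match="proximal"):
            proximal_distal_test(t, [("1", 5_000_000)])
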