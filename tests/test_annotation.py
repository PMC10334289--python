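"""TSS-window annotation, top-region gene selection, metagene matrices."""

import numpy as np
import pandas as pd
import pytest

from dipsig.annotation import annotate_regions, metagene_matrix, select_top
from dipsig.io import GenomeModel
from dipsig.simulate import simulate_dip_sample


def region_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "pval", "tagdiff", "direction"])


def simple_genes(rows):
    genes = pd.DataFrame(rows, columns=["gene_id", "symbol", "chrom", "strand", "tx_start", "tx_end"])
    genes["tss"] = np.where(genes["strand"] == "+", genes["tx_start"], genes["tx_end"])
    genes["length"] = genes["tx_end"] - genes["tx_start"]
    return genes


class TestAnnotateRegions:
    def test_inside_window_signed_distance(self):
        genes = simple_genes([("g1", "A", "chr1", "+", 100_000, 150_000)])
        regions = region_frame([("chr1", 119_000, 121_000, 0.001, 20, "up")])
        ann = annotate_regions(regions, genes, half_window=25_000)
        assert ann["gene_id"].tolist() == ["g1"]
        assert ann["tss_distance"].tolist() == [20_000.0]

    def test_outside_window_dropped(self):
        genes = simple_genes([("g1", "A", "chr1", "+", 100_000, 150_000)])
        regions = region_frame([("chr1", 129_000, 131_000, 0.001, 20, "up")])
        ann = annotate_regions(regions, genes, half_window=25_000)
        assert ann.empty

    def test_closest_tss_wins(self):
        genes = simple_genes(
            [("g1", "A", "chr1", "+", 119_000, 125_000), ("g2", "B", "chr1", "+", 121_500, 128_000)]
        )
        regions = region_frame([("chr1", 119_500, 120_500, 0.001, 20, "up")])
        ann = annotate_regions(regions, genes, half_window=25_000)
        assert ann["gene_id"].tolist() == ["g1"]  # |-1000| < |+1500|
        assert ann["tss_distance"].tolist() == [1000.0]

    def test_equidistant_tie_breaks_to_smaller_id(self):
        genes = simple_genes(
            [("g2", "B", "chr1", "+", 119_000, 125_000), ("g1", "A", "chr1", "+", 121_000, 128_000)]
        )
        regions = region_frame([("chr1", 119_500, 120_500, 0.001, 20, "up")])
        ann = annotate_regions(regions, genes, half_window=25_000)
        assert ann["gene_id"].tolist() == ["g1"]

    def test_gene_body_mode_requires_containment(self):
        genes = simple_genes([("g1", "A", "chr1", "+", 100_000, 150_000)])
        inside = region_frame([("chr1", 140_000, 142_000, 0.001, 20, "up")])
        outside = region_frame([("chr1", 160_000, 162_000, 0.001, 20, "up")])
        assert len(annotate_regions(inside, genes, mode="gene_body")) == 1
        assert annotate_regions(outside, genes, mode="gene_body").empty

    def test_input_order_invariance(self):
        genes = simple_genes(
            [("g1", "A", "chr1", "+", 100_000, 150_000), ("g2", "B", "chr1", "-", 400_000, 410_000)]
        )
        regions = region_frame(
            [
                ("chr1", 99_000, 101_000, 0.001, 20, "up"),
                ("chr1", 409_000, 411_000, 0.002, 15, "up"),
            ]
        )
        a = annotate_regions(regions, genes)
        b = annotate_regions(regions.iloc[::-1].reset_index(drop=True), genes)
        assert set(a["gene_id"]) == set(b["gene_id"])

    def test_empty_gene_table_rejected(self):
        with pytest.raises(ValueError):
            annotate_regions(region_frame([]), simple_genes([]).iloc[0:0])


class TestSelectTop:
    def _annotated(self):
        rows = [
            ("chr1", 0, 1000, 0.0005, 11, "up"),
            ("chr1", 2000, 3000, 0.001, 12, "up"),
            ("chr1", 4000, 5000, 0.005, 15, "up"),
            ("chr1", 6000, 7000, 0.008, 20, "up"),
            ("chr1", 8000, 9000, 0.02, 9, "up"),
        ]
        df = region_frame(rows)
        df["gene_id"] = ["gA", "gB", "gC", "gD", "gE"]
        return df

    def test_hand_enumeration(self):
        # Delta=9 row fails the tagdiff filter and p=.02 fails p_cut even
        # though listed; truncation to 3 then drops the p=.008 region.
        gs = select_top(self._annotated(), n_top=3, p_cut=0.01, min_abs_tagdiff=10)
        assert gs.genes == frozenset({"gA", "gB", "gC"})

    def test_duplicate_gene_collapses(self):
        df = self._annotated()
        df["gene_id"] = ["gA", "gA", "gC", "gD", "gE"]
        gs = select_top(df, n_top=3, p_cut=0.01, min_abs_tagdiff=10)
        assert gs.genes == frozenset({"gA", "gC"})

    def test_no_passing_regions_empty_set(self):
        gs = select_top(self._annotated(), n_top=3, p_cut=0.0001, min_abs_tagdiff=10)
        assert len(gs) == 0

    def test_tightening_p_cut_never_adds_genes(self):
        df = self._annotated()
        loose = select_top(df, n_top=5, p_cut=0.01, min_abs_tagdiff=5).genes
        tight = select_top(df, n_top=5, p_cut=0.001, min_abs_tagdiff=5).genes
        assert tight <= loose

    def test_direction_filter(self):
        df = self._annotated()
        df.loc[0, "direction"] = "down"
        gs = select_top(df, n_top=5, p_cut=0.01, min_abs_tagdiff=10, direction="down")
        assert gs.genes == frozenset({"gA"})


class TestMetageneMatrix:
    def _setup(self, strand="+"):
        genome = GenomeModel((("chr1", 200_000),))
        genes = simple_genes([("g1", "A", "chr1", strand, 50_000, 70_000)])
        ts = simulate_dip_sample(genome, [], 100_000, seed=0)
        return genome, genes, ts

    def test_uniform_tags_give_flat_row(self):
        _, genes, ts = self._setup()
        mat = metagene_matrix(ts, genes, {"g1": 1.0}, n_body_bins=20, flank_bp=2000, flank_bins=4)
        body = mat.iloc[0][[c for c in mat.columns if c.startswith("body")]]
        # ~500 tags/bin at this depth; CV well under 0.2, before capping effects
        assert body.std() / body.mean() < 0.2

    def test_all_zero_tags_zero_matrix(self, tagset_factory):
        genome = GenomeModel((("chr1", 200_000),))
        genes = simple_genes([("g1", "A", "chr1", "+", 50_000, 70_000)])
        ts = tagset_factory(genome, [])
        mat = metagene_matrix(ts, genes, {"g1": 1.0})
        assert (mat.to_numpy() == 0).all()

    def test_cap_equals_quantile(self):
        _, genes, ts = self._setup()
        mat = metagene_matrix(ts, genes, {"g1": 1.0}, cap_quantile=0.8)
        vals = mat.to_numpy()
        assert vals.max() <= np.quantile(vals, 1.0) + 1e-12
        # at least 20% of entries sit at the cap after clipping
        assert (np.isclose(vals, vals.max())).mean() >= 0.2

    def test_minus_strand_row_is_reversed_plus_strand(self, tagset_factory):
        genome = GenomeModel((("chr1", 200_000),))
        rng = np.random.default_rng(1)
        starts = np.sort(rng.integers(0, 199_000, 5000))
        ts = tagset_factory(genome, starts)
        L = 200_000
        mirrored = tagset_factory(genome, np.sort(L - 1 - starts))
        genes_plus = simple_genes([("g1", "A", "chr1", "+", 50_000, 70_000)])
        genes_minus = simple_genes([("g1", "A", "chr1", "-", L - 70_000, L - 50_000)])
        m_plus = metagene_matrix(ts, genes_plus, {"g1": 1.0}, n_body_bins=10, flank_bp=1000, flank_bins=2)
        m_minus = metagene_matrix(mirrored, genes_minus, {"g1": 1.0}, n_body_bins=10, flank_bp=1000, flank_bins=2)
        np.testing.assert_allclose(m_plus.to_numpy(), m_minus.to_numpy(), rtol=0.15, atol=0.2)

    def test_rows_sorted_by_expression(self):
        genome = GenomeModel((("chr1", 200_000),))
        genes = simple_genes(
            [("g1", "A", "chr1", "+", 10_000, 20_000), ("g2", "B", "chr1", "+", 100_000, 110_000)]
        )
        ts = simulate_dip_sample(genome, [], 10_000, seed=2)
        mat = metagene_matrix(ts, genes, {"g1": 1.0, "g2": 5.0})
        assert mat.index.tolist() == ["g2", "g1"]

    def test_missing_expression_rejected(self):
        _, genes, ts = self._setup()
        with pytest.raises(ValueError):
            metagene_matrix(ts, genes, {})
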