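"""Gene partitions, bivalency classes, metagene profiles, distal decay."""
import numpy as np
import pandas as pd
import pytest

from satchip import metagene as mg
from satchip import tracks


def gene_df(rows):
    return pd.DataFrame(rows, columns=mg.GENE_COLUMNS)


def flat_track(length=100000, w=100, value=0.0):
    t = tracks.SignalTrack({"chr1": np.full(length // w, value)}, w,
                           tracks.IPIN, {"chr1": length})
    return t


class TestExpressionPartition:
    def make_genes(self, expr):
        return gene_df([(f"g{i:02d}", "chr1", "+", 1000 + 3000 * i,
                         2000 + 3000 * i, e) for i, e in enumerate(expr)])

    def test_top_decile_is_single_highest_of_ten(self):
        genes = self.make_genes([1, 5, 3, 9, 2, 8, 7, 4, 6, 0])
        grouping = mg.partition_by_expression(genes, "deciles_extremes")
        assert grouping.genes_in("top10") == ["g03"]
        assert grouping.genes_in("bottom10") == ["g09"]

    def test_quintiles_equal_groups_of_twenty(self):
        genes = self.make_genes(list(range(100)))
        grouping = mg.partition_by_expression(genes, "quintiles")
        sizes = [len(grouping.genes_in(f"q{i}")) for i in range(1, 6)]
        assert sizes == [20] * 5
        assert grouping.genes_in("q5") == [f"g{i}" for i in range(80, 100)]

    def test_all_tied_quintiles_fill_by_stable_id_order(self):
        genes = self.make_genes([0.0] * 6)
        grouping = mg.partition_by_expression(genes, "quintiles")
        sizes = [len(grouping.genes_in(f"q{i}")) for i in range(1, 6)]
        assert sizes == [2, 1, 1, 1, 1]
        assert grouping.genes_in("q1") == ["g00", "g01"]

    def test_partition_covers_every_gene_once(self):
        genes = self.make_genes(list(np.random.default_rng(0).random(37)))
        for scheme in ("deciles_extremes", "quintiles"):
            grouping = mg.partition_by_expression(genes, scheme)
            assert sorted(grouping.labels) == sorted(genes["gene_id"])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            mg.partition_by_expression(gene_df([]), "quintiles")


class TestMarkPartition:
    def test_rank_groups_match_sort_oracle(self):
        rng = np.random.default_rng(4)
        genes = gene_df([(f"g{i:03d}", "chr1", "+", 2500 + 5000 * i,
                          4000 + 5000 * i, 1.0) for i in range(100)])
        t = flat_track(length=600000)
        t.data["chr1"] = rng.random(t.data["chr1"].size)
        grouping = mg.partition_by_mark(genes, t, k=5, tss_halfwidth=2000)
        # oracle: sort gene ids by independently computed mean, slice in 5
        scores = {}
        for row in genes.itertuples():
            lo, hi = (row.tss - 2000) // 100, (row.tss + 2000) // 100
            scores[row.gene_id] = t.data["chr1"][lo:hi].mean()
        ranked = sorted(genes["gene_id"], key=lambda g: (scores[g], g))
        for i in range(5):
            assert set(grouping.genes_in(f"m{i + 1}")) == \
                set(ranked[20 * i:20 * (i + 1)])

    def test_constant_track_grouping_by_tie_rule(self):
        genes = gene_df([(f"g{i}", "chr1", "+", 5000 + 5000 * i,
                          6000 + 5000 * i, 1.0) for i in range(4)])
        t = flat_track(value=3.0)
        grouping = mg.partition_by_mark(genes, t, k=2)
        assert grouping.genes_in("m1") == ["g0", "g1"]


class TestBivalency:
    genes = gene_df([("g1", "chr1", "+", 10000, 12000, 1.0),
                     ("g2", "chr1", "+", 50000, 52000, 1.0)])

    def test_tss_inside_both_sets(self):
        grouping = mg.classify_bivalent(self.genes,
                                        [("chr1", 9000, 11000)],
                                        [("chr1", 9500, 10500)])
        assert grouping.labels["g1"] == "K4+K27+"
        assert grouping.labels["g2"] == "K4-K27-"

    def test_empty_region_lists(self):
        grouping = mg.classify_bivalent(self.genes, [], [])
        assert set(grouping.labels.values()) == {"K4-K27-"}

    def test_half_open_touch_is_no_overlap(self):
        # region starts exactly tss + halfwidth: [tss-hw, tss+hw) does not
        # intersect [tss+hw, ...)
        grouping = mg.classify_bivalent(self.genes, [("chr1", 11000, 12000)],
                                        [], tss_halfwidth=1000)
        assert grouping.labels["g1"] == "K4-K27-"
        grouping2 = mg.classify_bivalent(self.genes, [("chr1", 10999, 12000)],
                                         [], tss_halfwidth=1000)
        assert grouping2.labels["g1"] == "K4+K27-"


class TestMetageneProfile:
    def test_constant_track_gives_constant_profile(self):
        genes = gene_df([("g1", "chr1", "+", 30000, 32000, 5.0),
                         ("g2", "chr1", "-", 62000, 60000, 1.0)])
        prof = mg.metagene_profile(flat_track(value=2.5), genes, None,
                                   flank=2000)
        assert np.allclose(prof["mean"], 2.5)
        assert (prof["n_genes"] == 2).all()

    def test_plus_strand_hand_computed_means(self):
        t = flat_track(length=10000)
        t.data["chr1"] = np.arange(100.0)
        genes = gene_df([("g1", "chr1", "+", 3000, 4000, 1.0),
                         ("g2", "chr1", "+", 5000, 6000, 1.0)])
        prof = mg.metagene_profile(t, genes, None, flank=200)
        # offsets -200,-100,0,100: windows (28,29,30,31) and (48,49,50,51)
        by_off = prof.set_index("offset")["mean"]
        assert by_off[-200] == pytest.approx((28 + 48) / 2)
        assert by_off[0] == pytest.approx((30 + 50) / 2)

    def test_minus_strand_mirrors_offsets(self):
        t = flat_track(length=10000)
        t.data["chr1"] = np.arange(100.0)
        genes = gene_df([("g1", "chr1", "-", 3000, 2000, 1.0)])
        prof = mg.metagene_profile(t, genes, None, flank=200)
        by_off = prof.set_index("offset")["mean"]
        # bin [0,100) downstream of the TSS runs 5'->3' leftwards in genome
        # coordinates: genomic [2900,3000) -> window 29
        assert by_off[0] == 29.0
        assert by_off[-100] == 30.0
        assert by_off[100] == 28.0

    def test_bins_off_chromosome_excluded(self):
        genes = gene_df([("g1", "chr1", "+", 50, 2000, 1.0)])
        prof = mg.metagene_profile(flat_track(value=1.0), genes, None,
                                   flank=500)
        n_obs = prof.set_index("offset")["n_obs"]
        assert n_obs[-500] == 0 and n_obs[0] == 1

    def test_union_profile_is_weighted_mean_of_groups(self):
        rng = np.random.default_rng(8)
        t = flat_track(length=200000)
        t.data["chr1"] = rng.normal(size=t.data["chr1"].size)
        genes = gene_df([(f"g{i:02d}", "chr1", "+", 20000 + 5000 * i,
                          22000 + 5000 * i, float(i)) for i in range(30)])
        grouping = mg.partition_by_expression(genes, "deciles_extremes")
        prof = mg.metagene_profile(t, genes, grouping, flank=1000)
        prof_all = mg.metagene_profile(t, genes, None, flank=1000)
        merged = prof.pivot(index="offset", columns="group", values="mean")
        ngenes = prof.pivot(index="offset", columns="group", values="n_genes")
        weighted = (merged * ngenes).sum(axis=1) / ngenes.sum(axis=1)
        assert np.allclose(weighted.to_numpy(),
                           prof_all.set_index("offset")["mean"].to_numpy())

    def test_bin_must_match_track_window(self):
        genes = gene_df([("g1", "chr1", "+", 3000, 4000, 1.0)])
        with pytest.raises(ValueError):
            mg.metagene_profile(flat_track(), genes, None, bin=200)


class TestDistalDecay:
    def test_single_gene_nothing_excluded(self):
        genes = gene_df([("g1", "chr1", "+", 5000, 7000, 1.0)])
        out = mg.distal_decay(flat_track(value=4.0), genes, [0, 1000, 5000],
                              exclusion_radius=1000)
        assert (out["value"] == 4.0).all()
        assert len(out) == 5  # 0, +-1000, +-5000

    def test_close_gene_pair_excludes_all_distal_points(self):
        genes = gene_df([("g1", "chr1", "+", 5000, 7000, 1.0),
                         ("g2", "chr1", "+", 5500, 8000, 1.0)])
        out = mg.distal_decay(flat_track(), genes, [200, 400],
                              exclusion_radius=1000)
        assert len(out) == 0
        # far points are beyond the other gene's exclusion zone and survive
        far = mg.distal_decay(flat_track(), genes, [4000],
                              exclusion_radius=1000)
        assert len(far) == 4

    def test_constant_track_values_all_equal(self):
        genes = gene_df([("g1", "chr1", "+", 5000, 7000, 1.0),
                         ("g2", "chr1", "+", 50000, 52000, 1.0)])
        out = mg.distal_decay(flat_track(value=1.5), genes, [0, 3000],
                              exclusion_radius=2000)
        assert len(out) == 6 and (out["value"] == 1.5).all()
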