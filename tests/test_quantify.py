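"""Counting, normalization, fold-change classes, ratios, and the rank-sum
test."""

import numpy as np
import pandas as pd
import pytest

from polwave.io import GeneModel, GenomeAssembly, Peak, StrandedCoverage
from polwave.quantify import (
    bh_adjust,
    classify_expressed,
    count_window,
    diff_table,
    erna_windows,
    fold_change,
    gene_rpkm,
    normalize_counts,
    processivity_ratio,
    rank_sum_test,
    stratify_by_distance,
    tes_readthrough,
)


@pytest.fixture
def flat_cov(assembly):
    cov = StrandedCoverage.zeros(assembly, 50)
    cov.get("chrS", "+")[:] = 2.0
    return cov


class TestCountWindow:
    def test_uniform_density(self, flat_cov):
        assert count_window(flat_cov, "chrS", 0, 500, "sense",
                            strand="+") == pytest.approx(20.0)

    def test_empty_track(self, coverage):
        assert count_window(coverage, "chrS", 0, 500, "both") == 0.0

    def test_both_sums_strands(self, flat_cov):
        flat_cov.get("chrS", "-")[:] = 1.0
        assert count_window(flat_cov, "chrS", 0, 100, "both") \
            == pytest.approx(6.0)

    def test_antisense(self, flat_cov):
        flat_cov.get("chrS", "-")[:] = 1.0
        assert count_window(flat_cov, "chrS", 0, 100, "antisense",
                            strand="+") == pytest.approx(2.0)

    def test_matches_per_base_brute_force(self, assembly):
        rng = np.random.default_rng(21)
        cov = StrandedCoverage.zeros(assembly, 50)
        arr = cov.get("chrS", "+")
        arr[:] = rng.poisson(2.0, arr.size)
        per_base = np.repeat(arr, 50) / 50.0
        for _ in range(30):
            a = int(rng.integers(0, 99_000))
            b = a + int(rng.integers(1, 1_000))
            assert count_window(cov, "chrS", a, b, "sense", strand="+") \
                == pytest.approx(per_base[a:b].sum(), abs=1e-9)


class TestErnaWindows:
    def test_pad_rule(self, assembly):
        (w,) = erna_windows([Peak("chrS", 5_000, 5_200, "p")], assembly, 1_000)
        assert (w.start, w.end) == (4_000, 6_200)

    def test_pad_zero_identity(self, assembly):
        peak = Peak("chrS", 5_000, 5_200, "p")
        assert erna_windows([peak], assembly, 0) == [peak]

    def test_clipped_at_chromosome_start(self, assembly):
        (w,) = erna_windows([Peak("chrS", 300, 500, "p")], assembly, 1_000)
        assert (w.start, w.end) == (0, 1_500)


class TestNormalizeCounts:
    def spike_frame(self, eff_null):
        rows = []
        for ab in (100, 400, 1600):
            rows.append(("s%d" % ab, ab, "wt", ab))
            rows.append(("s%d" % ab, ab, "null", ab * eff_null))
        return pd.DataFrame(rows, columns=["species", "abundance",
                                           "condition", "observed"])

    def test_half_efficiency_doubles_counts(self):
        counts = pd.DataFrame({"wt": [10.0], "null": [10.0]})
        norm = normalize_counts(counts, "spike",
                                spike_counts=self.spike_frame(0.5))
        assert norm["wt"].iloc[0] == pytest.approx(10.0)
        assert norm["null"].iloc[0] == pytest.approx(20.0)

    def test_equal_efficiencies_equal_factors(self):
        counts = pd.DataFrame({"wt": [7.0], "null": [7.0]})
        norm = normalize_counts(counts, "spike",
                                spike_counts=self.spike_frame(1.0))
        assert norm["wt"].iloc[0] == norm["null"].iloc[0]

    def test_all_zero_spikes_rejected(self):
        frame = self.spike_frame(1.0)
        frame.loc[frame["condition"] == "null", "observed"] = 0
        with pytest.raises(ValueError, match="zero"):
            normalize_counts(pd.DataFrame({"wt": [1.0], "null": [1.0]}),
                             "spike", spike_counts=frame)

    def test_library_mode_per_million(self):
        counts = pd.DataFrame({"wt": [10.0], "null": [10.0]})
        norm = normalize_counts(counts, "library",
                                library_totals={"wt": 1e6, "null": 2e6})
        assert norm["wt"].iloc[0] == pytest.approx(10.0)
        assert norm["null"].iloc[0] == pytest.approx(5.0)

    def test_simulated_efficiency_recovered_within_five_percent(self):
        rng = np.random.default_rng(5)
        abundances = np.array([100, 200, 400, 800, 1600, 3200, 6400, 12800])
        rows = []
        for cond, eff in (("wt", 1.0), ("null", 0.7)):
            obs = rng.poisson(abundances * eff)
            rows += [("s%d" % a, a, cond, o)
                     for a, o in zip(abundances, obs)]
        spikes = pd.DataFrame(rows, columns=["species", "abundance",
                                             "condition", "observed"])
        counts = pd.DataFrame({"wt": [100.0], "null": [70.0]})
        norm = normalize_counts(counts, "spike", spike_counts=spikes)
        # the 0.7 efficiency confound is removed within 5%
        assert norm["null"].iloc[0] / norm["wt"].iloc[0] \
            == pytest.approx(1.0, rel=0.05)


class TestExpressionFilter:
    def test_rpkm_and_threshold(self, assembly):
        cov = StrandedCoverage.zeros(assembly, 50)
        arr = cov.get("chrS", "+")
        # gene A [0, 10k): 300 reads; rest of the track holds 599,700 reads
        arr[:200] = 1.5
        arr[200:] = 599_700 / 1_800
        gene_a = GeneModel("a", "chrS", "+", 0, 10_000)
        assert gene_rpkm(cov, gene_a) == pytest.approx(300 / 10 / 0.6)
        # library of ~1e6 reads: gene a has 4 reads (RPKM 0.4), gene s 1e5
        weak = StrandedCoverage.zeros(assembly, 50)
        weak.get("chrS", "+")[:200] = 0.02
        weak.get("chrS", "-")[:] = 500.0
        strong_gene = GeneModel("s", "chrS", "-", 50_000, 60_000)
        kept = classify_expressed([gene_a, strong_gene], weak, 0.5)
        assert [g.gene_id for g in kept] == ["s"]

    def test_zero_track_keeps_nothing(self, coverage):
        genes = [GeneModel("a", "chrS", "+", 0, 10_000)]
        assert classify_expressed(genes, coverage, 0.0) == []


class TestFoldChange:
    def test_pseudocounted_fc_and_class(self):
        res = fold_change(10, 20, 1.0)
        assert res.fc == pytest.approx(21 / 11)
        assert res.klass == "up"

    @pytest.mark.parametrize(
        "wt,null,expected",
        [(10, 10, "unchanged"), (0, 0, "unchanged"), (30, 10, "down"),
         (100, 100 * 1.49, "unchanged"), (100, 160, "up")],
    )
    def test_class_boundaries(self, wt, null, expected):
        assert fold_change(wt, null, 1.0).klass == expected

    def test_table_matches_scalar(self):
        norm = pd.DataFrame({"wt": [10.0, 5.0, 0.0],
                             "null": [20.0, 5.0, 0.0]},
                            index=list("abc"))
        table = diff_table(norm)
        for (idx, row) in table.iterrows():
            scalar = fold_change(norm.loc[idx, "wt"], norm.loc[idx, "null"])
            assert row["fc"] == pytest.approx(scalar.fc)
            assert row["class"] == scalar.klass

    def test_positive_pseudocount_required(self):
        with pytest.raises(ValueError):
            fold_change(1, 2, 0.0)


class TestProcessivity:
    def test_flat_gene_ratio_one(self, flat_cov):
        gene = GeneModel("g", "chrS", "+", 10_000, 40_000)
        assert processivity_ratio(flat_cov, gene) == pytest.approx(1.0)

    def test_invariant_to_global_rescaling(self, assembly):
        rng = np.random.default_rng(8)
        cov = StrandedCoverage.zeros(assembly, 50)
        cov.get("chrS", "+")[:] = rng.uniform(1, 5, 2_000)
        gene = GeneModel("g", "chrS", "+", 10_000, 40_000)
        r1 = processivity_ratio(cov, gene)
        r2 = processivity_ratio(cov.scaled(11.0), gene)
        assert r1 == pytest.approx(r2)

    def test_short_gene_dropped_with_warning(self, flat_cov):
        gene = GeneModel("g", "chrS", "+", 0, 8_000)
        with pytest.warns(UserWarning, match="short"):
            assert processivity_ratio(flat_cov, gene) is None

    def test_zero_proximal_dropped(self, coverage):
        gene = GeneModel("g", "chrS", "+", 0, 30_000)
        with pytest.warns(UserWarning, match="proximal"):
            assert processivity_ratio(coverage, gene) is None


class TestReadthrough:
    def test_uniform_density_returned(self, flat_cov):
        gene = GeneModel("g", "chrS", "+", 0, 20_000)
        assert tes_readthrough(flat_cov, gene, 10_000) \
            == pytest.approx(2.0 / 50)

    def test_clipped_at_downstream_neighbor(self, flat_cov):
        gene = GeneModel("g", "chrS", "+", 0, 20_000)
        neighbor = GeneModel("n", "chrS", "+", 25_000, 40_000)
        # region shrinks to 5 kb but density is unchanged
        assert tes_readthrough(flat_cov, gene, 10_000, [neighbor]) \
            == pytest.approx(2.0 / 50)


class TestStratify:
    GENES = [GeneModel("near", "chrS", "+", 65_000, 70_000),
             GeneModel("edge", "chrS", "+", 70_000, 75_000),
             GeneModel("mid", "chrS", "-", 1_000, 95_000)]
    ENH = [Peak("chrS", 49_000, 50_000, "e1")]

    def test_distance_bins(self):
        # tss "near"=65k: 15 kb from enhancer end -> <20; "edge"=70k: exactly
        # 20 kb -> 20-40 bin; "mid" tss=95k: 45 kb -> 40-60
        table = stratify_by_distance(self.GENES, self.ENH).set_index("gene_id")
        assert table.loc["near", "stratum"] == "0-20kb"
        assert table.loc["edge", "stratum"] == "20-40kb"
        assert table.loc["mid", "stratum"] == "40-60kb"

    def test_no_enhancer_on_chrom_excluded(self):
        far = [GeneModel("x", "chr9", "+", 0, 5_000)]
        assert len(stratify_by_distance(far, self.ENH)) == 0

    def test_beyond_last_break_excluded(self):
        genes = [GeneModel("far", "chrS", "+", 95_000, 99_000)]
        enh = [Peak("chrS", 0, 1_000, "e")]
        assert len(stratify_by_distance(genes, enh)) == 0


class TestRankSum:
    def test_identical_groups_p_one(self):
        stat, p = rank_sum_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert p >= 0.99

    def test_exact_enumeration_small_samples(self):
        # complete separation of n=3 vs 3: two-sided p = 2/20
        _, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_p_decreases_with_shift(self):
        rng = np.random.default_rng(13)
        base = rng.normal(0, 1, 50)
        ps = [rank_sum_test(base, base + shift)[1]
              for shift in (0.2, 0.8, 1.6)]
        assert ps[0] > ps[1] > ps[2]

    def test_minimum_group_size(self):
        with pytest.raises(ValueError, match="n >= 3"):
            rank_sum_test([1, 2], [3, 4, 5])

    def test_bh_batched(self):
        adj = bh_adjust([0.01, 0.02, 0.9])
        assert adj[0] <= adj[1] <= adj[2] <= 1.0
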