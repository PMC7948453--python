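"""Generator structure, kinematics, determinism, and closed-form read yield."""

import math

import numpy as np
import pandas as pd
import pytest

from polwave.io import PLUS
from polwave.simulate import (
    SimConfig,
    build_genome,
    read_truth,
    simulate_fp_washout,
    simulate_steady_state,
    write_truth,
)

TINY = dict(
    n_genes=24, n_chroms=1, chrom_length=800_000,
    gene_length_log_mean=np.log(12_000.0),
    n_enhancers=10, n_se_clusters=2, n_intragenic_enhancers=3,
    n_perturbed_enhancers=4,
)


@pytest.fixture(scope="module")
def tiny_genome():
    return build_genome(SimConfig(**TINY), seed=3)


class TestBuildGenome:
    def test_genes_disjoint_with_flanks(self, tiny_genome):
        for chrom in tiny_genome.assembly.chrom_names:
            spans = sorted((g.start, g.end) for g in tiny_genome.genes
                           if g.chrom == chrom)
            assert spans[0][0] >= 2_000
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert s2 - e1 >= 2_000
            assert spans[-1][1] <= tiny_genome.assembly.length(chrom) - 2_000

    def test_deterministic_under_seed(self):
        a = build_genome(SimConfig(**TINY), seed=3)
        b = build_genome(SimConfig(**TINY), seed=3)
        assert a.genes == b.genes
        assert a.enhancers == b.enhancers
        pd.testing.assert_frame_equal(a.truth.enhancers, b.truth.enhancers)

    def test_distinct_seeds_differ(self):
        a = build_genome(SimConfig(**TINY), seed=3)
        b = build_genome(SimConfig(**TINY), seed=4)
        assert a.genes != b.genes

    def test_intergenic_enhancers_clear_of_genes(self, tiny_genome):
        truth = tiny_genome.truth.enhancers
        inter = truth[truth["class"] == "intergenic"]
        for _, e in inter.iterrows():
            for g in tiny_genome.genes:
                if g.chrom != e["chrom"]:
                    continue
                assert e["end"] + 500 <= g.start or e["start"] >= g.end + 500

    def test_intragenic_enhancers_inside_genes(self, tiny_genome):
        truth = tiny_genome.truth.enhancers
        intra = truth[truth["class"] == "intragenic"]
        assert len(intra) == 3
        for _, e in intra.iterrows():
            assert any(g.chrom == e["chrom"] and g.start <= e["start"]
                       and e["end"] <= g.end for g in tiny_genome.genes)

    def test_superenhancer_rule_recovers_built_clusters(self, tiny_genome):
        """Brute-force single-linkage clustering at 12.5 kb finds exactly the
        flagged clusters of >= 3 members."""
        truth = tiny_genome.truth.enhancers
        inter = truth[truth["class"] == "intergenic"].sort_values(
            ["chrom", "start"])
        clusters = []
        current = []
        prev = None
        for _, e in inter.iterrows():
            if (prev is not None and e["chrom"] == prev["chrom"]
                    and e["start"] - prev["end"] <= 12_500):
                current.append(e["name"])
            else:
                clusters.append(current)
                current = [e["name"]]
            prev = e
        clusters.append(current)
        se_clusters = sorted(tuple(sorted(c)) for c in clusters if len(c) >= 3)
        flagged = inter[inter["is_superenhancer"]]
        built = sorted(
            tuple(sorted(sub["name"]))
            for _, sub in flagged.groupby(flagged["name"].str[:4]))
        assert se_clusters == built
        assert len(built) == 2


class TestWashout:
    def test_kinematic_front_bound(self):
        """With no background, sense signal never exceeds
        pause_max + v*T (+1 bin) downstream of any TSS."""
        cfg = SimConfig(**TINY, bg=0.0, pi=0.0)
        genome = build_genome(cfg, seed=3)
        tracks, _ = simulate_fp_washout(genome, cfg, seed=5,
                                        label_minutes=(5.0,),
                                        conditions=("wt",))
        cov = tracks[("wt", 5.0)]
        bound = cfg.pause_max + cfg.v * 1000 * 5.0 + cfg.bin_size
        for g in genome.genes:
            if g.length <= bound:
                continue
            if g.strand == PLUS:
                lo, hi = g.tss + bound, g.end
            else:
                lo, hi = g.start, g.tss - bound
            assert cov.window_sum(g.chrom, g.strand, lo, hi) == 0.0

    def test_no_initiation_no_cohort_gives_background_only(self):
        cfg = SimConfig(**TINY, alpha=0.0, bg=0.0)
        genome = build_genome(cfg, seed=3)
        tracks, _ = simulate_fp_washout(genome, cfg, seed=5,
                                        label_minutes=(5.0,),
                                        conditions=("wt",))
        assert tracks[("wt", 5.0)].total_reads == 0.0

    def test_deterministic_and_seed_sensitive(self):
        cfg = SimConfig(**TINY)
        genome = build_genome(cfg, seed=3)
        t1, _ = simulate_fp_washout(genome, cfg, seed=5, label_minutes=(5.0,))
        t2, _ = simulate_fp_washout(genome, cfg, seed=5, label_minutes=(5.0,))
        t3, _ = simulate_fp_washout(genome, cfg, seed=6, label_minutes=(5.0,))
        a = t1[("wt", 5.0)].get("chr1", "+")
        np.testing.assert_array_equal(a, t2[("wt", 5.0)].get("chr1", "+"))
        assert not np.array_equal(a, t3[("wt", 5.0)].get("chr1", "+"))

    def test_mean_reads_match_closed_form_expectation(self):
        """Total sense reads over long genes agree with the analytic expected
        labeled-RNA yield to within 3 SE over 200 replicate simulations."""
        cfg = SimConfig(
            n_genes=12, n_chroms=1, chrom_length=600_000,
            gene_length_log_mean=np.log(25_000.0), gene_length_log_sd=0.1,
            gene_length_min=15_000, gene_length_max=40_000,
            alpha=2.0, gene_strength_log_sd=0.0, pi=0.0, bg=0.0,
            n_enhancers=4, n_se_clusters=0, n_intragenic_enhancers=0,
            n_perturbed_enhancers=0,
        )
        genome = build_genome(cfg, seed=11)
        T, beta, v = 5.0, cfg.beta, cfg.v * 1000.0
        # cohort is 1 a.s. (Poisson(alpha*60) capped at 1); its labeled span
        # is v*(T - r)+ with r ~ Exp(beta); fresh initiations arrive at alpha.
        e_cohort = v * (T - (1 - math.exp(-beta * T)) / beta)
        e_new = cfg.alpha * v * (
            T ** 2 / 2 - T / beta
            + (1 - math.exp(-beta * T)) / beta ** 2)
        long_enough = [g for g in genome.genes
                       if g.length - cfg.pause_max >= v * T]
        assert len(long_enough) == len(genome.genes)  # law guarantees it
        expected = cfg.depth / 1000.0 * (e_cohort + e_new) * len(genome.genes)
        totals = []
        rng_seeds = range(200)
        for s in rng_seeds:
            tracks, _ = simulate_fp_washout(genome, cfg, seed=1000 + s,
                                            label_minutes=(T,),
                                            conditions=("wt",))
            totals.append(tracks[("wt", T)].total_reads)
        mean = np.mean(totals)
        se = np.std(totals, ddof=1) / math.sqrt(len(totals))
        assert abs(mean - expected) < 3 * se + 1e-9


class TestSteadyState:
    def test_flat_body_when_no_termination(self):
        from polwave.quantify import processivity_ratio

        cfg = SimConfig(**TINY, pi=0.0, bg=0.0, term_distance=0,
                        coupling=0.0)
        genome = build_genome(cfg, seed=3)
        cov, _ = simulate_steady_state(genome, cfg, "wt", seed=7)
        ratios = [processivity_ratio(cov, g) for g in genome.genes
                  if g.length > 12_000]
        ratios = [r for r in ratios if r is not None]
        assert np.median(ratios) == pytest.approx(1.0, abs=0.05)

    def test_no_readthrough_when_term_distance_zero(self):
        from polwave.quantify import tes_readthrough

        cfg = SimConfig(**TINY, term_distance=0, bg=0.0, coupling=0.0,
                        erna_rate=0.0)
        genome = build_genome(cfg, seed=3)
        cov, _ = simulate_steady_state(genome, cfg, "wt", seed=7)
        for g in genome.genes:
            v = tes_readthrough(cov, g, 5_000, neighbors=genome.genes)
            # only pro-rata bleed from the TES boundary bin is tolerated;
            # real readthrough at these settings would be ~0.05 reads/bp
            assert v * 5_000 < 5.0

    def test_conditions_differ_only_through_configured_effects(self):
        """The truth ledgers of wt and null differ exactly at the perturbed
        enhancers and the genes they couple to."""
        cfg = SimConfig(**TINY)
        genome = build_genome(cfg, seed=3)
        _, t_wt = simulate_steady_state(genome, cfg, "wt", seed=7)
        _, t_nl = simulate_steady_state(genome, cfg, "null", seed=7)
        e_wt = t_wt["enhancers"].set_index("name")["expected_reads"]
        e_nl = t_nl["enhancers"].set_index("name")["expected_reads"]
        mult = genome.truth.enhancers.set_index("name")["multiplier"]
        np.testing.assert_allclose(e_nl / e_wt, mult[e_nl.index])

    def test_spike_counts_scale_with_efficiency(self):
        cfg = SimConfig(**TINY)
        genome = build_genome(cfg, seed=3)
        _, t_wt = simulate_steady_state(genome, cfg, "wt", seed=7)
        _, t_nl = simulate_steady_state(genome, cfg, "null", seed=7)
        ratio = (t_nl["spikes"]["observed"].sum()
                 / t_wt["spikes"]["observed"].sum())
        assert ratio == pytest.approx(0.7, rel=0.1)


class TestTruthIO:
    def test_round_trip(self, tiny_genome, tmp_path):
        path = tmp_path / "truth.tsv"
        write_truth(tiny_genome.truth, path)
        back = read_truth(path)
        assert set(back) == {"genes", "enhancers", "spikes"}
        orig = tiny_genome.truth.enhancers
        got = back["enhancers"][orig.columns].astype(orig.dtypes.to_dict())
        pd.testing.assert_frame_equal(got, orig)

    def test_empty_truth(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_truth({}, path)
        assert path.read_text().startswith("table")


class TestConfigValidation:
    @pytest.mark.parametrize(
        "bad", [dict(v=-1.0), dict(pause_capacity=0),
                dict(block_minutes=1.0), dict(pause_min=0)])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            SimConfig(**bad).validate()

    def test_zero_label_window_rejected(self, tiny_genome):
        with pytest.raises(ValueError, match="label"):
            simulate_fp_washout(tiny_genome, SimConfig(**TINY), seed=1,
                                label_minutes=(0.0,))
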