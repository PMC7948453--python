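#!/usr/bin/env python
"""Generate the synthetic study: genome, annotation, and coverage tracks.

Builds the default synthetic genome (2 x 5 Mb, 500 genes, 150 enhancers of
which 50 carry a 2x eRNA effect in null cells), simulates the duplicate
block-and-release labeling experiments (5/10 min) and the steady-state
libraries for both genotypes, and writes:

  results/sim/      genes.bed12, enhancers.bed, truth.tsv, spike tables
  scratch/tracks/   stranded bedGraph coverage (large, regenerable)
"""

import argparse
from pathlib import Path

from polwave.io import write_bed, write_bedgraph, write_gene_models
from polwave.pipeline import RunConfig
from polwave.simulate import (
    build_genome,
    simulate_fp_washout,
    simulate_steady_state,
    write_truth,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/sim"))
    ap.add_argument("--tracks", type=Path, default=Path("scratch/tracks"))
    args = ap.parse_args()
    cfg = RunConfig(seed=args.seed)
    args.outdir.mkdir(parents=True, exist_ok=True)
    args.tracks.mkdir(parents=True, exist_ok=True)

    genome = build_genome(cfg.sim, cfg.stage_seed("genome"))
    write_gene_models(genome.genes, args.outdir / "genes.bed12")
    write_bed(genome.enhancers, args.outdir / "enhancers.bed")
    write_truth(genome.truth, args.outdir / "truth.tsv")
    n_long = sum(g.length > 30_000 for g in genome.genes)
    print(f"genome: {len(genome.genes)} genes ({n_long} > 30 kb), "
          f"{len(genome.enhancers)} enhancers")

    for rep in range(cfg.n_replicates):
        tracks, _ = simulate_fp_washout(
            genome, cfg.sim, cfg.stage_seed("washout") + rep)
        for (cond, T), cov in tracks.items():
            for strand, tag in (("+", "plus"), ("-", "minus")):
                name = f"washout_{cond}_{int(T)}min_rep{rep + 1}_{tag}.bedGraph"
                write_bedgraph(cov, args.tracks / name, strand)
        print(f"washout replicate {rep + 1}: "
              f"{tracks[('wt', 5.0)].total_reads:.0f} reads (wt, 5 min)")

    for cond in ("wt", "null"):
        cov, truth = simulate_steady_state(genome, cfg.sim, cond,
                                           cfg.stage_seed("steady"))
        for strand, tag in (("+", "plus"), ("-", "minus")):
            write_bedgraph(cov, args.tracks / f"steady_{cond}_{tag}.bedGraph",
                           strand)
        truth["spikes"].to_csv(args.outdir / f"spikes_{cond}.tsv", sep="\t",
                               index=False)
        print(f"steady-state {cond}: {cov.total_reads:.0f} reads")


if __name__ == "__main__":
    main()
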