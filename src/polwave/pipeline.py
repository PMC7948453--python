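"""End-to-end orchestration: simulate -> metagene -> rate -> quantify ->
annotate, with one config object, fanned-out stage seeds, and a
machine-readable report that is byte-identical under a fixed config + seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from . import metagene as mg
from . import quantify as qt
from .io import write_bed, write_bedgraph, write_gene_models
from .simulate import (
    SimConfig,
    build_genome,
    simulate_fp_washout,
    simulate_steady_state,
    write_truth,
)

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_all"]

log = logging.getLogger("polwave")

# fixed offsets fanning the global seed out to stages, so a stage can be
# re-run in isolation with a reproducible stream
STAGE_SEED_OFFSETS = {"genome": 11, "washout": 23, "steady": 37,
                      "bootstrap": 53}


class ConfigError(ValueError):
    """Invalid run configuration; message lists every violation."""


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 1
    outdir: str | None = None
    label_minutes: tuple = (5.0, 10.0)
    min_gene_length: dict = field(
        default_factory=lambda: {5.0: 15_000, 10.0: 30_000})
    windows: dict = field(
        default_factory=lambda: {5.0: (2_000, 18_000), 10.0: (2_000, 34_000)})
    front: mg.FrontConfig = field(default_factory=mg.FrontConfig)
    n_replicates: int = 2     # independent experiments averaged per profile
    n_boot: int = 100
    erna_pad: int = 1_000
    pseudocount: float = 1.0
    rpkm_threshold: float = 0.5
    strata_breaks: tuple = (0, 20_000, 40_000, 60_000)
    normalization: str = "spike"
    annotation: ann.AnnotationConfig = field(
        default_factory=ann.AnnotationConfig)

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) + STAGE_SEED_OFFSETS[stage]) % (2 ** 31)


def validate_config(config: RunConfig) -> tuple[list[str], list[str]]:
    """Cross-field checks; returns (errors, warnings), each listing every
    violation rather than stopping at the first."""
    errors, warns = [], []
    try:
        config.sim.validate()
    except ValueError as exc:
        errors.append(str(exc))
    if not config.label_minutes:
        errors.append("label_minutes is empty")
    for T in config.label_minutes:
        if T <= 0:
            errors.append(f"label time {T} must be > 0")
            continue
        if T not in config.windows:
            errors.append(f"no metagene window configured for T={T}")
            continue
        up, down = config.windows[T]
        expected_front = config.sim.v * 1000.0 * T
        if down <= expected_front:
            errors.append(
                f"T={T}: window end {down} bp does not clear the expected "
                f"front at ~{expected_front:.0f} bp")
        min_len = config.min_gene_length.get(T)
        if min_len is None:
            errors.append(f"no gene-length filter configured for T={T}")
        elif min_len < expected_front:
            warns.append(
                f"T={T}: gene filter {min_len} bp is shorter than the "
                f"expected front (~{expected_front:.0f} bp); fronts may run "
                f"past gene ends")
    if config.n_boot < 100:
        errors.append("n_boot must be >= 100")
    if config.pseudocount <= 0:
        errors.append("pseudocount must be > 0")
    if config.normalization not in ("spike", "library"):
        errors.append(f"unknown normalization {config.normalization!r}")
    return errors, warns


def _round(x, nd=6):
    if isinstance(x, dict):
        return {k: _round(v, nd) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round(v, nd) for v in x]
    if isinstance(x, (float, np.floating)):
        return round(float(x), nd)
    if isinstance(x, (int, np.integer)):
        return int(x)
    return x


def run_all(config: RunConfig) -> dict:
    """Execute the full synthetic study and return the report dict.

    When ``config.outdir`` is set, every intermediate artifact (bedGraph
    tracks, BED annotation, truth TSVs, profile TSVs) plus ``report.json``
    and the serialized config are written there.
    """
    errors, warns = validate_config(config)
    for w in warns:
        log.warning(w)
    if errors:
        raise ConfigError("; ".join(errors))

    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.json").write_text(
            json.dumps(_config_dict(config), indent=2, sort_keys=True) + "\n")

    report: dict = {"seed": int(config.seed)}
    sim = config.sim

    t0 = time.time()
    genome = build_genome(sim, config.stage_seed("genome"))
    log.info("stage=genome n_genes=%d n_enhancers=%d elapsed=%.1fs",
             len(genome.genes), len(genome.enhancers), time.time() - t0)
    if outdir:
        write_gene_models(genome.genes, outdir / "genes.bed12")
        write_bed(genome.enhancers, outdir / "enhancers.bed")
        write_truth(genome.truth, outdir / "truth.tsv")

    # --- washout: replicate experiments, metagenes, fronts, rate ---------
    t0 = time.time()
    rep_tracks = []  # one tracks dict per replicate experiment
    for rep in range(config.n_replicates):
        tracks, _events = simulate_fp_washout(
            genome, sim, config.stage_seed("washout") + rep,
            label_minutes=tuple(config.label_minutes))
        rep_tracks.append(tracks)
    log.info("stage=washout replicates=%d elapsed=%.1fs", len(rep_tracks),
             time.time() - t0)

    fronts: dict[str, dict] = {}
    rate_block: dict[str, dict] = {}
    for cond in ("wt", "null"):
        fronts[cond] = {}
        per_T = {}
        for T in config.label_minutes:
            genes_T = mg.filter_genes_by_length(
                genome.genes, config.min_gene_length[T])
            covs = [tr[(cond, T)] for tr in rep_tracks]
            prof = mg.build_metagene_replicates(covs, genes_T, "TSS",
                                                config.windows[T])
            log.info("stage=metagene cond=%s T=%g n_genes=%d", cond, T,
                     prof.n_genes)
            if outdir:
                mg.write_profile(
                    prof, outdir / f"metagene_{cond}_{int(T)}min.tsv")
            bg = mg.estimate_background(prof, config.front)
            wf = mg.detect_wavefront(prof, bg, config.front)
            fronts[cond][f"{int(T)}min"] = {
                "position_kb": wf.position / 1000.0,
                "background": wf.background,
                "threshold": wf.threshold,
                "n_genes": prof.n_genes,
            }
            per_T[T] = (covs, genes_T, wf.position)
        Ts = sorted(per_T)
        ta, tb = Ts[0], Ts[-1]
        est = mg.estimate_rate(per_T[ta][2], ta, per_T[tb][2], tb)
        boot = mg.bootstrap_rate(
            per_T[ta][0], per_T[tb][0], per_T[ta][1], per_T[tb][1],
            ta, tb, config.windows[ta], config.windows[tb],
            n_boot=config.n_boot, seed=config.stage_seed("bootstrap"),
            config=config.front)
        rate_block[cond] = {
            "rate_kb_min": est.rate,
            "method": est.method,
            "ci_kb_min": list(boot.ci),
        }
    report["wavefronts"] = fronts
    report["rate"] = rate_block
    report["rate_ratio_null_over_wt"] = (
        rate_block["null"]["rate_kb_min"] / rate_block["wt"]["rate_kb_min"])

    # --- steady state: eRNA diff, strata, processivity, readthrough ------
    t0 = time.time()
    ss = {}
    spike_frames = []
    for cond in ("wt", "null"):
        cov, truth = simulate_steady_state(
            genome, sim, cond, config.stage_seed("steady"))
        ss[cond] = cov
        spike_frames.append(truth["spikes"])
        if outdir:
            for strand, tag in (("+", "plus"), ("-", "minus")):
                write_bedgraph(cov, outdir / f"steady_{cond}_{tag}.bedGraph",
                               strand)
    spikes = pd.concat(spike_frames, ignore_index=True)
    log.info("stage=steady elapsed=%.1fs", time.time() - t0)
    if outdir:
        spikes.to_csv(outdir / "spike_counts.tsv", sep="\t", index=False)

    windows = qt.erna_windows(genome.enhancers, genome.assembly,
                              config.erna_pad)
    raw = pd.DataFrame(
        {
            cond: [qt.count_window(ss[cond], w.chrom, w.start, w.end, "both")
                   for w in windows]
            for cond in ("wt", "null")
        },
        index=[w.name for w in windows],
    )
    if config.normalization == "spike":
        norm = qt.normalize_counts(raw, "spike", spike_counts=spikes)
    else:
        norm = qt.normalize_counts(
            raw, "library",
            library_totals={c: ss[c].total_reads for c in ("wt", "null")})
    diff = qt.diff_table(norm, pseudocount=config.pseudocount)
    if outdir:
        diff.to_csv(outdir / "erna_diff.tsv", sep="\t")
    counts = diff["class"].value_counts()
    n_changed = int(counts.get("up", 0) + counts.get("down", 0))
    report["erna"] = {
        "n_windows": len(diff),
        "n_up": int(counts.get("up", 0)),
        "n_down": int(counts.get("down", 0)),
        "n_unchanged": int(counts.get("unchanged", 0)),
        "up_fraction_of_changed": (
            counts.get("up", 0) / n_changed if n_changed else 0.0),
    }

    # per-condition spike factors reused for gene-level comparisons
    spike_factor = {}
    for cond in ("wt", "null"):
        sub = spikes[(spikes["condition"] == cond) & (spikes["observed"] > 0)]
        spike_factor[cond] = float(
            np.median(sub["abundance"] / sub["observed"]))

    # neighbor-gene strata: genes near enhancers up in null cells
    up_names = set(diff.index[diff["class"] == "up"])
    up_enh = [e for e in genome.enhancers if e.name in up_names]
    expressed = qt.classify_expressed(genome.genes, ss["wt"],
                                      config.rpkm_threshold)
    log.info("stage=strata n_expressed=%d n_up_enhancers=%d",
             len(expressed), len(up_enh))
    strata = qt.stratify_by_distance(expressed, up_enh, config.strata_breaks)
    gene_by_id = {g.gene_id: g for g in genome.genes}
    strata_medians = {}
    for label, sub in strata.groupby("stratum", sort=True):
        ratios = []
        for gid in sub["gene_id"]:
            g = gene_by_id[gid]
            wt_c = qt.count_window(ss["wt"], g.chrom, g.start, g.end, "sense",
                                   strand=g.strand) * spike_factor["wt"]
            nl_c = qt.count_window(ss["null"], g.chrom, g.start, g.end,
                                   "sense", strand=g.strand) \
                * spike_factor["null"]
            ratios.append((nl_c + config.pseudocount)
                          / (wt_c + config.pseudocount))
        strata_medians[label] = {
            "n_genes": len(ratios),
            "median_ratio": float(np.median(ratios)) if ratios else None,
        }
    report["neighbor_gene_strata"] = strata_medians

    # processivity and readthrough
    prox_genes = [g for g in expressed if g.length > 12_000]
    ratios = {}
    for cond in ("wt", "null"):
        vals = [qt.processivity_ratio(ss[cond], g) for g in prox_genes]
        vals = [v for v in vals if v is not None]
        ratios[cond] = float(np.median(vals)) if vals else None
    report["processivity"] = {
        "median_wt": ratios["wt"],
        "median_null": ratios["null"],
        "n_genes": len(prox_genes),
    }
    rt = {}
    for cond in ("wt", "null"):
        vals = [qt.tes_readthrough(ss[cond], g, neighbors=genome.genes)
                for g in expressed]
        rt[cond] = (float(np.median(vals)) * spike_factor[cond]
                    if vals else None)
    report["readthrough"] = {
        "median_wt": rt["wt"],
        "median_null": rt["null"],
        "ratio_null_over_wt": (rt["null"] / rt["wt"]
                               if rt["wt"] else None),
    }

    # --- annotation summary over the enhancer peak set -------------------
    dist = ann.feature_distribution(genome.enhancers, genome.genes,
                                    genome.assembly, config.annotation)
    if outdir:
        dist.to_csv(outdir / "annotation_summary.tsv", sep="\t", index=False)
    report["annotation"] = {
        row["category"]: {"n_peaks": int(row["n_peaks"]),
                          "peak_fraction": row["peak_fraction"],
                          "genome_fraction": row["genome_fraction"]}
        for _, row in dist.iterrows()
    }
    intergenic = [p for p in genome.enhancers
                  if ann.classify_intergenic(p, genome.genes,
                                             config.annotation.span_pad)]
    se = [p for p in genome.enhancers if p.name.startswith("se")]
    overlap = ann.overlap_enhancers(intergenic, genome.enhancers, se)
    report["annotation"]["intergenic_overlap"] = {
        k: int(v) for k, v in
        overlap["overlap_class"].value_counts().items()
    }

    report = _round(report)
    if outdir:
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def elongation_rate_study(config: RunConfig | None = None,
                          seed: int | None = None,
                          conditions: tuple = ("wt",)) -> dict:
    """The block-and-release rate measurement, end to end.

    Simulates the genome and ``n_replicates`` labeling experiments, builds
    the replicate-averaged 5- and 10-min metagenes over length-filtered
    genes, calls both wave fronts against the distal-quartile background,
    and returns the two-timepoint rate per condition::

        {"wt": {"front_kb": {5.0: ..., 10.0: ...},
                "n_genes": {5.0: ..., 10.0: ...},
                "rate_kb_min": ...}, ...}
    """
    config = config or RunConfig()
    if seed is not None:
        config.seed = seed
    genome = build_genome(config.sim, config.stage_seed("genome"))
    reps = []
    for rep in range(config.n_replicates):
        tracks, _ = simulate_fp_washout(
            genome, config.sim, config.stage_seed("washout") + rep,
            label_minutes=tuple(config.label_minutes),
            conditions=conditions)
        reps.append(tracks)
    out = {}
    for cond in conditions:
        fronts, n_genes = {}, {}
        for T in config.label_minutes:
            genes_T = mg.filter_genes_by_length(
                genome.genes, config.min_gene_length[T])
            covs = [tr[(cond, T)] for tr in reps]
            prof = mg.build_metagene_replicates(covs, genes_T, "TSS",
                                                config.windows[T])
            bg = mg.estimate_background(prof, config.front)
            fronts[T] = mg.detect_wavefront(prof, bg, config.front).position
            n_genes[T] = prof.n_genes
        Ts = sorted(fronts)
        est = mg.estimate_rate(fronts[Ts[0]], Ts[0], fronts[Ts[-1]], Ts[-1])
        out[cond] = {
            "front_kb": {T: fronts[T] / 1000.0 for T in Ts},
            "n_genes": n_genes,
            "rate_kb_min": est.rate,
        }
    return out


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)

    def clean(x):
        if isinstance(x, dict):
            return {str(k): clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        return x

    return clean(d)
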