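"""Stochastic Pol II kinetics simulator with a ground-truth ledger.

Emulates the Bru-labeling nascent-RNA experiments the analysis modules are
built for:

* **Drug washout / wave front.**  Productive elongation is blocked for
  ``block_minutes`` (a CDK9-inhibitor block of pause release); gene bodies
  clear while initiation keeps loading polymerases onto the promoter-proximal
  pause site (capacity-capped).  At washout each paused polymerase escapes
  after an exponential waiting time and elongates at ``v`` kb/min; the RNA it
  synthesizes during the labeling window is what the library sees, so read
  density forms a cumulative wave whose front sits near
  ``pause_offset + v * label_minutes``.

* **Steady state.**  Pause-site occupancy ``alpha/beta``, gene-body density
  proportional to ``alpha/v`` with per-kb premature-termination dropout
  ``exp(-pi * x_kb)``, exponential post-TES readthrough, bidirectional eRNA
  at enhancers with per-enhancer condition multipliers, enhancer-to-gene
  rate coupling within 20 kb, and spike-in species at known abundances.

Two genetic conditions are simulated: ``wt`` and ``null``.  The null cell's
default perturbation is a 10% slower pause release (identical elongation
rate) plus the configured eRNA multipliers — a lesion upstream of productive
elongation, which the rate estimator should *not* see as a rate change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import (
    MINUS,
    PLUS,
    GeneModel,
    GenomeAssembly,
    Peak,
    StrandedCoverage,
    deposit,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "Genome",
    "build_genome",
    "simulate_fp_washout",
    "simulate_steady_state",
    "write_truth",
    "read_truth",
]

CONDITIONS = ("wt", "null")


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiments.

    Rates are per minute; lengths in bp unless suffixed ``_kb``.  Defaults
    reproduce the washout design (60-min block, 5/10-min labeling) at a
    true elongation rate of 2.2 kb/min and a 30-s release half-time.
    """

    # genome / annotation
    n_genes: int = 500
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    gene_length_log_mean: float = math.log(9_000.0)
    gene_length_log_sd: float = 0.8
    gene_length_min: int = 2_000
    gene_length_max: int = 100_000
    min_flank: int = 2_000
    # kinetics
    v: float = 2.2                      # elongation rate, kb/min
    beta: float = math.log(2.0) / 0.5   # pause-release rate, /min (t1/2 = 30 s)
    alpha: float = 0.5                  # initiation rate, /min/gene
    gene_strength_log_sd: float = 0.8   # per-gene lognormal scatter on alpha
    pause_min: int = 20                 # pause site offset from TSS, bp
    pause_max: int = 60
    pause_capacity: int = 1             # polymerases the pause site can hold
    block_minutes: float = 60.0
    pi: float = 0.02                    # premature termination, per kb
    term_distance: int = 2_000          # post-TES readthrough decay length, bp
    # read model
    depth: float = 50.0                 # reads per kb of labeled RNA
    bg: float = 2.0                     # background reads per kb per strand
    bin_size: int = 50
    # enhancers
    n_enhancers: int = 120              # intergenic, incl. superenhancer members
    n_se_clusters: int = 4
    se_cluster_size: int = 3
    se_cluster_span: int = 12_500
    n_intragenic_enhancers: int = 30
    enhancer_width: int = 400
    enhancer_score_log_sd: float = 0.5
    erna_rate: float = 300.0            # expected eRNA reads per enhancer (x1)
    erna_len_mean: float = 1_000.0
    erna_len_min: int = 200
    erna_len_max: int = 2_000
    n_perturbed_enhancers: int = 50
    perturbed_multiplier: float = 2.0
    coupling: float = 0.5               # enhancer-to-gene rate coupling strength
    coupling_decay: float = 10_000.0    # bp
    coupling_range: float = 20_000.0    # bp; no coupling beyond this
    null_release_factor: float = 0.9    # null beta multiplier (10% slower release)
    # spike-ins
    spike_abundance: tuple = (100, 200, 400, 800, 1600, 3200, 6400, 12800)
    spike_efficiency: dict = field(
        default_factory=lambda: {"wt": 1.0, "null": 0.7}
    )

    def validate(self) -> None:
        if self.v <= 0:
            raise ValueError("elongation rate v must be > 0")
        for name in ("beta", "alpha", "pi", "depth", "bg", "block_minutes",
                     "erna_rate", "coupling"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.pause_min <= self.pause_max):
            raise ValueError("need 0 < pause_min <= pause_max")
        if self.pause_capacity < 1:
            raise ValueError("pause_capacity must be >= 1")
        if self.gene_length_min < 1 or self.gene_length_max < self.gene_length_min:
            raise ValueError("bad gene length bounds")
        # block must clear every gene body so t=0 has no residual elongating Pol II
        if self.block_minutes * self.v * 1000.0 < self.gene_length_max:
            raise ValueError(
                "block_minutes * v shorter than the longest gene: "
                "gene bodies would not clear during the block"
            )


class SimTruth(NamedTuple):
    """Ground-truth tables keyed by the entities they describe."""

    genes: pd.DataFrame       # gene_id, pause_offset, strength, v, alpha
    enhancers: pd.DataFrame   # name, class, is_superenhancer, multiplier, score
    spikes: pd.DataFrame      # species, abundance, efficiency per condition

    def tables(self) -> dict[str, pd.DataFrame]:
        return {"genes": self.genes, "enhancers": self.enhancers,
                "spikes": self.spikes}


class Genome(NamedTuple):
    assembly: GenomeAssembly
    genes: list[GeneModel]
    enhancers: list[Peak]
    truth: SimTruth


class PackingError(RuntimeError):
    """Gene/enhancer placement failed under the configured genome size."""


# ---------------------------------------------------------------------------
# genome construction


def build_genome(config: SimConfig, seed: int) -> Genome:
    """Lay out genes, intergenic/intragenic enhancers, and superenhancer
    clusters on a synthetic assembly; deterministic under ``seed``."""
    config.validate()
    rng = np.random.default_rng([int(seed), 101])
    assembly = GenomeAssembly(
        {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    )

    genes: list[GeneModel] = []
    per_chrom = _split_counts(config.n_genes, config.n_chroms)
    gid = 0
    for ci, chrom in enumerate(assembly.chrom_names):
        n = per_chrom[ci]
        lengths = _draw_gene_lengths(rng, config, n, assembly.length(chrom))
        slack = assembly.length(chrom) - lengths.sum() - (n + 1) * config.min_flank
        gaps = config.min_flank + rng.dirichlet(np.ones(n + 1)) * slack
        pos = gaps[0]
        for k in range(n):
            start = int(round(pos))
            end = start + int(lengths[k])
            strand = PLUS if rng.random() < 0.5 else MINUS
            genes.append(GeneModel(f"g{gid:04d}", chrom, strand, start, end))
            gid += 1
            pos = end + gaps[k + 1]

    pause_offsets = rng.integers(config.pause_min, config.pause_max + 1,
                                 size=len(genes))
    strengths = rng.lognormal(0.0, config.gene_strength_log_sd, size=len(genes))

    enhancers, enh_truth = _place_enhancers(rng, config, assembly, genes)

    truth = SimTruth(
        genes=pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in genes],
                "chrom": [g.chrom for g in genes],
                "strand": [g.strand for g in genes],
                "start": [g.start for g in genes],
                "end": [g.end for g in genes],
                "pause_offset": pause_offsets,
                "strength": strengths,
                "v": config.v,
                "alpha": config.alpha * strengths,
            }
        ),
        enhancers=enh_truth,
        spikes=pd.DataFrame(
            {
                "species": [f"spike_{i:02d}" for i in
                            range(len(config.spike_abundance))],
                "abundance": list(config.spike_abundance),
                **{
                    f"efficiency_{c}": config.spike_efficiency[c]
                    for c in CONDITIONS
                },
            }
        ),
    )
    return Genome(assembly, genes, enhancers, truth)


def _split_counts(total: int, parts: int) -> list[int]:
    base = total // parts
    out = [base] * parts
    for i in range(total - base * parts):
        out[i] += 1
    return out


def _draw_gene_lengths(rng, config: SimConfig, n: int, chrom_len: int,
                       max_tries: int = 20) -> np.ndarray:
    for _ in range(max_tries):
        lengths = rng.lognormal(config.gene_length_log_mean,
                                config.gene_length_log_sd, size=n)
        lengths = np.clip(lengths, config.gene_length_min,
                          config.gene_length_max).astype(int)
        if lengths.sum() + (n + 1) * config.min_flank <= chrom_len:
            return lengths
    raise PackingError(
        f"could not pack {n} genes into a {chrom_len} bp chromosome "
        f"after {max_tries} draws"
    )


def _place_enhancers(rng, config: SimConfig, assembly: GenomeAssembly,
                     genes: list[GeneModel]):
    """Intergenic enhancers >= 0.5 kb from any gene span, superenhancers as
    clusters of >= se_cluster_size members within se_cluster_span, intragenic
    enhancers inside gene bodies.  Standalone enhancers are kept farther than
    se_cluster_span apart so the clustering rule recovers exactly the built
    clusters."""
    margin = 500
    w = config.enhancer_width
    # candidate intergenic intervals per chromosome
    free: dict[str, list[tuple[int, int]]] = {}
    for chrom in assembly.chrom_names:
        spans = sorted((g.start, g.end) for g in genes if g.chrom == chrom)
        intervals, cursor = [], margin
        for s, e in spans:
            if s - margin - cursor >= w:
                intervals.append((cursor, s - margin))
            cursor = e + margin
        end = assembly.length(chrom) - margin
        if end - cursor >= w:
            intervals.append((cursor, end))
        free[chrom] = intervals

    placed: list[tuple[str, int, int]] = []  # chrom, start, end

    def far_enough(chrom, start, end) -> bool:
        for c, s, e in placed:
            if c == chrom and not (start - e > config.se_cluster_span
                                   or s - end > config.se_cluster_span):
                return False
        return True

    records = []
    peaks: list[Peak] = []

    # superenhancer clusters
    se_members = config.se_cluster_size
    se_footprint = min(config.se_cluster_span,
                       se_members * (w + 1_000))  # members + spacing
    big = [(c, iv) for c in assembly.chrom_names for iv in free[c]
           if iv[1] - iv[0] >= se_footprint]
    if len(big) < config.n_se_clusters and config.n_se_clusters > 0:
        raise PackingError("not enough intergenic room for superenhancer clusters")
    order = rng.permutation(len(big))
    made = 0
    for idx in order:
        if made >= config.n_se_clusters:
            break
        chrom, (lo, hi) = big[idx]
        start = int(rng.integers(lo, hi - se_footprint + 1))
        if not far_enough(chrom, start, start + se_footprint):
            continue
        step = (se_footprint - w) // max(se_members - 1, 1)
        for j in range(se_members):
            s = start + j * step
            name = f"se{made:02d}_{j}"
            score = float(rng.lognormal(0.0, config.enhancer_score_log_sd))
            peaks.append(Peak(chrom, s, s + w, name, score))
            records.append((name, chrom, s, s + w, "intergenic", True, score))
        placed.append((chrom, start, start + se_footprint))
        made += 1
    if made < config.n_se_clusters:
        raise PackingError("superenhancer cluster placement failed")

    # standalone intergenic enhancers
    n_standalone = config.n_enhancers - made * se_members
    flat = [(c, iv) for c in assembly.chrom_names for iv in free[c]
            if iv[1] - iv[0] >= w]
    tries, k = 0, 0
    while k < n_standalone:
        tries += 1
        if tries > 200 * max(n_standalone, 1):
            raise PackingError("standalone enhancer placement failed")
        chrom, (lo, hi) = flat[int(rng.integers(len(flat)))]
        s = int(rng.integers(lo, hi - w + 1))
        if not far_enough(chrom, s, s + w):
            continue
        name = f"enh{k:03d}"
        score = float(rng.lognormal(0.0, config.enhancer_score_log_sd))
        peaks.append(Peak(chrom, s, s + w, name, score))
        records.append((name, chrom, s, s + w, "intergenic", False, score))
        placed.append((chrom, s, s + w))
        k += 1

    # intragenic enhancers, inside gene bodies away from TSS/TES
    host_pool = [g for g in genes if g.length >= w + 4_000]
    order = rng.permutation(len(host_pool))
    for j in range(min(config.n_intragenic_enhancers, len(host_pool))):
        g = host_pool[order[j]]
        s = int(rng.integers(g.start + 2_000, g.end - 2_000 - w + 1))
        name = f"ienh{j:03d}"
        score = float(rng.lognormal(0.0, config.enhancer_score_log_sd))
        peaks.append(Peak(g.chrom, s, s + w, name, score))
        records.append((name, g.chrom, s, s + w, "intragenic", False, score))

    df = pd.DataFrame(
        records,
        columns=["name", "chrom", "start", "end", "class",
                 "is_superenhancer", "score"],
    )
    # condition-specific effect multipliers (applied in the null condition)
    df["multiplier"] = 1.0
    n_pert = min(config.n_perturbed_enhancers, len(df))
    if n_pert > 0:
        pick = rng.choice(len(df), size=n_pert, replace=False)
        df.loc[df.index[pick], "multiplier"] = config.perturbed_multiplier
    return peaks, df


# ---------------------------------------------------------------------------
# washout experiment


def simulate_fp_washout(genome: Genome, config: SimConfig, seed: int,
                        label_minutes: tuple = (5.0, 10.0),
                        conditions: tuple = CONDITIONS):
    """Simulate the block-and-release labeling experiment.

    Returns ``(tracks, events)`` where ``tracks[(condition, T)]`` is a
    StrandedCoverage for labeling time ``T`` and ``events`` is a per-gene
    table of cohort sizes and first-release times.
    """
    config.validate()
    for T in label_minutes:
        if T <= 0:
            raise ValueError("label window must be > 0 minutes")
    assembly, genes = genome.assembly, genome.genes
    gtruth = genome.truth.genes
    pause = gtruth["pause_offset"].to_numpy()
    alpha_g = gtruth["alpha"].to_numpy()
    v_bp = config.v * 1000.0

    tracks: dict[tuple, StrandedCoverage] = {}
    rows = []
    for cond in conditions:
        beta_c = config.beta * (config.null_release_factor
                                if cond == "null" else 1.0)
        for ti, T in enumerate(label_minutes):
            rng = np.random.default_rng(
                [int(seed), 211, CONDITIONS.index(cond), ti])
            cov = StrandedCoverage.zeros(assembly, config.bin_size)
            _add_background(cov, config, rng)
            for gi, g in enumerate(genes):
                # cohort parked at the pause site during the block
                n0 = min(int(rng.poisson(alpha_g[gi] * config.block_minutes)),
                         config.pause_capacity)
                rel = rng.exponential(1.0 / beta_c, size=n0) if beta_c > 0 \
                    else np.full(n0, np.inf)
                if not np.isfinite(beta_c):
                    rel = np.zeros(n0)
                # fresh initiations during the label window join the queue
                n_new = int(rng.poisson(alpha_g[gi] * T))
                t_init = rng.uniform(0.0, T, size=n_new)
                wait = (rng.exponential(1.0 / beta_c, size=n_new)
                        if np.isfinite(beta_c) else np.zeros(n_new))
                rel = np.concatenate([rel, t_init + wait])
                rel = rel[rel < T]
                rows.append((cond, T, g.gene_id, n0, len(rel),
                             float(rel.min()) if rel.size else np.nan))
                if rel.size == 0:
                    continue
                dist = v_bp * (T - rel)
                if config.pi > 0:
                    dist = np.minimum(
                        dist, rng.exponential(1000.0 / config.pi,
                                              size=rel.size))
                dist = np.minimum(dist, g.length - pause[gi])
                arr = cov.get(g.chrom, g.strand)
                for d in dist:
                    if d <= 0:
                        continue
                    if g.strand == PLUS:
                        lo = g.tss + pause[gi]
                        hi = lo + d
                    else:
                        hi = g.tss - pause[gi]
                        lo = hi - d
                    deposit(arr, config.bin_size, lo, hi,
                            config.depth * d / 1000.0)
            _poissonize(cov, rng, config.spike_efficiency.get(cond, 1.0))
            tracks[(cond, T)] = cov
    events = pd.DataFrame(
        rows, columns=["condition", "label_minutes", "gene_id",
                       "cohort", "n_released", "first_release"])
    return tracks, events


def _add_background(cov: StrandedCoverage, config: SimConfig, rng) -> None:
    per_bin = config.bg * config.bin_size / 1000.0
    for chrom in cov.assembly.chrom_names:
        for strand in (PLUS, MINUS):
            cov.get(chrom, strand)[:] += per_bin


def _poissonize(cov: StrandedCoverage, rng, scale: float = 1.0) -> None:
    # `scale` is the per-sample recovery efficiency: it thins every read
    # source (signal and background) the same way the spike-ins are thinned,
    # which is exactly the confound spike normalization is meant to remove.
    for chrom in cov.assembly.chrom_names:
        for strand in (PLUS, MINUS):
            arr = cov.get(chrom, strand)
            arr[:] = rng.poisson(arr * scale).astype(float)


# ---------------------------------------------------------------------------
# steady state


def simulate_steady_state(genome: Genome, config: SimConfig, condition: str,
                          seed: int):
    """Simulate steady-state labeled coverage for one condition.

    Returns ``(coverage, truth)`` where ``truth`` has per-gene effective
    initiation rates, per-enhancer expected output, and observed spike-in
    counts for the condition.
    """
    config.validate()
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng([int(seed), 307, CONDITIONS.index(condition)])
    assembly, genes = genome.assembly, genome.genes
    gtruth = genome.truth.genes
    etruth = genome.truth.enhancers
    beta_c = config.beta * (config.null_release_factor
                            if condition == "null" else 1.0)
    cov = StrandedCoverage.zeros(assembly, config.bin_size)
    _add_background(cov, config, rng)

    mult = (etruth["multiplier"].to_numpy() if condition == "null"
            else np.ones(len(etruth)))
    boosts = _gene_boosts(genes, etruth, mult, config)

    gene_rows = []
    for gi, g in enumerate(genes):
        strength = gtruth["strength"].iloc[gi] * boosts[gi]
        gene_rows.append((g.gene_id, condition, strength))
        rate_bp = config.depth / 1000.0 * strength  # reads per bp at the TSS
        pause_off = int(gtruth["pause_offset"].iloc[gi])
        arr = cov.get(g.chrom, g.strand)
        nb = int(np.ceil(g.length / config.bin_size))
        x_kb = (np.arange(nb) + 0.5) * config.bin_size / 1000.0
        body = rate_bp * np.exp(-config.pi * x_kb) * config.bin_size
        if g.strand == PLUS:
            _add_profile(arr, config.bin_size, g.start, body, limit=g.end)
        else:
            _add_profile_rev(arr, config.bin_size, g.end, body,
                             limit=g.start)
        # pause peak: occupancy alpha/beta polymerases holding ~50 nt of RNA
        pause_mass = config.depth / 1000.0 \
            * (config.alpha * strength / max(beta_c, 1e-9)) * 50.0
        pos = g.tss + pause_off if g.strand == PLUS else g.tss - pause_off
        deposit(arr, config.bin_size, pos - 25, pos + 25, pause_mass)
        # post-TES readthrough, exponentially decaying
        if config.term_distance > 0:
            end_density = rate_bp * math.exp(-config.pi * g.length / 1000.0)
            reach = 5 * config.term_distance
            nrt = int(np.ceil(reach / config.bin_size))
            x = (np.arange(nrt) + 0.5) * config.bin_size
            rt = end_density * np.exp(-x / config.term_distance) * config.bin_size
            if g.strand == PLUS:
                _add_profile(arr, config.bin_size, g.end, rt)
            else:
                _add_profile_rev(arr, config.bin_size, g.start, rt)

    enh_rows = []
    half = _erna_half_profile(config)
    for ei in range(len(etruth)):
        row = etruth.iloc[ei]
        total = config.erna_rate * row["score"] * mult[ei]
        enh_rows.append((row["name"], condition, float(total)))
        center = (int(row["start"]) + int(row["end"])) // 2
        plus = cov.get(row["chrom"], PLUS)
        minus = cov.get(row["chrom"], MINUS)
        _add_profile(plus, config.bin_size, center, half * total / 2.0)
        _add_profile_rev(minus, config.bin_size, center, half * total / 2.0)

    _poissonize(cov, rng, config.spike_efficiency.get(condition, 1.0))

    spikes = genome.truth.spikes.copy()
    eff = spikes[f"efficiency_{condition}"].to_numpy()
    spikes["condition"] = condition
    spikes["observed"] = rng.poisson(spikes["abundance"].to_numpy() * eff)
    truth = {
        "genes": pd.DataFrame(gene_rows,
                              columns=["gene_id", "condition", "strength_eff"]),
        "enhancers": pd.DataFrame(enh_rows,
                                  columns=["name", "condition",
                                           "expected_reads"]),
        "spikes": spikes[["species", "abundance", "condition", "observed"]],
    }
    return cov, truth


def _gene_boosts(genes, etruth: pd.DataFrame, mult: np.ndarray,
                 config: SimConfig) -> np.ndarray:
    """Distance-decaying enhancer-to-gene coupling on initiation rate."""
    boosts = np.ones(len(genes))
    if len(etruth) == 0 or config.coupling == 0:
        return boosts
    e_chrom = etruth["chrom"].to_numpy()
    e_start = etruth["start"].to_numpy()
    e_end = etruth["end"].to_numpy()
    for gi, g in enumerate(genes):
        same = e_chrom == g.chrom
        if not same.any():
            continue
        d = np.maximum(0, np.maximum(e_start[same] - g.tss,
                                     g.tss - e_end[same]))
        near = d <= config.coupling_range
        if not near.any():
            continue
        factors = 1.0 + config.coupling * (mult[same][near] - 1.0) \
            * np.exp(-d[near] / config.coupling_decay)
        boosts[gi] = float(np.prod(factors))
    return boosts


def _erna_half_profile(config: SimConfig) -> np.ndarray:
    """Per-bin coverage profile (unit total mass) of one eRNA direction.

    Transcript length is exponential with mean ``erna_len_mean`` truncated to
    [erna_len_min, erna_len_max]; expected coverage at distance d from the
    start is the length survival function.
    """
    nb = int(np.ceil(config.erna_len_max / config.bin_size))
    d = (np.arange(nb) + 0.5) * config.bin_size
    lam = 1.0 / config.erna_len_mean
    lo, hi = config.erna_len_min, config.erna_len_max
    z = math.exp(-lam * lo) - math.exp(-lam * hi)
    surv = np.where(
        d <= lo, 1.0,
        np.where(d >= hi, 0.0, (np.exp(-lam * d) - math.exp(-lam * hi)) / z))
    total = surv.sum()
    return surv / total  # mass fractions per bin


def _add_profile(arr: np.ndarray, bin_size: int, start_bp: int,
                 mass_per_bin: np.ndarray, limit: float | None = None) -> None:
    """Add a forward profile whose bin 0 begins at start_bp (plus strand).

    ``limit`` truncates the profile (mass scaled to the clipped width)."""
    for k, m in enumerate(mass_per_bin):
        if m <= 0:
            continue
        lo = start_bp + k * bin_size
        hi = start_bp + (k + 1) * bin_size
        if limit is not None:
            if lo >= limit:
                break
            if hi > limit:
                m *= (limit - lo) / (hi - lo)
                hi = limit
        deposit(arr, bin_size, lo, hi, float(m))


def _add_profile_rev(arr: np.ndarray, bin_size: int, end_bp: int,
                     mass_per_bin: np.ndarray,
                     limit: float | None = None) -> None:
    """Add a profile running leftward from end_bp (minus strand)."""
    for k, m in enumerate(mass_per_bin):
        if m <= 0:
            continue
        lo = end_bp - (k + 1) * bin_size
        hi = end_bp - k * bin_size
        if limit is not None:
            if hi <= limit:
                break
            if lo < limit:
                m *= (hi - limit) / (hi - lo)
                lo = limit
        deposit(arr, bin_size, lo, hi, float(m))


# ---------------------------------------------------------------------------
# truth I/O


def write_truth(truth, path) -> None:
    """Dump truth tables to one TSV with a leading ``table`` column."""
    tables = truth.tables() if isinstance(truth, SimTruth) else dict(truth)
    frames = []
    for name, df in tables.items():
        d = df.copy()
        d.insert(0, "table", name)
        frames.append(d)
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame({"table": []})
    out.to_csv(path, sep="\t", index=False)


def read_truth(path) -> dict[str, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for name, sub in df.groupby("table", sort=False):
        sub = sub.drop(columns="table").dropna(axis=1, how="all")
        out[name] = sub.reset_index(drop=True)
    return out


def null_config(config: SimConfig, **overrides) -> SimConfig:
    """Convenience copy-with-overrides for perturbation studies."""
    return replace(config, **overrides)
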