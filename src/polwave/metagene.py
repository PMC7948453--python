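"""TSS-anchored metagene profiles, wave-front calling, and elongation rate.

A metagene is the unweighted mean, over a gene set, of sense-strand read
density extracted in anchor-relative coordinates (minus-strand genes are
flipped so downstream is positive), after scaling each library to reads per
million.  The wave front is the position downstream of the TSS where the
profile first settles back to background; its displacement between two
labeling times gives the elongation rate in kb/min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import PLUS, StrandedCoverage

__all__ = [
    "MetageneProfile",
    "WaveFront",
    "RateEstimate",
    "FrontDetectionError",
    "filter_genes_by_length",
    "build_metagene",
    "build_metagene_replicates",
    "gene_profile_matrix",
    "replicate_average_matrix",
    "average_replicates",
    "estimate_background",
    "detect_wavefront",
    "estimate_rate",
    "bootstrap_rate",
    "write_profile",
    "read_profile",
]


class FrontDetectionError(RuntimeError):
    """The profile never returns to background inside the window."""


@dataclass
class MetageneProfile:
    anchor: str                  # "TSS" or "TES"
    bin_size: int
    window: tuple[int, int]      # (upstream bp, downstream bp), both positive
    values: np.ndarray           # normalized density per bin (RPM per bin)
    n_genes: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        up, down = self.window
        expected = (up + down) // self.bin_size
        if self.values.shape != (expected,):
            raise ValueError(
                f"profile length {self.values.size} != window span / bin_size "
                f"({expected})"
            )
        if (self.values < 0).any():
            raise ValueError("negative profile values")

    @property
    def positions(self) -> np.ndarray:
        """Bin start positions relative to the anchor, bp."""
        up, _ = self.window
        return -up + np.arange(self.values.size) * self.bin_size


@dataclass
class WaveFront:
    position: float              # bp downstream of the anchor
    background: float
    threshold: float
    ci: tuple[float, float] | None = None

    def __post_init__(self):
        if self.threshold < self.background:
            raise ValueError("threshold below background")
        if self.position <= 0:
            raise ValueError("front position must be downstream of the anchor")


@dataclass
class RateEstimate:
    rate: float                  # kb/min
    method: str                  # "two-timepoint" or "single-timepoint"
    ci: tuple[float, float] | None = None

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("rate must be positive")


@dataclass
class FrontConfig:
    """Tunables for background estimation and front calling."""

    smooth_bins: int = 5         # moving-mean width for peak location
    threshold_frac: float = 0.05  # fraction of (max - background) above bg
    run_bins: int = 3            # consecutive sub-threshold bins required
    distal_fraction: float = 0.25  # tail fraction used for background


def filter_genes_by_length(genes, min_length: int):
    """Keep genes strictly longer than ``min_length`` bp, order preserved."""
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    out = [g for g in genes if g.length > min_length]
    if not out:
        import warnings

        warnings.warn("length filter removed every gene", stacklevel=2)
    return out


def gene_profile_matrix(coverage: StrandedCoverage, genes, anchor: str,
                        window: tuple[int, int]) -> tuple[np.ndarray, list]:
    """Per-gene sense-strand density rows in anchor-relative bins.

    Rows are raw (unnormalized) read mass per bin.  Genes whose window runs
    off the chromosome are dropped; the surviving gene list is returned
    alongside the matrix.
    """
    if anchor not in ("TSS", "TES"):
        raise ValueError("anchor must be TSS or TES")
    up, down = window
    bin_size = coverage.bin_size
    nb = (up + down) // bin_size
    rows, kept = [], []
    # cache cumulative mass per (chrom, strand)
    cums: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for g in genes:
        key = (g.chrom, g.strand)
        if key not in cums:
            arr = coverage.get(*key)
            cums[key] = (
                np.arange(arr.size + 1, dtype=float) * bin_size,
                np.concatenate(([0.0], np.cumsum(arr))),
            )
        edges, cum = cums[key]
        a = g.tss if anchor == "TSS" else g.tes
        rel = -up + np.arange(nb + 1, dtype=float) * bin_size
        pos = a + rel if g.strand == PLUS else a - rel
        lo, hi = (pos[0], pos[-1]) if g.strand == PLUS else (pos[-1], pos[0])
        if lo < 0 or hi > coverage.assembly.length(g.chrom):
            continue  # truncated by chromosome edge
        c = np.interp(pos, edges, cum)
        prof = np.diff(c) if g.strand == PLUS else -np.diff(c)
        rows.append(prof)
        kept.append(g)
    if not rows:
        raise ValueError("no usable genes for the metagene window")
    return np.vstack(rows), kept


def build_metagene(coverage: StrandedCoverage, genes, anchor: str = "TSS",
                   window: tuple[int, int] = (2_000, 18_000),
                   scale_to_rpm: bool = True) -> MetageneProfile:
    """Unweighted gene-mean profile, library-scaled to reads per million."""
    mat, kept = gene_profile_matrix(coverage, genes, anchor, window)
    scale = 1.0
    if scale_to_rpm:
        total = coverage.total_reads
        if total <= 0:
            raise ValueError("empty coverage track")
        scale = 1e6 / total
    return MetageneProfile(
        anchor=anchor,
        bin_size=coverage.bin_size,
        window=window,
        values=mat.mean(axis=0) * scale,
        n_genes=len(kept),
    )


def replicate_average_matrix(coverages, genes, anchor: str,
                             window: tuple[int, int]):
    """Per-gene profile rows averaged over replicate libraries.

    Each replicate's rows are scaled to reads per million before averaging,
    matching profile-level replicate averaging.  Returns (matrix, kept genes).
    """
    coverages = list(coverages)
    mats, kept_ref = [], None
    for cov in coverages:
        mat, kept = gene_profile_matrix(cov, genes, anchor, window)
        total = cov.total_reads
        if total <= 0:
            raise ValueError("empty coverage track")
        mats.append(mat * (1e6 / total))
        if kept_ref is None:
            kept_ref = kept
        elif [g.gene_id for g in kept] != [g.gene_id for g in kept_ref]:
            raise ValueError("replicates disagree on usable genes")
    return np.mean(mats, axis=0), kept_ref


def build_metagene_replicates(coverages, genes, anchor: str = "TSS",
                              window: tuple[int, int] = (2_000, 18_000),
                              ) -> MetageneProfile:
    """Replicate-averaged metagene: per-replicate RPM profiles, then mean."""
    coverages = list(coverages)
    mat, kept = replicate_average_matrix(coverages, genes, anchor, window)
    return MetageneProfile(anchor=anchor, bin_size=coverages[0].bin_size,
                           window=window, values=mat.mean(axis=0),
                           n_genes=len(kept))


def average_replicates(profiles) -> MetageneProfile:
    """Bin-wise mean across replicate profiles of identical geometry."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to average")
    first = profiles[0]
    for p in profiles[1:]:
        if (p.anchor, p.bin_size, p.window) != (first.anchor, first.bin_size,
                                                first.window):
            raise ValueError("replicate profile geometry mismatch")
    return MetageneProfile(
        anchor=first.anchor,
        bin_size=first.bin_size,
        window=first.window,
        values=np.mean([p.values for p in profiles], axis=0),
        n_genes=min(p.n_genes for p in profiles),
    )


def estimate_background(profile: MetageneProfile,
                        config: FrontConfig | None = None) -> float:
    """Median of the most distal fraction of the window (robust baseline)."""
    config = config or FrontConfig()
    n_tail = int(round(profile.values.size * config.distal_fraction))
    if n_tail < 1:
        raise ValueError("distal fraction selects no bins")
    return float(np.median(profile.values[-n_tail:]))


def _smooth(values: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return values.astype(float)
    import pandas as pd

    return (
        pd.Series(values).rolling(width, center=True, min_periods=1)
        .mean().to_numpy()
    )


def detect_wavefront(profile: MetageneProfile, background: float,
                     config: FrontConfig | None = None) -> WaveFront:
    """Call the background-crossing position downstream of the profile peak.

    The moving-mean smoothed profile locates the peak, sets the threshold
    scale, and anchors the run detection (the first run of ``run_bins``
    consecutive sub-threshold smoothed bins downstream of the peak), which
    suppresses single-bin noise crossings.  The position itself is then
    refined on the raw profile: walking back from the run start to the last
    raw bin at or above threshold and interpolating linearly inside the
    crossing bin, so smoothing does not smear a sharp front.
    """
    config = config or FrontConfig()
    raw = profile.values
    smoothed = _smooth(raw, config.smooth_bins)
    peak = float(smoothed.max())
    threshold = background + config.threshold_frac * (peak - background)
    if peak <= threshold:
        raise FrontDetectionError("profile peak does not exceed threshold")
    i0 = int(np.argmax(smoothed))
    below = smoothed < threshold
    k = config.run_bins
    j = None
    for i in range(i0 + 1, raw.size - k + 1):
        if below[i:i + k].all():
            j = i
            break
    if j is None:
        raise FrontDetectionError("front beyond window")
    pos = profile.positions
    i = j - 1
    while i > i0 and raw[i] < threshold:
        i -= 1
    if i < 0 or raw[i] < threshold:
        position = float(pos[j])
    else:
        frac = (raw[i] - threshold) / max(raw[i] - raw[i + 1], 1e-300)
        frac = min(max(frac, 0.0), 1.0)
        position = float(pos[i] + frac * profile.bin_size)
    if position <= 0:
        raise FrontDetectionError("front at or upstream of the anchor")
    return WaveFront(position=position, background=background,
                     threshold=threshold)


def estimate_rate(front_a: float, t_a: float, front_b: float,
                  t_b: float) -> RateEstimate:
    """Elongation rate from front displacement between two labeling times.

    With ``t_a == 0`` (front_a is just the pause offset) the single-timepoint
    form ``front_b / t_b`` is used.
    """
    if t_b <= t_a or t_a < 0:
        raise ValueError("need t_b > t_a >= 0")
    if front_b <= front_a:
        raise ValueError(
            "non-increasing front positions: front detection likely failed")
    if t_a == 0:
        return RateEstimate(rate=front_b / t_b / 1000.0,
                            method="single-timepoint")
    return RateEstimate(rate=(front_b - front_a) / (t_b - t_a) / 1000.0,
                        method="two-timepoint")


def bootstrap_rate(coverage_a: StrandedCoverage, coverage_b: StrandedCoverage,
                   genes_a, genes_b, t_a: float, t_b: float,
                   window_a: tuple[int, int], window_b: tuple[int, int],
                   n_boot: int = 200, seed: int = 0,
                   config: FrontConfig | None = None,
                   max_failure_frac: float = 0.2) -> RateEstimate:
    """Gene-resampling bootstrap CI around the two-timepoint rate.

    ``coverage_a``/``coverage_b`` may each be a single track or a list of
    replicate tracks (replicate profiles are averaged before calling).
    Genes are resampled with replacement independently for each timepoint's
    filtered set; profiles are rebuilt from cached per-gene rows, fronts
    re-called, and the rate re-estimated.  The CI is the [2.5, 97.5]
    percentile band.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    config = config or FrontConfig()
    rng = np.random.default_rng([int(seed), 409])

    def as_list(cov):
        return list(cov) if isinstance(cov, (list, tuple)) else [cov]

    covs_a, covs_b = as_list(coverage_a), as_list(coverage_b)
    bin_size = covs_a[0].bin_size
    mats = []
    for covs, genes, window in ((covs_a, genes_a, window_a),
                                (covs_b, genes_b, window_b)):
        mat, _ = replicate_average_matrix(covs, genes, "TSS", window)
        mats.append(mat)

    def front_from(mat, window, idx=None):
        vals = (mat if idx is None else mat[idx]).mean(axis=0)
        prof = MetageneProfile("TSS", bin_size, window, vals, mat.shape[0])
        bg = estimate_background(prof, config)
        return detect_wavefront(prof, bg, config).position

    fa = front_from(mats[0], window_a)
    fb = front_from(mats[1], window_b)
    point = estimate_rate(fa, t_a, fb, t_b)

    rates, failures = [], 0
    for _ in range(n_boot):
        ia = rng.integers(0, mats[0].shape[0], size=mats[0].shape[0])
        ib = rng.integers(0, mats[1].shape[0], size=mats[1].shape[0])
        try:
            ra = front_from(mats[0], window_a, ia)
            rb = front_from(mats[1], window_b, ib)
            rates.append(estimate_rate(ra, t_a, rb, t_b).rate)
        except (FrontDetectionError, ValueError):
            failures += 1
    if failures > max_failure_frac * n_boot:
        raise FrontDetectionError(
            f"{failures}/{n_boot} bootstrap resamples failed front detection")
    lo, hi = np.percentile(rates, [2.5, 97.5])
    return RateEstimate(rate=point.rate, method=point.method,
                        ci=(float(lo), float(hi)))


# ---------------------------------------------------------------------------
# profile TSV I/O (for the CLI and the analysis drivers)


def write_profile(profile: MetageneProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# anchor={profile.anchor} bin_size={profile.bin_size} "
                 f"up={profile.window[0]} down={profile.window[1]} "
                 f"n_genes={profile.n_genes}\n")
        fh.write("position\tvalue\n")
        for p, v in zip(profile.positions, profile.values):
            fh.write(f"{int(p)}\t{float(v)!r}\n")


def read_profile(path) -> MetageneProfile:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("profile file lacks metadata header")
        meta = dict(kv.split("=") for kv in header[1:].split())
        fh.readline()  # column header
        values = [float(line.split("\t")[1]) for line in fh if line.strip()]
    return MetageneProfile(
        anchor=meta["anchor"],
        bin_size=int(meta["bin_size"]),
        window=(int(meta["up"]), int(meta["down"])),
        values=np.array(values),
        n_genes=int(meta["n_genes"]),
    )
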