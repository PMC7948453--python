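"""Window counting, normalization, fold-change classes, and ratio statistics.

Implements the quantitative readouts of the nascent-RNA comparisons:
spike-in or library-size normalization, the FC > 1.5 up/down/unchanged
classifier on pseudocounted normalized counts, RPKM expression filtering,
TSS-distal/proximal processivity ratios, post-TES readthrough density, the
distance-stratified neighbor-gene comparison, and the rank-sum test used for
group contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneModel, Peak, StrandedCoverage

__all__ = [
    "WindowCount",
    "DiffResult",
    "count_window",
    "erna_windows",
    "normalize_counts",
    "classify_expressed",
    "gene_rpkm",
    "fold_change",
    "diff_table",
    "processivity_ratio",
    "tes_readthrough",
    "stratify_by_distance",
    "rank_sum_test",
    "bh_adjust",
]

FC_THRESHOLD = 1.5


@dataclass
class WindowCount:
    id: str
    raw: float
    normalized: float
    rpkm: float | None = None

    def __post_init__(self):
        if self.raw < 0:
            raise ValueError("raw count must be >= 0")


@dataclass
class DiffResult:
    id: str
    count_wt: float
    count_null: float
    fc: float
    klass: str

    def __post_init__(self):
        expected = classify_fc(self.fc)
        if self.klass != expected:
            raise ValueError(
                f"class {self.klass!r} inconsistent with fc={self.fc}")


def classify_fc(fc: float, threshold: float = FC_THRESHOLD) -> str:
    if fc > threshold:
        return "up"
    if fc < 1.0 / threshold:
        return "down"
    return "unchanged"


def count_window(coverage: StrandedCoverage, chrom: str, start: int, end: int,
                 strand_mode: str = "both", strand: str | None = None) -> float:
    """Read mass over [start, end), pro-rata at the edges.

    ``strand_mode``: "sense"/"antisense" need ``strand`` (the feature's
    strand); "both" sums the two strands.  Out-of-bounds windows are clipped
    with a warning (by the coverage container).
    """
    if strand_mode == "both":
        return (coverage.window_sum(chrom, "+", start, end)
                + coverage.window_sum(chrom, "-", start, end))
    if strand is None:
        raise ValueError("sense/antisense counting needs the feature strand")
    if strand_mode == "sense":
        return coverage.window_sum(chrom, strand, start, end)
    if strand_mode == "antisense":
        flipped = "-" if strand == "+" else "+"
        return coverage.window_sum(chrom, flipped, start, end)
    raise ValueError(f"unknown strand_mode {strand_mode!r}")


def erna_windows(peaks, assembly, pad: int = 1_000) -> list[Peak]:
    """Peak-centered eRNA windows: each peak padded by ``pad`` bp both sides,
    clipped to the chromosome.  Counting over these is always both-strand
    (eRNAs are bidirectional)."""
    if pad < 0:
        raise ValueError("pad must be >= 0")
    out = []
    for p in peaks:
        length = assembly.length(p.chrom)
        out.append(Peak(p.chrom, max(0, p.start - pad),
                        min(length, p.end + pad), p.name, p.score))
    return out


def normalize_counts(counts: pd.DataFrame, mode: str = "spike",
                     spike_counts: pd.DataFrame | None = None,
                     library_totals: dict | None = None) -> pd.DataFrame:
    """Scale raw count columns (one per condition) to a common footing.

    spike mode: per-condition factor = median(known abundance / observed
    spike count), multiplied in — anchoring conditions to the exogenous
    standard.  library mode: per-million scaling by the library totals.

    ``counts`` is indexed by feature id with one column per condition.
    ``spike_counts`` needs columns species/abundance/condition/observed.
    """
    out = counts.astype(float).copy()
    if mode == "spike":
        if spike_counts is None:
            raise ValueError("spike mode needs spike_counts")
        for cond in out.columns:
            sub = spike_counts[spike_counts["condition"] == cond]
            if len(sub) == 0:
                raise ValueError(f"no spike-in rows for condition {cond!r}")
            if (sub["observed"] <= 0).all():
                raise ValueError(f"all spike counts zero for {cond!r}")
            ok = sub["observed"] > 0
            factor = float(np.median(sub.loc[ok, "abundance"]
                                     / sub.loc[ok, "observed"]))
            out[cond] *= factor
        return out
    if mode == "library":
        if library_totals is None:
            raise ValueError("library mode needs library_totals")
        for cond in out.columns:
            total = library_totals[cond]
            if total <= 0:
                raise ValueError(f"non-positive library total for {cond!r}")
            out[cond] *= 1e6 / total
        return out
    raise ValueError(f"unknown normalization mode {mode!r}")


def gene_rpkm(coverage: StrandedCoverage, gene: GeneModel) -> float:
    """Sense-strand reads per kb per million mapped reads over the gene body."""
    raw = coverage.window_sum(gene.chrom, gene.strand, gene.start, gene.end)
    total = coverage.total_reads
    if total <= 0:
        return 0.0
    return raw / (gene.length / 1000.0) / (total / 1e6)


def classify_expressed(genes, coverage: StrandedCoverage,
                       threshold_rpkm: float = 0.5):
    """Genes with gene-body RPKM strictly above the threshold."""
    if threshold_rpkm < 0:
        raise ValueError("threshold must be >= 0")
    return [g for g in genes if gene_rpkm(coverage, g) > threshold_rpkm]


def fold_change(wt: float, null: float, pseudocount: float = 1.0,
                id: str = ".") -> DiffResult:
    """Pseudocounted fold change null/wt with the FC > 1.5 class rule."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    fc = (null + pseudocount) / (wt + pseudocount)
    return DiffResult(id=id, count_wt=wt, count_null=null, fc=fc,
                      klass=classify_fc(fc))


def diff_table(normalized: pd.DataFrame, wt_col: str = "wt",
               null_col: str = "null", pseudocount: float = 1.0) -> pd.DataFrame:
    """Vectorized fold_change over a normalized count table."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    fc = (normalized[null_col] + pseudocount) / (normalized[wt_col] + pseudocount)
    klass = np.where(fc > FC_THRESHOLD, "up",
                     np.where(fc < 1.0 / FC_THRESHOLD, "down", "unchanged"))
    return pd.DataFrame(
        {
            "wt": normalized[wt_col],
            "null": normalized[null_col],
            "fc": fc,
            "class": klass,
        },
        index=normalized.index,
    )


def processivity_ratio(coverage: StrandedCoverage, gene: GeneModel,
                       proximal: tuple[int, int] = (1_000, 5_000),
                       distal: tuple[int, int] = (5_000, 1_000)) -> float | None:
    """Distal/proximal mean sense density over the gene body.

    ``proximal`` is (from, to) bp downstream of the TSS; ``distal`` is
    (from, to) bp upstream of the TES.  Genes too short to host both windows,
    or with zero proximal signal, are dropped (None, with a warning).
    """
    p0, p1 = proximal
    d0, d1 = distal
    if gene.length < p1 + d0:
        warnings.warn(f"gene {gene.gene_id} too short for processivity windows",
                      stacklevel=2)
        return None
    if gene.strand == "+":
        prox = (gene.tss + p0, gene.tss + p1)
        dist = (gene.tes - d0, gene.tes - d1)
    else:
        prox = (gene.tss - p1, gene.tss - p0)
        dist = (gene.tes + d1, gene.tes + d0)
    prox_mean = coverage.window_sum(gene.chrom, gene.strand, *prox) \
        / (prox[1] - prox[0])
    dist_mean = coverage.window_sum(gene.chrom, gene.strand, *dist) \
        / (dist[1] - dist[0])
    if prox_mean <= 0:
        warnings.warn(f"gene {gene.gene_id}: zero proximal signal",
                      stacklevel=2)
        return None
    return dist_mean / prox_mean


def tes_readthrough(coverage: StrandedCoverage, gene: GeneModel,
                    downstream_bp: int = 10_000, neighbors=None) -> float:
    """Mean sense-strand density (reads/bp) over (TES, TES + downstream].

    Clipped at the chromosome edge and, if ``neighbors`` (other gene models)
    are given, at the nearest downstream neighbor's span.
    """
    length = coverage.assembly.length(gene.chrom)
    if gene.strand == "+":
        lo, hi = gene.tes, min(gene.tes + downstream_bp, length)
        if neighbors:
            for n in neighbors:
                if n.chrom == gene.chrom and n.start >= gene.tes:
                    hi = min(hi, n.start)
    else:
        lo, hi = max(gene.tes - downstream_bp, 0), gene.tes
        if neighbors:
            for n in neighbors:
                if n.chrom == gene.chrom and n.end <= gene.tes:
                    lo = max(lo, n.end)
    if hi <= lo:
        return 0.0
    return coverage.window_sum(gene.chrom, gene.strand, lo, hi) / (hi - lo)


def stratify_by_distance(genes, enhancers,
                         breaks=(0, 20_000, 40_000, 60_000)) -> pd.DataFrame:
    """Assign each gene to a distance stratum of its nearest enhancer.

    Distance is enhancer-edge to gene-TSS (0 if the TSS lies inside an
    enhancer).  Bins are [b_i, b_{i+1}) — a gene exactly 20 kb away falls in
    the 20–40 kb stratum — and genes beyond the last break are excluded.
    """
    breaks = list(breaks)
    rows = []
    for g in genes:
        best = None
        for e in enhancers:
            if e.chrom != g.chrom:
                continue
            d = max(0, e.start - g.tss, g.tss - e.end)
            if best is None or d < best[0]:
                best = (d, e.name)
        if best is None:
            continue
        d, ename = best
        idx = np.searchsorted(breaks[1:], d, side="right")
        if idx >= len(breaks) - 1:
            continue
        label = f"{breaks[idx] // 1000}-{breaks[idx + 1] // 1000}kb"
        rows.append((g.gene_id, ename, d, label))
    return pd.DataFrame(rows, columns=["gene_id", "enhancer", "distance",
                                       "stratum"])


def rank_sum_test(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) between two groups.

    Exact enumeration for small tie-free samples, normal approximation with
    tie correction otherwise.  Returns (U statistic, p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs n >= 3")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 20 and not ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg FDR adjustment for batched tests."""
    return multipletests(np.asarray(pvalues, dtype=float),
                         method="fdr_bh")[1]
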