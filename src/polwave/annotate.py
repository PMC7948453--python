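"""Peak-to-feature assignment, intergenic classification, enhancer overlap
taxonomy, bound genes, and enrichment tertiles.

Feature categories follow the annotatePeaks-style priority on the peak
midpoint: promoter (TSS −1 kb…+100 bp) > TTS (TES −100 bp…+1 kb) > gene
body > intergenic.  Gene models here are single-exon, so genic-body peaks
are not subdivided into exon/intron.  The gene span used for "intergenic"
and "bound" is the strand-aware [TSS − 0.5 kb, TES] window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import GeneModel, GenomeAssembly, Peak

__all__ = [
    "FeatureAnnotation",
    "AnnotationConfig",
    "gene_span",
    "classify_intergenic",
    "assign_feature",
    "annotate_peaks",
    "feature_distribution",
    "overlap_enhancers",
    "bind_genes",
    "tertile_by_enrichment",
]

CATEGORIES = ("promoter", "tts", "genic_body", "intergenic")


@dataclass
class AnnotationConfig:
    """Feature windows in bp around the strand-aware TSS/TES."""

    promoter_up: int = 1_000     # upstream of TSS
    promoter_down: int = 100     # downstream of TSS
    tts_up: int = 100            # upstream of TES
    tts_down: int = 1_000        # downstream of TES
    span_pad: int = 500          # TSS-side pad for the gene span rule


@dataclass
class FeatureAnnotation:
    peak: str
    category: str
    nearest_gene: str | None
    distance_to_tss: int | None  # signed, downstream positive

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def gene_span(gene: GeneModel, pad: int = 500) -> tuple[int, int]:
    """The [TSS − pad, TES] interval in genomic coordinates (half-open)."""
    if gene.strand == "+":
        return max(0, gene.start - pad), gene.end
    return gene.start, gene.end + pad


def _gene_tree(genes, pad: int) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        lo, hi = gene_span(g, pad)
        trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi, g)
    return trees


def classify_intergenic(peak: Peak, genes, pad: int = 500,
                        trees: dict | None = None) -> bool:
    """True iff the peak overlaps no gene's [TSS − pad, TES] span."""
    if trees is None:
        trees = _gene_tree(genes, pad)
    tree = trees.get(peak.chrom)
    return tree is None or not tree.overlaps(peak.start, peak.end)


def _signed_tss_distance(gene: GeneModel, pos: int) -> int:
    return pos - gene.tss if gene.strand == "+" else gene.tss - pos


def assign_feature(peak: Peak, genes, config: AnnotationConfig | None = None,
                   trees: dict | None = None) -> FeatureAnnotation:
    """Single feature category for a peak, by midpoint with priority.

    Ties across genes go to the smallest |distance to TSS|, then to the
    lower-coordinate gene.
    """
    config = config or AnnotationConfig()
    mid = peak.midpoint
    if trees is None:
        reach = max(config.promoter_up, config.promoter_down,
                    config.tts_up, config.tts_down, config.span_pad)
        trees = {}
        for g in genes:
            trees.setdefault(g.chrom, IntervalTree()).addi(
                g.start - reach, g.end + reach, g)
    tree = trees.get(peak.chrom)
    candidates = [iv.data for iv in tree[mid]] if tree is not None else []

    def tss_key(g: GeneModel):
        return (abs(_signed_tss_distance(g, mid)), g.start, g.gene_id)

    best = None  # (priority, gene)
    for g in sorted(candidates, key=tss_key):
        d_tss = _signed_tss_distance(g, mid)
        d_tes = mid - g.tes if g.strand == "+" else g.tes - mid
        if -config.promoter_up <= d_tss <= config.promoter_down:
            cat = "promoter"
        elif -config.tts_up <= d_tes <= config.tts_down:
            cat = "tts"
        elif g.start <= mid < g.end:
            cat = "genic_body"
        else:
            continue
        prio = CATEGORIES.index(cat)
        if best is None or prio < best[0]:
            best = (prio, g)
    if best is None:
        return FeatureAnnotation(peak.name, "intergenic", None, None)
    _, g = best
    return FeatureAnnotation(peak.name, CATEGORIES[best[0]], g.gene_id,
                             int(_signed_tss_distance(g, mid)))


def annotate_peaks(peaks, genes,
                   config: AnnotationConfig | None = None) -> pd.DataFrame:
    """Vectorized assign_feature over a peak set (shared lookup tree)."""
    config = config or AnnotationConfig()
    reach = max(config.promoter_up, config.promoter_down,
                config.tts_up, config.tts_down, config.span_pad)
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(
            g.start - reach, g.end + reach, g)
    rows = []
    for p in peaks:
        ann = assign_feature(p, genes, config, trees=trees)
        rows.append((p.name, ann.category, ann.nearest_gene,
                     ann.distance_to_tss))
    return pd.DataFrame(rows, columns=["peak", "category", "nearest_gene",
                                       "distance_to_tss"])


def feature_distribution(peaks, genes, assembly: GenomeAssembly,
                         config: AnnotationConfig | None = None) -> pd.DataFrame:
    """Per-category peak fractions next to the genome-wide bp fractions.

    The genome background partitions every base by the same priority the
    peaks get (promoter over TTS over body over intergenic).
    """
    config = config or AnnotationConfig()
    ann = annotate_peaks(peaks, genes, config)
    peak_counts = ann["category"].value_counts()

    codes = {"intergenic": 0, "genic_body": 1, "tts": 2, "promoter": 3}
    genome_bp = {c: 0 for c in CATEGORIES}
    for chrom in assembly.chrom_names:
        length = assembly.length(chrom)
        lab = np.zeros(length, dtype=np.uint8)
        for g in genes:
            if g.chrom != chrom:
                continue
            lab[g.start:g.end] = np.maximum(lab[g.start:g.end],
                                            codes["genic_body"])
        for g in genes:
            if g.chrom != chrom:
                continue
            if g.strand == "+":
                lo, hi = g.tes - config.tts_up, g.tes + config.tts_down
            else:
                lo, hi = g.tes - config.tts_down, g.tes + config.tts_up
            lo, hi = max(0, lo), min(length, hi)
            lab[lo:hi] = np.maximum(lab[lo:hi], codes["tts"])
        for g in genes:
            if g.chrom != chrom:
                continue
            if g.strand == "+":
                lo, hi = g.tss - config.promoter_up, g.tss + config.promoter_down
            else:
                lo, hi = g.tss - config.promoter_down, g.tss + config.promoter_up
            lo, hi = max(0, lo), min(length, hi)
            lab[lo:hi] = codes["promoter"]
        counts = np.bincount(lab, minlength=4)
        for cat, code in codes.items():
            genome_bp[cat] += int(counts[code])

    total_bp = assembly.total_length
    n_peaks = len(peaks)
    rows = []
    for cat in CATEGORIES:
        rows.append((
            cat,
            int(peak_counts.get(cat, 0)),
            peak_counts.get(cat, 0) / n_peaks if n_peaks else 0.0,
            genome_bp[cat] / total_bp,
        ))
    return pd.DataFrame(rows, columns=["category", "n_peaks", "peak_fraction",
                                       "genome_fraction"])


def overlap_enhancers(intergenic_peaks, enhancers,
                      superenhancers) -> pd.DataFrame:
    """Label each peak superenhancer / enhancer / none (SE takes priority,
    overlap is >= 1 bp)."""
    def tree_of(intervals):
        trees: dict[str, IntervalTree] = {}
        for p in intervals:
            trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)
        return trees

    se_trees = tree_of(superenhancers)
    enh_trees = tree_of(enhancers)
    rows = []
    for p in intergenic_peaks:
        se = p.chrom in se_trees and se_trees[p.chrom].overlaps(p.start, p.end)
        if se:
            label = "superenhancer"
        elif p.chrom in enh_trees and enh_trees[p.chrom].overlaps(p.start,
                                                                  p.end):
            label = "enhancer"
        else:
            label = "none"
        rows.append((p.name, label))
    return pd.DataFrame(rows, columns=["peak", "overlap_class"])


def bind_genes(peaks, genes, pad: int = 500) -> set[str]:
    """Genes with >= 1 peak overlapping their [TSS − pad, TES] span.

    The logical complement of :func:`classify_intergenic` over the same span
    definition: a peak is intergenic iff it binds no gene.
    """
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)
    bound = set()
    for g in genes:
        lo, hi = gene_span(g, pad)
        tree = trees.get(g.chrom)
        if tree is not None and tree.overlaps(lo, hi):
            bound.add(g.gene_id)
    return bound


def tertile_by_enrichment(genes, peaks, pad: int = 500) -> pd.DataFrame:
    """Rank genes by summed peak score over their span; split into tertiles.

    Boundaries are the 33.3/66.7 percentiles of the per-gene scores; scores
    exactly at a boundary go to the lower tertile, so all-equal scores
    collapse into the low tertile.
    """
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)
    scores = {}
    for g in genes:
        lo, hi = gene_span(g, pad)
        tree = trees.get(g.chrom)
        s = 0.0
        if tree is not None:
            s = sum(iv.data.score for iv in tree.overlap(lo, hi))
        scores[g.gene_id] = s
    vals = np.array(list(scores.values()))
    q1, q2 = np.percentile(vals, [100 / 3, 200 / 3])
    rows = []
    for gid, s in scores.items():
        if s <= q1:
            t = "low"
        elif s <= q2:
            t = "mid"
        else:
            t = "high"
        rows.append((gid, s, t))
    return pd.DataFrame(rows, columns=["gene_id", "score", "tertile"])
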