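"""Coordinate-safe interval algebra over 0-based half-open intervals.

Interval sets are pandas frames with at least ``chrom``, ``start`` and
``end`` columns (the BED frame produced by :mod:`strainreg.io`).  Gene
annotations carry ``gene_id``, ``chrom``, ``strand``, ``tss``, ``start``
and ``end``.

Promoter windows follow the -400..+100 bp definition around the TSS used
throughout the analyses (501 bp, strand-aware, clipped at chromosome
bounds).  Region categories are assigned by the midpoint with precedence
promoter > exon > intron > intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PROMOTER_UPSTREAM = 400
PROMOTER_DOWNSTREAM = 100


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float = 0.0

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

def promoter_window(tss: int, strand: str, chrom: str = ".",
                    chrom_length: int | None = None,
                    upstream: int = PROMOTER_UPSTREAM,
                    downstream: int = PROMOTER_DOWNSTREAM) -> Interval:
    """Strand-aware promoter window covering offsets -upstream..+downstream.

    For a '+' gene with TSS t the window is [t-400, t+101); for a '-' gene
    it is the mirror [t-100, t+401).  Coordinates are clipped at 0 and, when
    known, at the chromosome length.
    """
    if strand == "+":
        start, end = tss - upstream, tss + downstream + 1
    elif strand == "-":
        start, end = tss - downstream, tss + upstream + 1
    else:
        raise ValueError(f"promoter window needs a stranded gene, got {strand!r}")
    start = max(start, 0)
    if chrom_length is not None:
        end = min(end, chrom_length)
    if start >= end:
        raise ValueError(f"promoter window empty after clipping at TSS {tss}")
    return Interval(chrom, start, end, strand)


def promoter_windows(annotation: pd.DataFrame,
                     chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Promoter windows for every gene; one BED-like row per gene."""
    rows = []
    for g in annotation.itertuples(index=False):
        length = chrom_lengths.get(g.chrom) if chrom_lengths else None
        w = promoter_window(int(g.tss), g.strand, g.chrom, length)
        rows.append((w.chrom, w.start, w.end, g.gene_id, 0.0, g.strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "score", "strand"])


# ---------------------------------------------------------------------------
# intersection (sweep via sorted starts + prefix running maxima)
# ---------------------------------------------------------------------------

def _overlap_mask(a: pd.DataFrame, b: pd.DataFrame, min_bp: int) -> np.ndarray:
    """Boolean mask over rows of `a`: overlaps some row of `b` by >= min_bp."""
    if min_bp < 1:
        raise ValueError(f"min_bp must be >= 1, got {min_bp}")
    mask = np.zeros(len(a), dtype=bool)
    if len(a) == 0 or len(b) == 0:
        return mask
    a_idx = np.arange(len(a))
    for chrom, b_chr in b.groupby("chrom", sort=False):
        sel = (a["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        order = np.argsort(b_chr["start"].to_numpy(), kind="stable")
        b_start = b_chr["start"].to_numpy()[order]
        b_end = b_chr["end"].to_numpy()[order]
        # case 1: b starts inside [a.start, a.end - min_bp] and b is long enough
        long_start = np.sort(b_start[(b_end - b_start) >= min_bp])
        # case 2: b starts before a.start; need running max of b.end
        end_cummax = np.maximum.accumulate(b_end) if len(b_end) else b_end
        a_start = a["start"].to_numpy()[sel]
        a_end = a["end"].to_numpy()[sel]
        ok = np.zeros(sel.sum(), dtype=bool)
        if len(long_start):
            lo = np.searchsorted(long_start, a_start, side="left")
            hi = np.searchsorted(long_start, a_end - min_bp, side="right")
            ok |= hi > lo
        before = np.searchsorted(b_start, a_start, side="left")
        has_before = before > 0
        best_end = np.where(has_before, end_cummax[np.maximum(before - 1, 0)], -1)
        ok |= has_before & (best_end >= a_start + min_bp) & \
            (a_end - a_start >= min_bp)
        mask[a_idx[sel]] = ok
    return mask


def intersect(set_a: pd.DataFrame, set_b: pd.DataFrame,
              min_bp: int = 1) -> pd.DataFrame:
    """Members of A overlapping any member of B by at least ``min_bp``."""
    return set_a.loc[_overlap_mask(set_a, set_b, min_bp)]


def overlaps_any(set_a: pd.DataFrame, set_b: pd.DataFrame,
                 min_bp: int = 1) -> np.ndarray:
    """Vector of booleans, one per row of A (same test as :func:`intersect`)."""
    return _overlap_mask(set_a, set_b, min_bp)


# ---------------------------------------------------------------------------
# nearest TSS
# ---------------------------------------------------------------------------

def nearest_tss(interval, annotation: pd.DataFrame):
    """Gene whose TSS is closest to the interval midpoint.

    Returns ``(gene_id, signed_distance)`` or ``(None, None)`` when the
    chromosome has no annotated gene.  The distance is signed relative to
    the gene's orientation: negative upstream of the TSS, positive
    downstream.  Equidistant ties go to the gene with the smaller TSS
    coordinate (then lexicographically smaller id).
    """
    chrom = interval.chrom if hasattr(interval, "chrom") else interval[0]
    if hasattr(interval, "start"):
        mid = (int(interval.start) + int(interval.end)) // 2
    else:
        mid = (int(interval[1]) + int(interval[2])) // 2
    genes = annotation[annotation["chrom"] == chrom]
    if genes.empty:
        return None, None
    tss = genes["tss"].to_numpy()
    dist = np.abs(tss - mid)
    order = np.lexsort((genes["gene_id"].to_numpy(), tss, dist))
    best = genes.iloc[order[0]]
    signed = mid - int(best.tss)
    if best.strand == "-":
        signed = -signed
    return best.gene_id, int(signed)


def nearest_tss_table(intervals: pd.DataFrame,
                      annotation: pd.DataFrame) -> pd.DataFrame:
    """Nearest-TSS assignment for every interval (row order preserved)."""
    out = []
    for row in intervals.itertuples(index=False):
        gene, dist = nearest_tss(row, annotation)
        out.append((gene, dist))
    res = pd.DataFrame(out, columns=["gene_id", "distance"],
                       index=intervals.index)
    return res


# ---------------------------------------------------------------------------
# genomic category annotation
# ---------------------------------------------------------------------------

CATEGORIES = ("promoter", "exon", "intron", "intergenic")


def annotate_region(interval, annotation: pd.DataFrame,
                    promoters: pd.DataFrame | None = None,
                    exons: pd.DataFrame | None = None) -> str:
    """Category of the interval midpoint: promoter > exon > intron > intergenic."""
    if promoters is None:
        promoters = promoter_windows(annotation)
    chrom = interval.chrom if hasattr(interval, "chrom") else interval[0]
    if hasattr(interval, "start"):
        mid = (int(interval.start) + int(interval.end)) // 2
    else:
        mid = (int(interval[1]) + int(interval[2])) // 2
    prom = promoters[promoters["chrom"] == chrom]
    if ((prom["start"] <= mid) & (mid < prom["end"])).any():
        return "promoter"
    if exons is not None:
        exo = exons[exons["chrom"] == chrom]
        if ((exo["start"] <= mid) & (mid < exo["end"])).any():
            return "exon"
    genes = annotation[annotation["chrom"] == chrom]
    if ((genes["start"] <= mid) & (mid < genes["end"])).any():
        return "intron"
    return "intergenic"


def annotate_regions(intervals: pd.DataFrame, annotation: pd.DataFrame,
                     exons: pd.DataFrame | None = None) -> pd.Series:
    promoters = promoter_windows(annotation)
    cats = [annotate_region(row, annotation, promoters, exons)
            for row in intervals.itertuples(index=False)]
    return pd.Series(cats, index=intervals.index, name="category")


# ---------------------------------------------------------------------------
# differential-accessibility classification
# ---------------------------------------------------------------------------

def classify_peaks(peak_counts: pd.DataFrame, design: pd.DataFrame,
                   treated, control, fdr_threshold: float = 0.001):
    """Label peaks constitutive / induced / repressed from a pairwise NB test.

    ``treated`` / ``control`` select samples as in
    :func:`strainreg.countmodels.pairwise_de`.  Induced means
    FDR <= ``fdr_threshold`` with positive log2 fold-change; repressed is
    symmetric; everything else (including all-zero peaks, which are flagged
    ``low_information``) is constitutive.
    """
    from .countmodels import pairwise_de

    de = pairwise_de(peak_counts, design, control, treated)
    frame = de.frame.copy()
    sig = frame["fdr"] <= fdr_threshold
    label = np.where(sig & (frame["lfc"] > 0), "induced",
                     np.where(sig & (frame["lfc"] < 0), "repressed",
                              "constitutive"))
    label[frame["low_information"].to_numpy()] = "constitutive"
    frame["label"] = label
    return frame[["lfc", "pvalue", "fdr", "label", "low_information"]]


def strain_peak_overlap(peaks_a: pd.DataFrame, peaks_b: pd.DataFrame):
    """Partition peak sets by >= 1 bp cross-set overlap.

    Returns ``(shared_a, shared_b, unique_a, unique_b)`` frames; each peak
    is counted once however many partners it overlaps, and shared/unique
    are disjoint and exhaustive within each set.
    """
    in_b = overlaps_any(peaks_a, peaks_b)
    in_a = overlaps_any(peaks_b, peaks_a)
    return (peaks_a.loc[in_b], peaks_b.loc[in_a],
            peaks_a.loc[~in_b], peaks_b.loc[~in_a])
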