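"""Chromatin loops and topologically associating domains.

Loops arrive as BEDPE frames (``chrom1,start1,end1,chrom2,start2,end2``),
TADs as BED frames.  A loop is *promoter-based* when one anchor overlaps a
gene's promoter window by >= 1 bp; the opposite anchor is then that gene's
promoter-distal region.  TAD boundary regions are the 100-kb flank
upstream of each TAD start and downstream of each TAD end; promoter-to-
boundary distances are interval gaps (0 on overlap).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import overlaps_any

DEFAULT_FLANK = 100_000


def canonical_loops(loops: pd.DataFrame) -> pd.DataFrame:
    """Order anchors so anchor A starts first; drop inter-chromosomal loops."""
    intra = loops[loops["chrom1"] == loops["chrom2"]].copy()
    flip = intra["start1"] > intra["start2"]
    for a, b in (("chrom1", "chrom2"), ("start1", "start2"), ("end1", "end2")):
        tmp = intra.loc[flip, a].copy()
        intra.loc[flip, a] = intra.loc[flip, b]
        intra.loc[flip, b] = tmp
    return intra


def _anchor_frame(loops: pd.DataFrame, which: int) -> pd.DataFrame:
    cols = {1: ("chrom1", "start1", "end1"), 2: ("chrom2", "start2", "end2")}[which]
    return pd.DataFrame({
        "chrom": loops[cols[0]].to_numpy(),
        "start": loops[cols[1]].to_numpy(),
        "end": loops[cols[2]].to_numpy(),
    }, index=loops.index)


def promoter_loops(loops: pd.DataFrame, promoters: pd.DataFrame) -> dict:
    """Map each gene to the distal anchors of its promoter-based loops.

    ``promoters`` is a BED-like frame with the gene id in ``name``.  For a
    loop whose anchor overlaps a gene's promoter, the *other* anchor is
    recorded as a distal region for that gene; when both anchors overlap
    promoters each gene receives the opposite anchor.  Loops touching no
    promoter contribute nothing.
    """
    loops = canonical_loops(loops)
    out: dict[str, list] = {}
    a1 = _anchor_frame(loops, 1)
    a2 = _anchor_frame(loops, 2)
    for (anchors, others) in ((a1, a2), (a2, a1)):
        for i in range(len(loops)):
            arow = anchors.iloc[i]
            hit = promoters[(promoters["chrom"] == arow["chrom"])
                            & (promoters["start"] < arow["end"])
                            & (promoters["end"] > arow["start"])]
            for gene in hit["name"]:
                orow = others.iloc[i]
                out.setdefault(gene, []).append(
                    (orow["chrom"], int(orow["start"]), int(orow["end"])))
    return {g: pd.DataFrame(sorted(set(v)),
                            columns=["chrom", "start", "end"])
            for g, v in out.items()}


def accessible_distal_elements(gene_anchors: dict,
                               atac_peaks: pd.DataFrame) -> dict:
    """Per gene, the ATAC peaks overlapping any of its distal anchors.

    Genes with no accessible distal element are retained with empty frames.
    """
    out = {}
    for gene, anchors in gene_anchors.items():
        if len(anchors) == 0:
            out[gene] = atac_peaks.iloc[0:0]
            continue
        mask = overlaps_any(atac_peaks, anchors)
        out[gene] = atac_peaks.loc[mask]
    return out


def tad_boundaries(tads: pd.DataFrame, flank: int = DEFAULT_FLANK,
                   chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Two boundary regions per TAD: [start-flank, start) and [end, end+flank).

    Regions are clipped at chromosome bounds (and dropped if emptied by
    clipping); duplicates from adjacent TADs are retained.
    """
    if flank < 0:
        raise ValueError(f"flank must be >= 0, got {flank}")
    rows = []
    for i, tad in enumerate(tads.itertuples(index=False)):
        limit = chrom_lengths.get(tad.chrom) if chrom_lengths else None
        s0 = max(int(tad.start) - flank, 0)
        if s0 < tad.start:
            rows.append((tad.chrom, s0, int(tad.start), f"tad{i}_start", "start", i))
        e1 = int(tad.end) + flank
        if limit is not None:
            e1 = min(e1, limit)
        if e1 > tad.end:
            rows.append((tad.chrom, int(tad.end), e1, f"tad{i}_end", "end", i))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "side", "tad_index"])


def distance_to_boundary(promoter, boundaries: pd.DataFrame):
    """Minimum gap (bp) between a promoter interval and any boundary region.

    Returns 0 when they overlap and None when the chromosome carries no
    boundary region.
    """
    chrom = promoter.chrom if hasattr(promoter, "chrom") else promoter[0]
    if hasattr(promoter, "start"):
        p_start, p_end = int(promoter.start), int(promoter.end)
    else:
        p_start, p_end = int(promoter[1]), int(promoter[2])
    sub = boundaries[boundaries["chrom"] == chrom]
    if sub.empty:
        return None
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    gaps = np.maximum.reduce([starts - p_end, p_start - ends,
                              np.zeros(len(sub), dtype=np.int64)])
    return int(gaps.min())


def boundary_distances(promoters: pd.DataFrame,
                       boundaries: pd.DataFrame) -> pd.Series:
    """Distance-to-boundary per promoter row (gene id from ``name``)."""
    vals, idx = [], []
    for row in promoters.itertuples(index=False):
        d = distance_to_boundary(row, boundaries)
        idx.append(row.name)
        vals.append(np.nan if d is None else d)
    return pd.Series(vals, index=idx, name="boundary_distance")


def compare_tads(tads_a: pd.DataFrame, tads_b: pd.DataFrame,
                 reciprocal: float = 0.5):
    """Partition TADs by reciprocal overlap.

    A TAD in A is shared when some TAD in B overlaps it with
    overlap/len_A >= ``reciprocal`` and overlap/len_B >= ``reciprocal``;
    symmetrically for B.  Returns ``(shared_a, shared_b, unique_a,
    unique_b)``.
    """
    if not 0 < reciprocal <= 1:
        raise ValueError(f"reciprocal threshold {reciprocal} outside (0, 1]")

    def shared_mask(x: pd.DataFrame, y: pd.DataFrame) -> np.ndarray:
        mask = np.zeros(len(x), dtype=bool)
        for i, xi in enumerate(x.itertuples(index=False)):
            sub = y[y["chrom"] == xi.chrom]
            if sub.empty:
                continue
            ov = (np.minimum(sub["end"].to_numpy(), xi.end)
                  - np.maximum(sub["start"].to_numpy(), xi.start))
            len_x = xi.end - xi.start
            len_y = (sub["end"] - sub["start"]).to_numpy()
            ok = (ov >= reciprocal * len_x) & (ov >= reciprocal * len_y)
            mask[i] = bool(ok.any())
        return mask

    in_b = shared_mask(tads_a, tads_b)
    in_a = shared_mask(tads_b, tads_a)
    return (tads_a.loc[in_b], tads_b.loc[in_a],
            tads_a.loc[~in_b], tads_b.loc[~in_a])
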