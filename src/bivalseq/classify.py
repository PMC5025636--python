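"""Promoter classification from island calls and peak-geometry summaries.

A promoter is *bivalent* when an H3K4me3 island and an H3K27me3 island
both intersect the TSS window and also intersect each other (mark
co-occurrence on overlapping domains).  Promoters where both marks hit
the window but the islands do not mutually overlap are flagged
``bivalent_zonal``; in the default strict mode they fall into class
``none``, while the loose co-occurrence mode classes them bivalent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import ValidationError

CLASSES = ("bivalent", "K4_exclusive", "K27_exclusive", "none")


@dataclass(frozen=True)
class ClassifyParams:
    """TSS window radius: 2500 bp by default, 5000 bp as the broader
    "enriched promoter" alternative; both definitions are in active use
    for this assay."""

    radius: int = 2500
    require_overlap: bool = True

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValidationError("radius must be > 0")


def _trees(islands: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in islands.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e), name)
            for s, e, name in zip(sub["start"], sub["end"], sub["name"])
        )
    return trees


def classify_promoters(
    genes: pd.DataFrame,
    islands_k4: pd.DataFrame,
    islands_k27: pd.DataFrame,
    params: ClassifyParams = ClassifyParams(),
) -> pd.DataFrame:
    """Assign each transcript to bivalent / K4_exclusive / K27_exclusive / none.

    The classes partition the classified promoters.  Output columns:
    transcript_id, promoter_class, k4_islands, k27_islands (comma-joined
    island names), overlap_bp (largest mutual K4xK27 overlap within the
    hits), bivalent_zonal (both marks hit the window but no island pair
    overlaps).
    """
    if genes["transcript_id"].duplicated().any():
        dups = genes.loc[genes["transcript_id"].duplicated(), "transcript_id"].tolist()
        raise ValidationError(f"duplicate transcript ids: {dups[:5]}")
    t4 = _trees(islands_k4)
    t27 = _trees(islands_k27)
    rows = []
    for g in genes.itertuples():
        lo, hi = g.tss - params.radius, g.tss + params.radius
        hits4 = sorted(t4.get(g.chrom, IntervalTree()).overlap(lo, hi))
        hits27 = sorted(t27.get(g.chrom, IntervalTree()).overlap(lo, hi))
        overlap_bp = 0
        for a in hits4:
            for b in hits27:
                overlap_bp = max(overlap_bp, min(a.end, b.end) - max(a.begin, b.begin))
        zonal = bool(hits4 and hits27 and overlap_bp <= 0)
        if hits4 and hits27 and overlap_bp > 0:
            cls = "bivalent"
        elif hits4 and hits27:
            cls = "bivalent" if not params.require_overlap else "none"
        elif hits4:
            cls = "K4_exclusive"
        elif hits27:
            cls = "K27_exclusive"
        else:
            cls = "none"
        rows.append(
            (g.transcript_id, cls,
             ",".join(h.data for h in hits4), ",".join(h.data for h in hits27),
             int(max(overlap_bp, 0)), zonal)
        )
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "promoter_class", "k4_islands", "k27_islands",
                 "overlap_bp", "bivalent_zonal"],
    )


def overlap_zones(
    islands_k4: pd.DataFrame, islands_k27: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Pairwise K4 x K27 island intersections and their width summary.

    Returns the zone intervals (with parent island names) and a dict of
    min/median/max widths.  Nested islands return the inner island whole.
    """
    rows = []
    for chrom in sorted(set(islands_k4["chrom"]) & set(islands_k27["chrom"])):
        a = islands_k4[islands_k4["chrom"] == chrom].sort_values("start")
        b = islands_k27[islands_k27["chrom"] == chrom].sort_values("start")
        bi = 0
        b_start = b["start"].to_numpy()
        b_end = b["end"].to_numpy()
        b_name = b["name"].to_numpy()
        for s, e, name in zip(a["start"], a["end"], a["name"]):
            while bi < len(b_start) and b_end[bi] <= s:
                bi += 1
            j = bi
            while j < len(b_start) and b_start[j] < e:
                lo, hi = max(s, b_start[j]), min(e, b_end[j])
                if hi > lo:
                    rows.append((chrom, int(lo), int(hi), name, b_name[j]))
                j += 1
    zones = pd.DataFrame(rows, columns=["chrom", "start", "end", "k4_island", "k27_island"])
    widths = (zones["end"] - zones["start"]).to_numpy()
    summary = {
        "n": int(len(zones)),
        "min_width": int(widths.min()) if len(widths) else 0,
        "median_width": float(np.median(widths)) if len(widths) else 0.0,
        "max_width": int(widths.max()) if len(widths) else 0,
    }
    return zones, summary


def peak_center_offsets(
    islands: pd.DataFrame,
    genes: pd.DataFrame,
    classes: pd.DataFrame | None = None,
    flank: int = 5000,
) -> pd.DataFrame:
    """Strand-oriented island-center offsets from each promoter's TSS.

    For every island intersecting [tss - flank, tss + flank) the oriented
    offset (center - tss) * strand_sign is recorded; class labels are
    joined when a classification table is supplied.
    """
    trees = _trees(islands)
    rows = []
    for g in genes.itertuples():
        sign = 1 if g.strand == "+" else -1
        for h in trees.get(g.chrom, IntervalTree()).overlap(g.tss - flank, g.tss + flank):
            center = (h.begin + h.end) // 2
            rows.append((g.transcript_id, h.data, int((center - g.tss) * sign)))
    out = pd.DataFrame(rows, columns=["transcript_id", "island", "offset"])
    if classes is not None:
        out = out.merge(
            classes[["transcript_id", "promoter_class"]], on="transcript_id", how="left"
        )
    return out


def center_histogram(
    offsets: pd.DataFrame, flank: int = 5000, bin_size: int = 10
) -> dict[str, np.ndarray]:
    """Histogram of oriented peak-center offsets, per promoter class."""
    edges = np.arange(-flank, flank + bin_size, bin_size)
    groups = (
        offsets.groupby("promoter_class")
        if "promoter_class" in offsets.columns
        else [("all", offsets)]
    )
    return {str(cls): np.histogram(sub["offset"], bins=edges)[0] for cls, sub in groups}
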