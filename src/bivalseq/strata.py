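"""CpG-island, expression and methylation stratification of promoters.

Promoter CpG status is intersection of any CpG island with the TSS
+/-1500 bp window; alternate transcripts of a gene whose sibling TSS has
an island, but whose own TSS does not, are removed from the analysis.
Expression and CpG density are ranked into quintiles.  Methylation
classes come from Infinium-style beta values: at least one well-detected
probe with beta >= 0.75 is "methylated", all surviving probes below 0.25
is "unmethylated".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import ValidationError


@dataclass(frozen=True)
class StrataParams:
    cpg_radius: int = 1500
    n_quantiles: int = 5
    beta_methylated: float = 0.75
    beta_unmethylated: float = 0.25
    detect_p_max: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.beta_unmethylated < self.beta_methylated < 1:
            raise ValidationError("require 0 < beta_unmethylated < beta_methylated < 1")


def assign_cpg_status(
    genes: pd.DataFrame,
    cpg_islands: pd.DataFrame,
    params: StrataParams = StrataParams(),
) -> pd.DataFrame:
    """Per-transcript CpG status: cpg / non_cpg / removed (+ density).

    A transcript has a CpG island iff any island intersects
    [tss - cpg_radius, tss + cpg_radius); with several, the maximum
    density is taken.  An island-less transcript whose sibling transcript
    (same gene) has one is removed.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in cpg_islands.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e), float(d))
            for s, e, d in zip(sub["start"], sub["end"], sub["density"])
        )
    has_island = []
    density = []
    for g in genes.itertuples():
        hits = trees.get(g.chrom, IntervalTree()).overlap(
            g.tss - params.cpg_radius, g.tss + params.cpg_radius
        )
        has_island.append(bool(hits))
        density.append(max((h.data for h in hits), default=np.nan))
    out = pd.DataFrame(
        {
            "transcript_id": genes["transcript_id"].to_numpy(),
            "gene_id": genes["gene_id"].to_numpy(),
            "has_island": has_island,
            "cpg_density": density,
        }
    )
    sibling_has = out.groupby("gene_id")["has_island"].transform("any")
    out["cpg_status"] = np.select(
        [out["has_island"], ~out["has_island"] & sibling_has],
        ["cpg", "removed"],
        default="non_cpg",
    )
    return out[["transcript_id", "cpg_status", "cpg_density"]]


def quantile_groups(values: pd.Series | dict, n_quantiles: int = 5) -> pd.Series:
    """Rank-based assignment into n near-equal groups (1 = lowest).

    Group sizes differ by at most one, with the remainder going to the
    lowest groups; ties are broken by stable input order.
    """
    ser = pd.Series(values) if not isinstance(values, pd.Series) else values
    m = len(ser)
    if m < n_quantiles:
        raise ValidationError(f"need >= {n_quantiles} ids, got {m}")
    order = np.argsort(ser.to_numpy(), kind="mergesort")  # stable: ties keep input order
    base, rem = divmod(m, n_quantiles)
    sizes = [base + (1 if g < rem else 0) for g in range(n_quantiles)]
    groups = np.empty(m, dtype=np.int64)
    start = 0
    for g, size in enumerate(sizes, start=1):
        groups[order[start:start + size]] = g
        start += size
    return pd.Series(groups, index=ser.index, name="group")


def methylation_classes(
    meth: pd.DataFrame, params: StrataParams = StrataParams()
) -> pd.Series:
    """Per-transcript methylated / unmethylated / ambiguous / no_data.

    Probes with detection p above ``detect_p_max`` are dropped first.
    """
    out = {}
    for tid, sub in meth.groupby("transcript_id", sort=False):
        betas = sub.loc[sub["detect_p"] <= params.detect_p_max, "beta"]
        if len(betas) == 0:
            out[tid] = "no_data"
        elif (betas >= params.beta_methylated).any():
            out[tid] = "methylated"
        elif (betas < params.beta_unmethylated).all():
            out[tid] = "unmethylated"
        else:
            out[tid] = "ambiguous"
    return pd.Series(out, name="methylation_class")


def expression_quintiles(
    expression: pd.DataFrame, n_quantiles: int = 5
) -> pd.Series:
    """Per-gene expression quintiles (1 = lowest).

    Gene expression is the maximum log2 intensity over its probes.
    """
    col = "log2_intensity" if "log2_intensity" in expression.columns else "expression"
    per_gene = expression.groupby("gene_id", sort=False)[col].max()
    return quantile_groups(per_gene, n_quantiles)


def enhancer_cpg_split(
    enhancers: pd.DataFrame, cpg_islands: pd.DataFrame
) -> pd.Series:
    """True for enhancers overlapping (>= 1 bp) any CpG island."""
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in cpg_islands.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e)) for s, e in zip(sub["start"], sub["end"])
        )
    flags = [
        bool(trees.get(e.chrom, IntervalTree()).overlap(e.start, e.end))
        for e in enhancers.itertuples()
    ]
    return pd.Series(flags, index=enhancers["name"].to_numpy(), name="with_cpg")
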