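"""BED / annotation-table I/O and read-level filtering.

The mapped-read filters mirror the usual single-end ChIP-seq hygiene for
this kind of data: duplicate removal at a redundancy threshold of one,
mapping quality strictly greater than 20, and at most one mismatch (NM
tag).  Plain BED input carries no MAPQ/NM, so the quality filter is only
applicable to records that come with a quality sidecar (the simulator
emits one).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    GENE_COLUMNS,
    READ_COLUMNS,
    GenomeLayout,
    ParseError,
    ValidationError,
    empty_reads,
    sort_reads,
    validate_reads,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterParams:
    """Read-level filter thresholds.

    ``redundancy_threshold`` — max reads kept per (chrom, start, strand) key;
    ``max_mismatch`` — max NM value retained; ``min_mapq`` — reads must map
    with quality strictly greater than this.
    """

    redundancy_threshold: int = 1
    max_mismatch: int = 1
    min_mapq: int = 20

    def __post_init__(self) -> None:
        if self.redundancy_threshold < 1:
            raise ValidationError("redundancy_threshold must be >= 1")
        if self.max_mismatch < 0 or self.min_mapq < 0:
            raise ValidationError("filter thresholds must be >= 0")


# ---------------------------------------------------------------------------
# BED reads


def load_reads(path, layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Load a BED3/BED6 read file into the canonical read-set frame.

    Strand is taken from column 6 when present, else defaults to ``+`` with
    a logged warning.  Malformed lines raise :class:`ParseError` with the
    1-based line number.
    """
    path = Path(path)
    rows = []
    warned = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = fields[3] if len(fields) > 3 else f"r{lineno}"
            try:
                score = int(float(fields[4])) if len(fields) > 4 else 0
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            if len(fields) > 5:
                strand = fields[5]
                if strand not in ("+", "-"):
                    raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            else:
                strand = "+"
                if not warned:
                    log.warning("%s: no strand column; defaulting to '+'", path)
                    warned = True
            rows.append((fields[0], start, end, name, score, strand))
    if not rows:
        return empty_reads()
    reads = pd.DataFrame(rows, columns=READ_COLUMNS)
    reads["start"] = reads["start"].astype(np.int64)
    reads["end"] = reads["end"].astype(np.int64)
    try:
        validate_reads(reads, layout)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
    return reads


def write_reads(reads: pd.DataFrame, path) -> None:
    """Write a read set as BED6, sorted by (chrom, start)."""
    out = sort_reads(reads[READ_COLUMNS].copy())
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Annotation tables


def write_layout(layout: GenomeLayout, path) -> None:
    layout.to_frame().to_csv(path, sep="\t", index=False)


def load_layout(path) -> GenomeLayout:
    return GenomeLayout.from_frame(pd.read_csv(path, sep="\t"))


def write_genes(genes: pd.DataFrame, path) -> None:
    genes[GENE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")


def load_genes(path) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t")
    missing = set(GENE_COLUMNS) - set(genes.columns)
    if missing:
        raise ParseError(f"{path}: missing gene columns {sorted(missing)}")
    if genes["transcript_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate transcript_ids")
    return genes


def write_intervals(df: pd.DataFrame, path, extra: list[str] | None = None) -> None:
    """Write intervals as BED: chrom/start/end/name plus optional extras."""
    cols = ["chrom", "start", "end", "name"] + (extra or [])
    out = df[cols].sort_values(["chrom", "start"], kind="mergesort")
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def load_cpg_islands(path) -> pd.DataFrame:
    """CpG-island BED: chrom, start, end, name, density (CpG per bp)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "density"],
    )
    if (df["start"] >= df["end"]).any():
        raise ValidationError(f"{path}: CpG island with start >= end")
    if (df["density"] <= 0).any():
        raise ValidationError(f"{path}: CpG density must be > 0")
    return df


def load_enhancers(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "name"],
    )
    if (df["start"] >= df["end"]).any():
        raise ValidationError(f"{path}: enhancer with start >= end")
    return df


def load_expression(path) -> pd.DataFrame:
    """Expression table: gene_id, probe_id, log2_intensity."""
    return pd.read_csv(path, sep="\t")


def load_methylation(path) -> pd.DataFrame:
    """Methylation table: transcript_id, probe_id, beta, detect_p."""
    df = pd.read_csv(path, sep="\t")
    for col in ("beta", "detect_p"):
        if ((df[col] < 0) | (df[col] > 1)).any():
            raise ValidationError(f"{path}: {col} outside [0, 1]")
    return df


def load_qc_sidecar(path) -> pd.DataFrame:
    """Per-read quality sidecar: name, mapq, nm."""
    return pd.read_csv(path, sep="\t")


def attach_qc(reads: pd.DataFrame, qc: pd.DataFrame) -> pd.DataFrame:
    """Join MAPQ/NM columns onto a read set by read name."""
    return reads.merge(qc[["name", "mapq", "nm"]], on="name", how="left")


# ---------------------------------------------------------------------------
# Filters


def filter_redundant(reads: pd.DataFrame, redundancy_threshold: int = 1) -> pd.DataFrame:
    """Keep at most ``redundancy_threshold`` reads per (chrom, start, strand).

    Retention is deterministic: reads are put in canonical sorted order and
    the first occurrences per key are kept, so the result does not depend on
    input record order.  Idempotent.
    """
    if redundancy_threshold < 1:
        raise ValidationError("redundancy_threshold must be >= 1")
    if len(reads) == 0:
        return reads.reset_index(drop=True)
    out = reads.sort_values(
        ["chrom", "start", "end", "strand", "name"], kind="mergesort"
    ).reset_index(drop=True)
    rank = out.groupby(["chrom", "start", "strand"], sort=False).cumcount()
    return out[rank < redundancy_threshold].reset_index(drop=True)


def filter_quality(reads: pd.DataFrame, params: FilterParams = FilterParams()) -> pd.DataFrame:
    """Keep reads with MAPQ strictly above ``min_mapq`` and NM <= ``max_mismatch``."""
    for col in ("mapq", "nm"):
        if col not in reads.columns:
            raise ValidationError(
                f"quality filter requires a {col!r} column "
                "(attach a QC sidecar; plain BED skips this stage)"
            )
    keep = (reads["mapq"] > params.min_mapq) & (reads["nm"] <= params.max_mismatch)
    return reads[keep].reset_index(drop=True)
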