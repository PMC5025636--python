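"""Shared genomic containers and conventions.

All coordinates throughout the package are 0-based, half-open (BED
semantics).  Read sets, islands, gene models, CpG islands and enhancers
are plain :class:`pandas.DataFrame` objects with fixed column layouts so
that every stage of the pipeline can be inspected, serialized and diffed
as flat text.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Column layout of a read set (BED6).  ``start < end``; ``strand`` in {+, -}.
READ_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

#: Column layout of a gene/transcript annotation table.
GENE_COLUMNS = [
    "gene_id",
    "transcript_id",
    "chrom",
    "tss",
    "strand",
    "archetype",
    "expression",
    "cpg_density",
]


class BivalseqError(Exception):
    """Base class for package errors."""


class ParseError(BivalseqError):
    """Malformed input file; message carries the path and line number."""


class ValidationError(BivalseqError):
    """Structurally valid input violating a semantic invariant."""


class SizingError(BivalseqError):
    """Requested synthetic genome cannot accommodate the annotation."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths of a (miniature) genome.

    Parameters
    ----------
    chroms
        Sequence of ``(name, length_bp)`` pairs.  Names must be unique and
        lengths strictly positive.
    """

    chroms: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        chroms = tuple((str(c), int(n)) for c, n in self.chroms)
        object.__setattr__(self, "chroms", chroms)
        names = [c for c, _ in chroms]
        if len(set(names)) != len(names):
            raise ValidationError("chromosome names must be unique")
        if any(n <= 0 for _, n in chroms):
            raise ValidationError("chromosome lengths must be positive")

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chroms]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chroms)

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_length(self) -> int:
        return sum(n for _, n in self.chroms)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.chroms, columns=["chrom", "length"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenomeLayout":
        return cls(tuple(zip(df["chrom"].astype(str), df["length"].astype(int))))


def empty_reads() -> pd.DataFrame:
    """Empty read set with the canonical column layout."""
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "name": pd.Series(dtype=str),
            "score": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
        }
    )


def make_reads(chrom, start, end, strand, name=None, score=0) -> pd.DataFrame:
    """Assemble a read set from parallel arrays."""
    start = np.asarray(start, dtype=np.int64)
    end = np.asarray(end, dtype=np.int64)
    n = len(start)
    if name is None:
        name = [f"r{i}" for i in range(n)]
    df = pd.DataFrame(
        {
            "chrom": np.broadcast_to(np.asarray(chrom, dtype=object), (n,)).copy(),
            "start": start,
            "end": end,
            "name": name,
            "score": np.broadcast_to(np.asarray(score), (n,)).astype(np.int64),
            "strand": np.broadcast_to(np.asarray(strand, dtype=object), (n,)).copy(),
        }
    )
    return df


def sort_reads(reads: pd.DataFrame) -> pd.DataFrame:
    """Sort by (chrom, start, end, strand) — the canonical on-disk order."""
    return reads.sort_values(
        ["chrom", "start", "end", "strand"], kind="mergesort"
    ).reset_index(drop=True)


def validate_reads(reads: pd.DataFrame, layout: GenomeLayout | None = None) -> None:
    """Raise :class:`ValidationError` on interval or chromosome violations."""
    if len(reads) == 0:
        return
    if (reads["start"] >= reads["end"]).any():
        bad = reads.index[(reads["start"] >= reads["end"])][0]
        raise ValidationError(f"read {bad}: start >= end")
    if not reads["strand"].isin(["+", "-"]).all():
        raise ValidationError("strand must be '+' or '-'")
    if layout is not None:
        lengths = layout.lengths
        unknown = set(reads["chrom"]) - set(lengths)
        if unknown:
            raise ValidationError(f"unknown chromosomes: {sorted(unknown)}")
        ends = reads["chrom"].map(lengths)
        if (reads["end"] > ends).any() or (reads["start"] < 0).any():
            raise ValidationError("read extends past chromosome bounds")
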