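"""TSS-anchored and enhancer-scaled coverage profiles, input-normalized.

Coverage is extended-fragment overlap per 10-bp bin: each read is
extended to the fragment size (200 bp) from its 5' end, and a bin counts
the fragments overlapping it.  Rows are strand-oriented so transcription
always runs left to right; the TSS is the left edge of the central bin.
Average profiles are normalized as a ratio of category means,
(mean_chip + pc) / (mean_input + pc), with a small pseudocount keeping
zero-input bins finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import GenomeLayout, ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProfileParams:
    flank: int = 5000
    bin_size: int = 10
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.flank % self.bin_size != 0:
            raise ValidationError("flank must be divisible by bin_size")

    @property
    def n_bins(self) -> int:
        return 2 * self.flank // self.bin_size


def _fragments(reads: pd.DataFrame, fragment_size: int) -> pd.DataFrame:
    """Extend each read to fragment_size from its 5' end."""
    plus = reads["strand"].to_numpy() == "+"
    start = np.where(plus, reads["start"].to_numpy(),
                     reads["end"].to_numpy() - fragment_size)
    return pd.DataFrame(
        {"chrom": reads["chrom"].to_numpy(), "start": start,
         "end": start + fragment_size}
    )


def tss_profile(
    reads: pd.DataFrame,
    genes: pd.DataFrame,
    params: ProfileParams = ProfileParams(),
    fragment_size: int = 200,
) -> pd.DataFrame:
    """Promoters x bins fragment-coverage matrix over [-flank, +flank).

    Bin k of a row counts the extended fragments overlapping
    [tss - flank + k*bin, tss - flank + (k+1)*bin) in oriented
    coordinates; minus-strand rows are column-reversed so upstream is
    always on the left.
    """
    nb = params.n_bins
    bin_size = params.bin_size
    frags = _fragments(reads, fragment_size) if len(reads) else None
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if frags is not None:
        for chrom, sub in frags.groupby("chrom", sort=False):
            order = np.argsort(sub["start"].to_numpy(), kind="mergesort")
            by_chrom[chrom] = (sub["start"].to_numpy()[order],
                               sub["end"].to_numpy()[order])
    mat = np.zeros((len(genes), nb), dtype=np.int64)
    offsets = np.arange(-params.flank, params.flank, bin_size)
    for ri, g in enumerate(genes.itertuples()):
        if g.chrom not in by_chrom:
            continue
        fs, fe = by_chrom[g.chrom]
        w0 = g.tss - params.flank
        w1 = g.tss + params.flank
        lo = np.searchsorted(fs, w0 - fragment_size, "right")
        hi = np.searchsorted(fs, w1, "left")
        if hi <= lo:
            continue
        s = fs[lo:hi]
        e = fe[lo:hi]
        keep = e > w0
        s, e = s[keep], e[keep]
        b0 = np.clip((s - w0) // bin_size, 0, nb - 1)
        b1 = np.clip((e - 1 - w0) // bin_size, 0, nb - 1)
        diff = np.zeros(nb + 1, dtype=np.int64)
        np.add.at(diff, b0, 1)
        np.add.at(diff, b1 + 1, -1)
        row = np.cumsum(diff[:-1])
        if g.strand == "-":
            row = row[::-1]
        mat[ri] = row
    return pd.DataFrame(mat, index=genes["transcript_id"].to_numpy(), columns=offsets)


def average_profile(matrix: pd.DataFrame, subset=None) -> pd.Series:
    """Per-bin arithmetic mean over (a subset of) rows."""
    sub = matrix if subset is None else matrix.loc[list(subset)]
    if len(sub) == 0:
        raise ValidationError("average_profile: empty subset")
    return sub.mean(axis=0)


def normalize_to_input(avg_chip, avg_input, pseudocount: float = 0.5):
    """Elementwise (chip + pc) / (input + pc) ratio of average profiles."""
    chip = np.asarray(avg_chip, dtype=float)
    inp = np.asarray(avg_input, dtype=float)
    if chip.shape != inp.shape:
        raise ValidationError(
            f"profile length mismatch: {chip.shape} vs {inp.shape}"
        )
    out = (chip + pseudocount) / (inp + pseudocount)
    if isinstance(avg_chip, pd.Series):
        return pd.Series(out, index=avg_chip.index)
    return out


def _pileup(fs: np.ndarray, fe: np.ndarray, w0: int, w1: int) -> np.ndarray:
    """Per-base fragment pileup over [w0, w1)."""
    n = w1 - w0
    diff = np.zeros(n + 1, dtype=np.int64)
    s = np.clip(fs - w0, 0, n)
    e = np.clip(fe - w0, 0, n)
    keep = e > s
    np.add.at(diff, s[keep], 1)
    np.add.at(diff, e[keep], -1)
    return np.cumsum(diff[:-1])


def enhancer_profile(
    reads: pd.DataFrame,
    enhancers: pd.DataFrame,
    n_intervals: int = 10,
    flank: int = 5000,
    bin_size: int = 10,
    fragment_size: int = 200,
) -> np.ndarray:
    """Length-scaled enhancer metaprofile.

    Each enhancer body is split into ``n_intervals`` equal-width intervals
    (mean per-base coverage each); flanks are covered at ``bin_size``
    resolution.  The concatenated [left flank | body | right flank]
    vectors are averaged over enhancers.  Enhancers narrower than
    ``n_intervals`` bp are skipped with a warning.  Normalize against an
    input profile computed the same way via :func:`normalize_to_input`.
    """
    nfb = flank // bin_size
    frags = _fragments(reads, fragment_size) if len(reads) else None
    by_chrom = {}
    if frags is not None:
        for chrom, sub in frags.groupby("chrom", sort=False):
            order = np.argsort(sub["start"].to_numpy(), kind="mergesort")
            by_chrom[chrom] = (sub["start"].to_numpy()[order],
                               sub["end"].to_numpy()[order])
    acc = np.zeros(2 * nfb + n_intervals, dtype=float)
    used = 0
    for enh in enhancers.itertuples():
        width = enh.end - enh.start
        if width < n_intervals:
            log.warning("enhancer %s narrower than %d bp; skipped",
                        getattr(enh, "name", "?"), n_intervals)
            continue
        w0, w1 = enh.start - flank, enh.end + flank
        if enh.chrom in by_chrom:
            fs, fe = by_chrom[enh.chrom]
            lo = np.searchsorted(fs, w0 - fragment_size, "right")
            hi = np.searchsorted(fs, w1, "left")
            cov = _pileup(fs[lo:hi], fe[lo:hi], w0, w1)
        else:
            cov = np.zeros(w1 - w0, dtype=np.int64)
        left = cov[:flank].reshape(nfb, bin_size).mean(axis=1)
        right = cov[flank + width:].reshape(nfb, bin_size).mean(axis=1)
        body = cov[flank:flank + width]
        edges = np.floor(np.linspace(0, width, n_intervals + 1)).astype(int)
        body_means = np.array(
            [body[edges[i]:edges[i + 1]].mean() for i in range(n_intervals)]
        )
        acc += np.concatenate([left, body_means, right])
        used += 1
    if used == 0:
        raise ValidationError("no usable enhancers (all narrower than n_intervals)")
    return acc / used


def sample_matched_random(
    layout: GenomeLayout,
    enhancers: pd.DataFrame,
    n: int = 1000,
    seed: int = 0,
    exclusions: pd.DataFrame | None = None,
    max_tries: int = 1000,
) -> pd.DataFrame:
    """Random genomic intervals width-matched to the enhancer sample.

    When ``n`` equals the number of enhancers the output width multiset is
    exactly the input's; otherwise widths are resampled from it.
    Placement is uniform over the genome, rejecting overlaps with
    ``exclusions``; persistent placement failure raises.
    """
    rng = np.random.default_rng(seed)
    widths = (enhancers["end"] - enhancers["start"]).to_numpy()
    if n == len(widths):
        widths = rng.permutation(widths)
    else:
        widths = rng.choice(widths, size=n, replace=True)
    excl: dict[str, IntervalTree] = {}
    if exclusions is not None:
        for chrom, sub in exclusions.groupby("chrom", sort=False):
            excl[chrom] = IntervalTree.from_tuples(
                (int(s), int(e)) for s, e in zip(sub["start"], sub["end"])
            )
    names = np.array(layout.names, dtype=object)
    lens = np.array([L for _, L in layout.chroms], dtype=float)
    rows = []
    for k, w in enumerate(widths):
        placed = False
        for _ in range(max_tries):
            ci = int(rng.choice(len(names), p=lens / lens.sum()))
            limit = int(lens[ci]) - int(w)
            if limit <= 0:
                continue
            s = int(rng.integers(0, limit + 1))
            if names[ci] in excl and excl[names[ci]].overlap(s, s + int(w)):
                continue
            rows.append((names[ci], s, s + int(w), f"rand{k:04d}"))
            placed = True
            break
        if not placed:
            raise ValidationError(
                f"failed to place random interval of width {w} after {max_tries} tries"
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_profile(profile: pd.Series | np.ndarray, path, offsets=None) -> None:
    """Two-column TSV (offset, value) for an averaged profile."""
    if isinstance(profile, pd.Series):
        df = pd.DataFrame({"offset": profile.index, "value": profile.to_numpy()})
    else:
        if offsets is None:
            offsets = np.arange(len(profile))
        df = pd.DataFrame({"offset": offsets, "value": profile})
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
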