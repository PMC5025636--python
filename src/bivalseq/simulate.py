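"""Synthetic mononucleosome ChIP / sequential-ChIP data generator.

The generator builds a miniature genome in which every promoter belongs to
one of five chromatin archetypes and every simulated cell carries its own
copy of each promoter-proximal nucleosome.  This makes the distinction at
the heart of the analysis explicit and controllable:

* **true mononucleosome bivalency** — a single nucleosome copy carrying
  both H3K4me3 and H3K27me3, produced at the TSS-proximal position of
  ``bivalent`` promoters with probability ``f_biv``;
* **zonal / population bivalency** — overlapping K4 and K27 domains where
  each *cell* carries only one of the two marks, so no individual
  nucleosome is bivalent even though bulk ChIP tracks overlap;
* **flow-through** — single-marked H3K4me3 nucleosomes nonspecifically
  carried through the primary (anti-H3K27me3) IP into the secondary IP at
  rate ``phi``, the false-positive source a sequential-ChIP experiment
  must control for.

Promoters sit on a phased array of 147-bp nucleosomes.  A
nucleosome-depleted region (NDR) immediately downstream of active TSSs is
modelled two ways at once: occupancy is thinned (visible in the input
track) and marks on the remaining NDR-resident nucleosomes are attenuated
(fragile nucleosomes retain marks with probability
``ndr_mark_retention``).  The attenuation is what produces the central
dip of the input-normalized H3K4me3 profile; occupancy thinning alone
would divide out of the chip/input ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    BivalseqError,
    GenomeLayout,
    SizingError,
    ValidationError,
    empty_reads,
    make_reads,
    sort_reads,
)
from . import read_io

ARCHETYPES = ("bivalent", "K4_only", "K27_only", "silent_methylated", "none")

#: Per-track RNG stream offsets derived from the master seed.
_STREAMS = {
    "world": 1,
    "states": 2,
    "chip_K4": 3,
    "chip_K27": 4,
    "chip_H2AZ": 5,
    "seqchip": 6,
    "input": 7,
}

_PROFILE_FLANK = 5000  # bp of promoter context the tiled arrays must cover


@dataclass
class SimConfig:
    """Full parameterization of the cell-population chromatin model.

    Key rates: ``f_biv`` — fraction of TSS-proximal nucleosome copies at
    bivalent promoters carrying both marks (the rest carry one mark per
    cell, i.e. population heterogeneity); ``phi`` — flow-through rate of
    K4-only nucleosomes into the sequential IP; ``eps1``/``eps2`` —
    primary/secondary IP capture efficiencies; ``bg_rate`` — uniform
    background weight per bp, relative to per-nucleosome capture weights.
    ``zonal_k4_span``/``zonal_k27_span`` are (lo, hi) ranges from which a
    per-gene mark-domain width is drawn, sized so that called K4 islands
    fall around 1–4 kb and K27 islands around 4–8 kb.
    """

    n_cells: int = 100
    nucleosome_len: int = 147
    linker_len: int = 53
    ndr_start: int = 0
    ndr_end: int = 800
    ndr_occupancy: float = 0.8
    ndr_mark_retention: float = 0.1
    proximal_radius: int = 150
    f_biv: float = 0.8
    zonal_k4_span: tuple[int, int] = (1000, 4000)
    zonal_k27_span: tuple[int, int] = (4000, 8000)
    k27_upstream_offset: int = 2000
    eps1: float = 0.8
    eps2: float = 0.8
    phi: float = 0.0
    bg_rate: float = 1e-5
    depth: int = 200_000
    read_len: int = 36
    frag_jitter: int = 20
    jitter: int = 0
    dup_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nucleosome_len != 147:
            raise ValidationError("nucleosome_len is fixed at 147 bp")
        for name in ("ndr_occupancy", "f_biv", "ndr_mark_retention", "eps1", "eps2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if not 0.0 < self.eps1 <= 1.0 or not 0.0 < self.eps2 <= 1.0:
            raise ValidationError("capture efficiencies must be in (0, 1]")
        if not 0.0 <= self.phi < 1.0:
            raise ValidationError("phi must be in [0, 1)")
        if self.bg_rate < 0:
            raise ValidationError("bg_rate must be >= 0")
        if self.n_cells < 1 or self.depth < 0:
            raise ValidationError("n_cells >= 1 and depth >= 0 required")
        self.zonal_k4_span = _span_range(self.zonal_k4_span)
        self.zonal_k27_span = _span_range(self.zonal_k27_span)

    @property
    def phase(self) -> int:
        """Nucleosome repeat length (footprint + linker)."""
        return self.nucleosome_len + self.linker_len

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed) % (2**31), _STREAMS[stream]])
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["zonal_k4_span"] = list(d["zonal_k4_span"])
        d["zonal_k27_span"] = list(d["zonal_k27_span"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


def _span_range(v) -> tuple[int, int]:
    if np.isscalar(v):
        return (int(v), int(v))
    lo, hi = int(v[0]), int(v[1])
    if lo <= 0 or hi < lo:
        raise ValidationError("span range must satisfy 0 < lo <= hi")
    return (lo, hi)


@dataclass
class World:
    """Miniature genome plus all annotation the analysis consumes."""

    layout: GenomeLayout
    genes: pd.DataFrame         # GENE_COLUMNS + k4_span, k27_span
    cpg: pd.DataFrame           # chrom, start, end, name, density
    enhancers: pd.DataFrame     # chrom, start, end, name
    expression: pd.DataFrame    # gene_id, probe_id, log2_intensity
    methylation: pd.DataFrame   # transcript_id, probe_id, beta, detect_p


@dataclass
class ChromatinStates:
    """Per-cell nucleosome occupancy and mark flags.

    ``positions`` holds one row per nucleosome position (147-bp footprint);
    the boolean matrices are positions x cells.  A mark flag is only set on
    copies that are actually present in that cell.
    """

    layout: GenomeLayout
    positions: pd.DataFrame  # chrom, start, end, transcript_id, archetype, od, proximal, ndr
    occ: np.ndarray
    k4: np.ndarray
    k27: np.ndarray
    h2az: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.occ.shape[1]


# ---------------------------------------------------------------------------
# World construction

_EXPR_PRIORS = {
    "bivalent": (8.0, 1.0),
    "K4_only": (12.0, 1.0),
    "K27_only": (7.0, 1.0),
    "silent_methylated": (6.5, 0.5),
    "none": (9.0, 1.5),
}

_CPG_ARCHETYPES = {"bivalent", "K4_only", "silent_methylated"}


def _archetype_counts(mix: dict[str, float], n: int) -> list[str]:
    """Largest-remainder apportionment of n genes to archetypes."""
    total = sum(mix.values())
    quotas = {a: n * w / total for a, w in mix.items()}
    counts = {a: int(math.floor(q)) for a, q in quotas.items()}
    rem = n - sum(counts.values())
    for a in sorted(quotas, key=lambda a: quotas[a] - counts[a], reverse=True)[:rem]:
        counts[a] += 1
    out: list[str] = []
    for a in mix:
        out.extend([a] * counts[a])
    return out


def build_world(
    cfg: SimConfig,
    n_genes: int = 200,
    n_enhancers: int = 40,
    archetype_mix: dict[str, float] | None = None,
    spacing: int | None = None,
    chrom_length: int | None = None,
    n_chroms: int = 2,
    cpg_enhancer_fraction: float = 0.3,
) -> World:
    """Lay out genes, CpG islands, enhancers and array tables.

    Promoters are placed on a regular grid with ``spacing`` at least twice
    (profile flank + max K27 domain span) so islands of neighbouring genes
    can never merge.  Bivalent, K4-only and silent-methylated promoters
    receive a CpG island near the TSS; silent-methylated promoters receive
    hypermethylated probes (beta >= 0.75).  Deterministic under the seed.
    """
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    rng = cfg.rng("world")
    if archetype_mix is None:
        archetype_mix = {a: 1.0 for a in ARCHETYPES if a != "none"}
    unknown = set(archetype_mix) - set(ARCHETYPES)
    if unknown:
        raise ValidationError(f"unknown archetypes {sorted(unknown)}")

    min_spacing = 2 * (_PROFILE_FLANK + cfg.zonal_k27_span[1])
    if spacing is None:
        spacing = min_spacing
    elif spacing < min_spacing:
        raise ValidationError(
            f"spacing {spacing} < required {min_spacing} (2 x (flank + K27 span))"
        )
    margin = spacing

    n_chroms = min(n_chroms, n_genes)
    per_chrom = [n_genes // n_chroms + (1 if i < n_genes % n_chroms else 0)
                 for i in range(n_chroms)]
    if chrom_length is not None:
        capacity = max(0, (chrom_length - 2 * margin) // spacing + 1)
        if capacity * n_chroms < n_genes:
            raise SizingError(
                f"genome too small: {n_chroms} x {chrom_length} bp holds at most "
                f"{capacity * n_chroms} genes at spacing {spacing}, need {n_genes}"
            )
        lengths = [chrom_length] * n_chroms
    else:
        lengths = [2 * margin + max(k - 1, 0) * spacing for k in per_chrom]
    layout = GenomeLayout(tuple((f"chrS{i + 1}", L) for i, L in enumerate(lengths)))

    archetypes = np.array(_archetype_counts(archetype_mix, n_genes), dtype=object)
    rng.shuffle(archetypes)

    rows = []
    gi = 0
    for ci, (chrom, _) in enumerate(layout.chroms):
        for j in range(per_chrom[ci]):
            tss = margin + j * spacing
            rows.append((chrom, tss))
            gi += 1
    strands = rng.choice(["+", "-"], size=n_genes)
    mu_sd = np.array([_EXPR_PRIORS[a] for a in archetypes])
    expression = rng.normal(mu_sd[:, 0], mu_sd[:, 1])
    k4_span = rng.integers(cfg.zonal_k4_span[0], cfg.zonal_k4_span[1] + 1, n_genes)
    k27_span = rng.integers(cfg.zonal_k27_span[0], cfg.zonal_k27_span[1] + 1, n_genes)

    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i:04d}" for i in range(n_genes)],
            "transcript_id": [f"g{i:04d}.t1" for i in range(n_genes)],
            "chrom": [r[0] for r in rows],
            "tss": np.array([r[1] for r in rows], dtype=np.int64),
            "strand": strands,
            "archetype": archetypes,
            "expression": np.round(expression, 4),
            "k4_span": k4_span,
            "k27_span": k27_span,
        }
    )

    # CpG islands near the TSS of CpG-class archetypes
    cpg_rows = []
    for i, g in genes.iterrows():
        if g.archetype in _CPG_ARCHETYPES:
            center = int(g.tss + rng.integers(-300, 301))
            half = int(rng.integers(200, 751))
            cpg_rows.append(
                (g.chrom, center - half, center + half,
                 f"cpg{len(cpg_rows):04d}", float(np.round(rng.uniform(0.04, 0.12), 5)))
            )
    cpg = pd.DataFrame(cpg_rows, columns=["chrom", "start", "end", "name", "density"])
    # record the promoter CpG density on the gene table (NaN for non-CpG genes)
    dens = np.full(n_genes, np.nan)
    j = 0
    for i, g in genes.iterrows():
        if g.archetype in _CPG_ARCHETYPES:
            dens[i] = cpg["density"].iloc[j]
            j += 1
    genes["cpg_density"] = np.round(dens, 5)

    # Enhancers midway between promoter arrays (never inside profile windows)
    gaps = []
    for ci, (chrom, _) in enumerate(layout.chroms):
        for j in range(per_chrom[ci] - 1):
            gaps.append((chrom, margin + j * spacing + spacing // 2))
    if n_enhancers > len(gaps):
        raise SizingError(
            f"genome too small: {len(gaps)} intergenic gaps < {n_enhancers} enhancers"
        )
    pick = rng.choice(len(gaps), size=n_enhancers, replace=False)
    enh_rows = []
    cpg_extra = []
    for k, idx in enumerate(sorted(pick)):
        chrom, center = gaps[idx]
        width = int(rng.integers(200, 2001))
        start = center - width // 2
        enh_rows.append((chrom, start, start + width, f"enh{k:03d}"))
        if rng.random() < cpg_enhancer_fraction:
            w = int(min(width, rng.integers(200, 801)))
            s = center - w // 2
            cpg_extra.append(
                (chrom, s, s + w, f"cpgE{k:03d}",
                 float(np.round(rng.uniform(0.04, 0.12), 5)))
            )
    enhancers = pd.DataFrame(enh_rows, columns=["chrom", "start", "end", "name"])
    if cpg_extra:
        cpg = pd.concat(
            [cpg, pd.DataFrame(cpg_extra, columns=cpg.columns)], ignore_index=True
        )
    cpg = cpg.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    # Expression array: two probes per gene around the true intensity
    expr_rows = []
    for i, g in genes.iterrows():
        for p in range(2):
            expr_rows.append(
                (g.gene_id, f"{g.gene_id}.p{p}",
                 float(np.round(g.expression + rng.normal(0, 0.3), 4)))
            )
    expression_tbl = pd.DataFrame(
        expr_rows, columns=["gene_id", "probe_id", "log2_intensity"]
    )

    # Methylation array: hypermethylated probes only at silent promoters
    meth_rows = []
    for i, g in genes.iterrows():
        tid = g.transcript_id
        if g.archetype == "silent_methylated":
            meth_rows.append(
                (tid, f"{tid}.m0", float(np.round(rng.uniform(0.76, 0.97), 4)),
                 float(np.round(rng.uniform(0.001, 0.049), 4)))
            )
            meth_rows.append(
                (tid, f"{tid}.m1", float(np.round(rng.uniform(0.05, 0.20), 4)),
                 float(np.round(rng.uniform(0.001, 0.049), 4)))
            )
        else:
            for p in range(2):
                meth_rows.append(
                    (tid, f"{tid}.m{p}", float(np.round(rng.uniform(0.02, 0.22), 4)),
                     float(np.round(rng.uniform(0.001, 0.049), 4)))
                )
    methylation = pd.DataFrame(
        meth_rows, columns=["transcript_id", "probe_id", "beta", "detect_p"]
    )

    return World(layout, genes, cpg, enhancers, expression_tbl, methylation)


# ---------------------------------------------------------------------------
# Chromatin states


def sample_chromatin_states(world: World, cfg: SimConfig) -> ChromatinStates:
    """Tile phased nucleosomes around each TSS and draw per-cell mark flags.

    Geometry is strand-oriented: the NDR sits downstream of the TSS, the
    K27 domain center is shifted upstream by ``k27_upstream_offset``.  The
    TSS-proximal position (dyad within ``proximal_radius``, outside the
    NDR) is where true bivalency is generated at rate ``f_biv``.
    """
    rng = cfg.rng("states")
    phase = cfg.phase
    C = cfg.n_cells
    K = int(math.ceil((_PROFILE_FLANK + phase) / phase))
    ks = np.arange(-K, K + 1)

    pos_rows = []
    occ_list, k4_list, k27_list, hz_list = [], [], [], []

    expr = world.genes["expression"].to_numpy(dtype=float)
    expr_rank = expr.argsort().argsort() / max(len(expr) - 1, 1)

    for i, g in world.genes.iterrows():
        s = 1 if g.strand == "+" else -1
        od = ks * phase - 73  # oriented dyad offset from the TSS
        if cfg.jitter:
            od = od + rng.integers(-cfg.jitter, cfg.jitter + 1, size=od.size)
        dyad = g.tss + s * od
        start = dyad - 73
        end = dyad + 74
        P = od.size

        in_ndr = (od >= cfg.ndr_start) & (od < cfg.ndr_end)
        proximal = ~in_ndr & (np.abs(od) <= cfg.proximal_radius)
        k4_zone = np.abs(od) <= g.k4_span / 2
        k27_zone = np.abs(od + cfg.k27_upstream_offset) <= g.k27_span / 2

        if g.archetype == "silent_methylated":
            occ = np.ones((P, C), dtype=bool)
        else:
            occ = np.ones((P, C), dtype=bool)
            occ[in_ndr] = rng.random((int(in_ndr.sum()), C)) < cfg.ndr_occupancy

        k4 = np.zeros((P, C), dtype=bool)
        k27 = np.zeros((P, C), dtype=bool)
        if g.archetype == "bivalent":
            both = rng.random((P, C)) < cfg.f_biv
            coin = rng.random((P, C)) < 0.5
            prox = proximal[:, None]
            overlap = (k4_zone & k27_zone & ~proximal)[:, None]
            only4 = (k4_zone & ~k27_zone & ~proximal)[:, None]
            only27 = (k27_zone & ~k4_zone & ~proximal)[:, None]
            k4 = (prox & (both | coin)) | (overlap & coin) | only4
            k27 = (prox & (both | ~coin)) | (overlap & ~coin) | only27
        elif g.archetype == "K4_only":
            k4 = np.broadcast_to(k4_zone[:, None], (P, C)).copy()
        elif g.archetype == "K27_only":
            k27 = np.broadcast_to(k27_zone[:, None], (P, C)).copy()
        # silent_methylated / none: no marks

        if in_ndr.any():
            retain = rng.random((P, C)) < cfg.ndr_mark_retention
            ndr_col = in_ndr[:, None]
            k4 &= ~ndr_col | retain
            k27 &= ~ndr_col | retain
        k4 &= occ
        k27 &= occ

        hz = np.zeros((P, C), dtype=bool)
        if np.isfinite(g.cpg_density):
            p_hz = 1.0 / (1.0 + math.exp(-6.0 * (expr_rank[i] - 0.5)))
            near = np.abs(od) <= 400
            hz[near] = rng.random((int(near.sum()), C)) < p_hz
            hz &= occ

        for j in range(P):
            pos_rows.append(
                (g.chrom, int(start[j]), int(end[j]), g.transcript_id,
                 g.archetype, int(od[j]), bool(proximal[j]), bool(in_ndr[j]))
            )
        occ_list.append(occ)
        k4_list.append(k4)
        k27_list.append(k27)
        hz_list.append(hz)

    positions = pd.DataFrame(
        pos_rows,
        columns=["chrom", "start", "end", "transcript_id", "archetype",
                 "od", "proximal", "ndr"],
    )
    return ChromatinStates(
        world.layout,
        positions,
        np.concatenate(occ_list),
        np.concatenate(k4_list),
        np.concatenate(k27_list),
        np.concatenate(hz_list),
    )


# ---------------------------------------------------------------------------
# Read sampling

_MARK_FLAGS = {"K4": "k4", "K27": "k27", "H2AZ": "h2az"}


def _sample_track(
    states: ChromatinStates,
    weights: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
    prefix: str,
) -> pd.DataFrame:
    """Emit ~depth single-end reads from nucleosome footprints + background.

    Each read of ``read_len`` bp is emitted from the 5' end of the 147-bp
    fragment on a random strand.  A read is background with probability
    proportional to ``bg_rate * genome_length`` against the summed
    nucleosome capture weights.
    """
    layout = states.layout
    w_sig = float(weights.sum())
    w_bg = cfg.bg_rate * layout.total_length
    if w_sig + w_bg == 0.0 or cfg.depth == 0:
        return empty_reads()
    n_total = int(rng.poisson(cfg.depth))
    if n_total == 0:
        return empty_reads()
    n_bg = int(rng.binomial(n_total, w_bg / (w_sig + w_bg)))
    n_sig = n_total - n_bg

    chroms, starts = [], []
    if n_sig > 0:
        idx = rng.choice(len(weights), size=n_sig, p=weights / w_sig)
        fs = states.positions["start"].to_numpy()[idx]
        fe = states.positions["end"].to_numpy()[idx]
        if cfg.frag_jitter > 0:
            # MNase boundary wobble: fragment ends vary a few bp per molecule
            fs = fs + rng.integers(-cfg.frag_jitter, cfg.frag_jitter + 1, n_sig)
            fe = fe + rng.integers(-cfg.frag_jitter, cfg.frag_jitter + 1, n_sig)
        minus = rng.random(n_sig) < 0.5
        rs = np.where(minus, fe - cfg.read_len, fs)
        chroms.append(states.positions["chrom"].to_numpy()[idx])
        starts.append(rs)
        strands_sig = np.where(minus, "-", "+")
    else:
        strands_sig = np.array([], dtype=object)
    if n_bg > 0:
        lens = np.array([L for _, L in layout.chroms], dtype=float)
        ci = rng.choice(len(lens), size=n_bg, p=lens / lens.sum())
        rs = rng.integers(0, (lens[ci] - cfg.read_len + 1).astype(np.int64))
        chroms.append(np.array(layout.names, dtype=object)[ci])
        starts.append(rs)
        strands_bg = np.where(rng.random(n_bg) < 0.5, "-", "+")
    else:
        strands_bg = np.array([], dtype=object)

    chrom = np.concatenate(chroms) if chroms else np.array([], dtype=object)
    start = np.concatenate(starts).astype(np.int64) if starts else np.array([], dtype=np.int64)
    strand = np.concatenate([strands_sig, strands_bg])
    # clamp to chromosome bounds (arrays are placed with ample margins)
    maxs = np.array([layout.length(c) - cfg.read_len for c in chrom], dtype=np.int64)
    start = np.clip(start, 0, maxs)
    end = start + cfg.read_len

    reads = make_reads(chrom, start, end, strand)
    if cfg.dup_rate > 0 and len(reads):
        n_dup = int(rng.binomial(len(reads), cfg.dup_rate))
        if n_dup:
            dup = reads.iloc[rng.integers(0, len(reads), n_dup)]
            reads = pd.concat([reads, dup], ignore_index=True)
    reads = sort_reads(reads)
    reads["name"] = [f"{prefix}{i}" for i in range(len(reads))]
    # alignment-quality sidecar values: mostly confident, a tail of poor reads
    n = len(reads)
    good = rng.random(n) < 0.9
    reads["mapq"] = np.where(good, rng.integers(21, 61, n), rng.integers(0, 21, n))
    reads["nm"] = rng.choice([0, 1, 2], size=n, p=[0.85, 0.12, 0.03])
    return reads


def simulate_chip(
    states: ChromatinStates, mark: str, cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Single-ChIP read set for one mark (K4, K27 or H2AZ)."""
    if mark not in _MARK_FLAGS:
        raise ValidationError(f"unknown mark {mark!r}; expected one of {sorted(_MARK_FLAGS)}")
    flags = getattr(states, _MARK_FLAGS[mark])
    weights = cfg.eps1 * flags.sum(axis=1) / states.n_cells
    if rng is None:
        rng = cfg.rng(f"chip_{mark}")
    return _sample_track(states, weights.astype(float), cfg, rng, f"{mark.lower()}_")


def simulate_sequential_chip(
    states: ChromatinStates, cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sequential (anti-K27 then anti-K4) ChIP read set.

    Capture weight per nucleosome copy: ``eps1*eps2`` if truly bivalent,
    ``phi*eps2`` if K4-only (flow-through), zero otherwise.
    """
    n_biv = (states.k4 & states.k27).sum(axis=1)
    n_k4only = (states.k4 & ~states.k27).sum(axis=1)
    weights = (cfg.eps1 * cfg.eps2 * n_biv + cfg.phi * cfg.eps2 * n_k4only) / states.n_cells
    if rng is None:
        rng = cfg.rng("seqchip")
    return _sample_track(states, weights.astype(float), cfg, rng, "seq_")


def simulate_input(
    states: ChromatinStates, cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Input (no-IP) read set: occupancy-weighted, mark-blind."""
    if len(states.positions) == 0:
        return empty_reads()
    weights = states.occ.sum(axis=1) / states.n_cells
    if rng is None:
        rng = cfg.rng("input")
    return _sample_track(states, weights.astype(float), cfg, rng, "inp_")


TRACKS = ("h3k4me3", "h3k27me3", "h2az", "seqchip", "input")


def simulate_all_tracks(world: World, cfg: SimConfig) -> dict[str, pd.DataFrame]:
    """Generate chromatin states and all five read tracks."""
    states = sample_chromatin_states(world, cfg)
    return {
        "h3k4me3": simulate_chip(states, "K4", cfg),
        "h3k27me3": simulate_chip(states, "K27", cfg),
        "h2az": simulate_chip(states, "H2AZ", cfg),
        "seqchip": simulate_sequential_chip(states, cfg),
        "input": simulate_input(states, cfg),
    }


# ---------------------------------------------------------------------------
# Emission


def emit_tables(
    world: World,
    cfg: SimConfig,
    outdir,
    reads: dict[str, pd.DataFrame] | None = None,
) -> dict[str, Path]:
    """Write the world and read tracks as flat text files.

    Emits genome.tsv, genes.tsv, cpg.bed, enhancers.bed, expression.tsv,
    methylation.tsv, reads.<track>.bed (+ .qc.tsv quality sidecars) and a
    simconfig.yaml echo.  Everything round-trips through :mod:`read_io`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if reads is None:
        reads = simulate_all_tracks(world, cfg)
    paths: dict[str, Path] = {}

    def _write(key, fname, fn):
        p = outdir / fname
        try:
            fn(p)
        except OSError as exc:
            raise BivalseqError(f"failed writing {p}: {exc}") from exc
        paths[key] = p

    _write("genome", "genome.tsv", lambda p: read_io.write_layout(world.layout, p))
    _write("genes", "genes.tsv", lambda p: read_io.write_genes(world.genes, p))
    _write("cpg", "cpg.bed", lambda p: read_io.write_intervals(world.cpg, p, ["density"]))
    _write("enhancers", "enhancers.bed", lambda p: read_io.write_intervals(world.enhancers, p))
    _write("expression", "expression.tsv",
           lambda p: world.expression.to_csv(p, sep="\t", index=False))
    _write("methylation", "methylation.tsv",
           lambda p: world.methylation.to_csv(p, sep="\t", index=False))
    for track, df in reads.items():
        _write(f"reads.{track}", f"reads.{track}.bed",
               lambda p, df=df: read_io.write_reads(df, p))
        if "mapq" in df.columns:
            qc = sort_reads(df)[["name", "mapq", "nm"]]
            _write(f"qc.{track}", f"reads.{track}.qc.tsv",
                   lambda p, qc=qc: qc.to_csv(p, sep="\t", index=False))
    _write("simconfig", "simconfig.yaml",
           lambda p: p.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True)))
    return paths
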