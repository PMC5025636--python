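"""End-to-end pipeline: simulate/load -> filter -> islands -> classify ->
stratify -> profile, driven by a YAML config with a single master seed.

Every stage writes flat-text outputs that the corresponding CLI
subcommand can also consume standalone; a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classify as classify_mod
from . import islands as islands_mod
from . import profiles as profiles_mod
from . import read_io
from . import simulate as sim_mod
from . import strata as strata_mod
from .core import BivalseqError

log = logging.getLogger(__name__)

CHIP_TRACKS = ("h3k4me3", "h3k27me3", "h2az", "seqchip")
_MARK_OF_TRACK = {"h3k4me3": "K4", "h3k27me3": "K27", "h2az": "H2AZ"}

#: archetype -> expected promoter class under perfect recovery
RECOVERY_MAP = {
    "bivalent": "bivalent",
    "K4_only": "K4_exclusive",
    "K27_only": "K27_exclusive",
    "silent_methylated": "none",
    "none": "none",
}


@dataclass
class RunConfig:
    """Aggregated parameters for a full run.

    Exactly one of ``simulate`` (SimConfig fields plus n_genes /
    n_enhancers / archetype_mix) or ``inputs`` (paths to pre-existing
    files) drives the data source.  Per-mark island gap sizes default to
    K4 = 600 bp, K27 = 1000 bp.
    """

    seed: int = 0
    simulate: dict | None = None
    inputs: dict | None = None
    filter: dict = field(default_factory=dict)
    islands: dict = field(default_factory=dict)
    classify: dict = field(default_factory=dict)
    profile: dict = field(default_factory=dict)
    strata: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "simulate": self.simulate,
            "inputs": self.inputs,
            "filter": self.filter,
            "islands": self.islands,
            "classify": self.classify,
            "profile": self.profile,
            "strata": self.strata,
            "log_level": self.log_level,
        }

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _sim_config(cfg: RunConfig) -> tuple[sim_mod.SimConfig, dict]:
    d = dict(cfg.simulate or {})
    world_kw = {
        k: d.pop(k)
        for k in ("n_genes", "n_enhancers", "archetype_mix", "spacing",
                  "chrom_length", "n_chroms", "cpg_enhancer_fraction")
        if k in d
    }
    d.setdefault("seed", cfg.seed)
    return sim_mod.SimConfig(**d), world_kw


def _load_inputs(paths: dict):
    def _require(key):
        if key not in paths:
            raise BivalseqError(f"inputs config missing required path: {key!r}")
        p = Path(paths[key])
        if not p.exists():
            raise BivalseqError(f"input path does not exist: {p}")
        return p

    layout = read_io.load_layout(_require("genome"))
    genes = read_io.load_genes(_require("genes"))
    cpg = read_io.load_cpg_islands(_require("cpg"))
    enhancers = read_io.load_enhancers(_require("enhancers"))
    expression = read_io.load_expression(_require("expression"))
    methylation = read_io.load_methylation(_require("methylation"))
    reads = {}
    for track, rp in dict(paths.get("reads", {})).items():
        rp = Path(rp)
        if not rp.exists():
            raise BivalseqError(f"reads path does not exist: {rp}")
        df = read_io.load_reads(rp, layout)
        qc_path = dict(paths.get("qc", {})).get(track)
        if qc_path:
            df = read_io.attach_qc(df, read_io.load_qc_sidecar(qc_path))
        reads[track] = df
    if "input" not in reads:
        raise BivalseqError("inputs config must provide reads for the 'input' track")
    world = sim_mod.World(layout, genes, cpg, enhancers, expression, methylation)
    return world, reads


def _filter_reads(reads: dict, cfg: RunConfig) -> dict:
    fp = read_io.FilterParams(
        redundancy_threshold=int(cfg.filter.get("redundancy_threshold", 1)),
        max_mismatch=int(cfg.filter.get("max_mismatch", 1)),
        min_mapq=int(cfg.filter.get("min_mapq", 20)),
    )
    out = {}
    for track, df in reads.items():
        if "mapq" in df.columns and cfg.filter.get("apply_quality", True):
            df = read_io.filter_quality(df, fp)
        out[track] = read_io.filter_redundant(df, fp.redundancy_threshold)
    return out


def _island_params(cfg: RunConfig, mark: str) -> islands_mod.IslandParams:
    shared = {k: v for k, v in cfg.islands.items()
              if k not in ("k4", "k27", "h2az")}
    per_mark = dict(cfg.islands.get(mark.lower(), {}))
    return islands_mod.for_mark(mark, **{**shared, **per_mark})


def run_all(cfg: RunConfig, outdir) -> Path:
    """Execute every stage, writing all artifacts under ``outdir``.

    Produces islands.{k4,k27,h2az}.{tsv,bed}, classes.tsv, strata.tsv,
    overlap_zones.tsv, profiles/*.tsv, summary.json and manifest.json.
    Raises with the failing stage named.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "configure"
    try:
        if cfg.simulate is not None:
            stage = "simulate"
            sim_cfg, world_kw = _sim_config(cfg)
            world = sim_mod.build_world(sim_cfg, **world_kw)
            reads = sim_mod.simulate_all_tracks(world, sim_cfg)
            sim_mod.emit_tables(world, sim_cfg, outdir / "sim", reads=reads)
        elif cfg.inputs is not None:
            stage = "load"
            world, reads = _load_inputs(cfg.inputs)
        else:
            raise BivalseqError("config needs a 'simulate' or 'inputs' section")

        stage = "filter"
        raw_counts = {t: int(len(df)) for t, df in reads.items()}
        reads = _filter_reads(reads, cfg)
        filtered_counts = {t: int(len(df)) for t, df in reads.items()}

        stage = "call-islands"
        control = reads["input"]
        called: dict[str, pd.DataFrame] = {}
        for track in ("h3k4me3", "h3k27me3", "h2az"):
            mark = _MARK_OF_TRACK[track]
            if track in reads:
                params = _island_params(cfg, mark)
                called[mark] = islands_mod.call_islands(
                    reads[track], control, world.layout, params, name_prefix=mark
                )
            else:
                called[mark] = islands_mod._empty_islands()
            islands_mod.write_islands(
                called[mark],
                outdir / f"islands.{mark.lower()}.tsv",
                outdir / f"islands.{mark.lower()}.bed",
            )

        stage = "classify"
        cparams = classify_mod.ClassifyParams(
            radius=int(cfg.classify.get("radius", 2500)),
            require_overlap=bool(cfg.classify.get("require_overlap", True)),
        )
        classes = classify_mod.classify_promoters(
            world.genes, called["K4"], called["K27"], cparams
        )
        classes.to_csv(outdir / "classes.tsv", sep="\t", index=False)
        zones, zone_summary = classify_mod.overlap_zones(called["K4"], called["K27"])
        zones.to_csv(outdir / "overlap_zones.tsv", sep="\t", index=False)

        stage = "stratify"
        sparams = strata_mod.StrataParams(
            cpg_radius=int(cfg.strata.get("cpg_radius", 1500)),
            n_quantiles=int(cfg.strata.get("n_quantiles", 5)),
        )
        cpg_status = strata_mod.assign_cpg_status(world.genes, world.cpg, sparams)
        meth = strata_mod.methylation_classes(world.methylation, sparams)
        expr_q = strata_mod.expression_quintiles(world.expression, sparams.n_quantiles)
        strata_tbl = cpg_status.merge(
            world.genes[["transcript_id", "gene_id"]], on="transcript_id"
        )
        strata_tbl["expression_quintile"] = strata_tbl["gene_id"].map(expr_q)
        strata_tbl["methylation_class"] = (
            strata_tbl["transcript_id"].map(meth).fillna("no_data")
        )
        strata_tbl.to_csv(outdir / "strata.tsv", sep="\t", index=False)

        stage = "profile"
        pparams = profiles_mod.ProfileParams(
            flank=int(cfg.profile.get("flank", 5000)),
            bin_size=int(cfg.profile.get("bin_size", 10)),
            pseudocount=float(cfg.profile.get("pseudocount", 0.5)),
        )
        frag = int(cfg.profile.get("fragment_size", 200))
        prof_dir = outdir / "profiles"
        prof_dir.mkdir(exist_ok=True)
        matrices = {
            track: profiles_mod.tss_profile(reads[track], world.genes, pparams, frag)
            for track in reads
        }
        groups: dict[str, list[str]] = {}
        for cls, sub in classes.groupby("promoter_class"):
            groups[f"class_{cls}"] = sub["transcript_id"].tolist()
        meth_by_tid = strata_tbl.set_index("transcript_id")["methylation_class"]
        for mcls in ("methylated", "unmethylated"):
            tids = meth_by_tid.index[meth_by_tid == mcls].tolist()
            if tids:
                groups[f"meth_{mcls}"] = tids
        norm_profiles: dict[str, pd.Series] = {}
        for gname, tids in groups.items():
            avg_inp = profiles_mod.average_profile(matrices["input"], tids)
            for track in CHIP_TRACKS:
                if track not in matrices:
                    continue
                avg = profiles_mod.average_profile(matrices[track], tids)
                norm = profiles_mod.normalize_to_input(avg, avg_inp, pparams.pseudocount)
                key = f"{track}.{gname}"
                norm_profiles[key] = norm
                profiles_mod.write_profile(norm, prof_dir / f"{key}.tsv")

        stage = "summarize"
        summary = {
            "reads_raw": raw_counts,
            "reads_filtered": filtered_counts,
            "island_counts": {m: int(len(df)) for m, df in called.items()},
            "class_counts": {
                str(k): int(v)
                for k, v in classes["promoter_class"].value_counts().sort_index().items()
            },
            "overlap_zones": zone_summary,
            "methylation_counts": {
                str(k): int(v)
                for k, v in strata_tbl["methylation_class"].value_counts().sort_index().items()
            },
        }
        if "archetype" in world.genes.columns and cfg.simulate is not None:
            merged = classes.merge(
                world.genes[["transcript_id", "archetype"]], on="transcript_id"
            )
            expected = merged["archetype"].map(RECOVERY_MAP)
            summary["archetype_recovery"] = round(
                float((merged["promoter_class"] == expected).mean()), 6
            )
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
        manifest = {
            "config_hash": cfg.config_hash(),
            "seed": int(cfg.seed),
            "stages": ["simulate" if cfg.simulate else "load", "filter",
                       "call-islands", "classify", "stratify", "profile"],
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    except BivalseqError as exc:
        raise BivalseqError(f"stage {stage!r} failed: {exc}") from exc
    return outdir


DEMO_CONFIG = {
    "seed": 7,
    "simulate": {
        "n_genes": 200,
        "n_enhancers": 40,
        "archetype_mix": {
            "bivalent": 1.0,
            "K4_only": 1.0,
            "K27_only": 1.0,
            "silent_methylated": 1.0,
        },
        "depth": 200_000,
        "f_biv": 0.8,
        "phi": 0.0,
    },
    "classify": {"radius": 2500},
}


def make_demo_config(outpath) -> Path:
    """Write the self-contained demo scenario (200 promoters, 4 archetypes,
    2e5 reads per track, f_biv = 0.8, phi = 0) as a YAML config."""
    outpath = Path(outpath)
    outpath.write_text(yaml.safe_dump(DEMO_CONFIG, sort_keys=True))
    return outpath
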