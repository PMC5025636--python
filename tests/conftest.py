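"""Shared fixtures: a session-scoped demo simulation run the profile and
geometry tests interrogate, plus small constructed worlds."""

from __future__ import annotations

from types import SimpleNamespace

import pytest
from hypothesis import settings

from bivalseq import classify as classify_mod
from bivalseq import islands as islands_mod
from bivalseq import pipeline as pl
from bivalseq import profiles as profiles_mod
from bivalseq import read_io
from bivalseq import simulate as sm
from bivalseq import strata as strata_mod

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

DEMO_MIX = {"bivalent": 1.0, "K4_only": 1.0, "K27_only": 1.0, "silent_methylated": 1.0}


def run_demo_like(seed: int, *, f_biv: float = 0.8, phi: float = 0.0,
                  n_genes: int = 200, depth: int = 200_000,
                  tracks=("h3k4me3", "h3k27me3", "seqchip", "input")):
    """Simulate + filter + call islands + classify + profile, in memory.

    Returns everything the property tests need: the world, the filtered
    tracks, island calls, promoter classes and per-track profile matrices.
    """
    cfg = sm.SimConfig(seed=seed, depth=depth, f_biv=f_biv, phi=phi)
    world = sm.build_world(cfg, n_genes=n_genes, n_enhancers=40,
                           archetype_mix=DEMO_MIX)
    states = sm.sample_chromatin_states(world, cfg)
    reads = {}
    if "h3k4me3" in tracks:
        reads["h3k4me3"] = sm.simulate_chip(states, "K4", cfg)
    if "h3k27me3" in tracks:
        reads["h3k27me3"] = sm.simulate_chip(states, "K27", cfg)
    if "h2az" in tracks:
        reads["h2az"] = sm.simulate_chip(states, "H2AZ", cfg)
    if "seqchip" in tracks:
        reads["seqchip"] = sm.simulate_sequential_chip(states, cfg)
    reads["input"] = sm.simulate_input(states, cfg)

    fp = read_io.FilterParams()
    filtered = {
        t: read_io.filter_redundant(read_io.filter_quality(df, fp), 1)
        for t, df in reads.items()
    }
    k4 = islands_mod.call_islands(
        filtered["h3k4me3"], filtered["input"], world.layout,
        islands_mod.K4_PARAMS, name_prefix="K4")
    k27 = islands_mod.call_islands(
        filtered["h3k27me3"], filtered["input"], world.layout,
        islands_mod.K27_PARAMS, name_prefix="K27")
    classes = classify_mod.classify_promoters(world.genes, k4, k27)
    pparams = profiles_mod.ProfileParams()
    matrices = {
        t: profiles_mod.tss_profile(df, world.genes, pparams)
        for t, df in filtered.items()
    }
    meth = strata_mod.methylation_classes(world.methylation)
    return SimpleNamespace(
        cfg=cfg, world=world, reads=reads, filtered=filtered,
        k4=k4, k27=k27, classes=classes, matrices=matrices,
        pparams=pparams, methylation_classes=meth,
    )


@pytest.fixture(scope="session")
def demo():
    """The reference study conditions: 200 promoters, four archetypes,
    2e5 reads per track, f_biv = 0.8, phi = 0."""
    return run_demo_like(seed=7)


def norm_profile(demo, track: str, transcript_ids):
    """Input-normalized average profile over a promoter subset."""
    avg = profiles_mod.average_profile(demo.matrices[track], transcript_ids)
    inp = profiles_mod.average_profile(demo.matrices["input"], transcript_ids)
    return profiles_mod.normalize_to_input(avg, inp, demo.pparams.pseudocount)


def class_members(demo, cls: str) -> list[str]:
    sub = demo.classes[demo.classes["promoter_class"] == cls]
    return sub["transcript_id"].tolist()
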