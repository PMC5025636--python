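"""Synthetic-data generator: determinism, mark logic, sampling models."""

import numpy as np
import pandas as pd
import pytest

from bivalseq import read_io
from bivalseq import simulate as sm
from bivalseq import strata as strata_mod
from bivalseq.core import SizingError, ValidationError, validate_reads

FOUR = {"bivalent": 1.0, "K4_only": 1.0, "K27_only": 1.0, "silent_methylated": 1.0}


def _world(cfg, n_genes=20, **kw):
    kw.setdefault("archetype_mix", FOUR)
    kw.setdefault("n_enhancers", 4)
    return sm.build_world(cfg, n_genes=n_genes, **kw)


class TestBuildWorld:
    def test_one_gene_per_archetype_cpg_placement(self):
        cfg = sm.SimConfig(seed=1)
        mix = {a: 1.0 for a in sm.ARCHETYPES}
        world = sm.build_world(cfg, n_genes=5, n_enhancers=0, archetype_mix=mix)
        assert sorted(world.genes["archetype"]) == sorted(sm.ARCHETYPES)
        status = strata_mod.assign_cpg_status(world.genes, world.cpg)
        merged = world.genes.merge(status, on="transcript_id")
        has_cpg = merged["cpg_status_y" if "cpg_status_y" in merged else "cpg_status"] == "cpg"
        by_arch = dict(zip(merged["archetype"], has_cpg))
        assert by_arch["bivalent"] and by_arch["K4_only"] and by_arch["silent_methylated"]
        assert not by_arch["K27_only"] and not by_arch["none"]

    def test_same_seed_identical_world(self):
        cfg = sm.SimConfig(seed=42)
        w1, w2 = _world(cfg), _world(cfg)
        pd.testing.assert_frame_equal(w1.genes, w2.genes)
        pd.testing.assert_frame_equal(w1.cpg, w2.cpg)
        pd.testing.assert_frame_equal(w1.enhancers, w2.enhancers)

    def test_minimum_promoter_spacing(self):
        cfg = sm.SimConfig(seed=2)
        world = _world(cfg, n_genes=50)
        spacing = 2 * (5000 + cfg.zonal_k27_span[1])
        for _, sub in world.genes.groupby("chrom"):
            tss = np.sort(sub["tss"].to_numpy())
            # brute-force pairwise scan
            for i in range(len(tss)):
                for j in range(i + 1, len(tss)):
                    assert abs(tss[j] - tss[i]) >= spacing

    def test_genome_too_small_raises(self):
        cfg = sm.SimConfig(seed=0)
        with pytest.raises(SizingError, match="too small"):
            sm.build_world(cfg, n_genes=100, chrom_length=200_000)

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            sm.SimConfig(nucleosome_len=146)
        with pytest.raises(ValidationError):
            sm.SimConfig(f_biv=1.2)
        with pytest.raises(ValidationError):
            sm.SimConfig(phi=1.0)


class TestChromatinStates:
    def _states(self, **cfg_kw):
        cfg = sm.SimConfig(seed=5, n_cells=40, **cfg_kw)
        world = _world(cfg, n_genes=12)
        return world, cfg, sm.sample_chromatin_states(world, cfg)

    def test_fbiv_zero_no_doubly_marked_copy(self):
        _, _, st = self._states(f_biv=0.0)
        assert not (st.k4 & st.k27).any()

    def test_fbiv_one_every_occupied_proximal_copy_bivalent(self):
        world, _, st = self._states(f_biv=1.0)
        biv_tids = set(world.genes.loc[world.genes.archetype == "bivalent",
                                       "transcript_id"])
        prox = (st.positions["proximal"]
                & st.positions["transcript_id"].isin(biv_tids)).to_numpy()
        occ = st.occ[prox]
        assert ((st.k4[prox] & st.k27[prox]) == occ).all()

    def test_silent_gene_fully_unmarked_and_fully_occupied(self):
        world, _, st = self._states()
        silent = set(world.genes.loc[world.genes.archetype == "silent_methylated",
                                     "transcript_id"])
        rows = st.positions["transcript_id"].isin(silent).to_numpy()
        assert not st.k4[rows].any() and not st.k27[rows].any()
        assert st.occ[rows].all()

    def test_footprints_are_147bp(self):
        _, _, st = self._states()
        assert ((st.positions["end"] - st.positions["start"]) == 147).all()

    def test_fbiv_conservation_at_large_n_cells(self):
        f = 0.37
        cfg = sm.SimConfig(seed=9, n_cells=1000, f_biv=f)
        world = _world(cfg, n_genes=10,
                       archetype_mix={"bivalent": 1.0})
        st = sm.sample_chromatin_states(world, cfg)
        prox = st.positions["proximal"].to_numpy()
        n_occ = int(st.occ[prox].sum())
        n_both = int((st.k4[prox] & st.k27[prox]).sum())
        sigma = np.sqrt(f * (1 - f) / n_occ)
        assert abs(n_both / n_occ - f) <= 3 * sigma


class TestReadSampling:
    def _setup(self, **cfg_kw):
        cfg = sm.SimConfig(seed=3, n_cells=30, depth=20_000, **cfg_kw)
        world = _world(cfg, n_genes=12)
        return world, cfg, sm.sample_chromatin_states(world, cfg)

    def test_no_marks_no_background_empty(self):
        _, cfg, st = self._setup(bg_rate=0.0)
        world2 = sm.build_world(cfg, n_genes=4, n_enhancers=0,
                                archetype_mix={"silent_methylated": 1.0})
        st2 = sm.sample_chromatin_states(world2, cfg)
        assert len(sm.simulate_chip(st2, "K4", cfg)) == 0

    def test_unknown_mark_rejected(self):
        _, cfg, st = self._setup()
        with pytest.raises(ValidationError, match="unknown mark"):
            sm.simulate_chip(st, "K9", cfg)

    def test_all_read_midpoints_inside_marked_footprints(self):
        world, cfg, st = self._setup(bg_rate=0.0, eps1=1.0, frag_jitter=0)
        reads = sm.simulate_chip(st, "K4", cfg)
        assert len(reads) > 0
        marked = st.k4.any(axis=1)
        starts = st.positions["start"].to_numpy()[marked]
        ends = st.positions["end"].to_numpy()[marked]
        mid = (reads["start"] + reads["end"]).to_numpy() // 2
        ok = np.zeros(len(mid), dtype=bool)
        for s, e in zip(starts, ends):
            ok |= (mid >= s) & (mid < e)
        assert ok.all()

    def test_depth_doubling_doubles_read_count(self):
        _, cfg, st = self._setup()
        n1 = len(sm.simulate_chip(st, "K4", cfg))
        cfg2 = sm.SimConfig(**{**cfg.to_dict(), "depth": cfg.depth * 2})
        n2 = len(sm.simulate_chip(st, "K4", cfg2))
        assert abs(n2 - 2 * n1) <= 3 * np.sqrt(2 * cfg.depth) + 3 * np.sqrt(cfg.depth)

    def test_reads_never_extend_past_chromosome_ends(self):
        world, cfg, st = self._setup()
        for track, df in sm.simulate_all_tracks(world, cfg).items():
            validate_reads(df, world.layout)


class TestSequentialChip:
    def test_no_bivalency_no_flowthrough_background_only(self):
        cfg = sm.SimConfig(seed=4, n_cells=30, depth=10_000,
                           f_biv=0.0, phi=0.0, bg_rate=0.0)
        world = _world(cfg, n_genes=8)
        st = sm.sample_chromatin_states(world, cfg)
        assert len(sm.simulate_sequential_chip(st, cfg)) == 0

    def test_pure_bivalent_signal_sits_on_proximal_footprints(self):
        cfg = sm.SimConfig(seed=6, n_cells=30, depth=10_000, f_biv=1.0,
                           phi=0.0, bg_rate=0.0, frag_jitter=0)
        world = _world(cfg, n_genes=8, archetype_mix={"bivalent": 1.0})
        st = sm.sample_chromatin_states(world, cfg)
        reads = sm.simulate_sequential_chip(st, cfg)
        prox = st.positions["proximal"].to_numpy()
        starts = st.positions["start"].to_numpy()[prox]
        ends = st.positions["end"].to_numpy()[prox]
        mid = (reads["start"] + reads["end"]).to_numpy() // 2
        ok = np.zeros(len(mid), dtype=bool)
        for s, e in zip(starts, ends):
            ok |= (mid >= s) & (mid < e)
        assert len(reads) > 0 and ok.all()

    def test_flowthrough_signal_scales_with_phi(self):
        counts = {}
        for phi in (0.1, 0.2):
            cfg = sm.SimConfig(seed=8, n_cells=30, depth=40_000, f_biv=0.0,
                               phi=phi, bg_rate=5e-4)  # background-dominated
            world = _world(cfg, n_genes=10, archetype_mix={"K4_only": 1.0})
            st = sm.sample_chromatin_states(world, cfg)
            reads = sm.simulate_sequential_chip(st, cfg)
            mids = (reads["start"] + reads["end"]) // 2
            hits = bg = 0
            for g in world.genes.itertuples():
                sel = reads["chrom"] == g.chrom
                hits += int((sel & (abs(mids - g.tss) <= 1000)).sum())
                # matched-width window far from any promoter array: background
                bg += int((sel & (abs(mids - (g.tss - 10_000)) <= 1000)).sum())
            counts[phi] = hits - bg
        assert counts[0.2] > counts[0.1] > 0
        assert 1.4 <= counts[0.2] / counts[0.1] <= 2.8

    def test_seqchip_tss_signal_monotone_in_fbiv(self):
        signals = []
        for f in (0.0, 0.25, 0.5, 1.0):
            cfg = sm.SimConfig(seed=12, n_cells=30, depth=40_000, f_biv=f, phi=0.0)
            world = _world(cfg, n_genes=10, archetype_mix={"bivalent": 1.0})
            st = sm.sample_chromatin_states(world, cfg)
            reads = sm.simulate_sequential_chip(st, cfg)
            mids = (reads["start"] + reads["end"]) // 2
            hits = 0
            for g in world.genes.itertuples():
                near = (reads["chrom"] == g.chrom) & (abs(mids - g.tss) <= 300)
                hits += int(near.sum())
            signals.append(hits)
        assert all(b >= a for a, b in zip(signals, signals[1:]))
        assert signals[-1] > signals[0]


class TestInput:
    def _cov_ratio(self, cfg, world, st):
        reads = sm.simulate_input(st, cfg)
        mids = (reads["start"] + reads["end"]) // 2
        inside = outside = 0
        for g in world.genes.itertuples():
            s = 1 if g.strand == "+" else -1
            od = (mids - g.tss) * s
            sel = reads["chrom"] == g.chrom
            inside += int((sel & (od >= 0) & (od < 800)).sum())
            outside += int((sel & (od >= -4000) & (od < -800)).sum())
        return inside / 800, outside / 3200

    def test_full_occupancy_no_dip(self):
        cfg = sm.SimConfig(seed=13, n_cells=30, depth=60_000,
                           ndr_occupancy=1.0, bg_rate=0.0)
        world = _world(cfg, n_genes=10, archetype_mix={"K4_only": 1.0})
        st = sm.sample_chromatin_states(world, cfg)
        inside, outside = self._cov_ratio(cfg, world, st)
        assert abs(inside / outside - 1.0) < 0.15

    def test_depleted_occupancy_dip_ratio(self):
        cfg = sm.SimConfig(seed=14, n_cells=50, depth=120_000,
                           ndr_occupancy=0.3, bg_rate=0.0)
        world = _world(cfg, n_genes=10, archetype_mix={"K4_only": 1.0})
        st = sm.sample_chromatin_states(world, cfg)
        inside, outside = self._cov_ratio(cfg, world, st)
        ratio = inside / outside
        assert abs(ratio - 0.3) < 0.1

    def test_empty_states_empty_reads(self):
        cfg = sm.SimConfig(seed=1, bg_rate=0.0)
        world = _world(cfg, n_genes=4, n_enhancers=0)
        st = sm.sample_chromatin_states(world, cfg)
        st.positions = st.positions.iloc[0:0]
        st.occ = st.occ[:0]
        assert len(sm.simulate_input(st, cfg)) == 0


class TestEmission:
    def test_round_trip_and_methylation_by_construction(self, tmp_path):
        cfg = sm.SimConfig(seed=21, n_cells=10, depth=5_000)
        world = _world(cfg, n_genes=8)
        paths = sm.emit_tables(world, cfg, tmp_path)
        genes_back = read_io.load_genes(paths["genes"])
        from bivalseq.core import GENE_COLUMNS
        pd.testing.assert_frame_equal(
            genes_back[GENE_COLUMNS], world.genes[GENE_COLUMNS],
            check_dtype=False,
        )
        meth = read_io.load_methylation(paths["methylation"])
        classes = strata_mod.methylation_classes(meth)
        silent = world.genes.loc[world.genes.archetype == "silent_methylated",
                                 "transcript_id"]
        assert (classes.loc[silent] == "methylated").all()
        others = world.genes.loc[world.genes.archetype != "silent_methylated",
                                 "transcript_id"]
        assert (classes.loc[others] == "unmethylated").all()

    def test_bed_outputs_sorted(self, tmp_path):
        cfg = sm.SimConfig(seed=22, n_cells=10, depth=5_000)
        world = _world(cfg, n_genes=8)
        paths = sm.emit_tables(world, cfg, tmp_path)
        reads = read_io.load_reads(paths["reads.h3k4me3"])
        assert reads.sort_values(["chrom", "start"]).reset_index(drop=True).equals(
            reads.reset_index(drop=True)
        )

    def test_identical_seed_byte_identical_files(self, tmp_path):
        cfg = sm.SimConfig(seed=23, n_cells=10, depth=5_000)
        world = _world(cfg, n_genes=6)
        p1 = sm.emit_tables(world, cfg, tmp_path / "a")
        p2 = sm.emit_tables(world, cfg, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key
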