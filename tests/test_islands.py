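"""Island caller: tag arithmetic, eligibility, assembly, significance."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import poisson

from bivalseq import islands as im
from bivalseq.core import GenomeLayout, ValidationError, make_reads

from oracles import islands_by_regex, poisson_tail

LAYOUT = GenomeLayout((("c1", 20_000),))


def _tags(positions, chrom="c1"):
    return pd.DataFrame({"chrom": [chrom] * len(positions),
                         "pos": np.array(positions, dtype=np.int64)})


class TestTags:
    def test_plus_strand_shifted_downstream(self):
        reads = make_reads(["c1"], [250], [286], ["+"])
        assert im.tags_from_reads(reads, LAYOUT, 200)["pos"].iloc[0] == 350

    def test_minus_strand_shifted_upstream(self):
        reads = make_reads(["c1"], [250], [286], ["-"])
        assert im.tags_from_reads(reads, LAYOUT, 200)["pos"].iloc[0] == 186

    def test_tag_clipped_at_chrom_end(self):
        reads = make_reads(["c1"], [19_950], [19_986], ["+"])
        assert im.tags_from_reads(reads, LAYOUT, 200)["pos"].iloc[0] == 19_999


class TestWindowCounts:
    def test_window_index(self):
        wv = im.window_counts(_tags([350]), LAYOUT, 200)
        assert wv.counts["c1"][1] == 1 and wv.counts["c1"].sum() == 1

    def test_lambda_formula(self):
        layout = GenomeLayout((("c1", 2_000_000),))
        wv = im.window_counts(_tags([0] * 1000), layout, 200, egf=0.75)
        assert wv.lambda_bg == pytest.approx(1000 * 200 / (2e6 * 0.75))

    def test_zero_tags_degenerate(self):
        wv = im.window_counts(_tags([]), LAYOUT, 200)
        assert wv.lambda_bg == 0
        with pytest.raises(im.DegenerateBackgroundError):
            im.eligible_windows(wv)


class TestEligibility:
    @pytest.mark.parametrize(
        "lam,count,expected",
        [(1.0, 5, True), (1.0, 0, False), (5.0, 5, False)],
    )
    def test_examples_against_direct_tail_sum(self, lam, count, expected):
        tail = poisson_tail(count, lam)
        assert (count >= 1 and tail <= 0.2) is expected
        wv = im.WindowVector({"c1": np.array([count])}, 200, lam, count)
        assert im.eligible_windows(wv, 0.2)["c1"][0] == expected

    def test_scipy_tail_matches_direct_sum(self):
        for lam in (0.13, 1.0, 5.0, 10.7):
            for c in range(1, 40):
                assert poisson.sf(c - 1, lam) == pytest.approx(
                    poisson_tail(c, lam), abs=1e-9
                )


class TestAssembly:
    def _wv(self, elig_idx, n=12, lam=1.0):
        counts = np.zeros(n, dtype=np.int64)
        counts[list(elig_idx)] = 5
        elig = np.zeros(n, dtype=bool)
        elig[list(elig_idx)] = True
        return im.WindowVector({"c1": counts}, 200, lam, int(counts.sum())), {"c1": elig}

    def test_gap_bridged(self):
        wv, elig = self._wv([3, 4, 7])
        out = im.assemble_islands(elig, wv, gap_g=600)
        assert len(out) == 1
        assert (out.start.iloc[0], out.end.iloc[0]) == (600, 1600)

    def test_gap_too_wide_splits(self):
        wv, elig = self._wv([3, 7])
        out = im.assemble_islands(elig, wv, gap_g=200)
        assert len(out) == 2

    def test_no_eligible_windows(self):
        wv, elig = self._wv([])
        assert len(im.assemble_islands(elig, wv, gap_g=600)) == 0

    def test_matches_regex_oracle_randomized(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(5, 100))
            lam = float(rng.uniform(0.2, 4.0))
            counts = rng.poisson(lam, n) + rng.binomial(1, 0.2, n) * rng.integers(3, 9, n)
            wv = im.WindowVector({"c1": counts.astype(np.int64)}, 200, lam, int(counts.sum()))
            elig = im.eligible_windows(wv, 0.2)
            gap = int(rng.integers(0, 4)) * 200
            got = im.assemble_islands(elig, wv, gap)
            want = islands_by_regex(elig["c1"], counts, lam, gap // 200, 200)
            assert len(got) == len(want)
            for row, (s, e, score) in zip(got.itertuples(), want):
                assert (row.start, row.end) == (s, e)
                assert row.score == pytest.approx(score, rel=1e-9)

    def test_score_monotone_in_member_counts(self):
        # adding tags inside an island never decreases its score
        wv, elig = self._wv([3, 4, 7], lam=1.0)
        base = im.assemble_islands(elig, wv, 600).score.iloc[0]
        wv.counts["c1"][4] += 10
        boosted = im.assemble_islands(elig, wv, 600).score.iloc[0]
        assert boosted > base


class TestCallIslands:
    def _uniform_reads(self, rng, n, length, chrom="c1"):
        starts = rng.integers(0, length - 36, n)
        strands = np.where(rng.random(n) < 0.5, "+", "-")
        return make_reads([chrom] * n, starts, starts + 36, strands)

    def test_single_island_q_is_poisson_tail(self):
        # 50 chip tags in one window; control has 5 there out of 50 total,
        # so the scaled control rate is 5 and q = P(X >= 50 | 5).
        chip = make_reads(["c1"] * 50, np.full(50, 900) + np.arange(50),
                          np.full(50, 936) + np.arange(50), ["+"] * 50)
        ctrl_in = [900 + 7 * i for i in range(5)]
        ctrl_out = [15_000 + 50 * i for i in range(45)]
        starts = np.array(ctrl_in + ctrl_out)
        ctrl = make_reads(["c1"] * 50, starts, starts + 36, ["+"] * 50)
        out = im.call_islands(chip, ctrl, LAYOUT, im.IslandParams())
        assert len(out) == 1
        row = out.iloc[0]
        assert row.chip_count == 50
        assert row.q_value == pytest.approx(float(poisson.sf(49, 5.0)), rel=1e-9)
        assert row.q_value < 1e-6

    def test_empty_chip_returns_empty_with_warning(self, caplog):
        from bivalseq.core import empty_reads
        with caplog.at_level("WARNING"):
            out = im.call_islands(empty_reads(), None, LAYOUT,
                                  im.IslandParams(mode="background_only"))
        assert len(out) == 0
        assert "empty chip" in caplog.text

    def test_control_required_in_with_control_mode(self):
        chip = make_reads(["c1"], [0], [36], ["+"])
        with pytest.raises(ValidationError):
            im.call_islands(chip, None, LAYOUT, im.IslandParams())

    def test_islands_are_disjoint_and_sorted(self):
        rng = np.random.default_rng(3)
        layout = GenomeLayout((("c1", 100_000),))
        # two well-separated enriched clusters over a thin background
        sig1 = self._uniform_reads(rng, 300, 2000)
        sig1[["start", "end"]] += 10_000
        sig2 = self._uniform_reads(rng, 300, 2000)
        sig2[["start", "end"]] += 60_000
        bg = self._uniform_reads(rng, 500, 100_000)
        chip = pd.concat([sig1, sig2, bg], ignore_index=True)
        ctrl = self._uniform_reads(rng, 1000, 100_000)
        out = im.call_islands(chip, ctrl, layout, im.IslandParams())
        assert len(out) >= 2
        assert out["start"].is_monotonic_increasing
        assert (out["start"].to_numpy()[1:] >= out["end"].to_numpy()[:-1]).all()

    def test_params_validation(self):
        with pytest.raises(ValidationError):
            im.IslandParams(gap_g=700)  # not a multiple of the window
        with pytest.raises(ValidationError):
            im.IslandParams(egf=0.0)
        with pytest.raises(ValidationError):
            im.for_mark("K9")
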