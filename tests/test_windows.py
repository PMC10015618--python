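import numpy as np
import pandas as pd
import pytest

from mescan.bsfs import BsfsTally
from mescan.demography import BlockConfig, DemographyParams
from mescan.inference import GridSpec, evaluate_grid
from mescan.simulate import simulate_block_tallies
from mescan.windows import (
    Window,
    WindowResult,
    assign_windows_to_chromosomes,
    classify_barrier,
    cut_windows,
    scale_window_block_count,
    summarize_chromosomes,
    window_scan,
)


def block_table(n_per_chrom):
    rows = []
    for chrom, n in n_per_chrom.items():
        for i in range(n):
            rows.append((chrom, i * 100, i * 100 + 64))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end"])


class TestCutWindows:
    def test_tiles_exactly(self):
        wins = cut_windows(block_table({"c1": 9}), 3)
        assert len(wins) == 3
        assert [w.start for w in wins] == [0, 300, 600]

    def test_insufficient_blocks_yield_nothing(self, caplog):
        with caplog.at_level("WARNING"):
            assert cut_windows(block_table({"c1": 5}), 6) == []
        assert "no windows" in caplog.text

    def test_never_spans_chromosomes_and_drops_remainder(self):
        wins = cut_windows(block_table({"c1": 7, "c2": 6}), 3)
        assert [(w.chromosome, len(w.block_ids)) for w in wins] == [
            ("c1", 3), ("c1", 3), ("c2", 3), ("c2", 3),
        ]

    def test_matches_brute_force_partitioner(self, rng):
        counts = {f"c{i}": int(rng.integers(1, 40)) for i in range(6)}
        table = block_table(counts)
        wins = cut_windows(table, 7)
        expected = sum(n // 7 for n in counts.values())
        assert len(wins) == expected
        # each block in at most one window
        used = np.concatenate([w.block_ids for w in wins]) if wins else []
        assert len(set(used)) == len(used)


class TestScaleWindowBlockCount:
    def test_study_scaling(self):
        assert scale_window_block_count(30_000, 42, 6) == 4286

    def test_identity_and_proportionality(self):
        assert scale_window_block_count(12345, 7, 7) == 12345
        assert scale_window_block_count(30_000, 42, 84) == 60_000

    def test_rejects_zero(self):
        with pytest.raises(ValueError):
            scale_window_block_count(0, 1, 1)


def small_grid(split_time):
    return GridSpec(
        ne_a_values=(1e5, 3e5, 6e5),
        ne_b_values=(3e5, 9e5),
        ne_anc_values=(5e5, 1.5e6),
        me_values=(0.0, 1.75e-7, 3.5e-7),
        split_time=split_time,
    )


class TestWindowScan:
    @pytest.fixture(scope="class")
    def grid(self):
        spec = small_grid(1.5e6)
        points, probs = evaluate_grid(spec)
        return spec, points, probs

    def test_recovers_on_grid_truth_and_determinism(self, grid):
        spec, points, probs = grid
        truth = DemographyParams(3e5, 9e5, 1.5e6, spec.split_time, 1.75e-7, "into_A")
        tally = simulate_block_tallies(truth, BlockConfig(), 30_000, seed=71)
        win = Window("c1", 0, 10_000, np.arange(30_000))
        results = window_scan([win, win], [tally, tally], points, probs)
        assert results[0].best_point == (3e5, 9e5, 1.5e6, 1.75e-7)
        assert results[0].best_point == results[1].best_point
        assert results[0].lncl == results[1].lncl

    def test_profile_max_equals_unconditional_max(self, grid):
        spec, points, probs = grid
        truth = DemographyParams(1e5, 3e5, 5e5, spec.split_time)
        tally = simulate_block_tallies(truth, BlockConfig(), 5_000, seed=72)
        win = Window("c1", 0, 1000, np.arange(5000))
        (res,) = window_scan([win], [tally], points, probs)
        assert res.profile.max() == pytest.approx(res.lncl, abs=1e-9)

    def test_empty_tally_skipped(self, grid, caplog):
        spec, points, probs = grid
        win = Window("c1", 0, 1000, np.arange(10))
        with caplog.at_level("WARNING"):
            results = window_scan([win], [BsfsTally.zeros()], points, probs)
        assert results == [] and "empty tally" in caplog.text


class TestClassifyBarrier:
    def make_result(self, ln0, ln_bg):
        return WindowResult(
            window=Window("c1", 0, 1, np.array([0])),
            best_point=(1e5, 3e5, 5e5, 0.0),
            lncl=max(ln0, ln_bg),
            me_values=np.array([0.0, 1.75e-7, 3.5e-7]),
            profile=np.array([ln0, ln_bg, -1e9]),
        )

    def test_strict_inequality(self):
        assert classify_barrier(self.make_result(-1000.0, -1001.0), 1.75e-7)
        assert not classify_barrier(self.make_result(-1000.0, -1000.0), 1.75e-7)
        assert not classify_barrier(self.make_result(-1001.0, -1000.0), 1.75e-7)

    def test_absent_background_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            classify_barrier(self.make_result(-1.0, -2.0), 9e-7)

    def test_power_under_zero_vs_doubled_migration(self):
        """Windows simulated at me=0 are flagged far more often than
        windows simulated at twice the background rate."""
        spec = small_grid(1.5e6)
        points, probs = evaluate_grid(spec)
        flags = {}
        for label, me in (("zero", 0.0), ("double", 3.5e-7)):
            hits = 0
            for i in range(6):
                truth = DemographyParams(
                    3e5, 9e5, 1.5e6, spec.split_time, me,
                    "into_A" if me else "none",
                )
                tally = simulate_block_tallies(
                    truth, BlockConfig(), 5_000, seed=100 + 10 * i + int(me > 0)
                )
                win = Window("c1", 0, 1000, np.arange(5000))
                (res,) = window_scan([win], [tally], points, probs)
                hits += classify_barrier(res, 1.75e-7)
            flags[label] = hits
        assert flags["zero"] >= 5 and flags["double"] <= 1


class TestChromosomeSummaries:
    def make_results(self, table):
        out = []
        for _, row in table.iterrows():
            res = WindowResult(
                window=Window(row.chromosome, 0, 1, np.array([0])),
                best_point=(1e5, 3e5, 5e5, row.me),
                lncl=0.0,
                me_values=np.array([0.0]),
                profile=np.array([0.0]),
            )
            res.barrier = bool(row.barrier)
            out.append(res)
        return out

    def test_hand_computed_toy_table(self):
        table = pd.DataFrame(
            {
                "chromosome": ["c1", "c1", "c2", "c2", "c3", "c4", "c5", "c5"],
                "me": [1e-7, 3e-7, 0.0, 2e-7, 5e-7, 4e-7, 1e-7, 1e-7],
                "barrier": [True, False, True, True, False, False, True, False],
            }
        )
        lengths = {"c1": 10.0, "c2": 20.0, "c3": 30.0, "c4": 40.0, "c5": 50.0}
        summary, rho = summarize_chromosomes(self.make_results(table), lengths)
        s = summary.set_index("chromosome")
        assert s.loc["c1", "mean_me"] == pytest.approx(2e-7)
        assert s.loc["c2", "barrier_fraction"] == 1.0
        assert s.loc["c5", "mean_me"] == pytest.approx(1e-7)
        # hand-ranked: means (2,1,5,4,1)e-7 vs lengths 10..50
        import scipy.stats

        expect = scipy.stats.spearmanr(
            [10, 20, 30, 40, 50], [2e-7, 1e-7, 5e-7, 4e-7, 1e-7]
        )
        assert rho[0] == pytest.approx(expect.statistic)

    def test_constant_me_has_undefined_rho(self):
        table = pd.DataFrame(
            {
                "chromosome": ["c1", "c2", "c3"],
                "me": [2e-7] * 3,
                "barrier": [False] * 3,
            }
        )
        summary, rho = summarize_chromosomes(
            self.make_results(table), {"c1": 1, "c2": 2, "c3": 3}
        )
        assert rho is None
        assert (summary["mean_me"] == 2e-7).all()

    def test_monotone_relationship_gives_unit_rho(self):
        table = pd.DataFrame(
            {
                "chromosome": ["c1", "c2", "c3", "c4"],
                "me": [4e-7, 3e-7, 2e-7, 1e-7],
                "barrier": [False] * 4,
            }
        )
        _, rho = summarize_chromosomes(
            self.make_results(table), {"c1": 1, "c2": 2, "c3": 3, "c4": 4}
        )
        assert rho[0] == pytest.approx(-1.0)


class TestWindowAssignment:
    def test_majority_overlap_with_length_tiebreak(self):
        res = WindowResult(
            window=Window("q1", 0, 100, np.array([0])),
            best_point=(0, 0, 0, 0),
            lncl=0.0,
            me_values=np.array([0.0]),
            profile=np.array([0.0]),
        )
        alignments = pd.DataFrame(
            {
                "query_chrom": ["q1", "q1", "q1"],
                "query_start": [0, 60, 90],
                "query_end": [60, 90, 500],
                "target_chrom": ["t1", "t2", "t2"],
                "length": [60, 30, 410],
            }
        )
        assign_windows_to_chromosomes([res], alignments)
        # t1 overlaps 60 bases, t2 overlaps 30+10=40 -> majority t1
        assert res.assigned_chromosome == "t1"
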