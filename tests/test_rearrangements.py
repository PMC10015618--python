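
import pandas as pd
import pytest

from mescan.rearrangements import (
    RearrangementPoint,
    SyntenyAlignment,
    annotate_window_distance,
    detect_rearrangement_points,
    filter_alignments,
    polarize_parsimony,
    read_paf,
)
from mescan.simulate import (
    RearrangementEvent,
    RearrangementScenario,
    random_rearrangement_scenario,
    simulate_rearrangement_history,
)


def aln(q, qs, qe, t, ts=0, te=None, mapq=60):
    return SyntenyAlignment(q, qs, qe, t, ts, te if te is not None else qe - qs, mapq)


class TestAlignmentFilter:
    def test_length_strictly_greater(self):
        exact = aln("q1", 0, 50_000, "t1")
        longer = aln("q1", 0, 50_001, "t1")
        assert filter_alignments([exact, longer]) == [longer]

    def test_mapq_threshold_inclusive(self):
        low = aln("q1", 0, 60_000, "t1", mapq=59)
        ok = aln("q1", 0, 60_000, "t1", mapq=60)
        assert filter_alignments([low, ok]) == [ok]

    def test_toy_paf_two_of_five_pass(self, tmp_path):
        rows = [
            ("q1", 100_000, 0, 60_000, "+", "t1", 100_000, 0, 60_000, 55_000, 60_000, 60),
            ("q1", 100_000, 0, 40_000, "+", "t1", 100_000, 0, 40_000, 39_000, 40_000, 60),
            ("q2", 90_000, 0, 80_000, "-", "t2", 90_000, 0, 80_000, 70_000, 80_000, 60),
            ("q2", 90_000, 0, 70_000, "+", "t2", 90_000, 0, 70_000, 60_000, 70_000, 30),
            ("q3", 50_000, 0, 50_000, "+", "t3", 50_000, 0, 50_000, 50_000, 50_000, 60),
        ]
        path = tmp_path / "toy.paf"
        with open(path, "w") as fh:
            fh.write("\n".join("\t".join(map(str, r)) for r in rows))
            fh.write("\nthis line is malformed\n")
        alignments = read_paf(path)
        assert len(alignments) == 5  # malformed line skipped
        assert len(filter_alignments(alignments)) == 2


class TestRearrangementPoints:
    def test_split_query_yields_one_junction(self):
        alignments = [
            aln("qA", 0, 4_000_000, "t1"),
            aln("qA", 4_100_000, 8_000_000, "t2"),
        ]
        points = detect_rearrangement_points(alignments, {"qA": 8_000_000})
        junctions = [p for p in points if p.kind == "internal_junction"]
        assert len(junctions) == 1
        assert junctions[0].position == pytest.approx(4_050_000)

    def test_one_to_one_pair_has_no_points(self):
        alignments = [aln("qA", 0, 5_000_000, "t1"), aln("qB", 0, 4_000_000, "t2")]
        assert detect_rearrangement_points(
            alignments, {"qA": 5_000_000, "qB": 4_000_000}
        ) == []

    def test_planted_events_recovered_within_gap_resolution(self):
        """A synthetic genome pair built from a known event list: the
        query fused t1+t2 (one junction) and target t4 spans the fission
        products qC/qD (chromosome ends)."""
        alignments = [
            # query qF = fusion of target chromosomes t1 and t2
            aln("qF", 0, 2_995_000, "t1"),
            aln("qF", 3_005_000, 7_000_000, "t2"),
            # qC and qD are fission products of target t4
            aln("qC", 0, 2_000_000, "t4", ts=0, te=2_000_000),
            aln("qD", 0, 1_500_000, "t4", ts=2_000_000, te=3_500_000),
        ]
        lengths = {"qF": 7_000_000, "qC": 2_000_000, "qD": 1_500_000}
        points = detect_rearrangement_points(alignments, lengths)
        junctions = [p for p in points if p.kind == "internal_junction"]
        ends = [p for p in points if p.kind == "chromosome_end"]
        assert len(junctions) == 1
        assert abs(junctions[0].position - 3_000_000) <= 5_000  # gap resolution
        assert {(p.chromosome) for p in ends} == {"qC", "qD"}


def replay(ancestral_groups, events):
    """Apply an event list to the ancestral partition (test oracle)."""
    karyotype = [set(g) for g in ancestral_groups]
    for kind, operands in events:
        if kind == "fission":
            parent, part_a, part_b = operands
            karyotype.remove(set(parent))
            karyotype.extend([set(part_a), set(part_b)])
        else:
            x, y = operands
            karyotype.remove(set(x))
            karyotype.remove(set(y))
            karyotype.append(set(x) | set(y))
    return {frozenset(c) for c in karyotype}


def leaf_partition(df, taxon):
    return {
        frozenset(g["marker_id"])
        for _, g in df[df.taxon == taxon].groupby("chromosome")
    }


class TestPolarizeParsimony:
    def test_identical_partitions_need_no_events(self):
        df = simulate_rearrangement_history(RearrangementScenario(6, (), 5))
        es = polarize_parsimony(df)
        assert es.counts == {"A": (0, 0), "B": (0, 0)}
        assert es.n_ancestral_chromosomes == 6

    def test_single_fusion_polarized_to_correct_branch(self):
        sc = RearrangementScenario(
            5, (RearrangementEvent("A", "fusion", ("anc2", "anc4")),), 8
        )
        es = polarize_parsimony(simulate_rearrangement_history(sc))
        assert es.counts == {"A": (0, 1), "B": (0, 0)}
        assert es.n_ancestral_chromosomes == 5

    def test_study_history_recovered_exactly(self):
        """Root of 16 chromosomes, 2 fissions + 5 fusions on the A branch
        (including two small ancestral chromosomes fused to different
        partners in either species) and 2 fusions on the B branch."""
        events = [
            RearrangementEvent("A", "fission", ("anc1",), 5),
            RearrangementEvent("A", "fission", ("anc2",), 5),
            RearrangementEvent("A", "fusion", ("anc1:1", "anc3")),
            RearrangementEvent("A", "fusion", ("anc1:2", "anc4")),
            RearrangementEvent("A", "fusion", ("anc2:1", "anc5")),
            # the two small ancestral chromosomes anc9, anc11 fuse to
            # different partners in either lineage
            RearrangementEvent("A", "fusion", ("anc9", "anc6")),
            RearrangementEvent("A", "fusion", ("anc11", "anc7")),
            RearrangementEvent("B", "fusion", ("anc9", "anc10")),
            RearrangementEvent("B", "fusion", ("anc11", "anc12")),
        ]
        df = simulate_rearrangement_history(
            RearrangementScenario(16, tuple(events), 10)
        )
        es = polarize_parsimony(df)
        assert es.n_ancestral_chromosomes == 16
        assert es.counts["A"] == (2, 5)
        assert es.counts["B"] == (0, 2)

    def test_replay_reproduces_leaf_partitions(self):
        for seed in range(10):
            sc = random_rearrangement_scenario(10, 3, 2, markers_per_chrom=8, seed=seed)
            df = simulate_rearrangement_history(sc)
            es = polarize_parsimony(df)
            for taxon in ("A", "B"):
                assert replay(es.ancestral_groups, es.events[taxon]) == leaf_partition(
                    df, taxon
                )

    def test_chromosome_count_parity(self):
        for seed in (3, 7, 11):
            sc = random_rearrangement_scenario(9, 4, 4, markers_per_chrom=6, seed=seed)
            df = simulate_rearrangement_history(sc)
            es = polarize_parsimony(df)
            for taxon in ("A", "B"):
                fis, fus = es.counts[taxon]
                n_leaf = df[df.taxon == taxon]["chromosome"].nunique()
                assert n_leaf == es.n_ancestral_chromosomes + fis - fus

    def test_no_shared_markers_rejected(self):
        df = pd.DataFrame(
            {
                "marker_id": ["m1", "m2"],
                "taxon": ["A", "B"],
                "chromosome": ["A_1", "B_1"],
            }
        )
        with pytest.raises(ValueError, match="shared"):
            polarize_parsimony(df)


class TestWindowDistance:
    def point(self, chrom, pos):
        return RearrangementPoint("query", chrom, pos, "internal_junction")

    def test_overlapping_point_is_near_with_zero_distance(self):
        windows = pd.DataFrame(
            {"chromosome": ["c1"], "start": [100], "end": [200]}
        )
        out = annotate_window_distance(windows, [self.point("c1", 150)], radius=1e6)
        assert out.distance_to_point.iloc[0] == 0
        assert out.proximity.iloc[0] == "near"

    def test_far_beyond_radius(self):
        windows = pd.DataFrame(
            {"chromosome": ["c1"], "start": [0], "end": [100_000]}
        )
        out = annotate_window_distance(
            windows, [self.point("c1", 1_600_000)], radius=1e6
        )
        assert out.proximity.iloc[0] == "far"
        assert out.distance_to_point.iloc[0] == pytest.approx(1_500_000)

    def test_chromosome_without_points_is_not_applicable(self):
        windows = pd.DataFrame(
            {"chromosome": ["c9"], "start": [0], "end": [100]}
        )
        out = annotate_window_distance(windows, [self.point("c1", 5)], radius=1e6)
        assert out.proximity.iloc[0] == "not_applicable"

    def test_matches_brute_force_on_toy_set(self, rng):
        windows = pd.DataFrame(
            {
                "chromosome": rng.choice(["c1", "c2"], size=50),
                "start": rng.integers(0, 5_000_000, size=50),
            }
        )
        windows["end"] = windows["start"] + 100_000
        points = [
            self.point(c, float(p))
            for c, p in zip(
                rng.choice(["c1", "c2"], size=6), rng.integers(0, 5_000_000, size=6)
            )
        ]
        out = annotate_window_distance(windows, points, radius=1e6)
        for _, row in out.iterrows():
            ds = [
                0.0
                if row.start <= p.position <= row.end
                else min(abs(p.position - row.start), abs(p.position - row.end))
                for p in points
                if p.chromosome == row.chromosome
            ]
            if ds:
                assert row.distance_to_point == pytest.approx(min(ds))
            else:
                assert row.proximity == "not_applicable"
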