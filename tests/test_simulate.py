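import numpy as np
import pytest
import scipy.stats

from mescan.demography import (
    DemographyParams,
    expected_heterozygosity_two_epoch,
)
from mescan.simulate import (
    RearrangementEvent,
    RearrangementScenario,
    random_rearrangement_scenario,
    simulate_block_tallies,
    simulate_pairwise_diversity,
    simulate_rearrangement_history,
    simulate_vcf_bed,
)


class TestBlockTallies:
    def test_block_count_and_determinism(self, block_config):
        params = DemographyParams(1e5, 2e5, 3e5, 1e5)
        a = simulate_block_tallies(params, block_config, 500, n_pairs=3, seed=42)
        b = simulate_block_tallies(params, block_config, 500, n_pairs=3, seed=42)
        assert a.n_blocks == 1500
        assert np.array_equal(a.counts, b.counts)
        c = simulate_block_tallies(params, block_config, 500, n_pairs=3, seed=43)
        assert not np.array_equal(a.counts, c.counts)

    def test_rejects_invalid_inputs(self, block_config):
        params = DemographyParams(1e5, 2e5, 3e5, 1e5)
        with pytest.raises(ValueError):
            simulate_block_tallies(params, block_config, 0, seed=1)
        with pytest.raises(ValueError, match="ne_a"):
            DemographyParams(-1e5, 2e5, 3e5, 1e5)

    def test_panmixia_diversity_is_theta(self, block_config):
        """With split_time=0 the history collapses to one population of
        size Ne_anc: any two haplotypes differ at 4*Ne*mu per site."""
        params = DemographyParams(1e5, 1e5, 5e5, 0.0)
        pi = simulate_pairwise_diversity(params, block_config, 30_000, seed=8)
        assert pi == pytest.approx(4 * 5e5 * params.mu, rel=0.05)

    def test_within_donor_species_follows_two_epoch_form(
        self, im_params, block_config
    ):
        """B lineages never migrate backwards in time under gene flow into
        A, so within-B diversity follows the two-epoch closed form."""
        het = simulate_pairwise_diversity(
            im_params, block_config, 40_000, seed=9, pair=("B", "B")
        )
        expected = expected_heterozygosity_two_epoch(
            im_params.ne_b, im_params.ne_anc, im_params.split_time, im_params.mu
        )
        assert het == pytest.approx(expected, rel=0.05)

    def test_zero_migration_indistinguishable_from_div(self, block_config):
        """IM tallies at me=0 and DIV tallies at the same remaining
        parameters agree in distribution (chi-square on pooled bSFS bins)."""
        div = DemographyParams(2e5, 4e5, 8e5, 8e5)
        n = 15_000
        a = simulate_block_tallies(div, block_config, n, seed=21)
        b = simulate_block_tallies(div, block_config, n, seed=22)
        ca, cb = a.counts.ravel(), b.counts.ravel()
        keep = (ca + cb) >= 10
        obs = np.array([
            np.append(ca[keep], ca[~keep].sum()),
            np.append(cb[keep], cb[~keep].sum()),
        ])
        _, p, _, _ = scipy.stats.chi2_contingency(obs[:, obs.sum(axis=0) > 0])
        assert p > 1e-3

    def test_linked_mode_matches_unlinked_expectations(self, block_config):
        params = DemographyParams(2e5, 2e5, 2e5, 1e3)
        linked = simulate_block_tallies(
            params, block_config, 2000, seed=5, linked=True
        )
        assert linked.n_blocks == 2000
        # same overall polymorphism level as the unlinked mode
        unlinked = simulate_block_tallies(params, block_config, 2000, seed=5)
        rate_l = 1 - linked.counts[0, 0, 0, 0] / linked.n_blocks
        rate_u = 1 - unlinked.counts[0, 0, 0, 0] / unlinked.n_blocks
        assert rate_l == pytest.approx(rate_u, abs=0.05)


class TestVcfBed:
    def test_zero_mutation_rate_gives_empty_vcf(self, tmp_path, block_config):
        params = DemographyParams(1e5, 1e5, 1e5, 1e4, mu=0.0)
        vcf, bed = simulate_vcf_bed(
            params, block_config, 2, 2, [10_000], seed=3, out_dir=tmp_path
        )
        records = [l for l in open(vcf) if not l.startswith("#")]
        assert records == []
        chrom, start, end = open(bed).read().split()
        assert (start, end) == ("0", "10000")

    def test_missing_rate_masks_half_the_calls(self, tmp_path, block_config):
        params = DemographyParams(5e5, 5e5, 5e5, 1e4)
        vcf, _ = simulate_vcf_bed(
            params, block_config, 3, 3, [50_000], missing_rate=0.5,
            seed=4, out_dir=tmp_path,
        )
        total = missing = 0
        for line in open(vcf):
            if line.startswith("#"):
                continue
            for field in line.split("\t")[9:]:
                total += 1
                missing += field.startswith("./.")
        assert total > 500
        assert missing / total == pytest.approx(0.5, abs=0.05)

    def test_rejects_zero_individuals(self, tmp_path, block_config):
        params = DemographyParams(1e5, 1e5, 1e5, 1e4)
        with pytest.raises(ValueError, match="individual"):
            simulate_vcf_bed(params, block_config, 0, 2, [1000], out_dir=tmp_path)


class TestRearrangementHistories:
    def test_no_events_gives_identical_partitions(self):
        df = simulate_rearrangement_history(
            RearrangementScenario(n_ancestral_chroms=5, markers_per_chrom=4)
        )
        parts = {
            t: frozenset(
                frozenset(g["marker_id"])
                for _, g in df[df.taxon == t].groupby("chromosome")
            )
            for t in "ABO"
        }
        assert parts["A"] == parts["B"] == parts["O"]
        assert len(parts["A"]) == 5

    def test_fusion_reduces_chromosome_count_by_one(self):
        sc = RearrangementScenario(
            4, (RearrangementEvent("A", "fusion", ("anc1", "anc2")),), 5
        )
        df = simulate_rearrangement_history(sc)
        counts = df.groupby("taxon")["chromosome"].nunique()
        assert counts["A"] == 3 and counts["B"] == 4 and counts["O"] == 4

    def test_event_parity_in_any_order(self):
        """Chromosome counts follow root + fissions - fusions per branch."""
        for seed in range(5):
            sc = random_rearrangement_scenario(8, 4, 3, markers_per_chrom=6, seed=seed)
            df = simulate_rearrangement_history(sc)
            counts = df.groupby("taxon")["chromosome"].nunique()
            for branch in "AB":
                fis = sum(
                    1 for e in sc.events if e.branch == branch and e.kind == "fission"
                )
                fus = sum(
                    1 for e in sc.events if e.branch == branch and e.kind == "fusion"
                )
                assert counts[branch] == 8 + fis - fus

    def test_study_history_chromosome_counts(self):
        """Root of 16; 2 fissions + 5 fusions on one branch and 2 fusions
        on the other give 13 and 14 extant chromosomes."""
        events = [
            RearrangementEvent("A", "fission", ("anc1",), 5),
            RearrangementEvent("A", "fission", ("anc2",), 5),
            RearrangementEvent("A", "fusion", ("anc1:1", "anc3")),
            RearrangementEvent("A", "fusion", ("anc1:2", "anc4")),
            RearrangementEvent("A", "fusion", ("anc2:1", "anc5")),
            RearrangementEvent("A", "fusion", ("anc2:2", "anc6")),
            RearrangementEvent("A", "fusion", ("anc7", "anc8")),
            RearrangementEvent("B", "fusion", ("anc9", "anc10")),
            RearrangementEvent("B", "fusion", ("anc11", "anc12")),
        ]
        df = simulate_rearrangement_history(
            RearrangementScenario(16, tuple(events), 10)
        )
        counts = df.groupby("taxon")["chromosome"].nunique()
        assert (counts["A"], counts["B"], counts["O"]) == (13, 14, 16)

    def test_invalid_events_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            RearrangementEvent("A", "fusion", ("anc1", "anc1"))
        with pytest.raises(ValueError, match="unknown chromosome"):
            simulate_rearrangement_history(
                RearrangementScenario(
                    2, (RearrangementEvent("A", "fusion", ("anc1", "anc9")),), 3
                )
            )
        with pytest.raises(ValueError, match="empty"):
            simulate_rearrangement_history(
                RearrangementScenario(
                    2, (RearrangementEvent("A", "fission", ("anc1",), 3),), 3
                )
            )
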