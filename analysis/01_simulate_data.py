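"""Generate the synthetic study inputs every later step consumes.

Writes under results/synthetic/:
  * a diploid VCF + callable BED for 3+3 individuals on two ~150 kb
    chromosomes, simulated under the fitted IM history (gene flow B->A)
    with 0.5% missing genotype calls;
  * genic/repeat masks (arbitrary small intervals) for the intergenic
    filter;
  * a three-taxon marker table carrying the study's rearrangement
    history (root of 16 chromosomes; 2 fissions + 5 fusions on the A
    branch, 2 fusions on the B branch);
  * a toy PAF alignment between a fused query chromosome and its two
    target homologs, for rearrangement-point detection.
"""

from pathlib import Path

from mescan.demography import TABLE_IM_INTO_A, BlockConfig
from mescan.simulate import (
    RearrangementEvent,
    RearrangementScenario,
    simulate_rearrangement_history,
    simulate_vcf_bed,
)

OUT = Path("results/synthetic")
SEED = 20230222

STUDY_EVENTS = (
    RearrangementEvent("A", "fission", ("anc1",), 5),
    RearrangementEvent("A", "fission", ("anc2",), 5),
    RearrangementEvent("A", "fusion", ("anc1:1", "anc3")),
    RearrangementEvent("A", "fusion", ("anc1:2", "anc4")),
    RearrangementEvent("A", "fusion", ("anc2:1", "anc5")),
    RearrangementEvent("A", "fusion", ("anc9", "anc6")),
    RearrangementEvent("A", "fusion", ("anc11", "anc7")),
    RearrangementEvent("B", "fusion", ("anc9", "anc10")),
    RearrangementEvent("B", "fusion", ("anc11", "anc12")),
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    vcf, bed = simulate_vcf_bed(
        TABLE_IM_INTO_A,
        BlockConfig(),
        n_individuals_a=3,
        n_individuals_b=3,
        chrom_lengths=[150_000, 150_000],
        missing_rate=0.005,
        seed=SEED,
        out_dir=OUT,
    )
    n_records = sum(1 for line in open(vcf) if not line.startswith("#"))
    print(f"wrote {vcf} ({n_records} variant records) and {bed}")

    with open(OUT / "genic.bed", "w") as fh:
        fh.write("chr1\t40000\t55000\nchr2\t10000\t20000\nchr2\t90000\t96000\n")
    with open(OUT / "repeats.bed", "w") as fh:
        fh.write("chr1\t100000\t104000\nchr2\t50000\t51000\n")

    markers = simulate_rearrangement_history(
        RearrangementScenario(16, STUDY_EVENTS, markers_per_chrom=10)
    )
    markers.to_csv(OUT / "markers.tsv", sep="\t", index=False)
    counts = markers.groupby("taxon")["chromosome"].nunique().to_dict()
    print(f"marker table: chromosome counts per taxon {counts}")

    # toy alignment: query qF is a fusion of targets t1+t2; qC/qD are
    # fission products of t4; q5 maps one-to-one to t5
    paf_rows = [
        ("qF", 7_000_000, 0, 2_995_000, "+", "t1", 3_000_000, 0, 2_995_000,
         2_900_000, 2_995_000, 60),
        ("qF", 7_000_000, 3_005_000, 7_000_000, "+", "t2", 4_000_000, 0,
         3_995_000, 3_900_000, 3_995_000, 60),
        ("qC", 2_000_000, 0, 2_000_000, "+", "t4", 3_500_000, 0, 2_000_000,
         1_950_000, 2_000_000, 60),
        ("qD", 1_500_000, 0, 1_500_000, "-", "t4", 3_500_000, 2_000_000,
         3_500_000, 1_480_000, 1_500_000, 60),
        ("q5", 2_500_000, 0, 2_500_000, "+", "t5", 2_500_000, 0, 2_500_000,
         2_400_000, 2_500_000, 60),
        ("q5", 2_500_000, 100, 30_000, "+", "t9", 2_500_000, 0, 29_900,
         20_000, 29_900, 12),  # short low-quality alignment, filtered out
    ]
    with open(OUT / "alignment.paf", "w") as fh:
        for row in paf_rows:
            fh.write("\t".join(map(str, row)) + "\n")
    print(f"wrote {OUT / 'alignment.paf'} ({len(paf_rows)} records)")


if __name__ == "__main__":
    main()
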