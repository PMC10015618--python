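"""Filter the synthetic VCF and build the intergenic callable mask.

Applies the variant filter (SNPs >= 2 bp from indels, QUAL >= 10,
per-genotype depth within [8, 3x mean coverage]) and subtracts the
genic/repeat masks from the callable BED.  Writes
results/preprocess/{filtered.vcf, intergenic.bed}.
"""

from pathlib import Path

from mescan.preprocess import (
    CallableProfile,
    FilterRules,
    filter_variants,
    intergenic_callable,
    read_bed,
    read_vcf_records,
    write_bed,
    write_vcf_records,
)

IN = Path("results/synthetic")
OUT = Path("results/preprocess")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    records = read_vcf_records(IN / "synthetic.vcf")
    samples = records[0].samples
    profile = CallableProfile(mean_coverage={s: 20.0 for s in samples})
    kept = filter_variants(records, FilterRules(), profile)
    write_vcf_records(kept, OUT / "filtered.vcf", contigs=["chr1", "chr2"])
    print(f"variants: {len(records)} in, {len(kept)} retained")

    callable_bed = read_bed(IN / "synthetic.callable.bed")
    genic = read_bed(IN / "genic.bed")
    repeats = read_bed(IN / "repeats.bed")
    intergenic = intergenic_callable(callable_bed, genic, repeats)
    write_bed(intergenic, OUT / "intergenic.bed")
    before = int((callable_bed.end - callable_bed.start).sum())
    after = int((intergenic.end - intergenic.start).sum())
    print(f"callable: {before} bp -> {after} bp intergenic")


if __name__ == "__main__":
    main()
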