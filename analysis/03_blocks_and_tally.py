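"""Cut pairwise blocks and tally the genome-wide bSFS plus summaries.

For every interspecific pair (3 x 3 diploids) blocks of 64 callable
bases (max span 128) are cut from the intergenic mask and tallied at
kmax = 2 per mutation type.  Also computes heterozygosity, dxy and FST
from the filtered variants.  Writes results/blocks/{tally.tsv,
diversity.json}.
"""

import itertools
import json
from pathlib import Path

from mescan.blocks import cut_blocks, read_vcf_pair_genotypes, tally_blocks
from mescan.bsfs import BsfsTally
from mescan.demography import BlockConfig
from mescan.preprocess import read_bed
from mescan.stats import diversity_stats

IN = Path("results/preprocess")
OUT = Path("results/blocks")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = BlockConfig()
    bed = read_bed(IN / "intergenic.bed")
    samples_a = [f"A_{i}" for i in range(3)]
    samples_b = [f"B_{i}" for i in range(3)]

    total = BsfsTally.zeros(kmax=cfg.kmax, block_span=cfg.block_span)
    n_pairs = 0
    for sa, sb in itertools.product(samples_a, samples_b):
        variants = read_vcf_pair_genotypes(IN / "filtered.vcf", sa, sb)
        for chrom, group in bed.groupby("chrom"):
            blocks = cut_blocks(
                group[["start", "end"]].to_numpy(), cfg, chromosome=str(chrom)
            )
            total = total + tally_blocks(
                blocks, variants, kmax=cfg.kmax, block_span=cfg.block_span
            )
        n_pairs += 1
    total.to_frame().to_csv(OUT / "tally.tsv", sep="\t", index=False)
    print(
        f"{n_pairs} pairs: {total.n_blocks} blocks retained, "
        f"{total.n_discarded} discarded (missing/multiallelic sites)"
    )

    groups = {s: "A" for s in samples_a} | {s: "B" for s in samples_b}
    stats = diversity_stats(IN / "filtered.vcf", bed, groups)
    summary = {
        "dxy": stats.dxy,
        "fst": stats.fst,
        "heterozygosity": stats.heterozygosity,
        "n_callable": stats.n_sites,
    }
    with open(OUT / "diversity.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(f"dxy={stats.dxy:.4f} fst={stats.fst:.4f}")


if __name__ == "__main__":
    main()
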