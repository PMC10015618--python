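"""Cutting callable sequence into fixed-content blocks and tallying the bSFS.

Blocks contain exactly ``block_span`` callable bases for one
interspecific pair (one diploid per species) and may stretch over at
most ``max_span`` genomic bases.  Packing is greedy and left-anchored:
starting at the leftmost unused callable base, the next ``block_span``
callable bases form a candidate block; it is emitted iff its genomic
span fits, otherwise packing restarts at the next callable base.

Each biallelic site within a block is classified into one of the four
unpolarized mutation types (hetA/hetB/hetAB/fixed); callable positions
with no variant record are invariant.  Sites that are missing or carry
more than two alleles within the sampled pair are unusable and void the
block (conservative; such blocks are counted in the discard log).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .bsfs import BsfsTally
from .demography import BlockConfig

logger = logging.getLogger(__name__)

__all__ = [
    "Block",
    "classify_site",
    "cut_blocks",
    "tally_blocks",
    "intersect_intervals",
    "read_vcf_pair_genotypes",
]

MISSING = -1

_TYPE_INDEX = {"hetA": 0, "hetB": 1, "hetAB": 2, "fixed": 3}


@dataclasses.dataclass(frozen=True)
class Block:
    """A block of exactly ``block_span`` callable positions for one pair."""

    chromosome: str
    positions: np.ndarray  # 0-based, strictly increasing

    @property
    def start(self) -> int:
        return int(self.positions[0])

    @property
    def end(self) -> int:  # 0-based half-open genomic span
        return int(self.positions[-1]) + 1

    @property
    def span(self) -> int:
        return self.end - self.start


def classify_site(genotype_a, genotype_b) -> str:
    """Mutation type of one site for two unphased diploid genotypes.

    Genotypes are pairs of allele indices; ``-1`` marks a missing
    allele.  Returns one of ``hetA``, ``hetB``, ``hetAB``, ``fixed``,
    ``invariant``, ``unusable``.
    """
    a = (int(genotype_a[0]), int(genotype_a[1]))
    b = (int(genotype_b[0]), int(genotype_b[1]))
    if MISSING in a or MISSING in b:
        return "unusable"
    alleles = set(a) | set(b)
    if len(alleles) > 2:
        return "unusable"
    het_a = a[0] != a[1]
    het_b = b[0] != b[1]
    if het_a and het_b:
        return "hetAB"
    if het_a:
        return "hetA"
    if het_b:
        return "hetB"
    if a[0] != b[0]:
        return "fixed"
    return "invariant"


def intersect_intervals(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Intersection of two sorted (n, 2) half-open interval arrays."""
    a = np.asarray(a, dtype=np.int64).reshape(-1, 2)
    b = np.asarray(b, dtype=np.int64).reshape(-1, 2)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if lo < hi:
            out.append((lo, hi))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def cut_blocks(
    pair_callable: np.ndarray,
    config: BlockConfig,
    chromosome: str = "chr",
) -> list[Block]:
    """Greedy left-anchored packing of callable intervals into blocks.

    ``pair_callable`` is an (n, 2) array of sorted, non-overlapping
    0-based half-open intervals (already intersected across the two
    individuals of the pair).  Deterministic; gappy regions that cannot
    satisfy ``max_span`` simply yield no blocks.
    """
    intervals = np.asarray(pair_callable, dtype=np.int64).reshape(-1, 2)
    if len(intervals) == 0:
        return []
    positions = np.concatenate([np.arange(lo, hi) for lo, hi in intervals])
    span = config.block_span
    blocks = []
    i = 0
    n = len(positions)
    while i + span <= n:
        genomic_span = positions[i + span - 1] - positions[i] + 1
        if genomic_span <= config.max_span:
            blocks.append(Block(chromosome, positions[i : i + span].copy()))
            i += span
        else:
            i += 1
    return blocks


def tally_blocks(
    blocks: list[Block],
    variants: dict,
    kmax=(2, 2, 2, 2),
    block_span: int = 64,
) -> BsfsTally:
    """Tally the bSFS of a list of blocks against pair genotypes.

    ``variants`` maps ``(chromosome, 0-based position) -> (genotype_a,
    genotype_b)``.  Callable block positions absent from ``variants``
    are invariant.  Blocks containing any unusable site are discarded
    and counted in ``BsfsTally.n_discarded``.
    """
    raw = []
    discarded = 0
    for block in blocks:
        counts = [0, 0, 0, 0]
        usable = True
        for pos in block.positions:
            gt = variants.get((block.chromosome, int(pos)))
            if gt is None:
                continue
            kind = classify_site(*gt)
            if kind == "unusable":
                usable = False
                break
            if kind != "invariant":
                counts[_TYPE_INDEX[kind]] += 1
        if usable:
            raw.append(counts)
        else:
            discarded += 1
    if discarded:
        logger.info("tally_blocks discarded %d blocks with unusable sites", discarded)
    raw_arr = np.array(raw, dtype=np.int64).reshape(-1, 4)
    tally = BsfsTally.from_raw_counts(raw_arr, kmax=tuple(kmax), block_span=block_span)
    tally.n_discarded = discarded
    return tally


def read_vcf_pair_genotypes(vcf_path, sample_a: str, sample_b: str) -> dict:
    """Read pair genotypes from a VCF into a ``tally_blocks`` variants map.

    Only SNP records are used (indels are expected to have been removed
    by the filtering stage).  Missing genotypes are encoded as ``-1``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    try:
        idx_a = vcf.samples.index(sample_a)
        idx_b = vcf.samples.index(sample_b)
    except ValueError as err:
        raise ValueError(
            f"samples {sample_a!r}/{sample_b!r} not found in {vcf_path}"
        ) from err
    variants = {}
    for rec in vcf:
        if not rec.is_snp:
            continue
        g = rec.genotype.array()
        gt_a = (int(g[idx_a][0]), int(g[idx_a][1]))
        gt_b = (int(g[idx_b][0]), int(g[idx_b][1]))
        variants[(rec.CHROM, rec.POS - 1)] = (gt_a, gt_b)
    return variants
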