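"""Variant and callable-site filtering.

Reproduces the preprocessing semantics of the variant-filtering stage
upstream of blockwise-SFS inference:

* SNPs within ``snp_gap`` bases of an indel are removed (distance to the
  indel's reference footprint; ``<= snp_gap`` removes, matching the
  SnpGap convention of bcftools),
* records with QUAL below ``min_qual`` are removed,
* per-sample genotypes with depth outside
  ``[min_depth, floor(max_depth_factor * sample mean coverage)]``
  (bounds inclusive) are set to missing,
* multiallelic SNP records are retained if they satisfy all other
  criteria; indel records themselves are excluded from the SNP output,
* the callable BED is stripped of genic and repeat regions to leave
  intergenic callable sequence.

Callable masks are kept per sample; pairwise intersection happens at
block construction.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import pyranges as pr

logger = logging.getLogger(__name__)

__all__ = [
    "FilterRules",
    "CallableProfile",
    "VariantRecord",
    "filter_variants",
    "intergenic_callable",
    "read_vcf_records",
    "write_vcf_records",
    "read_bed",
    "write_bed",
    "gff_genes_to_bed",
]

MISSING = -1


@dataclasses.dataclass(frozen=True)
class FilterRules:
    """Thresholds of the variant filter."""

    snp_gap: int = 2
    min_qual: float = 10.0
    min_depth: int = 8
    max_depth_factor: float = 3.0

    def __post_init__(self) -> None:
        if self.snp_gap < 0 or self.min_qual < 0 or self.min_depth < 0:
            raise ValueError("filter thresholds must be >= 0")
        if self.max_depth_factor <= 0:
            raise ValueError("max_depth_factor must be > 0")


@dataclasses.dataclass
class CallableProfile:
    """Per-sample mean coverage and callable intervals.

    ``intervals[sample]`` is a DataFrame with columns
    ``chrom, start, end`` (0-based half-open, sorted, non-overlapping).
    """

    mean_coverage: dict[str, float]
    intervals: dict[str, pd.DataFrame] = dataclasses.field(default_factory=dict)

    def max_depth(self, sample: str, rules: FilterRules) -> int:
        # the depth cap is stated in units of mean coverage; its rounding
        # is unspecified upstream, floor is this package's convention
        return int(np.floor(rules.max_depth_factor * self.mean_coverage[sample]))


@dataclasses.dataclass
class VariantRecord:
    """Minimal in-memory VCF record used by the filtering stage."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    qual: float
    samples: tuple[str, ...]
    genotypes: np.ndarray  # (n_samples, 2), -1 = missing
    depths: np.ndarray | None  # (n_samples,), None if absent

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) > 1 or any(len(a) != len(self.ref) for a in self.alts)

    def indel_footprint(self) -> tuple[int, int]:
        """1-based inclusive interval of reference bases the indel touches."""
        return self.pos, self.pos + len(self.ref) - 1


def filter_variants(
    records: list[VariantRecord],
    rules: FilterRules,
    profile: CallableProfile,
) -> list[VariantRecord]:
    """Apply the variant filter; returns retained SNP records.

    Genotypes failing the depth bounds are set to missing in place on
    copies of the input records.  Records without depth annotations are
    dropped with a per-record diagnostic.
    """
    indel_spans: dict[str, list[tuple[int, int]]] = {}
    for rec in records:
        if rec.is_indel:
            indel_spans.setdefault(rec.chrom, []).append(rec.indel_footprint())
    out = []
    for rec in records:
        if rec.is_indel or not rec.is_snp:
            continue
        if rec.qual < rules.min_qual:
            continue
        near_indel = any(
            lo - rules.snp_gap <= rec.pos <= hi + rules.snp_gap
            for lo, hi in indel_spans.get(rec.chrom, ())
        )
        if near_indel:
            continue
        if rec.depths is None:
            logger.warning(
                "dropping %s:%d: no depth annotation", rec.chrom, rec.pos
            )
            continue
        genotypes = rec.genotypes.copy()
        for i, sample in enumerate(rec.samples):
            depth = int(rec.depths[i])
            if depth < rules.min_depth or depth > profile.max_depth(sample, rules):
                genotypes[i] = MISSING
        out.append(dataclasses.replace(rec, genotypes=genotypes))
    return out


def _to_pyranges(bed: pd.DataFrame) -> pr.PyRanges:
    if (bed["start"] < 0).any() or (bed["end"] < 0).any():
        raise ValueError("negative coordinates in BED input")
    return pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": bed["chrom"].astype(str),
                "Start": bed["start"].astype(np.int64),
                "End": bed["end"].astype(np.int64),
            }
        )
    )


def _from_pyranges(gr: pr.PyRanges) -> pd.DataFrame:
    df = gr.df
    if len(df) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    out = pd.DataFrame(
        {"chrom": df["Chromosome"].astype(str), "start": df["Start"], "end": df["End"]}
    )
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def intergenic_callable(
    callable_bed: pd.DataFrame,
    genic: pd.DataFrame,
    repeats: pd.DataFrame,
) -> pd.DataFrame:
    """Subtract genic and repeat regions from callable intervals.

    All inputs are BED-like DataFrames (``chrom, start, end``, 0-based
    half-open).  Unsorted input is tolerated; the output is sorted and
    merged.  Negative coordinates are rejected.
    """
    gr = _to_pyranges(callable_bed).merge()
    masks = pd.concat(
        [df for df in (genic, repeats) if df is not None and len(df)],
        ignore_index=True,
    ) if (len(genic) or len(repeats)) else pd.DataFrame(
        columns=["chrom", "start", "end"]
    )
    if len(masks):
        gr = gr.subtract(_to_pyranges(masks).merge())
    return _from_pyranges(gr.merge() if len(gr) else gr)


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------


def read_vcf_records(vcf_path) -> list[VariantRecord]:
    """Read a VCF into :class:`VariantRecord` objects via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = tuple(vcf.samples)
    records = []
    for rec in vcf:
        g = rec.genotype.array()[:, :2].astype(np.int64)
        try:
            depths = rec.format("DP")
            depths = None if depths is None else depths.reshape(-1).astype(np.int64)
        except KeyError:
            depths = None
        records.append(
            VariantRecord(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alts=tuple(rec.ALT),
                qual=float(rec.QUAL) if rec.QUAL is not None else 0.0,
                samples=samples,
                genotypes=g,
                depths=depths,
            )
        )
    return records


def write_vcf_records(records: list[VariantRecord], path, contigs=None) -> None:
    """Write records as a minimal VCF v4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig in contigs or sorted({r.chrom for r in records}):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = records[0].samples if records else ()
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for rec in records:
            gts = [
                "./." if MISSING in gt else f"{gt[0]}/{gt[1]}"
                for gt in rec.genotypes
            ]
            fh.write(
                "\t".join(
                    [
                        rec.chrom,
                        str(rec.pos),
                        ".",
                        rec.ref,
                        ",".join(rec.alts),
                        f"{rec.qual:g}",
                        "PASS",
                        ".",
                        "GT",
                    ]
                    + gts
                )
                + "\n"
            )


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def gff_genes_to_bed(gff_path) -> pd.DataFrame:
    """Extract gene features from a GFF3 file as a BED DataFrame."""
    rows = []
    with open(gff_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5 or parts[2] != "gene":
                continue
            # GFF is 1-based inclusive; BED is 0-based half-open
            rows.append((parts[0], int(parts[3]) - 1, int(parts[4])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
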