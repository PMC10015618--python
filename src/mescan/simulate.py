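"""Synthetic-data generators for the whole pipeline.

Three generators stand in for the study system's raw data so that every
downstream stage is testable without external downloads:

* coalescent block tallies under DIV/IM histories (unlinked blocks by
  default; a linked mode with inter-block recombination reproduces the
  parametric-bootstrap setting),
* VCF + BED output of diploid genotypes with optional missingness, for
  end-to-end tests of the preprocess/blocks stages,
* three-taxon marker tables produced by applying fission and fusion
  events along a rooted tree ((A,B),O).

All randomness is seeded explicitly; no global random state is used.
Forwards-in-time migration donor -> recipient is simulated as
recipient-lineage movement into the donor deme at rate ``me`` per
lineage per generation (the standard backwards-time convention).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import msprime
import numpy as np
import pandas as pd

from .bsfs import BsfsTally
from .demography import BlockConfig, DemographyParams, Direction

__all__ = [
    "RearrangementEvent",
    "RearrangementScenario",
    "build_demography",
    "simulate_block_tallies",
    "simulate_pairwise_diversity",
    "simulate_vcf_bed",
    "simulate_rearrangement_history",
    "random_rearrangement_scenario",
]

# lineage subtending (na, nb) haplotypes -> mutation-type axis
_TYPE_OF = {
    (1, 0): 0,
    (0, 1): 1,
    (1, 1): 2,
    (2, 0): 3,
    (0, 2): 3,
    (2, 1): 1,
    (1, 2): 0,
}


def build_demography(params: DemographyParams) -> msprime.Demography:
    """msprime demography for a two-population DIV/IM history.

    A zero split time collapses to a single panmictic population of
    size ``ne_anc`` (msprime cannot place a split at time 0).
    """
    if params.split_time == 0:
        dem = msprime.Demography()
        dem.add_population(name="anc", initial_size=params.ne_anc)
        return dem
    dem = msprime.Demography()
    dem.add_population(name="A", initial_size=params.ne_a)
    dem.add_population(name="B", initial_size=params.ne_b)
    dem.add_population(name="anc", initial_size=params.ne_anc)
    if params.me > 0:
        # backwards in time, recipient lineages move into the donor deme
        recipient = "A" if params.direction is Direction.into_A else "B"
        donor = "B" if recipient == "A" else "A"
        dem.set_migration_rate(source=recipient, dest=donor, rate=params.me)
    dem.add_population_split(
        time=params.split_time, derived=["A", "B"], ancestral="anc"
    )
    return dem


def _simulate_block_trees(
    params: DemographyParams, block_span: int, n_reps: int, seed: int
):
    """Simulate independent 2+2-haplotype block genealogies.

    Returns per-replicate edge child/parent indices, node times and
    per-node subtended leaf counts.  Sample nodes 0,1 are the A diploid;
    2,3 the B diploid.  Every genealogy has 7 nodes and 6 edges.
    """
    if n_reps < 1:
        raise ValueError(f"need at least one replicate, got {n_reps}")
    samples = {"anc": 2} if params.split_time == 0 else {"A": 1, "B": 1}
    reps = msprime.sim_ancestry(
        samples=samples,
        demography=build_demography(params),
        ploidy=2,
        sequence_length=block_span,
        num_replicates=n_reps,
        random_seed=seed,
    )
    child = np.empty((n_reps, 6), dtype=np.int32)
    parent = np.empty((n_reps, 6), dtype=np.int32)
    times = np.empty((n_reps, 7))
    for i, ts in enumerate(reps):
        t = ts.tables
        child[i] = t.edges.child
        parent[i] = t.edges.parent
        times[i] = t.nodes.time
    # per-node counts of subtended sampled leaves (a1, a2, b1, b2)
    rows = np.arange(n_reps)
    leaves = np.zeros((n_reps, 7, 4), dtype=np.int16)
    for leaf in range(4):
        leaves[:, leaf, leaf] = 1
    # tskit edges are sorted by parent time, so a single pass accumulates
    for e in range(6):
        leaves[rows, parent[:, e]] += leaves[rows, child[:, e]]
    return child, parent, times, leaves


def _branch_types_and_lengths(child, parent, times, leaves):
    """Per-edge mutation type and branch length (generations)."""
    rows = np.arange(child.shape[0])[:, None]
    blen = times[rows, parent] - times[rows, child]
    na = (leaves[rows, child, 0] + leaves[rows, child, 1]).astype(np.int64)
    nb = (leaves[rows, child, 2] + leaves[rows, child, 3]).astype(np.int64)
    typ = np.empty(child.shape, dtype=np.int64)
    for (a, b), t in _TYPE_OF.items():
        typ[(na == a) & (nb == b)] = t
    return typ, blen


def simulate_block_tallies(
    params: DemographyParams,
    config: BlockConfig,
    n_blocks: int,
    n_pairs: int = 1,
    seed: int = 1,
    linked: bool = False,
) -> BsfsTally:
    """Simulate a blockwise-SFS tally under a DIV/IM history.

    The returned tally contains ``n_blocks * n_pairs`` blocks.  In the
    default unlinked mode every block is an independent genealogy and
    mutations of each type are Poisson on the branches of that genealogy
    (infinite sites within a block).  In linked mode a single sequence of
    ``n_blocks * block_span`` bases is simulated per pair with
    ``config.recomb_rate`` recombination and cut into consecutive blocks.
    """
    if n_blocks < 1 or n_pairs < 1:
        raise ValueError("n_blocks and n_pairs must be >= 1")
    if linked:
        return _simulate_linked_tallies(params, config, n_blocks, n_pairs, seed)
    n_reps = n_blocks * n_pairs
    child, parent, times, leaves = _simulate_block_trees(
        params, config.block_span, n_reps, seed
    )
    typ, blen = _branch_types_and_lengths(child, parent, times, leaves)
    rng = np.random.default_rng(seed + 1)
    u = params.mu * config.block_span
    muts = rng.poisson(u * blen)
    raw = np.zeros((n_reps, 4), dtype=np.int64)
    for t in range(4):
        raw[:, t] = np.where(typ == t, muts, 0).sum(axis=1)
    return BsfsTally.from_raw_counts(
        raw, kmax=config.kmax, block_span=config.block_span
    )


def _simulate_linked_tallies(params, config, n_blocks, n_pairs, seed):
    span = config.block_span
    length = n_blocks * span
    raws = []
    samples = {"anc": 2} if params.split_time == 0 else {"A": 1, "B": 1}
    for p in range(n_pairs):
        ts = msprime.sim_ancestry(
            samples=samples,
            demography=build_demography(params),
            ploidy=2,
            sequence_length=length,
            recombination_rate=config.recomb_rate,
            random_seed=seed + 2 * p,
        )
        ts = msprime.sim_mutations(
            ts, rate=params.mu, random_seed=seed + 2 * p + 1, discrete_genome=True
        )
        raw = np.zeros((n_blocks, 4), dtype=np.int64)
        for var in ts.variants():
            g = var.genotypes
            t = _classify_genotype_vector(g)
            if t is None:
                continue
            raw[int(var.site.position) // span, t] += 1
        raws.append(raw)
    return BsfsTally.from_raw_counts(
        np.concatenate(raws), kmax=config.kmax, block_span=span
    )


def _classify_genotype_vector(g) -> int | None:
    """Mutation type of a site from the 4 haplotype alleles (a1,a2,b1,b2)."""
    a, b = set(g[:2]), set(g[2:])
    het_a, het_b = len(a) == 2, len(b) == 2
    if len(a | b) > 2:
        return None  # >2 alleles across the pair
    if het_a and het_b:
        return 2
    if het_a:
        return 0
    if het_b:
        return 1
    if a != b:
        return 3
    return None  # invariant


def simulate_pairwise_diversity(
    params: DemographyParams,
    config: BlockConfig,
    n_blocks: int,
    seed: int = 1,
    pair: tuple[str, str] = ("A", "B"),
) -> float:
    """Mean per-site pairwise diversity between two sampled haplotypes.

    ``pair`` selects the haplotypes compared in each block: ``("A","B")``
    gives interspecific diversity (one haplotype per species, i.e. dxy of
    the sampled pair), ``("B","B")`` the heterozygosity of the B diploid,
    ``("A","A")`` that of the A diploid.  Mutational noise is included
    (Poisson on the connecting path), so this is an estimate whose
    expectation is ``2 * mu * E[pairwise coalescence time]``.
    """
    leaf_of = {"A": (0, 1), "B": (2, 3)}
    if pair == ("A", "B") or pair == ("B", "A"):
        i, j = 0, 2
    elif pair == ("A", "A"):
        i, j = leaf_of["A"]
    elif pair == ("B", "B"):
        i, j = leaf_of["B"]
    else:
        raise ValueError(f"unknown pair {pair}")
    child, parent, times, leaves = _simulate_block_trees(
        params, config.block_span, n_blocks, seed
    )
    # tmrca(i, j) = earliest node subtending both haplotypes
    both = (leaves[:, :, i] > 0) & (leaves[:, :, j] > 0)
    tmrca = np.where(both, times, np.inf).min(axis=1)
    rng = np.random.default_rng(seed + 1)
    diffs = rng.poisson(2.0 * params.mu * config.block_span * tmrca)
    return float(diffs.sum() / (n_blocks * config.block_span))


# ---------------------------------------------------------------------------
# VCF + BED emission
# ---------------------------------------------------------------------------


def simulate_vcf_bed(
    params: DemographyParams,
    config: BlockConfig,
    n_individuals_a: int,
    n_individuals_b: int,
    chrom_lengths: list[int],
    missing_rate: float = 0.0,
    seed: int = 1,
    out_dir: str | Path = ".",
    prefix: str = "synthetic",
    mean_depth: float = 20.0,
) -> tuple[Path, Path]:
    """Simulate diploid genotypes and write a VCF v4.2 plus a callable BED.

    One linked sequence per chromosome is simulated with recombination at
    ``config.recomb_rate`` and mutations at ``params.mu`` (Jukes-Cantor,
    discrete sites, so occasional multiallelic sites arise as in real
    SNP data).  A fraction ``missing_rate`` of genotype calls is set to
    missing.  The BED lists callable intervals (here: whole chromosomes,
    0-based half-open); VCF positions are 1-based.  Per-genotype depths
    are Poisson(``mean_depth``) so the filtering stage can run end to end.
    """
    if n_individuals_a < 1 or n_individuals_b < 1:
        raise ValueError("need at least one individual per species")
    if not chrom_lengths:
        raise ValueError("chrom_lengths must be non-empty")
    if not (0 <= missing_rate < 1):
        raise ValueError(f"missing_rate must be in [0, 1), got {missing_rate}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vcf_path = out_dir / f"{prefix}.vcf"
    bed_path = out_dir / f"{prefix}.callable.bed"
    rng = np.random.default_rng(seed)
    samples = [f"A_{i}" for i in range(n_individuals_a)] + [
        f"B_{i}" for i in range(n_individuals_b)
    ]
    n_samples = len(samples)
    with open(vcf_path, "w") as vcf, open(bed_path, "w") as bed:
        vcf.write("##fileformat=VCFv4.2\n")
        vcf.write(f"##source=mescan simulate_vcf_bed seed={seed}\n")
        for c, length in enumerate(chrom_lengths, start=1):
            vcf.write(f"##contig=<ID=chr{c},length={int(length)}>\n")
        vcf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        vcf.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        vcf.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for c, length in enumerate(chrom_lengths, start=1):
            chrom = f"chr{c}"
            bed.write(f"{chrom}\t0\t{int(length)}\n")
            sample_conf = (
                {"anc": n_individuals_a + n_individuals_b}
                if params.split_time == 0
                else {"A": n_individuals_a, "B": n_individuals_b}
            )
            ts = msprime.sim_ancestry(
                samples=sample_conf,
                demography=build_demography(params),
                ploidy=2,
                sequence_length=length,
                recombination_rate=config.recomb_rate,
                random_seed=int(rng.integers(1, 2**31 - 1)),
            )
            ts = msprime.sim_mutations(
                ts,
                rate=params.mu,
                random_seed=int(rng.integers(1, 2**31 - 1)),
                discrete_genome=True,
            )
            for var in ts.variants():
                alleles = var.alleles
                ref, alts = alleles[0], [a for a in alleles[1:] if a is not None]
                if not alts:
                    continue
                g = var.genotypes.reshape(n_samples, 2)
                missing = rng.random(n_samples) < missing_rate
                depth = rng.poisson(mean_depth, size=n_samples)
                gts = [
                    "./."
                    if missing[s]
                    else f"{g[s, 0]}/{g[s, 1]}"
                    for s in range(n_samples)
                ]
                fields = [
                    chrom,
                    str(int(var.site.position) + 1),
                    ".",
                    ref,
                    ",".join(alts),
                    "999",
                    "PASS",
                    ".",
                    "GT:DP",
                ] + [f"{gt}:{d}" for gt, d in zip(gts, depth)]
                vcf.write("\t".join(fields) + "\n")
    return vcf_path, bed_path


# ---------------------------------------------------------------------------
# rearrangement histories
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class RearrangementEvent:
    """One fission or fusion on a branch of the tree ((A,B),O).

    For a fusion, ``chroms`` names two distinct chromosomes existing at
    the time of the event.  For a fission, ``chroms`` names one
    chromosome and ``split_after`` gives the number of markers retained
    in the first product (both products must be non-empty).
    """

    branch: str  # "A", "B" or "O"
    kind: str  # "fission" or "fusion"
    chroms: tuple[str, ...]
    split_after: int | None = None

    def __post_init__(self) -> None:
        if self.branch not in ("A", "B", "O"):
            raise ValueError(f"branch must be A, B or O, got {self.branch!r}")
        if self.kind == "fusion":
            if len(self.chroms) != 2 or self.chroms[0] == self.chroms[1]:
                raise ValueError(f"fusion needs two distinct chromosomes: {self}")
        elif self.kind == "fission":
            if len(self.chroms) != 1 or not self.split_after or self.split_after < 1:
                raise ValueError(f"fission needs one chromosome and split_after >= 1: {self}")
        else:
            raise ValueError(f"kind must be fission or fusion, got {self.kind!r}")


@dataclasses.dataclass(frozen=True)
class RearrangementScenario:
    """A rooted 3-taxon rearrangement history.

    The tree is ((A,B),O); the root carries ``n_ancestral_chroms``
    chromosomes of ``markers_per_chrom`` markers each.  Events are
    applied in order along their branch; the outgroup O retains the root
    karyotype unless events are placed on its branch.
    """

    n_ancestral_chroms: int
    events: tuple[RearrangementEvent, ...] = ()
    markers_per_chrom: int = 10
    tree: str = "((A,B),O);"

    def __post_init__(self) -> None:
        if self.n_ancestral_chroms < 1:
            raise ValueError("need at least one ancestral chromosome")
        if self.markers_per_chrom < 1:
            raise ValueError("need at least one marker per chromosome")
        object.__setattr__(self, "events", tuple(self.events))


def _apply_events(root: dict[str, list[str]], events) -> dict[str, list[str]]:
    karyotype = {k: list(v) for k, v in root.items()}
    for ev in events:
        for c in ev.chroms:
            if c not in karyotype:
                raise ValueError(f"event {ev} references unknown chromosome {c!r}")
        if ev.kind == "fusion":
            c1, c2 = ev.chroms
            karyotype[f"({c1}+{c2})"] = karyotype.pop(c1) + karyotype.pop(c2)
        else:
            (c,) = ev.chroms
            markers = karyotype.pop(c)
            if not (0 < ev.split_after < len(markers)):
                raise ValueError(
                    f"fission of {c!r} at {ev.split_after} would empty a product "
                    f"(chromosome has {len(markers)} markers)"
                )
            karyotype[f"{c}:1"] = markers[: ev.split_after]
            karyotype[f"{c}:2"] = markers[ev.split_after:]
    return karyotype


def simulate_rearrangement_history(
    scenario: RearrangementScenario,
) -> pd.DataFrame:
    """Apply a rearrangement scenario; return the three-taxon marker table.

    The result has one row per marker per taxon with columns
    ``marker_id``, ``taxon``, ``chromosome``; chromosome ids are
    namespaced by taxon (``A_1``, ``B_3``, ...).
    """
    width = len(str(scenario.n_ancestral_chroms * scenario.markers_per_chrom))
    root: dict[str, list[str]] = {}
    m = 0
    for c in range(1, scenario.n_ancestral_chroms + 1):
        root[f"anc{c}"] = [
            f"m{str(m + i + 1).zfill(width)}" for i in range(scenario.markers_per_chrom)
        ]
        m += scenario.markers_per_chrom
    rows = []
    for taxon in ("A", "B", "O"):
        events = [e for e in scenario.events if e.branch == taxon]
        karyotype = _apply_events(root, events)
        # stable taxon-namespaced names, ordered by smallest marker
        ordered = sorted(karyotype.items(), key=lambda kv: min(kv[1]))
        for idx, (_, markers) in enumerate(ordered, start=1):
            for marker in markers:
                rows.append((marker, taxon, f"{taxon}_{idx}"))
    return pd.DataFrame(rows, columns=["marker_id", "taxon", "chromosome"])


def random_rearrangement_scenario(
    n_ancestral_chroms: int,
    n_events_a: int,
    n_events_b: int,
    markers_per_chrom: int = 10,
    seed: int = 1,
) -> RearrangementScenario:
    """Draw a random scenario with the given per-branch event counts.

    Event kinds are drawn uniformly (fission vs fusion) subject to
    feasibility: fusions need two chromosomes, fissions a chromosome
    with at least two markers.
    """
    rng = np.random.default_rng(seed)
    width = len(str(n_ancestral_chroms * markers_per_chrom))
    root = {}
    m = 0
    for c in range(1, n_ancestral_chroms + 1):
        root[f"anc{c}"] = [
            f"m{str(m + i + 1).zfill(width)}" for i in range(markers_per_chrom)
        ]
        m += markers_per_chrom
    events = []
    for branch, n_events in (("A", n_events_a), ("B", n_events_b)):
        karyotype = {k: list(v) for k, v in root.items()}
        for _ in range(n_events):
            splittable = [c for c, mk in karyotype.items() if len(mk) >= 2]
            can_fuse = len(karyotype) >= 2
            kinds = (["fission"] if splittable else []) + (["fusion"] if can_fuse else [])
            if not kinds:
                break
            kind = kinds[int(rng.integers(len(kinds)))]
            if kind == "fusion":
                c1, c2 = rng.choice(sorted(karyotype), size=2, replace=False)
                ev = RearrangementEvent(branch, "fusion", (str(c1), str(c2)))
            else:
                c = str(rng.choice(sorted(splittable)))
                split = int(rng.integers(1, len(karyotype[c])))
                ev = RearrangementEvent(branch, "fission", (str(c),), split)
            karyotype = _apply_events(karyotype, [ev])
            events.append(ev)
    return RearrangementScenario(
        n_ancestral_chroms=n_ancestral_chroms,
        events=tuple(events),
        markers_per_chrom=markers_per_chrom,
    )
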