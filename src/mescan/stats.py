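"""Diversity/divergence summaries and permutation tests.

Summaries are computed over sites callable in every individual:
per-individual heterozygosity, mean pairwise interspecific diversity
(dxy) and Hudson-style FST (``1 - Hw/Hb`` with the within-group
diversity averaged over the two species).

Two one-tailed permutation tests link chromosome rearrangement status
to the effective migration rate:

* **label switching** — whole chromosomes are relabelled
  rearranged/non-rearranged (the rearranged group size is held fixed)
  to test whether rearranged chromosomes have lower mean me and a
  higher barrier-window fraction;
* **adjacent windows** — random points are drawn on rearranged
  chromosomes and matched numbers of adjacent windows sampled around
  them (rolling over circularly across rearranged chromosomes in
  karyotype-name order) to test whether windows near rearrangement
  points have lower me than the rest of the rearranged chromosomes.
  Permutations that sample any window twice are discarded.

p-values use the add-one estimator ``(b + 1) / (n + 1)``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = [
    "DiversityStats",
    "PermutationOutcome",
    "diversity_from_matrix",
    "diversity_stats",
    "permute_chromosome_labels",
    "permute_adjacent_windows",
]

MISSING = -1


@dataclasses.dataclass
class DiversityStats:
    heterozygosity: dict[str, float]
    dxy: float
    fst: float
    n_sites: int  # callable denominator


@dataclasses.dataclass
class PermutationOutcome:
    observed: dict[str, float]
    null: dict[str, np.ndarray]
    p_value: dict[str, float]
    n_perm: int
    seed: int
    n_discarded: int = 0


def diversity_from_matrix(
    genotypes: np.ndarray,
    n_callable: int,
    group_a: list[int],
    group_b: list[int],
    sample_names: list[str] | None = None,
) -> DiversityStats:
    """Heterozygosity, dxy and FST from a genotype array.

    ``genotypes`` is (n_sites, n_samples, 2) of allele indices with
    ``-1`` for missing; ``n_callable`` is the number of sites callable
    in all individuals (the denominator — invariant callable sites carry
    no record).  Sites with any missing genotype are excluded from the
    numerators, mirroring an all-individuals-callable site set.
    """
    if n_callable <= 0:
        raise ValueError("n_callable must be positive")
    g = np.asarray(genotypes)
    if g.ndim != 3 or g.shape[2] != 2:
        raise ValueError(f"genotypes must be (sites, samples, 2), got {g.shape}")
    n_sites, n_samples, _ = g.shape
    if not group_a or not group_b:
        raise ValueError("both groups need at least one sample")
    names = sample_names or [f"s{i}" for i in range(n_samples)]
    complete = ~np.any(g < 0, axis=(1, 2))
    g = g[complete]
    het = {
        names[i]: float(np.sum(g[:, i, 0] != g[:, i, 1]) / n_callable)
        for i in range(n_samples)
    }
    # per-site dosage of the "1" allele treated as frequency per diploid
    dose = g.sum(axis=2) / 2.0  # (sites, samples)
    pa = dose[:, group_a]
    pb = dose[:, group_b]
    # dxy: mean over interspecific individual pairs of p(1-q) + q(1-p)
    dxy_sites = (
        pa[:, :, None] * (1 - pb[:, None, :]) + (1 - pa[:, :, None]) * pb[:, None, :]
    ).mean(axis=(1, 2))
    dxy = float(dxy_sites.sum() / n_callable)
    # within-group diversity from haplotype frequencies (unbiased)
    def pi_within(group):
        n_h = 2 * len(group)
        p = g[:, group, :].reshape(len(g), -1).mean(axis=1)
        if n_h < 2:
            return np.nan
        return float(
            (2 * p * (1 - p) * n_h / (n_h - 1)).sum() / n_callable
        )

    hw = 0.5 * (pi_within(group_a) + pi_within(group_b))
    fst = float(1.0 - hw / dxy) if dxy > 0 else float("nan")
    return DiversityStats(heterozygosity=het, dxy=dxy, fst=fst, n_sites=n_callable)


def diversity_stats(
    vcf_path,
    callable_bed: pd.DataFrame,
    groups: dict[str, str],
) -> DiversityStats:
    """Summaries from a filtered VCF over a callable BED.

    ``groups`` maps sample name to species label; exactly two species
    are expected.  The callable BED provides the denominator (total
    length); only SNPs inside callable intervals are counted.
    """
    from cyvcf2 import VCF

    n_callable = int((callable_bed["end"] - callable_bed["start"]).sum())
    if n_callable == 0:
        raise ValueError("zero callable sites")
    intervals = {
        chrom: grp[["start", "end"]].to_numpy()
        for chrom, grp in callable_bed.groupby("chrom")
    }
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    species = sorted(set(groups.values()))
    if len(species) != 2:
        raise ValueError(f"expected two species, got {species}")
    group_a = [i for i, s in enumerate(samples) if groups.get(s) == species[0]]
    group_b = [i for i, s in enumerate(samples) if groups.get(s) == species[1]]
    rows = []
    for rec in vcf:
        if not rec.is_snp:
            continue
        iv = intervals.get(rec.CHROM)
        if iv is None:
            continue
        pos0 = rec.POS - 1
        j = np.searchsorted(iv[:, 0], pos0, side="right") - 1
        if j < 0 or pos0 >= iv[j, 1]:
            continue
        rows.append(rec.genotype.array()[:, :2])
    g = np.array(rows, dtype=np.int64).reshape(-1, len(samples), 2)
    return diversity_from_matrix(
        g, n_callable, group_a, group_b, sample_names=samples
    )


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------


def permute_chromosome_labels(
    window_table: pd.DataFrame,
    n_rearranged: int,
    n_perm: int = 10_000,
    seed: int = 1,
) -> PermutationOutcome:
    """Chromosome label-switching test.

    ``window_table`` needs columns ``chromosome, me, barrier,
    rearranged`` (the observed labels; the rearranged group must contain
    ``n_rearranged`` chromosomes).  Each permutation draws
    ``n_rearranged`` chromosomes uniformly without replacement.  The
    statistics are oriented so that larger values support the
    alternative (rearranged chromosomes have *lower* me and *more*
    barrier windows): ``me_deficit = mean me(non) - mean me(rearranged)``
    and ``barrier_excess = barrier fraction(rearranged) - (non)``.
    """
    chroms = window_table["chromosome"].unique()
    n_chrom = len(chroms)
    if not (0 < n_rearranged < n_chrom):
        raise ValueError("need 0 < n_rearranged < number of chromosomes")
    agg = window_table.groupby("chromosome").agg(
        me_sum=("me", "sum"),
        n=("me", "size"),
        barrier_sum=("barrier", "sum"),
    )
    rearranged_chroms = set(
        window_table.loc[window_table["rearranged"], "chromosome"]
    )
    if len(rearranged_chroms) != n_rearranged:
        raise ValueError(
            f"observed rearranged group has {len(rearranged_chroms)} "
            f"chromosomes, expected {n_rearranged}"
        )
    me_sum = agg["me_sum"].to_numpy()
    n_win = agg["n"].to_numpy().astype(float)
    barrier_sum = agg["barrier_sum"].to_numpy().astype(float)
    is_rearr = np.array([c in rearranged_chroms for c in agg.index])

    def stats(sel):
        me_r = sel @ me_sum / (sel @ n_win)
        me_n = (~sel if sel.ndim == 1 else 1 - sel) @ me_sum / (
            (~sel if sel.ndim == 1 else 1 - sel) @ n_win
        )
        bf_r = sel @ barrier_sum / (sel @ n_win)
        bf_n = (~sel if sel.ndim == 1 else 1 - sel) @ barrier_sum / (
            (~sel if sel.ndim == 1 else 1 - sel) @ n_win
        )
        return me_n - me_r, bf_r - bf_n

    obs_me, obs_bf = stats(is_rearr)
    rng = np.random.default_rng(seed)
    draws = np.argsort(rng.random((n_perm, n_chrom)), axis=1)[:, :n_rearranged]
    sel = np.zeros((n_perm, n_chrom))
    np.put_along_axis(sel, draws, 1.0, axis=1)
    null_me, null_bf = stats(sel)
    p_me = float((1 + np.sum(null_me >= obs_me)) / (1 + n_perm))
    p_bf = float((1 + np.sum(null_bf >= obs_bf)) / (1 + n_perm))
    return PermutationOutcome(
        observed={"me_deficit": float(obs_me), "barrier_excess": float(obs_bf)},
        null={"me_deficit": null_me, "barrier_excess": null_bf},
        p_value={"me_deficit": p_me, "barrier_excess": p_bf},
        n_perm=n_perm,
        seed=seed,
    )


def permute_adjacent_windows(
    window_table: pd.DataFrame,
    matched_counts: list[int],
    n_perm: int = 100_000,
    seed: int = 1,
) -> PermutationOutcome:
    """Adjacent-window sampling test on rearranged chromosomes.

    ``window_table`` holds only rearranged-chromosome windows in genome
    order with columns ``chromosome, me, near`` (observed proximity
    labels).  Per permutation, ``len(matched_counts)`` points are drawn
    uniformly from window positions and, around the j-th point, the
    matched number of adjacent windows is sampled (centered, rolling
    over circularly across chromosomes concatenated in karyotype-name
    order).  Permutations sampling any window twice are discarded.  The
    statistic is ``mean me(elsewhere) - mean me(sampled)``, oriented so
    larger values support the alternative (near-point windows have
    lower me).
    """
    matched_counts = [int(k) for k in matched_counts]
    if any(k < 1 for k in matched_counts):
        raise ValueError("matched_counts entries must be >= 1")
    table = window_table.sort_values(
        ["chromosome"], kind="stable"
    )  # genome order within chromosome assumed from input order
    me = table["me"].to_numpy(dtype=float)
    near = table["near"].to_numpy(dtype=bool)
    n = len(me)
    total_k = sum(matched_counts)
    if total_k >= n:
        raise ValueError(
            f"matched_counts sample {total_k} windows but only {n} exist"
        )
    total = me.sum()
    obs_near = me[near].mean()
    obs_rest = me[~near].mean()
    observed = float(obs_rest - obs_near)
    rng = np.random.default_rng(seed)
    points = rng.integers(0, n, size=(n_perm, len(matched_counts)))
    cols = []
    for j, k in enumerate(matched_counts):
        offsets = np.arange(k) - (k - 1) // 2
        cols.append((points[:, j : j + 1] + offsets) % n)
    sampled = np.concatenate(cols, axis=1)  # (n_perm, total_k)
    srt = np.sort(sampled, axis=1)
    valid = ~np.any(srt[:, 1:] == srt[:, :-1], axis=1)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("every permutation sampled a window twice")
    sampled_sum = me[sampled[valid]].sum(axis=1)
    null = (total - sampled_sum) / (n - total_k) - sampled_sum / total_k
    p = float((1 + np.sum(null >= observed)) / (1 + n_valid))
    return PermutationOutcome(
        observed={"me_deficit_near_points": observed},
        null={"me_deficit_near_points": null},
        p_value={"me_deficit_near_points": p},
        n_perm=n_perm,
        seed=seed,
        n_discarded=n_perm - n_valid,
    )
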