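"""Genomic windows: grid scans, barrier classification, chromosome summaries.

Blocks in genome order are tiled into non-overlapping windows of a
fixed number of consecutive blocks (windows never span chromosomes;
trailing remainders are dropped).  Each window's bSFS tally is scored
against every point of a precomputed likelihood grid; the
maximum-composite-likelihood point and the profile of conditional
maxima over each me value are recorded.  A window is a *barrier window*
when the likelihood conditioned on ``me = 0`` strictly exceeds the
likelihood at the background me grid value (the grid value nearest the
genome-wide estimate).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import scipy.stats

from .bsfs import BsfsTally

logger = logging.getLogger(__name__)

__all__ = [
    "Window",
    "WindowResult",
    "cut_windows",
    "scale_window_block_count",
    "window_scan",
    "classify_barrier",
    "assign_windows_to_chromosomes",
    "summarize_chromosomes",
]


@dataclasses.dataclass(frozen=True)
class Window:
    chromosome: str
    start: int
    end: int
    block_ids: np.ndarray  # row indices into the source block table


@dataclasses.dataclass
class WindowResult:
    window: Window
    best_point: tuple[float, float, float, float]  # (ne_a, ne_b, ne_anc, me)
    lncl: float
    me_values: np.ndarray
    profile: np.ndarray  # conditional max lnCL per me value
    barrier: bool | None = None
    assigned_chromosome: str | None = None
    distance_to_point: float | None = None


def cut_windows(block_table: pd.DataFrame, window_blocks: int) -> list[Window]:
    """Tile consecutive blocks into fixed-size windows per chromosome.

    ``block_table`` must be sorted by (chromosome, start) and carry
    columns ``chromosome, start, end``.  Chromosomes with fewer than
    ``window_blocks`` blocks yield no windows (warning); remainders are
    dropped and logged.
    """
    if window_blocks < 1:
        raise ValueError("window_blocks must be >= 1")
    windows = []
    for chrom, group in block_table.groupby("chromosome", sort=False):
        starts = group["start"].to_numpy()
        if not np.all(np.diff(starts) >= 0):
            raise ValueError(f"block table not sorted within {chrom}")
        n = len(group)
        n_windows, remainder = divmod(n, window_blocks)
        if n_windows == 0:
            logger.warning(
                "%s has %d blocks (< %d); no windows", chrom, n, window_blocks
            )
            continue
        if remainder:
            logger.info("%s: dropping %d trailing blocks", chrom, remainder)
        idx = group.index.to_numpy()
        for w in range(n_windows):
            rows = idx[w * window_blocks : (w + 1) * window_blocks]
            windows.append(
                Window(
                    chromosome=str(chrom),
                    start=int(block_table.loc[rows[0], "start"]),
                    end=int(block_table.loc[rows[-1], "end"]),
                    block_ids=rows,
                )
            )
    return windows


def scale_window_block_count(base_blocks: int, base_pairs: int, new_pairs: int) -> int:
    """Blocks per window rescaled to a different number of sampled pairs.

    Keeps the genomic span of windows comparable when fewer pairwise
    comparisons contribute blocks (e.g. male-only Z-chromosome scans):
    ``round(base_blocks * new_pairs / base_pairs)``.
    """
    if min(base_blocks, base_pairs, new_pairs) < 1:
        raise ValueError("all counts must be >= 1")
    return int(np.floor(base_blocks * new_pairs / base_pairs + 0.5))


def window_scan(
    windows: list[Window],
    tallies: list[BsfsTally],
    points: list[tuple[float, float, float, float]],
    probs: np.ndarray,
) -> list[WindowResult]:
    """Score each window's tally at every grid point.

    The MCL point is the argmax over the grid (exact ties broken toward
    smaller me, then smaller ne_a); the conditional profile records, for
    each me value, the maximum lnCL over grid points with that me.
    Windows with empty tallies are skipped with a diagnostic.
    """
    if len(windows) != len(tallies):
        raise ValueError("windows and tallies differ in length")
    pts = np.asarray(points, dtype=float)
    n_points = len(pts)
    log_probs = np.log(np.clip(probs.reshape(n_points, -1), 1e-300, None))
    me_values = np.unique(pts[:, 3])
    me_groups = [np.flatnonzero(pts[:, 3] == me) for me in me_values]
    # tie-break order: me ascending then ne_a ascending
    tie_order = np.lexsort((pts[:, 0], pts[:, 3]))
    results = []
    for window, tally in zip(windows, tallies):
        if tally.n_blocks == 0:
            logger.warning("window %s:%d-%d has empty tally; skipped",
                           window.chromosome, window.start, window.end)
            continue
        flat = tally.counts.reshape(-1).astype(float)
        lncl = log_probs @ flat
        best = np.max(lncl)
        candidates = tie_order[np.isclose(lncl[tie_order], best, rtol=0, atol=0)]
        best_idx = int(candidates[0]) if len(candidates) else int(np.argmax(lncl))
        profile = np.array([lncl[g].max() for g in me_groups])
        results.append(
            WindowResult(
                window=window,
                best_point=tuple(pts[best_idx]),
                lncl=float(lncl[best_idx]),
                me_values=me_values,
                profile=profile,
            )
        )
    return results


def classify_barrier(result: WindowResult, me_background: float) -> bool:
    """Barrier flag: lnCL at me=0 strictly exceeds lnCL at the background me."""
    me = result.me_values
    zero = np.flatnonzero(me == 0.0)
    bg = np.flatnonzero(np.isclose(me, me_background, rtol=1e-12, atol=0))
    if len(zero) == 0:
        raise ValueError("grid has no me=0 value")
    if len(bg) == 0:
        raise ValueError(f"background me {me_background} absent from grid")
    flag = bool(result.profile[zero[0]] > result.profile[bg[0]])
    result.barrier = flag
    return flag


def assign_windows_to_chromosomes(
    results: list[WindowResult],
    alignments: pd.DataFrame,
) -> None:
    """Assign each window to a chromosome of the aligned (donor) genome.

    ``alignments`` carries columns ``query_chrom, query_start,
    query_end, target_chrom, length`` in the window coordinate system
    (query).  The majority rule uses aligned bases overlapping the
    window; ties go to the longer alignment's chromosome.  Windows with
    no overlapping alignment are left unassigned.
    """
    for res in results:
        w = res.window
        sub = alignments[alignments["query_chrom"] == w.chromosome]
        votes: dict[str, float] = {}
        longest: dict[str, float] = {}
        for _, row in sub.iterrows():
            ov = min(w.end, row["query_end"]) - max(w.start, row["query_start"])
            if ov > 0:
                votes[row["target_chrom"]] = votes.get(row["target_chrom"], 0) + ov
                longest[row["target_chrom"]] = max(
                    longest.get(row["target_chrom"], 0), row["length"]
                )
        if votes:
            res.assigned_chromosome = max(
                votes, key=lambda c: (votes[c], longest[c])
            )


def summarize_chromosomes(
    results: list[WindowResult],
    lengths: dict[str, float],
    use_assigned: bool = False,
) -> tuple[pd.DataFrame, tuple[float, float] | None]:
    """Per-chromosome mean me and barrier fraction, plus Spearman's rho.

    Windows are grouped by their own chromosome, or by the assigned
    (donor-genome) chromosome when ``use_assigned`` (unassigned windows
    are excluded and logged).  Returns the summary table and
    ``(rho, p)`` for the rank correlation of chromosome length with mean
    me, or ``None`` when the correlation is undefined (fewer than two
    chromosomes or zero variance in either variable).
    """
    rows = []
    for res in results:
        chrom = res.assigned_chromosome if use_assigned else res.window.chromosome
        if chrom is None:
            logger.info("window %s:%d-%d unassigned; excluded",
                        res.window.chromosome, res.window.start, res.window.end)
            continue
        rows.append((chrom, res.best_point[3], bool(res.barrier)))
    df = pd.DataFrame(rows, columns=["chromosome", "me", "barrier"])
    summary = (
        df.groupby("chromosome")
        .agg(mean_me=("me", "mean"), barrier_fraction=("barrier", "mean"),
             n_windows=("me", "size"))
        .reset_index()
    )
    summary["length"] = summary["chromosome"].map(lengths)
    rho = None
    if len(summary) >= 2:
        x, y = summary["length"].to_numpy(), summary["mean_me"].to_numpy()
        if np.ptp(x) > 0 and np.ptp(y) > 0:
            r = scipy.stats.spearmanr(x, y)
            rho = (float(r.statistic), float(r.pvalue))
    return summary, rho
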