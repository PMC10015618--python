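"""Blockwise site-frequency-spectrum containers.

A block is a stretch of callable sequence from which one diploid genome
per species has been sampled (2+2 haplotypes).  Each biallelic site in a
block falls into one of four unpolarized mutation types:

* ``hetA``  — heterozygous in the A diploid only,
* ``hetB``  — heterozygous in the B diploid only,
* ``hetAB`` — heterozygous in both (same two alleles),
* ``fixed`` — opposite homozygotes.

Per-block counts of the four types are truncated at ``kmax`` per type;
counts exceeding ``kmax`` are pooled into a marginal overflow bin, so
each axis of the tally has ``kmax + 2`` categories (0..kmax, >kmax).
"""

from __future__ import annotations

import dataclasses

import numpy as np

#: Fixed axis order for mutation-type counts.
TYPE_NAMES: tuple[str, ...] = ("hetA", "hetB", "hetAB", "fixed")

HETA, HETB, HETAB, FIXED = 0, 1, 2, 3


def tally_shape(kmax: tuple[int, ...]) -> tuple[int, ...]:
    """Array shape of a tally/table: one overflow category per axis."""
    return tuple(int(k) + 2 for k in kmax)


def clip_counts(counts: np.ndarray, kmax: tuple[int, ...]) -> np.ndarray:
    """Truncate raw per-type counts at kmax+1 (the overflow index)."""
    k = np.asarray(kmax, dtype=counts.dtype)
    return np.minimum(counts, k + 1)


@dataclasses.dataclass
class BsfsTally:
    """Counts of blocks indexed by the joint mutation-type vector.

    ``counts[i_hetA, i_hetB, i_hetAB, i_fixed]`` is the number of blocks
    whose (truncated) per-type mutation counts equal that index vector.
    """

    counts: np.ndarray
    kmax: tuple[int, int, int, int]
    block_span: int
    n_discarded: int = 0
    pairs: tuple | None = None

    def __post_init__(self) -> None:
        self.kmax = tuple(int(k) for k in self.kmax)
        expected = tally_shape(self.kmax)
        if self.counts.shape != expected:
            raise ValueError(
                f"tally shape {self.counts.shape} does not match kmax "
                f"{self.kmax} (expected {expected})"
            )

    @property
    def n_blocks(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def zeros(cls, kmax=(2, 2, 2, 2), block_span: int = 64) -> "BsfsTally":
        return cls(
            counts=np.zeros(tally_shape(kmax), dtype=np.int64),
            kmax=tuple(kmax),
            block_span=block_span,
        )

    @classmethod
    def from_raw_counts(
        cls, raw: np.ndarray, kmax=(2, 2, 2, 2), block_span: int = 64
    ) -> "BsfsTally":
        """Tally an (n_blocks, 4) array of raw per-type mutation counts."""
        raw = np.asarray(raw, dtype=np.int64)
        if raw.ndim != 2 or raw.shape[1] != 4:
            raise ValueError(f"raw counts must be (n, 4), got {raw.shape}")
        clipped = clip_counts(raw, tuple(kmax))
        shape = tally_shape(tuple(kmax))
        flat = np.ravel_multi_index(tuple(clipped.T), shape)
        counts = np.bincount(flat, minlength=int(np.prod(shape))).reshape(shape)
        return cls(counts=counts, kmax=tuple(kmax), block_span=block_span)

    def __add__(self, other: "BsfsTally") -> "BsfsTally":
        if self.kmax != other.kmax or self.block_span != other.block_span:
            raise ValueError("tallies have incompatible kmax/block_span")
        return BsfsTally(
            counts=self.counts + other.counts,
            kmax=self.kmax,
            block_span=self.block_span,
            n_discarded=self.n_discarded + other.n_discarded,
        )

    def to_frame(self):
        """Long-format DataFrame (hetA, hetB, hetAB, fixed, n_blocks)."""
        import pandas as pd

        idx = np.argwhere(self.counts > 0)
        return pd.DataFrame(
            {
                **{name: idx[:, i] for i, name in enumerate(TYPE_NAMES)},
                "n_blocks": self.counts[tuple(idx.T)],
            }
        )


@dataclasses.dataclass
class ProbabilityTable:
    """Model-predicted probabilities over the same index set as a tally."""

    probs: np.ndarray
    kmax: tuple[int, int, int, int]
    params: object = None

    def __post_init__(self) -> None:
        self.kmax = tuple(int(k) for k in self.kmax)
        expected = tally_shape(self.kmax)
        if self.probs.shape != expected:
            raise ValueError(
                f"table shape {self.probs.shape} does not match kmax {self.kmax}"
            )

    def validate(self, atol: float = 1e-10) -> None:
        if np.any(self.probs < -atol):
            raise ValueError("negative probability in table")
        total = float(self.probs.sum())
        if abs(total - 1.0) > atol:
            raise ValueError(f"table probabilities sum to {total}, not 1")
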