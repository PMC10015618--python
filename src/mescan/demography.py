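"""Demographic model cards for two-population divergence/migration histories.

The pipeline works with two sister species, A and B, that split from a
common ancestral population ``split_time`` generations ago.  Two model
families are supported:

* ``DIV`` — strict divergence, no post-split gene flow.
* ``IM``  — isolation with migration: a constant per-generation,
  per-lineage probability ``me`` that a lineage migrates, in one
  direction only.

Directions are stated forwards in time (donor -> recipient):
``into_A`` means gene flow from B into A.  Backwards in time this is
simulated (and computed) as lineages sampled in the *recipient* deme
moving into the donor deme at rate ``me`` per lineage per generation.
"""

from __future__ import annotations

import dataclasses
import enum
import math


class Direction(str, enum.Enum):
    """Forwards-in-time direction of gene flow."""

    none = "none"
    into_A = "into_A"
    into_B = "into_B"


@dataclasses.dataclass(frozen=True)
class DemographyParams:
    """Parameters of a two-population DIV/IM history.

    Attributes
    ----------
    ne_a, ne_b, ne_anc
        Diploid effective population sizes (individuals) of species A,
        species B and the ancestral population.
    split_time
        Time of the split in generations before present.
    me
        Effective migration rate: per-generation per-lineage migration
        probability.  ``0`` for a DIV history.
    direction
        Forwards-in-time direction of gene flow; ``none`` iff ``me == 0``.
    mu
        Per-site per-generation mutation rate.
    gen_time
        Years per generation (used only to convert times for reporting).
    """

    ne_a: float
    ne_b: float
    ne_anc: float
    split_time: float
    me: float = 0.0
    direction: Direction = Direction.none
    mu: float = 2.9e-9
    gen_time: float = 1.0

    def __post_init__(self) -> None:
        for name in ("ne_a", "ne_b", "ne_anc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.split_time < 0:
            raise ValueError(f"split_time must be >= 0, got {self.split_time}")
        if not (0 <= self.me < 1):
            raise ValueError(f"me must be in [0, 1), got {self.me}")
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")
        direction = Direction(self.direction)
        object.__setattr__(self, "direction", direction)
        if (self.me == 0) != (direction is Direction.none):
            raise ValueError(
                f"direction must be 'none' iff me == 0 (me={self.me}, "
                f"direction={direction.value})"
            )

    @property
    def recipient_ne(self) -> float:
        """Diploid Ne of the recipient population (forwards-in-time)."""
        if self.direction is Direction.into_A:
            return self.ne_a
        if self.direction is Direction.into_B:
            return self.ne_b
        raise ValueError("no recipient for a DIV history")


@dataclasses.dataclass(frozen=True)
class BlockConfig:
    """Blocking scheme for the blockwise SFS.

    ``block_span`` callable bases are packed into each block, allowed to
    stretch over at most ``max_span`` genomic bases.  Mutation counts per
    block are truncated at ``kmax`` per type (overflow pooled into a
    marginal bin).  ``recomb_rate`` is the per-base per-generation
    recombination rate used when simulating linked blocks.
    """

    block_span: int = 64
    max_span: int = 128
    kmax: tuple[int, int, int, int] = (2, 2, 2, 2)
    recomb_rate: float = 8.5e-9

    def __post_init__(self) -> None:
        if not (0 < self.block_span <= self.max_span):
            raise ValueError(
                f"need 0 < block_span <= max_span, got "
                f"{self.block_span}, {self.max_span}"
            )
        if len(self.kmax) != 4 or any(k < 1 for k in self.kmax):
            raise ValueError(f"kmax must be 4 entries >= 1, got {self.kmax}")
        if self.recomb_rate < 0:
            raise ValueError(f"recomb_rate must be >= 0, got {self.recomb_rate}")
        object.__setattr__(self, "kmax", tuple(int(k) for k in self.kmax))


# Parameters of the best-fitting IM history (gene flow into species A)
# used throughout the analysis scripts and tests: Ne_A=0.171e6,
# Ne_B=0.880e6, Ne_anc=1.116e6, T=2.202e6 gen, me=1.811e-7.
TABLE_IM_INTO_A = DemographyParams(
    ne_a=0.171e6,
    ne_b=0.880e6,
    ne_anc=1.116e6,
    split_time=2.202e6,
    me=1.811e-7,
    direction=Direction.into_A,
)

# Maximum-composite-likelihood strict-divergence history.
TABLE_DIV = DemographyParams(
    ne_a=0.252e6,
    ne_b=0.683e6,
    ne_anc=1.433e6,
    split_time=1.183e6,
)


def expected_pairwise_coalescence_two_epoch(
    ne_recent: float, ne_anc: float, split_time: float
) -> float:
    """E[T] for two lineages under a two-epoch history (no migration).

    The pair coalesces at rate 1/(2*ne_recent) until ``split_time``
    generations ago and at rate 1/(2*ne_anc) beyond.  Closed form:
    ``2*N1 + (2*Nanc - 2*N1) * exp(-T / (2*N1))``.
    """
    n1 = 2.0 * ne_recent
    na = 2.0 * ne_anc
    return n1 + (na - n1) * math.exp(-split_time / n1)


def expected_heterozygosity_two_epoch(
    ne_recent: float, ne_anc: float, split_time: float, mu: float
) -> float:
    """Expected per-site heterozygosity ``2*mu*E[T]`` for a two-epoch history."""
    return 2.0 * mu * expected_pairwise_coalescence_two_epoch(
        ne_recent, ne_anc, split_time
    )
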