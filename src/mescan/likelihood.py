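"""Exact blockwise-SFS probabilities and composite likelihood.

For a block of ``block_span`` callable sites with one diploid sampled
from each of two species (2+2 haplotypes), this module computes the
exact joint distribution of the four mutation-type counts
(hetA, hetB, hetAB, fixed), truncated at ``kmax`` per type, under a
two-epoch structured coalescent:

* epoch 1 (present back to ``split_time``): two demes with diploid
  sizes ``ne_a`` and ``ne_b``; under an IM model, lineages currently in
  the recipient deme migrate into the donor deme at rate ``me`` per
  lineage per generation (the backwards-time equivalent of forwards
  gene flow donor -> recipient);
* epoch 2 (beyond ``split_time``): a single deme of size ``ne_anc``.

The computation augments the coalescent's lineage-configuration Markov
chain with per-type mutation counters truncated at ``kmax + 1``
(overflow absorbing).  Each ancestral lineage is labelled by the number
of sampled A and B haplotypes it subtends, which determines the
mutation type of any mutation falling on it:

    (1,0) -> hetA   (0,1) -> hetB   (1,1) -> hetAB
    (2,0), (0,2) -> fixed
    (2,1) -> hetB   (1,2) -> hetA   (unpolarized complement classes)

Epoch 1 is solved by uniformization of the augmented generator up to
``split_time``; lineages are then pooled into one deme and epoch 2 is
solved to absorption at the MRCA by a direct sweep that exploits the
acyclic structure of the chain (coalescence only reduces the lineage
count; counters only increase).  Mutations above the MRCA are
unobservable and excluded.

Probabilities are exact up to floating-point error; every table sums to
one over the full index set including overflow bins.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import scipy.sparse

from .bsfs import BsfsTally, ProbabilityTable
from .demography import DemographyParams, Direction

__all__ = [
    "ModelSpec",
    "bsfs_probabilities",
    "composite_lnCL",
    "migrants_per_generation",
]

# Probabilities below this are clamped when taking logs.
_LOG_FLOOR = 1e-300

# mutation type of a lineage subtending (na, nb) sampled haplotypes
_TYPE_OF = {
    (1, 0): 0,  # hetA
    (0, 1): 1,  # hetB
    (1, 1): 2,  # hetAB
    (2, 0): 3,  # fixed
    (0, 2): 3,  # fixed
    (2, 1): 1,  # complement of a B singleton
    (1, 2): 0,  # complement of an A singleton
}

_MRCA = ()  # absorbing configuration


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """A demographic model with its free parameters and fixed constants.

    ``model`` is one of ``DIV``, ``IM_into_A``, ``IM_into_B`` (directions
    forwards in time).  DIV has no ``me``; IM models require ``me >= 0``.
    """

    model: str
    ne_a: float
    ne_b: float
    ne_anc: float
    split_time: float
    me: float = 0.0
    mu: float = 2.9e-9
    block_span: int = 64

    def __post_init__(self) -> None:
        if self.model not in ("DIV", "IM_into_A", "IM_into_B"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "DIV" and self.me != 0:
            raise ValueError("DIV model has no me parameter")
        if self.me < 0:
            raise ValueError(f"me must be >= 0, got {self.me}")
        for name in ("ne_a", "ne_b", "ne_anc", "split_time"):
            if getattr(self, name) <= 0 and not (name == "split_time" and self.split_time == 0):
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    @property
    def backwards_migration_deme(self) -> int | None:
        """Deme (0=A, 1=B) whose lineages migrate, backwards in time."""
        if self.model == "DIV" or self.me == 0:
            return None
        return 0 if self.model == "IM_into_A" else 1

    @classmethod
    def from_demography(cls, params: DemographyParams, block_span: int = 64) -> "ModelSpec":
        model = {
            Direction.none: "DIV",
            Direction.into_A: "IM_into_A",
            Direction.into_B: "IM_into_B",
        }[params.direction]
        return cls(
            model=model,
            ne_a=params.ne_a,
            ne_b=params.ne_b,
            ne_anc=params.ne_anc,
            split_time=params.split_time,
            me=params.me,
            mu=params.mu,
            block_span=block_span,
        )


# ---------------------------------------------------------------------------
# state-space enumeration (cached per migration direction)
# ---------------------------------------------------------------------------


def _canon(lineages) -> tuple:
    return tuple(sorted(lineages))


def _epoch1_transitions(config: tuple, mig_deme: int | None):
    """Yield (new_config, kind, multiplicity) for one epoch-1 config.

    kind: 0 = coalescence in deme A, 1 = coalescence in deme B,
    2 = migration of one lineage out of ``mig_deme``.
    """
    lineages = list(config)
    n = len(lineages)
    seen: dict[tuple, list] = {}
    # coalescence of same-deme pairs
    for i in range(n):
        for j in range(i + 1, n):
            (na1, nb1, d1), (na2, nb2, d2) = lineages[i], lineages[j]
            if d1 != d2:
                continue
            merged = (na1 + na2, nb1 + nb2, d1)
            rest = [lin for k, lin in enumerate(lineages) if k not in (i, j)]
            new = _MRCA if merged[:2] == (2, 2) else _canon(rest + [merged])
            key = (new, d1)
            seen.setdefault(key, [0])[0] += 1
    for (new, deme), (mult,) in seen.items():
        yield new, deme, mult
    # migration
    if mig_deme is not None:
        seen = {}
        for i, (na, nb, d) in enumerate(lineages):
            if d != mig_deme:
                continue
            moved = (na, nb, 1 - mig_deme)
            new = _canon([lin for k, lin in enumerate(lineages) if k != i] + [moved])
            seen.setdefault(new, [0])[0] += 1
        for new, (mult,) in seen.items():
            yield new, 2, mult


def _epoch2_transitions(config: tuple):
    """Yield (new_config, multiplicity) under coalescence in one deme."""
    lineages = list(config)
    n = len(lineages)
    seen: dict[tuple, list] = {}
    for i in range(n):
        for j in range(i + 1, n):
            (na1, nb1), (na2, nb2) = lineages[i], lineages[j]
            merged = (na1 + na2, nb1 + nb2)
            rest = [lin for k, lin in enumerate(lineages) if k not in (i, j)]
            new = _MRCA if merged == (2, 2) else _canon(rest + [merged])
            seen.setdefault(new, [0])[0] += 1
    for new, (mult,) in seen.items():
        yield new, mult


def _enumerate_states(initial: tuple, transition_fn) -> tuple[list, dict, list]:
    """BFS closure of the configuration space; returns (configs, index, edges)."""
    configs = [initial]
    index = {initial: 0}
    edges = []  # (i, j, *tag)
    frontier = [initial]
    while frontier:
        nxt = []
        for cfg in frontier:
            if cfg == _MRCA:
                continue
            for new, *tag in transition_fn(cfg):
                if new not in index:
                    index[new] = len(configs)
                    configs.append(new)
                    nxt.append(new)
                edges.append((index[cfg], index[new], *tag))
        frontier = nxt
    return configs, index, edges


def _type_counts(config: tuple) -> np.ndarray:
    """Number of lineages of each mutation type in a configuration."""
    out = np.zeros(4, dtype=np.int64)
    for lin in config:
        na, nb = lin[0], lin[1]
        out[_TYPE_OF[(na, nb)]] += 1
    return out


class _StateSpaces:
    """Cached epoch-1/epoch-2 state spaces for one migration direction."""

    _cache: dict = {}

    def __init__(self, mig_deme: int | None):
        initial1 = _canon([(1, 0, 0), (1, 0, 0), (0, 1, 1), (0, 1, 1)])
        self.configs1, self.index1, self.edges1 = _enumerate_states(
            initial1, lambda c: _epoch1_transitions(c, mig_deme)
        )
        initial2 = _canon([(1, 0), (1, 0), (0, 1), (0, 1)])
        self.configs2, self.index2, self.edges2 = _enumerate_states(
            initial2, _epoch2_transitions
        )
        # make sure every deme-stripped epoch-1 config exists in epoch 2
        for cfg in self.configs1:
            stripped = _MRCA if cfg == _MRCA else _canon([lin[:2] for lin in cfg])
            if stripped not in self.index2:
                self.index2[stripped] = len(self.configs2)
                self.configs2.append(stripped)
                for new, mult in _epoch2_transitions(stripped):
                    self.edges2.append((self.index2[stripped], self.index2[new], mult))
        self.types1 = np.array([_type_counts(c) for c in self.configs1])
        self.types2 = np.array([_type_counts(c) for c in self.configs2])
        # map epoch-1 config -> epoch-2 config
        self.map12 = np.array(
            [
                self.index2[_MRCA if c == _MRCA else _canon([lin[:2] for lin in c])]
                for c in self.configs1
            ]
        )
        # epoch-2 topological order: decreasing lineage count
        self.order2 = sorted(
            range(len(self.configs2)), key=lambda i: -len(self.configs2[i])
        )

    @classmethod
    def get(cls, mig_deme: int | None) -> "_StateSpaces":
        if mig_deme not in cls._cache:
            cls._cache[mig_deme] = cls(mig_deme)
        return cls._cache[mig_deme]


# ---------------------------------------------------------------------------
# epoch 1: uniformized matrix exponential on the augmented chain
# ---------------------------------------------------------------------------


def _epoch1_structural(ss: _StateSpaces, spec: ModelSpec) -> scipy.sparse.csr_matrix:
    n = len(ss.configs1)
    rate_of_kind = (
        1.0 / (2.0 * spec.ne_a),
        1.0 / (2.0 * spec.ne_b),
        spec.me,
    )
    rows, cols, vals = [], [], []
    out = np.zeros(n)
    for i, j, kind, mult in ss.edges1:
        r = mult * rate_of_kind[kind]
        if r == 0.0:
            continue
        rows.append(i)
        cols.append(j)
        vals.append(r)
        out[i] += r
    A = scipy.sparse.csr_matrix(
        (vals, (rows, cols)), shape=(n, n), dtype=np.float64
    )
    return A, out


def _apply_generator(P, A_T, struct_out, types, u, kmax):
    """dP/dt for P of shape (n_configs, m0, m1, m2, m3)."""
    n = P.shape[0]
    flat = P.reshape(n, -1)
    dP = (A_T @ flat).reshape(P.shape)
    dP -= struct_out.reshape((n,) + (1,) * 4) * P
    for t in range(4):
        nt = types[:, t].astype(float)
        if not nt.any():
            continue
        scaled = u * nt.reshape((n,) + (1,) * 4) * P
        sl_src = [slice(None)] * 5
        sl_dst = [slice(None)] * 5
        # outflow from non-overflow counter states
        sl_src[1 + t] = slice(0, kmax[t] + 1)
        dP[tuple(sl_src)] -= scaled[tuple(sl_src)]
        # inflow shifted up by one mutation
        sl_dst[1 + t] = slice(1, kmax[t] + 2)
        dP[tuple(sl_dst)] += scaled[tuple(sl_src)]
    return dP


def _epoch1_propagate(P0, ss, spec, kmax):
    """P(split_time) = exp(Q * T) P0 via uniformization."""
    T = spec.split_time
    if T == 0:
        return P0
    A, struct_out = _epoch1_structural(ss, spec)
    A_T = A.T.tocsr()
    u = spec.mu * spec.block_span
    n_mut_max = 4.0 * u  # at most 4 lineages
    lam = float(struct_out.max() + n_mut_max)
    if lam == 0.0:
        return P0
    total = lam * T
    n_steps = max(1, int(math.ceil(total / 250.0)))
    dt = T / n_steps
    lam_dt = lam * dt
    n_terms = int(lam_dt + 8.0 * math.sqrt(lam_dt + 16.0) + 20.0)
    P = P0
    for _ in range(n_steps):
        # e^{Q dt} = e^{-lam dt} sum_m (lam dt)^m / m! * (I + Q/lam)^m
        w = math.exp(-lam_dt)
        v = P
        result = w * v
        for m in range(1, n_terms + 1):
            v = v + _apply_generator(v, A_T, struct_out, ss.types1, u, kmax) / lam
            w *= lam_dt / m
            result += w * v
        P = result
    return P


# ---------------------------------------------------------------------------
# epoch 2: absorption by acyclic sweep
# ---------------------------------------------------------------------------


class _CounterLattice:
    """Static sweep order over the truncated counter lattice.

    Cells are visited by increasing total count so that every cell's
    per-type predecessor (one fewer mutation of that type) has already
    been computed.  ``pred[cell, t]`` is the flat index of that
    predecessor (-1 at zero); ``active[cell, t]`` marks cells that can
    still receive a type-t mutation (i.e. are not in overflow).
    """

    _cache: dict = {}

    def __init__(self, kmax: tuple[int, ...]):
        shape = tuple(k + 2 for k in kmax)
        cells = np.array(list(np.ndindex(*shape)), dtype=np.int64)
        n = len(cells)
        flat = np.ravel_multi_index(tuple(cells.T), shape)
        assert np.array_equal(flat, np.arange(n))
        self.shape = shape
        pred = np.full((n, 4), -1, dtype=np.int64)
        for t in range(4):
            has = cells[:, t] > 0
            src = cells[has].copy()
            src[:, t] -= 1
            pred[has, t] = np.ravel_multi_index(tuple(src.T), shape)
        self.pred = pred
        self.active = cells <= np.array(kmax)  # not yet in overflow
        totals = cells.sum(axis=1)
        self.levels = [
            np.flatnonzero(totals == s) for s in range(int(totals.max()) + 1)
        ]

    @classmethod
    def get(cls, kmax: tuple[int, ...]) -> "_CounterLattice":
        if kmax not in cls._cache:
            cls._cache[kmax] = cls(kmax)
        return cls._cache[kmax]


def _epoch2_absorb(P2, ss, spec, kmax):
    """Distribution of counters at the MRCA, given mass P2 at split time.

    Coalescence only reduces the lineage count and mutations only
    increase counters, so the augmented chain is acyclic and the
    integrated occupancy of each transient state solves in one sweep:
    configurations in order of decreasing lineage count, counters in
    order of increasing total count.
    """
    rate = 1.0 / (2.0 * spec.ne_anc)
    u = spec.mu * spec.block_span
    n2 = len(ss.configs2)
    mrca = ss.index2[_MRCA]
    lattice = _CounterLattice.get(kmax)
    n_cells = len(lattice.pred)
    in_edges: dict[int, list] = {i: [] for i in range(n2)}
    struct_out = np.zeros(n2)
    for i, j, mult in ss.edges2:
        r = mult * rate
        in_edges[j].append((i, r))
        struct_out[i] += r
    P2f = P2.reshape(n2, n_cells)
    z = np.zeros((n2, n_cells))  # integrated occupancy of transient states
    absorbed = P2f[mrca].copy()
    for g in ss.order2:
        if g == mrca:
            continue
        nt = ss.types2[g]
        inflow = P2f[g].copy()
        for i, r in in_edges[g]:
            if i != g:
                inflow += r * z[i]
        # total outflow per cell: coalescence + mutations still possible
        out = struct_out[g] + u * (lattice.active @ nt.astype(float))
        zg = np.zeros(n_cells)
        for cells in lattice.levels:
            val = inflow[cells]
            for t in range(4):
                if nt[t] == 0:
                    continue
                src = lattice.pred[cells, t]
                ok = src >= 0
                if ok.any():
                    val = val + (u * nt[t]) * np.where(ok, zg[src], 0.0)
            zg[cells] = val / out[cells]
        z[g] = zg
    for i, r in in_edges[mrca]:
        absorbed += r * z[i]
    return absorbed.reshape(lattice.shape)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def bsfs_probabilities(spec: ModelSpec, kmax=(2, 2, 2, 2)) -> ProbabilityTable:
    """Exact probability table of joint mutation-type counts for one block.

    Returns a :class:`ProbabilityTable` over the ``(kmax+2)^4`` index
    set (overflow bins included); entries sum to one.
    """
    kmax = tuple(int(k) for k in kmax)
    ss = _StateSpaces.get(spec.backwards_migration_deme)
    shape_c = tuple(k + 2 for k in kmax)
    n1 = len(ss.configs1)
    P0 = np.zeros((n1,) + shape_c)
    P0[(0,) + (0,) * 4] = 1.0
    P1 = _epoch1_propagate(P0, ss, spec, kmax)
    # pool demes: map epoch-1 configs onto epoch-2 configs
    n2 = len(ss.configs2)
    P2 = np.zeros((n2,) + shape_c)
    np.add.at(P2, ss.map12, P1)
    probs = _epoch2_absorb(P2, ss, spec, kmax)
    total = float(probs.sum())
    if not np.isfinite(total) or abs(total - 1.0) > 1e-6:
        raise ArithmeticError(
            f"likelihood kernel failed to conserve probability "
            f"(sum={total!r}) at {spec}"
        )
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum()
    table = ProbabilityTable(probs=probs, kmax=kmax, params=spec)
    table.validate(atol=1e-9)
    return table


def composite_lnCL(tally: BsfsTally, table: ProbabilityTable) -> float:
    """Composite log-likelihood sum(n_k * log p_k) over occupied bins.

    Probabilities below 1e-300 (including exact zeros) are clamped to
    the floor before the log and the occurrence is reported via a
    RuntimeWarning.  Occupied zero-probability bins arise when data
    violate the single-genealogy-per-block assumption (intra-block
    recombination can combine hetAB- and fixed-type sites, which no one
    genealogy can produce); the floor keeps the score finite while
    penalizing such blocks maximally.
    """
    if tuple(tally.kmax) != tuple(table.kmax):
        raise ValueError(
            f"tally kmax {tally.kmax} does not match table kmax {table.kmax}"
        )
    occupied = tally.counts > 0
    if not occupied.any():
        return 0.0
    p = table.probs[occupied]
    n = tally.counts[occupied]
    n_floored = int(np.sum(p < _LOG_FLOOR))
    if n_floored:
        warnings.warn(
            f"{n_floored} occupied bSFS bin(s) with model probability below "
            f"{_LOG_FLOOR:g}; clamped for the log",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(np.sum(n * np.log(np.maximum(p, _LOG_FLOOR))))


def migrants_per_generation(ne_recipient: float, me: float) -> float:
    """Effective migrants per generation, ``4 * Ne_recipient * me``."""
    if ne_recipient < 0 or me < 0:
        raise ValueError("ne_recipient and me must be >= 0")
    return 4.0 * ne_recipient * me
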