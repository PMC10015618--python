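"""Fission/fusion detection from whole-genome alignments and outgroup
parsimony over marker co-occurrence.

Two complementary views of inter-chromosomal rearrangement:

* **Alignment view** — filtered pairwise alignments (PAF) between two
  chromosome-level assemblies yield *rearrangement points*: internal
  junctions where flanking alignments connect different chromosome
  pairs, and chromosome ends implicated in fissions/fusions.
* **Marker view** — single-copy orthologs present in three assemblies
  (ingroups A, B and outgroup O on the tree ((A,B),O)) are collapsed
  into maximal sets that co-occur on one chromosome in every taxon;
  parsimony over these sets reconstructs the chromosome content of the
  (A,B) ancestor and polarizes fissions and fusions onto branches.

The minimum number of fissions+fusions transforming partition R into
partition P is ``(c - |R|) + (c - |P|)`` where ``c`` is the number of
non-empty pairwise intersections of their blocks: split every R-block
into its intersection cells, then merge cells into P-blocks.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SyntenyAlignment",
    "RearrangementPoint",
    "EventSet",
    "read_paf",
    "filter_alignments",
    "detect_rearrangement_points",
    "polarize_parsimony",
    "annotate_window_distance",
]


@dataclasses.dataclass(frozen=True)
class SyntenyAlignment:
    query_chrom: str
    query_start: int
    query_end: int
    target_chrom: str
    target_start: int
    target_end: int
    mapq: int
    orientation: str = "+"

    @property
    def length(self) -> int:
        return self.query_end - self.query_start


@dataclasses.dataclass(frozen=True)
class RearrangementPoint:
    genome: str
    chromosome: str
    position: float
    kind: str  # "chromosome_end" or "internal_junction"


def read_paf(path) -> list[SyntenyAlignment]:
    """Read a PAF file (12+ tab-separated columns per record).

    Malformed lines are skipped with a line-number diagnostic.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                if len(parts) < 12:
                    raise ValueError("fewer than 12 columns")
                out.append(
                    SyntenyAlignment(
                        query_chrom=parts[0],
                        query_start=int(parts[2]),
                        query_end=int(parts[3]),
                        orientation=parts[4],
                        target_chrom=parts[5],
                        target_start=int(parts[7]),
                        target_end=int(parts[8]),
                        mapq=int(parts[11]),
                    )
                )
            except ValueError as err:
                logger.warning("skipping malformed PAF line %d: %s", lineno, err)
    return out


def filter_alignments(
    alignments: list[SyntenyAlignment],
    min_length: int = 50_000,
    min_mapq: int = 60,
) -> list[SyntenyAlignment]:
    """Retain alignments strictly longer than ``min_length`` with
    ``mapq >= min_mapq``."""
    return [
        a for a in alignments if a.length > min_length and a.mapq >= min_mapq
    ]


def detect_rearrangement_points(
    alignments: list[SyntenyAlignment],
    query_chrom_lengths: dict[str, int],
) -> list[RearrangementPoint]:
    """Rearrangement points on the query genome.

    Internal junctions: between adjacent filtered alignments (query
    order) mapping to different target chromosomes, at the midpoint of
    the inter-alignment gap.  Chromosome ends: for every target
    chromosome shared by two or more query chromosomes (a fusion in one
    genome or fission in the other), each involved query chromosome
    contributes the end nearest its alignments to that target.
    Duplicate calls at the same coordinate are collapsed.
    """
    by_query: dict[str, list[SyntenyAlignment]] = {}
    by_target: dict[str, set[str]] = {}
    for a in alignments:
        by_query.setdefault(a.query_chrom, []).append(a)
        by_target.setdefault(a.target_chrom, set()).add(a.query_chrom)
    for chrom in query_chrom_lengths:
        if chrom not in by_query:
            logger.warning("query chromosome %s has no alignments", chrom)
    points = set()
    for q, alns in by_query.items():
        alns = sorted(alns, key=lambda a: a.query_start)
        for left, right in zip(alns, alns[1:]):
            if left.target_chrom != right.target_chrom:
                mid = 0.5 * (left.query_end + right.query_start)
                points.add((q, mid, "internal_junction"))
    shared_targets = {t for t, qs in by_target.items() if len(qs) >= 2}
    for q, alns in by_query.items():
        qlen = query_chrom_lengths.get(q)
        if qlen is None:
            continue
        for t in {a.target_chrom for a in alns} & shared_targets:
            sub = [a for a in alns if a.target_chrom == t]
            span_lo = min(a.query_start for a in sub)
            span_hi = max(a.query_end for a in sub)
            end = 0.0 if span_lo < qlen - span_hi else float(qlen)
            points.add((q, end, "chromosome_end"))
    return [
        RearrangementPoint(genome="query", chromosome=q, position=pos, kind=kind)
        for q, pos, kind in sorted(points)
    ]


# ---------------------------------------------------------------------------
# parsimony polarization
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class EventSet:
    """Polarized rearrangement history at the (A,B) ancestor.

    ``ancestral_groups`` are the inferred ancestral chromosomes, each a
    frozenset of marker ids.  ``events[branch]`` lists ``(kind,
    operands)`` tuples whose replay from the ancestor reproduces the
    leaf partition; ``counts[branch]`` is ``(n_fissions, n_fusions)``.
    """

    ancestral_groups: tuple[frozenset, ...]
    events: dict[str, list]
    counts: dict[str, tuple[int, int]]

    @property
    def n_ancestral_chromosomes(self) -> int:
        return len(self.ancestral_groups)


def _partition_of(table: pd.DataFrame, taxon: str, markers: set) -> dict[str, frozenset]:
    sub = table[(table["taxon"] == taxon) & table["marker_id"].isin(markers)]
    return {
        chrom: frozenset(g["marker_id"])
        for chrom, g in sub.groupby("chromosome")
    }


def _blocks_to_cellsets(blocks, cell_of: dict) -> list[frozenset]:
    out: dict = {}
    for block in blocks:
        for m in block:
            out.setdefault(id(block), set()).add(cell_of[m])
    return [frozenset(v) for v in out.values()]


def _event_cost(ancestor: list[frozenset], leaf: list[frozenset]) -> tuple[int, int]:
    """(fissions, fusions) from ancestor partition to leaf partition."""
    cells = 0
    for r in ancestor:
        pieces = {i for i, p in enumerate(leaf) if r & p}
        cells += len(pieces)
    return cells - len(ancestor), cells - len(leaf)


def _set_partitions(items: list):
    """All set partitions of ``items`` (restricted growth strings)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [smaller[i] | {first}] + smaller[i + 1 :]
        yield smaller + [{first}]


def _majority_components(cells: list[int], leaf_partitions: list[list[set]]) -> list[set]:
    """Connected components of the 'co-chromosomal in >=2 taxa' graph."""
    n = len(cells)
    adj = {c: set() for c in cells}
    for i, j in itertools.combinations(cells, 2):
        votes = sum(
            any(i in b and j in b for b in part) for part in leaf_partitions
        )
        if votes >= 2:
            adj[i].add(j)
            adj[j].add(i)
    seen, comps = set(), []
    for c in cells:
        if c in seen:
            continue
        comp, stack = set(), [c]
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        seen |= comp
        comps.append(comp)
    return comps


def _score(ancestor, parts_ab, part_o):
    ingroup = sum(sum(_event_cost(ancestor, p)) for p in parts_ab)
    outgroup = sum(_event_cost(ancestor, part_o))
    return ingroup, outgroup


def polarize_parsimony(
    marker_table: pd.DataFrame,
    taxa: tuple[str, str, str] = ("A", "B", "O"),
) -> EventSet:
    """Infer the (A,B) ancestral chromosomes and per-branch events.

    ``marker_table`` has columns ``marker_id, taxon, chromosome``; only
    markers present in all three taxa are used.  Markers are collapsed
    into maximal co-occurrence sets; the ancestral partition of these
    sets minimizes the fission+fusion count on the A- and B-branches,
    with ties broken toward partitions closer to the outgroup.  The
    search is exact (full enumeration) for up to 8 co-occurrence sets
    and otherwise seeds hill-climbing (merge and split moves) from the
    majority-rule linkage of the three taxa.
    """
    taxon_a, taxon_b, taxon_o = taxa
    present = None
    for t in taxa:
        markers_t = set(marker_table.loc[marker_table["taxon"] == t, "marker_id"])
        present = markers_t if present is None else (present & markers_t)
    if not present:
        raise ValueError("no markers shared by all three taxa")
    # collapse markers into co-occurrence cells
    chrom_of = {
        t: dict(
            zip(
                marker_table.loc[marker_table["taxon"] == t, "marker_id"],
                marker_table.loc[marker_table["taxon"] == t, "chromosome"],
            )
        )
        for t in taxa
    }
    cell_key = {
        m: (chrom_of[taxon_a][m], chrom_of[taxon_b][m], chrom_of[taxon_o][m])
        for m in present
    }
    cells: dict[tuple, set] = {}
    for m, key in cell_key.items():
        cells.setdefault(key, set()).add(m)
    cell_ids = list(range(len(cells)))
    cell_markers = list(cells.values())
    cell_of_marker = {}
    for i, ms in enumerate(cell_markers):
        for m in ms:
            cell_of_marker[m] = i
    # leaf partitions over cell ids
    def leaf_partition(taxon):
        part: dict[str, set] = {}
        for i, ms in enumerate(cell_markers):
            chrom = chrom_of[taxon][next(iter(ms))]
            part.setdefault(chrom, set()).add(i)
        return [set(v) for v in part.values()]

    part_a = leaf_partition(taxon_a)
    part_b = leaf_partition(taxon_b)
    part_o = leaf_partition(taxon_o)
    as_fs = lambda part: [frozenset(b) for b in part]

    if len(cell_ids) <= 8:
        best, best_score = None, None
        for cand in _set_partitions(cell_ids):
            sc = _score(as_fs(cand), (as_fs(part_a), as_fs(part_b)), as_fs(part_o))
            if best_score is None or sc < best_score:
                best, best_score = [set(b) for b in cand], sc
        ancestor = best
    else:
        ancestor = _majority_components(cell_ids, [part_a, part_b, part_o])
        ancestor = _hill_climb(ancestor, part_a, part_b, part_o)

    anc_fs = as_fs(ancestor)
    events: dict[str, list] = {}
    counts: dict[str, tuple[int, int]] = {}
    for branch, part in ((taxon_a, part_a), (taxon_b, part_b)):
        evs = _explicit_events(ancestor, part, cell_markers)
        events[branch] = evs
        n_fis = sum(1 for kind, _ in evs if kind == "fission")
        n_fus = sum(1 for kind, _ in evs if kind == "fusion")
        check = _event_cost(anc_fs, as_fs(part))
        assert (n_fis, n_fus) == check, "event replay inconsistent with cost"
        counts[branch] = (n_fis, n_fus)
    groups = tuple(
        frozenset().union(*(cell_markers[i] for i in block)) for block in ancestor
    )
    return EventSet(ancestral_groups=groups, events=events, counts=counts)


def _hill_climb(ancestor, part_a, part_b, part_o, max_iter: int = 200):
    parts_ab = ([frozenset(b) for b in part_a], [frozenset(b) for b in part_b])
    fs_o = [frozenset(b) for b in part_o]
    current = [set(b) for b in ancestor]
    score = _score([frozenset(b) for b in current], parts_ab, fs_o)
    for _ in range(max_iter):
        improved = False
        # merge moves
        for i, j in itertools.combinations(range(len(current)), 2):
            cand = [b for k, b in enumerate(current) if k not in (i, j)]
            cand.append(current[i] | current[j])
            sc = _score([frozenset(b) for b in cand], parts_ab, fs_o)
            if sc < score:
                current, score, improved = cand, sc, True
                break
        if improved:
            continue
        # split moves along any leaf-partition boundary
        for i, block in enumerate(current):
            if len(block) < 2:
                continue
            for part in (part_a, part_b, part_o):
                for leaf_block in part:
                    piece = block & leaf_block
                    if piece and piece != block:
                        cand = [b for k, b in enumerate(current) if k != i]
                        cand.extend([set(piece), set(block - piece)])
                        sc = _score([frozenset(b) for b in cand], parts_ab, fs_o)
                        if sc < score:
                            current, score, improved = cand, sc, True
                            break
                if improved:
                    break
            if improved:
                break
        if not improved:
            break
    return current


def _explicit_events(ancestor, leaf, cell_markers):
    """Fission-then-fusion event list transforming ancestor into leaf."""

    def markers_of(block):
        return frozenset().union(*(cell_markers[i] for i in block))

    events = []
    pieces = []
    for block in ancestor:
        sub = [block & lb for lb in leaf if block & lb]
        remaining = set(block)
        for piece in sub[:-1]:
            part_a, part_b = piece, remaining - piece
            events.append(
                ("fission", (markers_of(remaining), markers_of(part_a), markers_of(part_b)))
            )
            remaining = part_b
            pieces.append(set(piece))
        pieces.append(set(remaining) if sub[:-1] else set(block))
    for lb in leaf:
        members = [p for p in pieces if p <= lb]
        while len(members) > 1:
            a, b = members[0], members[1]
            events.append(("fusion", (markers_of(a), markers_of(b))))
            members = [a | b] + members[2:]
    return events


# ---------------------------------------------------------------------------
# window annotation
# ---------------------------------------------------------------------------


def annotate_window_distance(
    windows: pd.DataFrame,
    points: list[RearrangementPoint],
    radius: float = 1e6,
) -> pd.DataFrame:
    """Distance of each window to the nearest rearrangement point.

    ``windows`` needs columns ``chromosome, start, end``.  Distance is
    the gap between the window span and the nearest point on the same
    chromosome (0 if the point falls inside the span).  Windows on
    chromosomes without any point get label ``not_applicable``;
    otherwise ``near`` iff distance < radius, else ``far``.
    """
    by_chrom: dict[str, list[float]] = {}
    for p in points:
        by_chrom.setdefault(p.chromosome, []).append(p.position)
    out = windows.copy()
    dists, labels = [], []
    for _, row in out.iterrows():
        positions = by_chrom.get(row["chromosome"])
        if not positions:
            dists.append(np.nan)
            labels.append("not_applicable")
            continue
        d = min(
            0.0
            if row["start"] <= pos <= row["end"]
            else min(abs(pos - row["start"]), abs(pos - row["end"]))
            for pos in positions
        )
        dists.append(d)
        labels.append("near" if d < radius else "far")
    out["distance_to_point"] = dists
    out["proximity"] = labels
    return out
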