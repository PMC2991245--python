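"""Compatibility segmentation, pattern trees and recombinant identification.

The detector treats each grain column's most frequent pattern as the
ancestral backbone (the *dominant* pattern) and every other shared pattern
as a *subdominant* clade inherited like a point mutation. Two columns are
compatible when no subdominant block of one *crosses* a subdominant block
of the other (overlap without nesting) — the rooted analogue of the
four-gamete test for multi-allelic pattern characters. Within a compatible
run of columns the subdominant blocks form a laminar family, so the
segment is exactly representable as a tree whose edges carry the inherited
patterns (a perfect phylogeny; no recurrence).

Merging two adjacent segments exposes recombination: a subdominant clade
``p`` from the left tree that crosses a subdominant clade ``q`` from the
right tree forces the sequences in ``p ∩ q`` to descend from two parental
nodes at once — those sequences are the recombinants, reported with the
SNP interval spanned by the two segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Tuple

import numpy as np

from .io import HaplotypeMatrix
from .patterns import RecodedMatrix, make_layout, merge_patterns, recode

__all__ = [
    "PatternTree",
    "DetectionRecord",
    "columns_compatible",
    "segment",
    "build_tree",
    "merge_trees",
    "run_single",
]


# ---------------------------------------------------------------------------
# dominance and crossing
# ---------------------------------------------------------------------------


def _dominant_code(col: np.ndarray) -> int:
    """Most frequent nonzero code; ties go to the first-appearing (lowest) code.

    Returns 0 for a column with no shared pattern at all.
    """
    if col.size == 0:
        return 0
    counts = np.bincount(col)
    if len(counts) < 2:
        return 0
    counts = counts[1:]  # code 0 is never dominant
    best = int(counts.max())
    if best == 0:
        return 0
    return int(np.flatnonzero(counts == best)[0]) + 1


def _crossings(c1: np.ndarray, c2: np.ndarray) -> List[Tuple[int, int]]:
    """Subdominant code pairs (a, b) whose blocks cross.

    Blocks cross when p∩q, p\\q and q\\p are all non-empty: no rooted tree
    can carry both patterns on single edges then.
    """
    d1 = _dominant_code(c1)
    d2 = _dominant_code(c2)
    mask = (c1 > 0) & (c2 > 0)
    if not mask.any():
        return []
    cnt1 = np.bincount(c1)
    cnt2 = np.bincount(c2)
    k2 = len(cnt2)
    keys = c1[mask].astype(np.int64) * k2 + c2[mask].astype(np.int64)
    pair_keys, inter = np.unique(keys, return_counts=True)
    out: List[Tuple[int, int]] = []
    for key, i in zip(pair_keys, inter):
        a = int(key // k2)
        b = int(key % k2)
        if a == d1 or b == d2:
            continue
        if cnt1[a] - i > 0 and cnt2[b] - i > 0:
            out.append((a, b))
    return out


_SHIFT = 1 << 20  # code values are bounded by the number of sequences


def _prep_column(col: np.ndarray):
    """Precomputed view of a code column for repeated compatibility checks."""
    col = np.asarray(col)
    return col, col > 0, col.astype(np.int64) * _SHIFT


def _compat_prepped(p1, p2) -> bool:
    c1, m1, s1 = p1
    c2, m2, s2 = p2
    both = m1 & m2
    if not both.any():
        return True
    keys = np.unique(s1[both] + c2[both])
    # union-find acyclicity over the distinct (code1, code2) edges
    parent: Dict[int, int] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for key in keys.tolist():
        u = key >> 20 << 1
        v = (key & (_SHIFT - 1)) * 2 + 1
        parent.setdefault(u, u)
        parent.setdefault(v, v)
        ru, rv = find(u), find(v)
        if ru == rv:
            return False
        parent[ru] = rv
    return True


def columns_compatible(c1: np.ndarray, c2: np.ndarray) -> bool:
    """TRUE iff the partition intersection graph of the two columns is acyclic.

    The graph has one vertex per nonzero pattern code of each column and
    one edge per observed co-occurring code pair; acyclicity is the
    multi-allelic generalization of the four-gamete test and governs
    segmentation. Unique patterns (code 0) are never considered.
    """
    return _compat_prepped(_prep_column(c1), _prep_column(c2))


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


@dataclass
class PatternTree:
    """A maximal run of mutually compatible grain columns.

    ``col_range`` indexes the recoded matrix's working columns; the SNP
    interval is always in forward coordinates. ``tree``/``edge_labels``
    (built by :func:`build_tree`) hold the laminar perfect phylogeny:
    adjacency over node ids and, per edge (parent, child), the (column,
    code) patterns inherited below it.
    """

    col_range: Tuple[int, int]
    snp_interval: Tuple[int, int]
    columns: List[np.ndarray]
    n_sequences: int
    tree: Optional[Dict[int, List[int]]] = None
    node_members: Optional[Dict[int, FrozenSet[int]]] = None
    edge_labels: Optional[Dict[Tuple[int, int], List[Tuple[int, int]]]] = None


@dataclass(frozen=True)
class DetectionRecord:
    """One raw detection from one run: recombinant rows and a SNP interval."""

    rows: FrozenSet[int]
    interval: Tuple[int, int]  # forward SNP indices, half-open
    run: Tuple[int, int, str]  # (grain, offset, direction)

    def __post_init__(self) -> None:
        if len(self.rows) < 1:
            raise ValueError("a detection needs at least one recombinant")
        if self.interval[0] >= self.interval[1]:
            raise ValueError("empty detection interval")


def segment(recoded: RecodedMatrix) -> List[PatternTree]:
    """Greedy left-to-right maximal segmentation into compatible column runs.

    The incoming column must be compatible with *every* column already in
    the open segment; on the first failure the segment is closed and a new
    one starts at the incoming column.
    """
    if recoded.n_columns < 1:
        raise ValueError("need at least one column")
    prepped = [_prep_column(recoded.column(c)) for c in range(recoded.n_columns)]
    segments: List[PatternTree] = []
    start = 0
    cur = [prepped[0]]
    for c in range(1, recoded.n_columns):
        col = prepped[c]
        ok = all(_compat_prepped(prev, col) for prev in reversed(cur))
        if ok:
            cur.append(col)
        else:
            segments.append(
                _make_segment(recoded, start, c, [p[0] for p in cur])
            )
            start = c
            cur = [col]
    segments.append(
        _make_segment(recoded, start, recoded.n_columns, [p[0] for p in cur])
    )
    return segments


def _make_segment(recoded: RecodedMatrix, i: int, j: int,
                  cols: List[np.ndarray]) -> PatternTree:
    return PatternTree(
        col_range=(i, j),
        snp_interval=recoded.layout.forward_span(i, j),
        columns=list(cols),
        n_sequences=recoded.n_sequences,
    )


# ---------------------------------------------------------------------------
# perfect-phylogeny construction
# ---------------------------------------------------------------------------


def build_tree(tree: PatternTree) -> PatternTree:
    """Construct the segment's perfect phylogeny, in place, and return it.

    Within a compatible segment the subdominant blocks of all columns are
    laminar (pairwise nested or disjoint), so the rooted tree is built
    directly: one internal node per distinct block, parent = smallest
    strictly-containing block, root = all sequences; each pattern code
    labels exactly one edge (no recurrence). Dominant patterns are carried
    by the root.
    """
    n = tree.n_sequences
    blocks: Dict[FrozenSet[int], List[Tuple[int, int]]] = {}
    root_labels: List[Tuple[int, int]] = []
    for ci, col in enumerate(tree.columns):
        dom = _dominant_code(col)
        for code in range(1, int(col.max()) + 1 if col.size else 1):
            members = frozenset(np.flatnonzero(col == code).tolist())
            if not members:
                continue
            if code == dom:
                root_labels.append((ci, code))
            else:
                blocks.setdefault(members, []).append((ci, code))
    root = frozenset(range(n))
    ordered = sorted(blocks, key=len, reverse=True)
    # laminar insertion: parent = smallest strictly containing block
    parent_of: Dict[FrozenSet[int], FrozenSet[int]] = {}
    for b in ordered:
        parent = root
        for other in ordered:
            if other is b or len(other) <= len(b):
                continue
            if b < other and (parent is root or len(other) < len(parent)):
                parent = other
        if b != root:
            parent_of[b] = parent
    ids: Dict[FrozenSet[int], int] = {root: n}
    for b in ordered:
        if b not in ids:
            ids[b] = n + len(ids)
    adj: Dict[int, List[int]] = {ids[root]: []}
    labels: Dict[Tuple[int, int], List[Tuple[int, int]]] = {}
    members_of: Dict[int, FrozenSet[int]] = {ids[root]: root}
    for b, parent in parent_of.items():
        u, v = ids[parent], ids[b]
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
        labels[(u, v)] = list(blocks[b])
        members_of[v] = b
    # attach leaves to the smallest block containing them
    leaf_parent: Dict[int, FrozenSet[int]] = {}
    for b in sorted(ordered, key=len):
        for s in b:
            if s not in leaf_parent:
                leaf_parent[s] = b
    for s in range(n):
        host = ids[leaf_parent.get(s, root)]
        adj.setdefault(host, []).append(s)
        adj.setdefault(s, []).append(host)
        members_of[s] = frozenset([s])
    if root_labels:
        labels[(ids[root], ids[root])] = root_labels
    tree.tree = adj
    tree.node_members = members_of
    tree.edge_labels = labels
    return tree


# ---------------------------------------------------------------------------
# tree merging / recombinant identification
# ---------------------------------------------------------------------------


def merge_trees(t1: PatternTree, t2: PatternTree,
                run: Tuple[int, int, str] = (0, 0, "forward")) -> List[DetectionRecord]:
    """Merge two adjacent segments into a network; report recombinants.

    For every crossing pair of subdominant blocks (p from the left
    segment's columns, q from the right segment's), the sequences in
    ``p ∩ q`` descend from two parents in the merged network and are
    emitted as one detection spanning both segments. Identical recombinant
    sets arising from several column pairs of the same merge are reported
    once. Returns an empty list when the pooled columns are compatible.
    """
    lo = min(t1.snp_interval[0], t2.snp_interval[0])
    hi = max(t1.snp_interval[1], t2.snp_interval[1])
    interval = (lo, hi)
    seen: set = set()
    sets: List[FrozenSet[int]] = []
    n = t1.n_sequences
    for c1 in t1.columns:
        for c2 in t2.columns:
            for a, b in _crossings(c1, c2):
                rows = frozenset(np.flatnonzero((c1 == a) & (c2 == b)).tolist())
                if not rows or len(rows) >= n or rows in seen:
                    continue
                seen.add(rows)
                sets.append(rows)
    # a biparental node is the maximal set descending from two parents;
    # crossings of its sub-clades repeat the same junction and are dropped
    maximal = [
        s for s in sets
        if not any(s < t for t in sets)
    ]
    return [DetectionRecord(rows, interval, run) for rows in maximal]


# ---------------------------------------------------------------------------
# one full run
# ---------------------------------------------------------------------------


def run_single(haps: HaplotypeMatrix, grain: int, offset: int,
               direction: str = "forward",
               mergepats: bool = False) -> List[DetectionRecord]:
    """Recode, segment and merge adjacent trees for one (grain, offset, direction).

    Consecutive segment pairs overlap (1-2, 2-3, ...), so one run can
    report the same recombinant set twice with overlapping intervals; both
    records are kept and both feed the aggregation. Intervals are always in
    forward SNP coordinates.
    """
    layout = make_layout(haps.n_snps, grain, offset, direction)
    rec = recode(haps, layout)
    if mergepats:
        rec = merge_patterns(rec, haps)
    segments = segment(rec)
    if len(segments) < 2:
        return []
    run = (grain, offset, direction)
    records: List[DetectionRecord] = []
    for t1, t2 in zip(segments[:-1], segments[1:]):
        records.extend(merge_trees(t1, t2, run))
    return records
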