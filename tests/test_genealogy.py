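import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from recombscan.genealogy import (
    PatternTree,
    build_tree,
    columns_compatible,
    merge_trees,
    run_single,
    segment,
)
from recombscan.io import HaplotypeMatrix
from recombscan.patterns import make_layout, recode


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def _unrooted_trees(leaves):
    """All unrooted binary trees over the given leaves, as edge lists."""
    k = len(leaves)
    if k == 1:
        yield []
        return
    if k == 2:
        yield [(leaves[0], leaves[1])]
        return
    internal = [f"i{n}" for n in range(k)]

    def grow(edges, next_leaf, next_internal):
        if next_leaf == k:
            yield edges
            return
        for idx in range(len(edges)):
            u, v = edges[idx]
            w = internal[next_internal]
            new = edges[:idx] + edges[idx + 1:] + [
                (u, w), (v, w), (leaves[next_leaf], w)
            ]
            yield from grow(new, next_leaf + 1, next_internal + 1)

    start = [(leaves[0], internal[0]), (leaves[1], internal[0]),
             (leaves[2], internal[0])]
    yield from grow(start, 3, 1)


def _min_changes(edges, leaf_state, states):
    """Brute-force small parsimony: try all internal-node state labelings."""
    nodes = sorted({n for e in edges for n in e}, key=str)
    internal = [n for n in nodes if isinstance(n, str) and n.startswith("i")]
    best = None
    for labels in itertools.product(states, repeat=len(internal)):
        assign = dict(zip(internal, labels))
        for leaf, s in leaf_state.items():
            assign[leaf] = s
        free = [n for n in nodes if n not in assign]
        # leaves with unique patterns (state 0) may take any state: try all
        for extra in itertools.product(states, repeat=len(free)):
            a = dict(assign)
            a.update(zip(free, extra))
            changes = sum(1 for u, v in edges if a[u] != a[v])
            best = changes if best is None else min(best, changes)
    return best


def _two_characters_tree_exists(c1, c2):
    """Exhaustive search for a perfect phylogeny on two multi-state columns."""
    n = len(c1)
    leaves = list(range(n))
    for edges in _unrooted_trees(leaves):
        ok = True
        for col in (np.asarray(c1), np.asarray(c2)):
            states = sorted({int(x) for x in col if x > 0})
            if len(states) <= 1:
                continue
            leaf_state = {i: int(col[i]) for i in range(n) if col[i] > 0}
            if _min_changes(edges, leaf_state, states) != len(states) - 1:
                ok = False
                break
        if ok:
            return True
    return False


def _dominant(col):
    counts = np.bincount(np.asarray(col))
    if len(counts) < 2 or counts[1:].max() == 0:
        return 0
    return int(np.flatnonzero(counts[1:] == counts[1:].max())[0]) + 1


def _crossing_sets_oracle(cols1, cols2, n):
    """Set-logic re-derivation of the maximal crossing intersections."""
    sets = []
    for c1 in cols1:
        for c2 in cols2:
            d1, d2 = _dominant(c1), _dominant(c2)
            codes1 = {int(x) for x in c1 if x > 0} - {d1}
            codes2 = {int(x) for x in c2 if x > 0} - {d2}
            for a in codes1:
                p = {i for i in range(n) if c1[i] == a}
                for b in codes2:
                    q = {i for i in range(n) if c2[i] == b}
                    inter = p & q
                    if inter and (p - q) and (q - p):
                        if 0 < len(inter) < n:
                            sets.append(frozenset(inter))
    uniq = set(sets)
    return {s for s in uniq if not any(s < t for t in uniq)}


# ---------------------------------------------------------------------------
# compatibility
# ---------------------------------------------------------------------------


class TestColumnsCompatible:
    def test_identical_columns(self):
        c = np.array([1, 1, 2, 2, 3, 3])
        assert columns_compatible(c, c)

    def test_classical_four_gamete_failure(self):
        c1 = np.array([1, 1, 2, 2])
        c2 = np.array([1, 2, 1, 2])
        assert not columns_compatible(c1, c2)

    def test_multistate_path_is_compatible(self):
        c1 = np.array([1, 1, 2, 2, 3])
        c2 = np.array([1, 2, 2, 3, 3])
        assert columns_compatible(c1, c2)

    def test_unique_patterns_excluded(self):
        # the cycle only closes through a code-0 entry, so no conflict
        c1 = np.array([1, 1, 2, 2, 0])
        c2 = np.array([1, 2, 1, 0, 2])
        c2b = np.array([1, 2, 1, 2, 2])
        assert columns_compatible(c1, c2)
        assert not columns_compatible(c1, c2b)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_exhaustive_perfect_phylogeny_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        c1 = _recode_random(rng, n)
        c2 = _recode_random(rng, n)
        assert columns_compatible(c1, c2) == _two_characters_tree_exists(c1, c2)


def _recode_random(rng, n):
    raw = rng.integers(0, 3, size=n)
    codes = np.zeros(n, dtype=np.int32)
    nxt = 1
    seen = {}
    counts = np.bincount(raw, minlength=3)
    for i, v in enumerate(raw):
        if counts[v] < 2:
            continue
        if v not in seen:
            seen[v] = nxt
            nxt += 1
        codes[i] = seen[v]
    return codes


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def _recoded_from(block, grain, offset=None):
    haps = HaplotypeMatrix(
        np.asarray(block, dtype=np.int16),
        np.arange(np.asarray(block).shape[1]) * 10.0,
        [f"r{i}" for i in range(np.asarray(block).shape[0])],
        [f"s{j}" for j in range(np.asarray(block).shape[1])],
    )
    lay = make_layout(haps.n_snps, grain, offset or grain)
    return recode(haps, lay)


class TestSegment:
    def test_all_compatible_single_segment(self, tree_matrix):
        rec = recode(tree_matrix, make_layout(tree_matrix.n_snps, 10, 10))
        segs = segment(rec)
        assert len(segs) == 1
        assert segs[0].snp_interval == (0, tree_matrix.n_snps)

    def test_single_cut(self, splice_matrix):
        rec = recode(splice_matrix, make_layout(40, 10, 10))
        segs = segment(rec)
        assert len(segs) == 2
        assert segs[0].snp_interval[1] == segs[1].snp_interval[0]

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        block = rng.integers(0, 2, size=(8, 18))
        rec = _recoded_from(block, 3)
        segs = segment(rec)
        # oracle: greedy left-to-right from the pairwise test
        cols = [rec.column(c) for c in range(rec.n_columns)]
        cuts = []
        start = 0
        for c in range(1, len(cols)):
            if not all(columns_compatible(cols[p], cols[c])
                       for p in range(start, c)):
                cuts.append(c)
                start = c
        got = [s.col_range[0] for s in segs[1:]]
        assert got == cuts


# ---------------------------------------------------------------------------
# tree construction
# ---------------------------------------------------------------------------


class TestBuildTree:
    def test_single_column_two_clusters(self):
        rec = _recoded_from([[0, 0], [0, 0], [1, 1], [1, 1]], 2)
        seg = segment(rec)[0]
        t = build_tree(seg)
        assert t.tree is not None
        # the subdominant block {2,3} hangs below one labeled edge
        labeled = {tuple(sorted(t.node_members[v]))
                   for (u, v) in t.edge_labels if u != v}
        assert (2, 3) in labeled

    def test_redundant_column_same_topology(self):
        one = _recoded_from([[0, 0], [0, 0], [1, 1], [1, 1], [0, 1]], 2)
        two = _recoded_from(
            [[0, 0, 0, 0], [0, 0, 0, 0], [1, 1, 1, 1], [1, 1, 1, 1],
             [0, 1, 0, 1]], 2)
        t1 = build_tree(segment(one)[0])
        t2 = build_tree(segment(two)[0])
        m1 = {frozenset(v) for v in t1.node_members.values()}
        m2 = {frozenset(v) for v in t2.node_members.values()}
        assert m1 == m2

    def test_every_pattern_on_exactly_one_edge(self, tree_matrix):
        rec = recode(tree_matrix, make_layout(tree_matrix.n_snps, 10, 10))
        seg = segment(rec)[0]
        t = build_tree(seg)
        labels = [lab for labs in t.edge_labels.values() for lab in labs]
        assert len(labels) == len(set(labels))  # no recurrence
        # every nonzero code of every column appears exactly once
        expected = set()
        for ci, col in enumerate(seg.columns):
            for code in set(int(x) for x in col if x > 0):
                expected.add((ci, code))
        assert set(labels) == expected


# ---------------------------------------------------------------------------
# merging / recombinant identification
# ---------------------------------------------------------------------------


class TestMergeTrees:
    def test_compatible_segments_no_detection(self, tree_matrix):
        rec = recode(tree_matrix, make_layout(tree_matrix.n_snps, 5, 5))
        segs = segment(rec)
        assert len(segs) == 1  # tree-like data never splits
        # force a split in the middle and merge the halves
        mid = rec.n_columns // 2
        t1 = PatternTree((0, mid), (0, 20), [rec.column(c) for c in range(mid)],
                         rec.n_sequences)
        t2 = PatternTree((mid, rec.n_columns), (20, 40),
                         [rec.column(c) for c in range(mid, rec.n_columns)],
                         rec.n_sequences)
        assert merge_trees(t1, t2) == []

    def test_single_splice_identified(self, splice_matrix):
        rec = recode(splice_matrix, make_layout(40, 10, 10))
        segs = segment(rec)
        records = merge_trees(segs[0], segs[1])
        assert len(records) >= 1
        splice_row = splice_matrix.row_index("F")
        assert any(r.rows == {splice_row} for r in records)

    def test_two_independent_splices_two_records(self):
        n = 40
        def hap(muts):
            h = np.zeros(n, dtype=np.int16)
            h[list(muts)] = 1
            return h
        A = hap({2, 7, 12, 17}); B = A.copy()
        D = hap({22, 27, 32, 37}); D2 = D.copy()
        E1 = hap(set()); E2 = hap(set())
        C1 = hap({4, 9, 14, 19}); C2 = C1.copy()
        G1 = hap({21, 26, 31, 36}); G2 = G1.copy()
        F = np.concatenate([A[:20], D[20:]])      # splice 1
        H = np.concatenate([C1[:20], G1[20:]])    # splice 2
        haps = HaplotypeMatrix(
            np.array([A, B, C1, C2, D, D2, E1, E2, G1, G2, F, H]),
            np.arange(n) * 10.0,
            [f"r{i}" for i in range(12)],
            [f"s{j}" for j in range(n)],
        )
        rec = recode(haps, make_layout(n, 10, 10))
        segs = segment(rec)
        records = [r for pair in zip(segs[:-1], segs[1:])
                   for r in merge_trees(*pair)]
        sets = {r.rows for r in records}
        assert frozenset({10}) in sets
        assert frozenset({11}) in sets
        assert frozenset({10, 11}) not in sets

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_crossing_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        block = rng.integers(0, 2, size=(n, 8))
        rec = _recoded_from(block, 2)
        cols = [rec.column(c) for c in range(rec.n_columns)]
        half = len(cols) // 2
        t1 = PatternTree((0, half), (0, 4), cols[:half], n)
        t2 = PatternTree((half, len(cols)), (4, 8), cols[half:], n)
        got = {r.rows for r in merge_trees(t1, t2)}
        assert got == _crossing_sets_oracle(cols[:half], cols[half:], n)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_removing_recombinants_restores_compatibility(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 10))
        block = rng.integers(0, 2, size=(n, 6))
        rec = _recoded_from(block, 3)
        cols = [rec.column(c) for c in range(rec.n_columns)]
        t1 = PatternTree((0, 1), (0, 3), cols[:1], n)
        t2 = PatternTree((1, 2), (3, 6), cols[1:2], n)
        records = merge_trees(t1, t2)
        removed = sorted({r for rec_ in records for r in rec_.rows})
        keep = [i for i in range(n) if i not in removed]
        # with dominance and codes frozen, no crossing may survive among
        # the kept rows for the merged column pair
        for c1 in t1.columns:
            for c2 in t2.columns:
                d1, d2 = _dominant(c1), _dominant(c2)
                for a in set(c1[keep]) - {0, d1}:
                    p = {i for i in keep if c1[i] == a}
                    for b in set(c2[keep]) - {0, d2}:
                        q = {i for i in keep if c2[i] == b}
                        assert not (p & q and p - q and q - p)


class TestRunSingle:
    def test_tree_data_yields_nothing(self, tree_matrix):
        assert run_single(tree_matrix, 10, 10, "forward") == []

    def test_splice_detected_with_interval_covering_breakpoint(self, splice_matrix):
        records = run_single(splice_matrix, 10, 10, "forward")
        splice_row = splice_matrix.row_index("F")
        mine = [r for r in records if r.rows == {splice_row}]
        assert mine
        a, b = mine[0].interval
        assert a <= 19 < 20 <= b  # true junction between SNPs 19 and 20

    def test_forward_reverse_intervals_mirror(self, splice_matrix):
        fw = run_single(splice_matrix, 10, 10, "forward")
        rv = run_single(splice_matrix, 10, 10, "reverse")
        fw_set = {(r.rows, r.interval) for r in fw}
        rv_set = {(r.rows, r.interval) for r in rv}
        # grain 10 divides the 40 SNPs evenly, so the reverse tiling is the
        # same as the forward one and detections must agree exactly
        assert fw_set == rv_set
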