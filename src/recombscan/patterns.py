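"""Grain-column decomposition and pattern recoding.

The detector never looks at individual alleles: the haplotype matrix is cut
into *grain columns* of ``n`` consecutive SNPs and every distinct allele
tuple inside a column becomes an integer *pattern code*. Sequences sharing
a code share the tuple; code 0 is reserved for patterns seen in exactly one
sequence, which carry no grouping evidence and are ignored downstream.
Codes are local to their column.

The optional ``mergepats`` step absorbs patterns at Hamming distance 1 into
more frequent ones, which makes the detector robust to genotyping errors
and recurrent mutation at the cost of a little resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal, Tuple

import numpy as np

from .io import HaplotypeMatrix

__all__ = ["GrainLayout", "RecodedMatrix", "make_layout", "recode", "merge_patterns"]

Direction = Literal["forward", "reverse"]


@dataclass(frozen=True)
class GrainLayout:
    """Column boundaries for one run of the detector.

    Boundaries are half-open SNP-index intervals in *working* orientation:
    for ``direction="reverse"`` the SNP order is reversed before cutting and
    :meth:`forward_interval` maps a column back to forward coordinates.
    The first column has width ``offset`` (1..grain); middle columns have
    width ``grain``; the last column takes whatever remains.
    """

    n_snps: int
    grain: int
    offset: int
    direction: Direction
    columns: Tuple[Tuple[int, int], ...]

    def forward_interval(self, col: int) -> Tuple[int, int]:
        a, b = self.columns[col]
        if self.direction == "forward":
            return a, b
        return self.n_snps - b, self.n_snps - a

    def forward_span(self, col_start: int, col_end: int) -> Tuple[int, int]:
        """Forward SNP interval covered by working columns [col_start, col_end)."""
        a = self.columns[col_start][0]
        b = self.columns[col_end - 1][1]
        if self.direction == "forward":
            return a, b
        return self.n_snps - b, self.n_snps - a

    @property
    def n_columns(self) -> int:
        return len(self.columns)


def make_layout(n_snps: int, grain: int, offset: int,
                direction: Direction = "forward") -> GrainLayout:
    """Cut ``n_snps`` SNPs into grain columns with a leading partial column."""
    if grain < 1 or grain > n_snps:
        raise ValueError(f"grain {grain} must be in [1, n_snps={n_snps}]")
    if not (1 <= offset <= grain):
        raise ValueError(f"offset {offset} must be in [1, grain={grain}]")
    if direction not in ("forward", "reverse"):
        raise ValueError(f"unknown direction {direction!r}")
    bounds = [0, offset]
    while bounds[-1] < n_snps:
        bounds.append(min(bounds[-1] + grain, n_snps))
    cols = tuple((bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1))
    return GrainLayout(n_snps, grain, offset, direction, cols)


@dataclass
class RecodedMatrix:
    """Integer pattern codes per sequence per grain column.

    ``patterns[c]`` maps each nonzero code of column ``c`` to its allele
    tuple (as an int array); singletons (code 0) keep their tuples in
    ``singleton_patterns[c]`` keyed by row index, so that ``mergepats`` can
    still absorb them.
    """

    codes: np.ndarray  # (n_sequences, n_columns) int32
    layout: GrainLayout
    patterns: List[Dict[int, np.ndarray]] = field(default_factory=list)

    @property
    def n_sequences(self) -> int:
        return self.codes.shape[0]

    @property
    def n_columns(self) -> int:
        return self.codes.shape[1]

    def column(self, c: int) -> np.ndarray:
        return self.codes[:, c]


def _recode_column(block: np.ndarray) -> Tuple[np.ndarray, Dict[int, np.ndarray]]:
    """Assign first-appearance codes to rows of ``block``; singletons get 0."""
    _, inverse, counts = np.unique(
        block, axis=0, return_inverse=True, return_counts=True
    )
    inverse = inverse.ravel()
    codes = np.zeros(block.shape[0], dtype=np.int32)
    mapping: Dict[int, np.ndarray] = {}
    next_code = 1
    remap: Dict[int, int] = {}
    for row, u in enumerate(inverse):
        if counts[u] < 2:
            continue
        if u not in remap:
            remap[u] = next_code
            mapping[next_code] = block[row].copy()
            next_code += 1
        codes[row] = remap[u]
    return codes, mapping


def recode(haps: HaplotypeMatrix, layout: GrainLayout) -> RecodedMatrix:
    """Recode each grain column's allele tuples into integer pattern codes."""
    if layout.n_snps != haps.n_snps:
        raise ValueError("layout does not match matrix width")
    work = haps.alleles if layout.direction == "forward" else haps.alleles[:, ::-1]
    codes = np.empty((haps.n_sequences, layout.n_columns), dtype=np.int32)
    patterns: List[Dict[int, np.ndarray]] = []
    for c, (a, b) in enumerate(layout.columns):
        col_codes, mapping = _recode_column(work[:, a:b])
        codes[:, c] = col_codes
        patterns.append(mapping)
    return RecodedMatrix(codes, layout, patterns)


def merge_patterns(recoded: RecodedMatrix, haps: HaplotypeMatrix) -> RecodedMatrix:
    """Hierarchical Hamming-distance-1 pattern merging (``mergepats``).

    Per column, the most frequent pattern absorbs every other pattern at
    Hamming distance exactly 1 from it; then the next most frequent pattern
    not yet absorbed does the same, and so on. Absorbed patterns adopt the
    absorber's code. Processing by decreasing (original) frequency keeps a
    sample from collapsing into a single pattern. Singleton status is
    re-evaluated after all merging in a column: a group formed from former
    singletons is real evidence and receives a nonzero code.
    """
    layout = recoded.layout
    work = haps.alleles if layout.direction == "forward" else haps.alleles[:, ::-1]
    new_codes = np.empty_like(recoded.codes)
    new_patterns: List[Dict[int, np.ndarray]] = []
    for c, (a, b) in enumerate(layout.columns):
        block = work[:, a:b]
        uniq, inverse, counts = np.unique(
            block, axis=0, return_inverse=True, return_counts=True
        )
        inverse = inverse.ravel()
        # order patterns by decreasing count, ties by first appearance
        first_row = np.full(len(uniq), block.shape[0], dtype=int)
        for row in range(block.shape[0] - 1, -1, -1):
            first_row[inverse[row]] = row
        order = sorted(range(len(uniq)), key=lambda u: (-counts[u], first_row[u]))
        group_of = np.arange(len(uniq))
        absorbed = np.zeros(len(uniq), dtype=bool)
        for u in order:
            if absorbed[u]:
                continue
            for v in range(len(uniq)):
                if v == u or absorbed[v] or group_of[v] != v:
                    continue
                if int(np.sum(uniq[u] != uniq[v])) == 1:
                    group_of[v] = u
                    absorbed[v] = True
        # re-code groups in first-appearance order; groups of size 1 -> 0
        row_group = group_of[inverse]
        group_sizes = np.zeros(len(uniq), dtype=int)
        for u in range(len(uniq)):
            group_sizes[group_of[u]] += counts[u]
        codes = np.zeros(block.shape[0], dtype=np.int32)
        mapping: Dict[int, np.ndarray] = {}
        remap: Dict[int, int] = {}
        next_code = 1
        for row in range(block.shape[0]):
            g = row_group[row]
            if group_sizes[g] < 2:
                continue
            if g not in remap:
                remap[g] = next_code
                mapping[next_code] = uniq[g].copy()
                next_code += 1
            codes[row] = remap[g]
        new_codes[:, c] = codes
        new_patterns.append(mapping)
    return RecodedMatrix(new_codes, layout, new_patterns)
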