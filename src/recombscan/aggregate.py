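"""Aggregation of detections across grains, offsets and directions.

A single run of the detector is noisy; the caller therefore runs it once
per offset (1..grain) for every grain size and direction and pools the raw
detections into per-SNP *detection distributions*: how many runs placed a
given recombinant in a network covering each SNP. The primary aggregation
unit is the recombinant sequence — a network's recombinant set credits
each of its members — which makes the counts robust to run-to-run noise in
set membership. Sequences whose distribution reaches the calling threshold
``T`` are thresholded into candidate junctions (one per contiguous >=T
region; a sequence may carry several) and candidates are grouped into
events when their regions coincide and they co-occur in raw detections.
Within a candidate region, the argmax plateau (maximum interval) midpoint
is the inferred breakpoint and the contiguous >=T region around it is the
threshold interval the caller guarantees to contain the event.

Per-set distributions (grouping records by exact recombinant-set equality)
are also provided for inspection of individual aggregation lines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .genealogy import DetectionRecord, run_single
from .io import HaplotypeMatrix, PopulationMap, RecotypeMatrix

__all__ = [
    "CallerConfig",
    "DetectionDistribution",
    "RecombinationEvent",
    "run_all",
    "aggregate_detections",
    "sequence_distributions",
    "call_events",
    "call_from_records",
    "build_recotypes",
    "filter_phasing_artifacts",
]


@dataclass(frozen=True)
class CallerConfig:
    """Detection parameters: grain sizes, directions, calling threshold.

    The default is the calibrated optimum: grains 20/10/5 run in both
    directions with an absolute threshold of 42 detections (60% of the 70
    runs). ``threshold_frac`` may be given instead of ``threshold``.
    """

    grains: Tuple[int, ...] = (20, 10, 5)
    directions: str = "both"  # forward | reverse | both
    threshold: Optional[int] = 42
    threshold_frac: Optional[float] = None
    mergepats: bool = False

    def __post_init__(self) -> None:
        if len(set(self.grains)) != len(self.grains):
            raise ValueError("grain sizes must be distinct")
        if any(g < 2 for g in self.grains):
            raise ValueError("grain sizes must be >= 2")
        if self.directions not in ("forward", "reverse", "both"):
            raise ValueError(f"unknown directions {self.directions!r}")
        if self.threshold is None and self.threshold_frac is None:
            raise ValueError("need threshold or threshold_frac")
        if self.resolved_threshold > self.total_runs:
            raise ValueError("threshold exceeds the total number of runs")

    @property
    def direction_list(self) -> Tuple[str, ...]:
        if self.directions == "both":
            return ("forward", "reverse")
        return (self.directions,)

    @property
    def total_runs(self) -> int:
        return sum(self.grains) * len(self.direction_list)

    @property
    def resolved_threshold(self) -> int:
        if self.threshold is not None:
            return int(self.threshold)
        return int(round(self.threshold_frac * self.total_runs))


@dataclass
class DetectionDistribution:
    """Per-SNP detection counts for one recombinant set."""

    rows: FrozenSet[int]
    counts: np.ndarray  # (n_snps,) int


@dataclass
class RecombinationEvent:
    """A called recombination event after thresholding.

    ``breakpoint`` is in SNP-index space (half-integers allowed: the
    midpoint of an even argmax plateau falls between two SNPs).
    """

    rows: FrozenSet[int]
    peak_count: int
    maximum_interval: Tuple[int, int]  # SNP indices, half-open argmax plateau
    breakpoint: float
    threshold_interval: Tuple[int, int]  # SNP indices, half-open, counts >= T

    def __post_init__(self) -> None:
        a, b = self.maximum_interval
        ta, tb = self.threshold_interval
        if not (ta <= a < b <= tb):
            raise ValueError("maximum interval must sit inside threshold interval")
        if not (a <= self.breakpoint <= b - 1):
            raise ValueError("breakpoint must lie in the maximum interval")


def run_all(haps: HaplotypeMatrix, config: CallerConfig,
            log: Optional[List[Tuple[int, int, str]]] = None) -> List[DetectionRecord]:
    """Execute one detector run per (grain, offset 1..grain, direction)."""
    if max(config.grains) > haps.n_snps:
        raise ValueError("largest grain exceeds the number of SNPs")
    records: List[DetectionRecord] = []
    for grain in config.grains:
        for direction in config.direction_list:
            for offset in range(1, grain + 1):
                if log is not None:
                    log.append((grain, offset, direction))
                records.extend(
                    run_single(haps, grain, offset, direction, config.mergepats)
                )
    return records


def aggregate_detections(records: Sequence[DetectionRecord],
                         n_snps: int) -> List[DetectionDistribution]:
    """Group records by exact recombinant-set equality and accumulate counts.

    ``counts[i]`` is the number of records whose interval contains SNP i.
    """
    grouped: Dict[FrozenSet[int], np.ndarray] = {}
    order: List[FrozenSet[int]] = []
    for rec in records:
        if rec.rows not in grouped:
            grouped[rec.rows] = np.zeros(n_snps, dtype=np.int32)
            order.append(rec.rows)
        a, b = rec.interval
        grouped[rec.rows][a:b] += 1
    return [DetectionDistribution(rows, grouped[rows]) for rows in order]


def call_events(distributions: Sequence[DetectionDistribution],
                config: CallerConfig) -> List[RecombinationEvent]:
    """Threshold the distributions and locate breakpoints.

    The maximum interval is the maximal contiguous argmax run; its midpoint
    is the breakpoint. The threshold interval is the contiguous region with
    counts >= T that contains the maximum interval; any other >=T region of
    the same distribution is ignored (single-breakpoint model). Events are
    returned sorted by breakpoint.
    """
    T = config.resolved_threshold
    if T < 1:
        raise ValueError("threshold must be >= 1")
    events: List[RecombinationEvent] = []
    for dist in distributions:
        counts = dist.counts
        peak = int(counts.max()) if counts.size else 0
        if peak < T:
            continue
        argmax = np.flatnonzero(counts == peak)
        # maximal contiguous run containing the first argmax
        start = argmax[0]
        end = start
        for i in argmax[1:]:
            if i == end + 1:
                end = i
            else:
                break
        bkp = (start + end) / 2.0
        ta = start
        while ta > 0 and counts[ta - 1] >= T:
            ta -= 1
        tb = end
        while tb < len(counts) - 1 and counts[tb + 1] >= T:
            tb += 1
        events.append(
            RecombinationEvent(
                rows=dist.rows,
                peak_count=peak,
                maximum_interval=(int(start), int(end) + 1),
                breakpoint=float(bkp),
                threshold_interval=(int(ta), int(tb) + 1),
            )
        )
    events.sort(key=lambda e: (e.breakpoint, sorted(e.rows)))
    return events


def sequence_distributions(records: Sequence[DetectionRecord], n_sequences: int,
                           n_snps: int) -> np.ndarray:
    """Per-sequence detection counts: one row per sequence, one column per SNP.

    Every record credits each member of its recombinant set over its
    interval, so a junction's support does not fragment when the detected
    set varies slightly between runs.
    """
    counts = np.zeros((n_sequences, n_snps), dtype=np.int32)
    for rec in records:
        a, b = rec.interval
        counts[sorted(rec.rows), a:b] += 1
    return counts


def _argmax_plateau(c: np.ndarray, ta: int, tb: int) -> Tuple[int, int, int]:
    """First maximal argmax plateau within [ta, tb); returns (a, b, peak)."""
    seg = c[ta:tb]
    peak = int(seg.max())
    argmax = np.flatnonzero(seg == peak)
    start = int(argmax[0])
    end = start
    for i in argmax[1:]:
        if i == end + 1:
            end = int(i)
        else:
            break
    return ta + start, ta + end + 1, peak


def _extract_peaks(row: int, recs: List[DetectionRecord], n_snps: int,
                   T: int) -> List[Tuple[int, Tuple[int, int], Tuple[int, int], int, float]]:
    """Junction candidates for one sequence: local-maximum plateaus >= T.

    A sequence can carry several junctions whose detection mass overlaps
    within one >=T region, so every maximal plateau that is a local
    maximum of the distribution (strictly higher than the values flanking
    the plateau) yields one candidate; its threshold interval is the
    contiguous >=T region around it.
    """
    if not recs:
        return []
    c = np.zeros(n_snps, dtype=np.int32)
    for rec in recs:
        c[rec.interval[0]:rec.interval[1]] += 1
    out = []
    i = 0
    while i < n_snps:
        if c[i] < T:
            i += 1
            continue
        j = i
        while j + 1 < n_snps and c[j + 1] == c[i]:
            j += 1
        left_lower = i == 0 or c[i - 1] < c[i]
        right_lower = j == n_snps - 1 or c[j + 1] < c[i]
        if left_lower and right_lower:
            ta = i
            while ta > 0 and c[ta - 1] >= T:
                ta -= 1
            tb = j
            while tb < n_snps - 1 and c[tb + 1] >= T:
                tb += 1
            out.append((row, (ta, tb + 1), (i, j + 1), int(c[i]), (i + j) / 2.0))
        i = j + 1
    return out


def call_from_records(records: Sequence[DetectionRecord],
                      haps: HaplotypeMatrix,
                      config: CallerConfig,
                      group_tolerance: int = 2) -> List[RecombinationEvent]:
    """Call events from raw records via per-sequence aggregation.

    Each sequence is thresholded on its own detection distribution; every
    contiguous >=T region yields one candidate junction. Candidates from
    different sequences are one event when their threshold regions
    overlap, their breakpoints lie within ``group_tolerance`` SNPs, and
    the pair co-occurs in at least one raw record covering both peaks.
    The grouped event takes its breakpoint and intervals from the member
    with the highest peak (ties to the lowest sequence index).
    """
    T = config.resolved_threshold
    if T < 1:
        raise ValueError("threshold must be >= 1")
    n_seq, n_snps = haps.n_sequences, haps.n_snps
    # records indexed by member row for peak extraction
    by_row: Dict[int, List[DetectionRecord]] = {}
    for rec in records:
        for r in rec.rows:
            by_row.setdefault(r, []).append(rec)
    cands: List[Tuple[int, Tuple[int, int], Tuple[int, int], int, float]] = []
    for r in range(n_seq):
        cands.extend(_extract_peaks(r, by_row.get(r, []), n_snps, T))
    if not cands:
        return []
    # membership matrix plus a (row, cell) -> record-id index so that
    # co-occurrence queries touch only the records of one row at one SNP
    member = np.zeros((len(records), n_seq), dtype=bool)
    pair_rec: List[int] = []
    pair_row: List[int] = []
    pair_a: List[int] = []
    pair_w: List[int] = []
    for k, rec in enumerate(records):
        rows_sorted = sorted(rec.rows)
        member[k, rows_sorted] = True
        a, b = rec.interval
        for r in rows_sorted:
            pair_rec.append(k)
            pair_row.append(r)
            pair_a.append(a)
            pair_w.append(b - a)
    pr = np.asarray(pair_rec, dtype=np.int32)
    rw = np.asarray(pair_row, dtype=np.int64)
    aa = np.asarray(pair_a, dtype=np.int64)
    ww = np.asarray(pair_w, dtype=np.int64)
    total = int(ww.sum())
    rec_exp = np.repeat(pr, ww)
    starts = np.concatenate([[0], np.cumsum(ww)[:-1]])
    within = np.arange(total) - np.repeat(starts, ww)
    keys = np.repeat(rw, ww) * n_snps + np.repeat(aa, ww) + within
    order_keys = np.argsort(keys, kind="stable")
    keys_sorted = keys[order_keys]
    recs_by_key = rec_exp[order_keys]

    def _records_at(row: int, cell: int) -> np.ndarray:
        key = row * n_snps + cell
        a = int(np.searchsorted(keys_sorted, key, side="left"))
        b = int(np.searchsorted(keys_sorted, key, side="right"))
        return recs_by_key[a:b]

    def co_occur(i: int, j: int) -> bool:
        # the pair must be co-detected in the majority of the runs that
        # detect either of them at this locus; occasional joint membership
        # (e.g. two junctions sharing a hotspot) does not merge events
        ri, rj = cands[i][0], cands[j][0]
        q = int((cands[i][4] + cands[j][4]) // 2)
        q = min(max(q, 0), n_snps - 1)
        ai = _records_at(ri, q)
        aj = _records_at(rj, q)
        if ai.size == 0 or aj.size == 0:
            return False
        n_both = int(member[ai, rj].sum())
        if n_both == 0:
            return False
        return 2 * n_both > min(ai.size, aj.size)

    parent = list(range(len(cands)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    order = sorted(range(len(cands)), key=lambda i: cands[i][4])
    for ii in range(len(order)):
        i = order[ii]
        for jj in range(ii + 1, len(order)):
            j = order[jj]
            if cands[j][4] - cands[i][4] > group_tolerance:
                break
            if cands[i][0] == cands[j][0]:
                continue
            (ta_i, tb_i), (ta_j, tb_j) = cands[i][1], cands[j][1]
            if tb_i <= ta_j or tb_j <= ta_i:
                continue
            if co_occur(i, j):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    groups: Dict[int, List[int]] = {}
    for i in range(len(cands)):
        groups.setdefault(find(i), []).append(i)
    events: List[RecombinationEvent] = []
    for members in groups.values():
        rep = min(members, key=lambda i: (-cands[i][3], cands[i][0]))
        rows = frozenset(cands[i][0] for i in members)
        _, (ta, tb), _, peak, bkp = cands[rep]
        # the event's plateau is the union of its members' argmax plateaus:
        # each member's peak is an independent read of the same junction
        a = min(cands[i][2][0] for i in members)
        b = max(cands[i][2][1] for i in members)
        ta = min(ta, a)
        tb = max(tb, b)
        events.append(
            RecombinationEvent(
                rows=rows,
                peak_count=peak,
                maximum_interval=(a, b),
                breakpoint=bkp,
                threshold_interval=(ta, tb),
            )
        )
    events.sort(key=lambda e: (e.breakpoint, sorted(e.rows)))
    return events


def build_recotypes(events: Sequence[RecombinationEvent],
                    haps: HaplotypeMatrix) -> RecotypeMatrix:
    """Binary presence/absence matrix of events (columns ordered by breakpoint)."""
    events = sorted(events, key=lambda e: (e.breakpoint, sorted(e.rows)))
    matrix = np.zeros((haps.n_sequences, len(events)), dtype=np.int8)
    for j, ev in enumerate(events):
        matrix[sorted(ev.rows), j] = 1
    return RecotypeMatrix(
        matrix=matrix,
        sequence_ids=list(haps.sequence_ids),
        event_ids=[f"R{j + 1}" for j in range(len(events))],
        breakpoints=np.array([ev.breakpoint for ev in events]),
        threshold_intervals=[ev.threshold_interval for ev in events],
    )


def filter_phasing_artifacts(
    events: Sequence[RecombinationEvent],
    haps: HaplotypeMatrix,
    pairing: Optional[PopulationMap],
    max_snp_distance: int = 6,
) -> Tuple[List[RecombinationEvent], List[RecombinationEvent]]:
    """Drop reciprocal single-recombinant event pairs on one individual.

    A phasing switch shows up as two singleton events, one on each homolog
    of the same individual, at (nearly) the same position. Every pair of
    singleton events on the two homologs of one individual with breakpoints
    closer than ``max_snp_distance`` SNPs is removed; both members of each
    removed pair are returned for audit. Without a pairing map this is a
    no-op (with a warning).
    """
    import warnings

    if pairing is None or not pairing.pairs:
        warnings.warn("no haplotype pairing provided; phasing filter skipped")
        return list(events), []
    pairing.validate_against(haps)
    mate: Dict[int, int] = {}
    for a, b in pairing.pairs.values():
        ia, ib = haps.row_index(a), haps.row_index(b)
        mate[ia] = ib
        mate[ib] = ia
    removed_idx: set = set()
    evs = list(events)
    for i, ev1 in enumerate(evs):
        if len(ev1.rows) != 1:
            continue
        (r1,) = ev1.rows
        if r1 not in mate:
            continue
        for j in range(i + 1, len(evs)):
            ev2 = evs[j]
            if len(ev2.rows) != 1:
                continue
            (r2,) = ev2.rows
            if r2 != mate[r1]:
                continue
            if abs(ev1.breakpoint - ev2.breakpoint) < max_snp_distance:
                removed_idx.add(i)
                removed_idx.add(j)
    kept = [ev for i, ev in enumerate(evs) if i not in removed_idx]
    removed = [ev for i, ev in enumerate(evs) if i in removed_idx]
    return kept, removed
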