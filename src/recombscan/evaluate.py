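"""Scoring detections against simulated ground truth.

The evaluation protocol mirrors the calibration pipeline: simulated true
events are first pruned of those that are undetectable in principle
(recombination between parental lineages identical over one flank of the
breakpoint, or falling outside the ascertained SNP span); detections are
then matched one-to-one against the surviving events — a detection is
correct when its recombinant set equals the true descendant set (or a
subset of it, when every excluded descendant carries a younger overlapping
event that masks the older junction) and the true breakpoint lies inside
the detection's threshold interval. False discovery rate, sensitivity and
breakpoint-placement accuracy (distances in SNP slots; the empirical 90th
percentile by nearest rank) summarize each replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .aggregate import RecombinationEvent
from .io import HaplotypeMatrix
from .simulate import TrueEvent

__all__ = [
    "EvaluationReport",
    "Matching",
    "prune_undetectable",
    "match",
    "score",
    "sweep",
    "random_control",
    "nearest_rank_percentile",
]


def nearest_rank_percentile(values: Sequence[float], q: float) -> float:
    """Nearest-rank percentile: the ceil(q*n)-th smallest value."""
    vals = sorted(values)
    if not vals:
        raise ValueError("empty sample")
    rank = int(np.ceil(q / 100.0 * len(vals)))
    return float(vals[max(rank, 1) - 1])


# ---------------------------------------------------------------------------
# undetectable-event pruning
# ---------------------------------------------------------------------------


def prune_undetectable(truth: Sequence[TrueEvent], haps: HaplotypeMatrix,
                       site_times: Optional[np.ndarray] = None,
                       window: int = 20) -> List[TrueEvent]:
    """Drop true events that cannot leave an observable trace.

    An event is pruned when (a) its breakpoint lies outside the ascertained
    SNP span, or (b) the two parental sequences were identical over at
    least one flank of the breakpoint at the time of the event. Identity is
    tested on realized data: a descendant matching an extant carrier of the
    *other* parent's material (the event's parental context on that side)
    over the flank means the recombinant is indistinguishable from a plain
    inheritance of that parent. When per-SNP mutation ages are supplied
    (``site_times``), the comparison is restricted to SNPs older than the
    event — younger mutations did not exist when the recombination
    happened and cannot bear on parental identity. The comparison is
    further limited to ``window`` SNPs on each side of the breakpoint:
    the detector only reads patterns within a grain of the junction, and
    beyond that range the extant rows stop being faithful proxies for the
    parental flanks. Pruned events are excluded from sensitivity
    denominators downstream.
    """
    positions = haps.positions
    alleles = haps.alleles
    n_snps = haps.n_snps
    if site_times is None:
        site_times = np.full(n_snps, np.inf)
    site_times = np.asarray(site_times)
    kept: List[TrueEvent] = []
    for ev in truth:
        j = int(np.searchsorted(positions, ev.breakpoint, side="left"))
        if j <= 0 or j >= n_snps:
            continue
        old = site_times > ev.age
        lo = max(0, j - window)
        hi = min(n_snps, j + window)
        left = lo + np.flatnonzero(old[lo:j])
        right = j + np.flatnonzero(old[j:hi])
        desc = np.fromiter(ev.descendants, dtype=int)
        # parents identical over the left flank -> invisible junction
        if _parents_identical(alleles, desc, ev.right_context, left):
            continue
        if _parents_identical(alleles, desc, ev.left_context, right):
            continue
        kept.append(ev)
    return kept


_HASH_RNG = np.random.default_rng(987654321)
_HASH_W: np.ndarray = _HASH_RNG.integers(1, 2 ** 62, size=4096, dtype=np.int64)


def _row_hashes(alleles: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    w = _HASH_W
    while cols.size > w.size:  # pragma: no cover - very wide matrices
        w = np.concatenate([w, w])
    return (alleles[np.ix_(rows, cols)].astype(np.int64) * w[: cols.size]).sum(axis=1)


def _modal_hash(hashes: np.ndarray) -> np.int64:
    vals, counts = np.unique(hashes, return_counts=True)
    return vals[int(np.argmax(counts))]


def _parents_identical(alleles: np.ndarray, desc: np.ndarray, context,
                       cols: np.ndarray) -> bool:
    """True iff the two parental flank sequences look identical over ``cols``.

    The parent transmitting this flank is proxied by the modal descendant
    pattern (descendants inherited it directly); the other parent by the
    modal pattern of its nearest extant relatives. An empty comparison (no
    informative SNP on the flank, or no extant representative of the other
    parent) counts as identity: nothing distinguishes the parents there.
    Rows are compared through seeded 64-bit fingerprints.
    """
    if len(context) == 0 or cols.size == 0:
        return True
    ctx = np.fromiter(context, dtype=int)
    return _modal_hash(_row_hashes(alleles, desc, cols)) == _modal_hash(
        _row_hashes(alleles, ctx, cols)
    )


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------


@dataclass
class Matching:
    """One-to-one assignment of detections to true events."""

    pairs: List[Tuple[int, int, float]]  # (event index, truth index, distance SNPs)
    n_detections: int
    n_truth: int

    @property
    def matched_detections(self) -> set:
        return {i for i, _, _ in self.pairs}

    @property
    def matched_truth(self) -> set:
        return {j for _, j, _ in self.pairs}

    @property
    def distances(self) -> List[float]:
        return [d for _, _, d in self.pairs]


def _true_slot(positions: np.ndarray, breakpoint: float) -> float:
    """SNP-space coordinate of the inter-SNP slot holding a bp breakpoint."""
    j = int(np.searchsorted(positions, breakpoint, side="left"))
    return j - 0.5


def match(events: Sequence[RecombinationEvent], truth: Sequence[TrueEvent],
          positions: np.ndarray,
          all_truth: Optional[Sequence[TrueEvent]] = None,
          interval: str = "threshold") -> Matching:
    """One-to-one matching of detections to true events.

    A detection can match a true event iff (a) its recombinant set equals
    the descendant set, or is a proper subset of it such that every
    excluded descendant carries a younger true event (from ``all_truth``)
    whose breakpoint overlaps the detection interval — masking of the older
    junction; and (b) the true breakpoint lies inside the detection's
    interval (``"threshold"`` by default, ``"maximum"`` as the stricter
    alternative). Candidates are assigned greedily by increasing
    breakpoint distance so one true event never absorbs two detections.
    """
    if interval not in ("threshold", "maximum"):
        raise ValueError("interval must be 'threshold' or 'maximum'")
    all_truth = list(all_truth) if all_truth is not None else list(truth)
    positions = np.asarray(positions)
    # truths sorted by breakpoint for windowed candidate generation
    t_bkpts = np.array([t.breakpoint for t in truth])
    t_order = np.argsort(t_bkpts, kind="stable")
    t_sorted = t_bkpts[t_order]
    # per-sequence index of (breakpoint, age) for the masking rule
    by_seq: Dict[int, List[Tuple[float, float]]] = {}
    for t in all_truth:
        for s in t.descendants:
            by_seq.setdefault(s, []).append((t.breakpoint, t.age))
    seq_bk: Dict[int, np.ndarray] = {}
    seq_age: Dict[int, np.ndarray] = {}
    for s, lst in by_seq.items():
        lst.sort()
        seq_bk[s] = np.array([x[0] for x in lst])
        seq_age[s] = np.array([x[1] for x in lst])

    def youngest_in(s: int, lo: float, hi: float) -> float:
        """Age of the youngest junction of sequence s inside [lo, hi] bp."""
        bk = seq_bk.get(s)
        if bk is None:
            return np.inf
        a = int(np.searchsorted(bk, lo, side="left"))
        b = int(np.searchsorted(bk, hi, side="right"))
        if a >= b:
            return np.inf
        return float(seq_age[s][a:b].min())

    def slot_window(a: int, b: int) -> Tuple[float, float]:
        # an interval covering SNPs [a, b) contains the inter-SNP slots
        # a-0.5 .. b-0.5, i.e. breakpoints between positions[a-1] and
        # positions[b] (the flanking SNPs of the interval's ends)
        lo = float(positions[a - 1]) if a > 0 else float(positions[0]) - 1.0
        hi = float(positions[b]) if b < len(positions) else float(positions[-1]) + 1.0
        return lo, hi

    candidates: List[Tuple[int, float, int, int]] = []
    for i, ev in enumerate(events):
        a, b = ev.threshold_interval if interval == "threshold" else ev.maximum_interval
        lo_bp, hi_bp = slot_window(a, b)
        # masking is judged over the detection's full support region: a
        # younger junction anywhere under the threshold interval can erase
        # the older trace in a descendant
        mlo_bp, mhi_bp = slot_window(*ev.threshold_interval)
        rows = frozenset(ev.rows)
        wa = int(np.searchsorted(t_sorted, lo_bp, side="left"))
        wb = int(np.searchsorted(t_sorted, hi_bp, side="right"))
        young_cache: Dict[int, float] = {}
        for j in (int(x) for x in t_order[wa:wb]):
            t = truth[j]
            dset = t.descendants
            if rows == dset:
                pass
            elif rows < dset:
                ok = True
                for e in dset - rows:
                    y = young_cache.get(e)
                    if y is None:
                        y = youngest_in(e, mlo_bp, mhi_bp)
                        young_cache[e] = y
                    if y >= t.age:
                        ok = False
                        break
                if not ok:
                    continue
            else:
                continue
            dist = abs(ev.breakpoint - _true_slot(positions, t.breakpoint))
            candidates.append((len(dset - rows), dist, i, j))
    # exact descendant-set matches take precedence over masked subsets
    # (fewest excluded descendants first), then closest breakpoint
    candidates.sort()
    used_e: set = set()
    used_t: set = set()
    pairs: List[Tuple[int, int, float]] = []
    for _, dist, i, j in candidates:
        if i in used_e or j in used_t:
            continue
        used_e.add(i)
        used_t.add(j)
        pairs.append((i, j, dist))
    return Matching(pairs=pairs, n_detections=len(events), n_truth=len(truth))


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Replicate-level (or aggregated) detection quality metrics."""

    fdr: Optional[float]  # %, None when there are no detections
    sensitivity: Optional[float]  # %, None when no true events survive pruning
    distances: List[float] = field(default_factory=list)  # SNP slots
    matched_ages: List[float] = field(default_factory=list)  # generations
    n_detections: int = 0
    n_truth: int = 0
    n_matched: int = 0

    @property
    def accuracy_p90(self) -> Optional[float]:
        if not self.distances:
            return None
        return nearest_rank_percentile(self.distances, 90)

    @property
    def median_distance(self) -> Optional[float]:
        if not self.distances:
            return None
        return float(np.median(self.distances))


def score(matching: Matching, truth: Sequence[TrueEvent],
          kept: Optional[Sequence[TrueEvent]] = None) -> EvaluationReport:
    """FDR, sensitivity, placement distances and matched ages for one replicate.

    ``matching`` pairs detections with entries of ``truth`` (typically all
    recorded events); ``kept`` is the pruned subset that defines the
    sensitivity denominator — a matched event outside ``kept`` counts as a
    correct detection but not towards sensitivity. Ages are reported for
    matched kept events.
    """
    kept = list(truth) if kept is None else list(kept)
    kept_ids = {id(t) for t in kept}
    n_det = matching.n_detections
    n_matched = len(matching.pairs)
    fdr = None if n_det == 0 else 100.0 * (n_det - n_matched) / n_det
    matched_kept = [j for _, j, _ in matching.pairs if id(truth[j]) in kept_ids]
    sens = None if not kept else 100.0 * len(matched_kept) / len(kept)
    ages = [truth[j].age for j in matched_kept]
    return EvaluationReport(
        fdr=fdr,
        sensitivity=sens,
        distances=list(matching.distances),
        matched_ages=ages,
        n_detections=n_det,
        n_truth=len(kept),
        n_matched=n_matched,
    )


# ---------------------------------------------------------------------------
# parameter sweep
# ---------------------------------------------------------------------------


def sweep(setting_reports: Dict[str, Sequence[EvaluationReport]]) -> pd.DataFrame:
    """Rank parameter settings by the aggregate z-score.

    Per setting the mean FDR, mean sensitivity and mean 90th-percentile
    distance are computed over replicates; z-scores are taken across the
    settings and combined as ``-2 z(FDR) + z(sensitivity) - z(p90)`` (false
    discovery weighted double, errors negative). Returns a DataFrame
    sorted by decreasing aggregate score.
    """
    if len(setting_reports) < 2:
        raise ValueError("need at least two settings to sweep")
    rows = []
    for name, reports in setting_reports.items():
        fdrs = [r.fdr for r in reports if r.fdr is not None]
        sens = [r.sensitivity for r in reports if r.sensitivity is not None]
        p90s = [r.accuracy_p90 for r in reports if r.accuracy_p90 is not None]
        rows.append(
            {
                "setting": name,
                "mean_fdr": float(np.mean(fdrs)) if fdrs else np.nan,
                "mean_sensitivity": float(np.mean(sens)) if sens else np.nan,
                "mean_p90_distance": float(np.mean(p90s)) if p90s else np.nan,
            }
        )
    df = pd.DataFrame(rows)

    def zscores(col: pd.Series) -> pd.Series:
        sd = col.std(ddof=0)
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(f"degenerate sweep column {col.name!r}; z-scores set to 0")
            return col * 0.0
        return (col - col.mean()) / sd

    df["z_fdr"] = zscores(df["mean_fdr"])
    df["z_sensitivity"] = zscores(df["mean_sensitivity"])
    df["z_p90"] = zscores(df["mean_p90_distance"])
    df["aggregate_z"] = -2.0 * df["z_fdr"] + df["z_sensitivity"] - df["z_p90"]
    return df.sort_values("aggregate_z", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# permutation control
# ---------------------------------------------------------------------------


def random_control(
    events_by_replicate: Sequence[Sequence[RecombinationEvent]],
    truth_by_replicate: Sequence[Sequence[TrueEvent]],
    positions_by_replicate: Sequence[np.ndarray],
    kept_by_replicate: Optional[Sequence[Sequence[TrueEvent]]] = None,
    permutation_seed: int = 0,
    identity: bool = False,
    interval: str = "maximum",
) -> List[EvaluationReport]:
    """Score each replicate's detections against a different replicate's truth.

    A seeded derangement pairs every detection set with a non-matching
    truth set (``identity=True`` scores against own truth, for testing
    only). Chance agreement should drive FDR up and sensitivity down.
    """
    n = len(events_by_replicate)
    if n != len(truth_by_replicate) or n != len(positions_by_replicate):
        raise ValueError("replicate lists must align")
    if kept_by_replicate is None:
        kept_by_replicate = truth_by_replicate
    if n < 2 and not identity:
        raise ValueError("need at least two replicates for a derangement")
    if identity:
        perm = np.arange(n)
    else:
        rng = np.random.default_rng(permutation_seed)
        order = rng.permutation(n)
        # rotate the shuffled order by one: a seeded derangement
        perm = np.empty(n, dtype=int)
        perm[order] = order[(np.arange(n) + 1) % n]
    reports = []
    for i in range(n):
        j = int(perm[i])
        m = match(
            events_by_replicate[i],
            truth_by_replicate[j],
            positions_by_replicate[i],
            interval=interval,
        )
        reports.append(score(m, truth_by_replicate[j], kept_by_replicate[j]))
    return reports
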