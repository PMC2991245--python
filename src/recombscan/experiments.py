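"""End-to-end calibration experiments.

One replicate of the evaluation protocol: (1) simulate a 250 kb region
with full recombination ground truth; (2) ascertain SNPs (MAF floor plus
pairwise tag selection); (3) prune true events that cannot leave a trace;
(4) run the detector and match detections to surviving events (descendant
sets, masking-aware subsets, breakpoint inside the threshold interval);
(5) score false discovery rate, sensitivity and placement accuracy.
Replicates with 80 or fewer ascertained SNPs are discarded and redrawn.

The module also provides the blank (recombination-free) control, the
permuted-truth control and the age analyses used in the calibration
study, plus the in-silico splice detection-frequency experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence

import numpy as np

from .aggregate import CallerConfig, RecombinationEvent
from .evaluate import (
    EvaluationReport,
    match,
    nearest_rank_percentile,
    prune_undetectable,
    random_control,
    score,
)
from .io import HaplotypeMatrix
from .model import RecombinationScan
from .simulate import (
    AscertainmentConfig,
    SimParams,
    TrueEvent,
    ascertain,
    select_parents,
    simulate_dataset,
    splice_recombinant,
)

__all__ = [
    "ReplicateResult",
    "CalibrationResult",
    "run_replicate",
    "run_calibration",
    "blank_control",
    "permuted_truth_control",
    "age_binned_sensitivity",
    "splice_detection_frequencies",
]


@dataclass
class ReplicateResult:
    """Everything the downstream analyses need from one replicate."""

    seed: int
    events: List[RecombinationEvent]
    kept_truth: List[TrueEvent]
    all_truth: List[TrueEvent]
    positions: np.ndarray
    n_snps: int
    report: EvaluationReport
    matched_kept_ids: frozenset = frozenset()  # id() of matched kept events


@dataclass
class CalibrationResult:
    """Per-replicate results plus the headline aggregate metrics."""

    replicates: List[ReplicateResult]

    @property
    def mean_fdr(self) -> float:
        vals = [r.report.fdr for r in self.replicates if r.report.fdr is not None]
        return float(np.mean(vals))

    @property
    def mean_sensitivity(self) -> float:
        vals = [
            r.report.sensitivity
            for r in self.replicates
            if r.report.sensitivity is not None
        ]
        return float(np.mean(vals))

    @property
    def pooled_distances(self) -> List[float]:
        return [d for r in self.replicates for d in r.report.distances]

    @property
    def median_distance(self) -> float:
        return float(np.median(self.pooled_distances))

    @property
    def p90_distance(self) -> float:
        return nearest_rank_percentile(self.pooled_distances, 90)

    @property
    def pooled_matched_ages(self) -> List[float]:
        return [a for r in self.replicates for a in r.report.matched_ages]

    @property
    def median_age_per_replicate(self) -> float:
        """Central value across replicates of the per-replicate median age."""
        meds = [
            float(np.median(r.report.matched_ages))
            for r in self.replicates
            if r.report.matched_ages
        ]
        return float(np.median(meds))

    @property
    def age_p90(self) -> float:
        return nearest_rank_percentile(self.pooled_matched_ages, 90)


def run_replicate(seed: int,
                  params: Optional[SimParams] = None,
                  caller: Optional[CallerConfig] = None,
                  asc: Optional[AscertainmentConfig] = None) -> ReplicateResult:
    """Simulate, ascertain, detect, prune, match and score one replicate."""
    params = (params or SimParams()).with_seed(seed)
    caller = caller or CallerConfig()
    asc = asc or AscertainmentConfig()
    ds = simulate_dataset(params)
    haps = ascertain(ds.haplotypes, asc)
    asc_idx = np.searchsorted(ds.haplotypes.positions, haps.positions)
    site_times = None if ds.site_times is None else ds.site_times[asc_idx]
    kept_truth = prune_undetectable(ds.true_events, haps, site_times=site_times)
    scan = RecombinationScan(
        haps,
        grains=caller.grains,
        directions=caller.directions,
        threshold=caller.threshold,
        threshold_frac=caller.threshold_frac,
        mergepats=caller.mergepats,
    )
    res = scan.fit()
    # the true breakpoint must fall inside the argmax plateau — the region
    # the caller pins the junction to
    m = match(res.events, ds.true_events, haps.positions,
              all_truth=ds.true_events, interval="maximum")
    report = score(m, ds.true_events, kept_truth)
    kept_ids = {id(t) for t in kept_truth}
    matched_kept = frozenset(
        id(ds.true_events[j]) for _, j, _ in m.pairs
        if id(ds.true_events[j]) in kept_ids
    )
    return ReplicateResult(
        seed=seed,
        events=res.events,
        kept_truth=kept_truth,
        all_truth=list(ds.true_events),
        positions=haps.positions.copy(),
        n_snps=haps.n_snps,
        report=report,
        matched_kept_ids=matched_kept,
    )


def _replicate_seeds(base_seed: int, n: int, stream: int = 0):
    """Deterministic stream of sub-2^31 seeds for replicate draws."""
    rng = np.random.default_rng([base_seed, stream])
    while True:
        for s in rng.integers(1, 2 ** 31 - 1, size=max(2 * n, 16)):
            yield int(s)


def run_calibration(n_replicates: int = 100,
                    base_seed: int = 1,
                    params: Optional[SimParams] = None,
                    caller: Optional[CallerConfig] = None,
                    asc: Optional[AscertainmentConfig] = None,
                    min_snps: int = 80,
                    progress: bool = False) -> CalibrationResult:
    """Run the calibration over ``n_replicates`` datasets with > min_snps SNPs.

    Replicates whose ascertained matrix has ``min_snps`` or fewer SNPs are
    discarded and fresh seeds drawn, mirroring the retention rule of the
    calibration protocol.
    """
    seeds = _replicate_seeds(base_seed, n_replicates)
    out: List[ReplicateResult] = []
    attempts = 0
    while len(out) < n_replicates:
        seed = next(seeds)
        attempts += 1
        if attempts > 20 * n_replicates:
            raise RuntimeError("too many replicates rejected by the SNP filter")
        rep = run_replicate(seed, params=params, caller=caller, asc=asc)
        if rep.n_snps <= min_snps:
            continue
        out.append(rep)
        if progress and len(out) % 10 == 0:
            print(f"  replicate {len(out)}/{n_replicates}", flush=True)
    return CalibrationResult(out)


def blank_control(n_replicates: int = 100,
                  base_seed: int = 2,
                  params: Optional[SimParams] = None,
                  caller: Optional[CallerConfig] = None,
                  asc: Optional[AscertainmentConfig] = None,
                  min_snps: Optional[int] = None) -> List[int]:
    """Called-event counts on recombination-free simulations.

    Ascertainment defaults to the MAF floor alone and the calibration SNP
    filter is relaxed to the largest grain size (the minimum the detector
    can run on): without recombination all SNPs of a clade are perfectly
    correlated, so pairwise tag selection is degenerate — it collapses the
    panel to roughly one SNP per clade (10-15 SNPs) and no blank replicate
    could be analyzed at all.
    """
    params = replace(params or SimParams(), recombination="none")
    caller = caller or CallerConfig()
    asc = asc or AscertainmentConfig(scheme="all")
    if min_snps is None:
        min_snps = max(caller.grains)
    seeds = _replicate_seeds(base_seed, n_replicates, stream=1)
    counts: List[int] = []
    attempts = 0
    while len(counts) < n_replicates:
        seed = next(seeds)
        attempts += 1
        if attempts > 20 * n_replicates:
            raise RuntimeError("too many replicates rejected by the SNP filter")
        ds = simulate_dataset(params.with_seed(seed))
        haps = ascertain(ds.haplotypes, asc)
        if haps.n_snps <= min_snps:
            continue
        res = RecombinationScan(
            haps,
            grains=caller.grains,
            directions=caller.directions,
            threshold=caller.threshold,
            threshold_frac=caller.threshold_frac,
            mergepats=caller.mergepats,
        ).fit()
        counts.append(res.n_events)
    return counts


def permuted_truth_control(calib: CalibrationResult,
                           permutation_seed: int = 0) -> List[EvaluationReport]:
    """Score every replicate's detections against another replicate's truth."""
    return random_control(
        [r.events for r in calib.replicates],
        [r.all_truth for r in calib.replicates],
        [r.positions for r in calib.replicates],
        kept_by_replicate=[r.kept_truth for r in calib.replicates],
        permutation_seed=permutation_seed,
    )


def age_binned_sensitivity(calib: CalibrationResult,
                           bin_width: float = 500.0,
                           n_bins: int = 12) -> List[Optional[float]]:
    """Mean per-replicate sensitivity in ``bin_width``-generation age bins.

    Bin b covers ages [b*width, (b+1)*width); replicates with no surviving
    true event in a bin do not contribute to that bin's mean.
    """
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for rep in calib.replicates:
        per_bin_truth = np.zeros(n_bins, dtype=int)
        per_bin_hit = np.zeros(n_bins, dtype=int)
        for t in rep.kept_truth:
            b = int(t.age // bin_width)
            if b >= n_bins:
                continue
            per_bin_truth[b] += 1
            if id(t) in rep.matched_kept_ids:
                per_bin_hit[b] += 1
        for b in range(n_bins):
            if per_bin_truth[b] > 0:
                sums[b] += 100.0 * per_bin_hit[b] / per_bin_truth[b]
                counts[b] += 1
    return [
        float(sums[b] / counts[b]) if counts[b] else None for b in range(n_bins)
    ]


def splice_detection_frequencies(
    haps: HaplotypeMatrix,
    breakpoints: Sequence[int],
    n_replicates: int = 20,
    modes: Sequence[str] = ("random", "one_diff", "two_diff", "unique"),
    caller: Optional[CallerConfig] = None,
    seed: int = 0,
) -> Dict[str, float]:
    """In-silico splice experiment: detection frequency per parental mode.

    For each breakpoint position and replicate, two parents are drawn
    under the mode's constraint, their splice is appended to the dataset
    and the detector is run; a positive detection requires the spliced
    sequence to be called as a unique recombinant with the true breakpoint
    inside the threshold interval. Returns the fraction of positive
    detections per mode.
    """
    caller = caller or CallerConfig()
    rng = np.random.default_rng(seed)
    freqs: Dict[str, float] = {}
    for mode in modes:
        hits = 0
        total = 0
        for b in breakpoints:
            for _ in range(n_replicates):
                pair = select_parents(haps, b, mode, rng)
                if pair is None:
                    continue
                total += 1
                spliced = splice_recombinant(haps, pair[0], pair[1], b,
                                             new_id="insilico")
                res = RecombinationScan(
                    spliced,
                    grains=caller.grains,
                    directions=caller.directions,
                    threshold=caller.threshold,
                    threshold_frac=caller.threshold_frac,
                    mergepats=caller.mergepats,
                ).fit()
                new_row = spliced.n_sequences - 1
                for ev in res.events:
                    if ev.rows == {new_row}:
                        ta, tb = ev.threshold_interval
                        # splice slot b-0.5 inside the threshold interval
                        if ta <= b <= tb:
                            hits += 1
                            break
        freqs[mode] = hits / total if total else float("nan")
    return freqs
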