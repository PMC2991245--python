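"""Model/Results interface over the detection pipeline.

:class:`RecombinationScan` bundles a haplotype matrix with the caller
configuration; :meth:`RecombinationScan.fit` executes every run, aggregates
the detections and returns a :class:`ScanResults` carrying the called
events, the recotype matrix, per-event confidence (peak detection counts
out of the total number of runs) and the raw run log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import aggregate as agg
from .aggregate import CallerConfig, RecombinationEvent
from .genealogy import DetectionRecord
from .io import HaplotypeMatrix, PopulationMap, RecotypeMatrix, write_results

__all__ = ["RecombinationScan", "ScanResults"]


class RecombinationScan:
    """Detector for historical recombination events in phased haplotypes.

    Parameters
    ----------
    haplotypes : HaplotypeMatrix
        Phased input sequences.
    grains : sequence of int
        Grain sizes to combine (default the calibrated 20/10/5).
    directions : {"forward", "reverse", "both"}
    threshold : int, optional
        Absolute detection-count threshold T (default 42).
    threshold_frac : float, optional
        Alternative to ``threshold``: fraction of total runs.
    mergepats : bool
        Merge Hamming-distance-1 patterns (robustness to genotyping error
        and recurrent mutation).
    pairing : PopulationMap, optional
        Diploid pairing used for the phasing-artifact post-filter.
    """

    def __init__(self, haplotypes: HaplotypeMatrix,
                 grains: Sequence[int] = (20, 10, 5),
                 directions: str = "both",
                 threshold: Optional[int] = 42,
                 threshold_frac: Optional[float] = None,
                 mergepats: bool = False,
                 pairing: Optional[PopulationMap] = None):
        if threshold_frac is not None:
            threshold = None
        self.haplotypes = haplotypes
        self.config = CallerConfig(
            grains=tuple(grains), directions=directions, threshold=threshold,
            threshold_frac=threshold_frac, mergepats=mergepats,
        )
        self.pairing = pairing

    @classmethod
    def from_files(cls, haplotype_path: str, format: Optional[str] = None,
                   pairing_path: Optional[str] = None, **kwargs) -> "RecombinationScan":
        from .io import read_haplotypes

        haps = read_haplotypes(haplotype_path, format)
        pairing = PopulationMap.read(pairing_path) if pairing_path else None
        return cls(haps, pairing=pairing, **kwargs)

    def fit(self, filter_phasing: Optional[bool] = None) -> "ScanResults":
        """Run all (grain, offset, direction) passes and call events.

        ``filter_phasing`` defaults to True when a pairing map is present.
        """
        log: List[Tuple[int, int, str]] = []
        records = agg.run_all(self.haplotypes, self.config, log=log)
        events = agg.call_from_records(records, self.haplotypes, self.config)
        removed: List[RecombinationEvent] = []
        if filter_phasing is None:
            filter_phasing = self.pairing is not None and bool(self.pairing.pairs)
        if filter_phasing:
            events, removed = agg.filter_phasing_artifacts(
                events, self.haplotypes, self.pairing
            )
        return ScanResults(
            model=self,
            records=records,
            events=events,
            removed_events=removed,
            run_log=log,
        )


@dataclass
class ScanResults:
    """Called recombination events, recotypes and diagnostics for one scan."""

    model: RecombinationScan
    records: List[DetectionRecord]
    events: List[RecombinationEvent]
    removed_events: List[RecombinationEvent]
    run_log: List[Tuple[int, int, str]]
    _recotypes: Optional[RecotypeMatrix] = field(default=None, repr=False)

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def config(self) -> CallerConfig:
        return self.model.config

    @property
    def recotypes(self) -> RecotypeMatrix:
        if self._recotypes is None:
            self._recotypes = agg.build_recotypes(self.events, self.model.haplotypes)
        return self._recotypes

    def events_frame(self) -> pd.DataFrame:
        """Events as a DataFrame (one row per called event)."""
        haps = self.model.haplotypes
        rows = []
        for j, ev in enumerate(
            sorted(self.events, key=lambda e: (e.breakpoint, sorted(e.rows)))
        ):
            lo = int(np.floor(ev.breakpoint))
            hi = int(np.ceil(ev.breakpoint))
            bp = (haps.positions[lo] + haps.positions[hi]) / 2.0
            rows.append(
                {
                    "event_id": f"R{j + 1}",
                    "breakpoint_snp": ev.breakpoint,
                    "breakpoint_bp": bp,
                    "threshold_start": ev.threshold_interval[0],
                    "threshold_end": ev.threshold_interval[1],
                    "peak_count": ev.peak_count,
                    "n_recombinants": len(ev.rows),
                    "recombinants": ",".join(
                        haps.sequence_ids[r] for r in sorted(ev.rows)
                    ),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "event_id", "breakpoint_snp", "breakpoint_bp", "threshold_start",
                "threshold_end", "peak_count", "n_recombinants", "recombinants",
            ],
        )

    def summary(self) -> str:
        cfg = self.config
        haps = self.model.haplotypes
        lines = [
            "Recombination scan results",
            "==========================",
            f"sequences: {haps.n_sequences}    SNPs: {haps.n_snps}",
            f"grains: {','.join(str(g) for g in cfg.grains)}  "
            f"directions: {cfg.directions}  runs: {cfg.total_runs}",
            f"threshold: {cfg.resolved_threshold} detections "
            f"({cfg.resolved_threshold / cfg.total_runs:.0%} of runs)"
            + ("  [mergepats]" if cfg.mergepats else ""),
            f"raw detections: {len(self.records)}",
            f"called events: {self.n_events}"
            + (
                f"  (phasing filter removed {len(self.removed_events)})"
                if self.removed_events
                else ""
            ),
            "",
        ]
        df = self.events_frame()
        if len(df):
            lines.append(
                df.drop(columns=["recombinants"]).to_string(index=False)
            )
        else:
            lines.append("no events above threshold")
        return "\n".join(lines)

    def save(self, out_prefix: str) -> Dict[str, str]:
        """Write recotypes/events/BED files; see :func:`recombscan.io.write_results`."""
        peaks = [
            ev.peak_count
            for ev in sorted(self.events, key=lambda e: (e.breakpoint, sorted(e.rows)))
        ]
        return write_results(
            self.recotypes, self.model.haplotypes, out_prefix, peak_counts=peaks
        )
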