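"""Population-genetic summaries over recotypes.

Once recombination events are recoded as binary allelic states per
sequence (recotypes), they can be analysed like any other marker:
*recombination diversity* applies the nucleotide-diversity formula (mean
pairwise difference per column) to the binary matrix; the
*recombinational distance* between two populations summarizes how many
detected events they share; and the ordination input matrix (populations
by carrier proportions) feeds a standard PCA or MDS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import PopulationMap, RecotypeMatrix

__all__ = [
    "DistanceMatrix",
    "recombination_diversity",
    "recombination_distance",
    "ordination_input",
]


@dataclass
class DistanceMatrix:
    """Pairwise recombinational distances with sharing bookkeeping.

    ``r_counts[p]`` is the number of qualifying events present in
    population p; ``shared[(p, q)]`` the number present in both.
    """

    populations: List[str]
    values: np.ndarray
    r_counts: Dict[str, int]
    shared: Dict[Tuple[str, str], int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.populations,
                            columns=self.populations)


def recombination_diversity(recotypes: RecotypeMatrix,
                            group: Sequence[str],
                            corrected: bool = False) -> float:
    """Mean pairwise recotype difference per event column within ``group``.

    The binary analogue of nucleotide diversity: average over all sequence
    pairs of the fraction of event columns at which they differ.
    ``corrected=True`` applies the n/(n-1) sample-size correction.
    Zero events gives 0 by convention.
    """
    idx = [recotypes.sequence_ids.index(s) for s in group]
    if len(idx) < 2:
        raise ValueError("need at least two sequences")
    if recotypes.n_events == 0:
        return 0.0
    sub = recotypes.matrix[idx].astype(float)
    n = len(idx)
    freq = sub.mean(axis=0)
    # mean pairwise difference per column: n1*n0 / C(n,2) = 2p(1-p) n/(n-1)
    pairwise_mean = 2.0 * freq * (1.0 - freq) * n / (n - 1)
    div = float(pairwise_mean.mean())
    if corrected:
        div *= n / (n - 1)
    return div


def _presence_by_population(recotypes: RecotypeMatrix,
                            popmap: PopulationMap) -> Tuple[List[str], np.ndarray]:
    pops = sorted({popmap.populations[s] for s in recotypes.sequence_ids
                   if s in popmap.populations})
    presence = np.zeros((len(pops), recotypes.n_events), dtype=bool)
    for i, sid in enumerate(recotypes.sequence_ids):
        pop = popmap.populations.get(sid)
        if pop is None:
            continue
        presence[pops.index(pop)] |= recotypes.matrix[i].astype(bool)
    return pops, presence


def recombination_distance(recotypes: RecotypeMatrix, popmap: PopulationMap,
                           form: str = "dice") -> DistanceMatrix:
    """Pairwise D_AB from event sharing between populations.

    Only events present in at least two populations are considered. With
    R_A and R_B the qualifying-event counts per population and R_AB the
    number shared, the default (Dice-complement) form is
    ``D_AB = 1 - 2 R_AB / (R_A + R_B)``; ``form="jaccard"`` uses
    ``1 - R_AB / (R_A + R_B - R_AB)``. A population with no qualifying
    events is at distance 1 from everything (with a warning).
    """
    if form not in ("dice", "jaccard"):
        raise ValueError("form must be 'dice' or 'jaccard'")
    pops, presence = _presence_by_population(recotypes, popmap)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    qualifying = presence.sum(axis=0) >= 2
    pres = presence[:, qualifying]
    r_counts = {p: int(pres[i].sum()) for i, p in enumerate(pops)}
    for p, c in r_counts.items():
        if c == 0:
            warnings.warn(f"population {p!r} has no event shared with others")
    n = len(pops)
    values = np.zeros((n, n))
    shared: Dict[Tuple[str, str], int] = {}
    for i in range(n):
        for j in range(i + 1, n):
            r_ab = int((pres[i] & pres[j]).sum())
            shared[(pops[i], pops[j])] = r_ab
            ra, rb = r_counts[pops[i]], r_counts[pops[j]]
            if ra + rb == 0:
                d = 1.0
            elif form == "dice":
                d = 1.0 - 2.0 * r_ab / (ra + rb)
            else:
                union = ra + rb - r_ab
                d = 1.0 - (r_ab / union if union else 0.0)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(pops, values, r_counts, shared)


def ordination_input(recotypes: RecotypeMatrix, popmap: PopulationMap,
                     min_carriers: int = 2) -> pd.DataFrame:
    """Population-by-event carrier-proportion matrix for PCA/MDS.

    Events carried by fewer than ``min_carriers`` chromosomes overall are
    excluded; entries are the proportion of each population's chromosomes
    carrying the event. Use the correlation matrix of the result for PCA
    (the values are not normalized).
    """
    if min_carriers < 1:
        raise ValueError("min_carriers must be >= 1")
    pops = sorted({popmap.populations[s] for s in recotypes.sequence_ids
                   if s in popmap.populations})
    qualifying = np.flatnonzero(recotypes.matrix.sum(axis=0) >= min_carriers)
    data = np.zeros((len(pops), len(qualifying)))
    sizes = {p: 0 for p in pops}
    for sid in recotypes.sequence_ids:
        p = popmap.populations.get(sid)
        if p is not None:
            sizes[p] += 1
    for i, sid in enumerate(recotypes.sequence_ids):
        p = popmap.populations.get(sid)
        if p is None:
            continue
        data[pops.index(p)] += recotypes.matrix[i, qualifying]
    for k, p in enumerate(pops):
        if sizes[p]:
            data[k] /= sizes[p]
    return pd.DataFrame(
        data, index=pops,
        columns=[recotypes.event_ids[j] for j in qualifying],
    )
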