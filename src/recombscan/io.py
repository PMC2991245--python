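"""Data model and readers/writers for phased haplotypes and detection results.

The universal input is a :class:`HaplotypeMatrix`: one row per phased
chromosome, one column per SNP, alleles coded as small non-negative
integers, with strictly increasing physical positions. Haplotypes are read
either from a simple tab-separated dialect or from a fully phased VCF
(each diploid sample is expanded into two haplotype rows).

Missing or unphased genotypes are rejected outright: the detector works on
pattern identity, and imputation belongs upstream.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "HaplotypeMatrix",
    "PopulationMap",
    "RecotypeMatrix",
    "read_haplotypes",
    "write_haplotypes",
    "read_recotypes",
    "write_results",
]


@dataclass
class HaplotypeMatrix:
    """Phased haplotype alleles with per-SNP physical positions.

    Parameters
    ----------
    alleles : ndarray of int, shape (n_sequences, n_snps)
        Allele codes, all >= 0.
    positions : ndarray of float, shape (n_snps,)
        Physical coordinates in bp, strictly increasing.
    sequence_ids : list of str
        Unique row labels.
    snp_ids : list of str
        Unique column labels.
    """

    alleles: np.ndarray
    positions: np.ndarray
    sequence_ids: List[str]
    snp_ids: List[str]

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        n_seq, n_snp = self.alleles.shape
        if n_seq < 2 or n_snp < 1:
            raise ValueError("need at least 2 sequences and 1 SNP")
        if len(self.positions) != n_snp:
            raise ValueError("positions length must equal number of SNPs")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.alleles < 0):
            raise ValueError("missing or negative allele codes are not allowed")
        if len(self.sequence_ids) != n_seq or len(set(self.sequence_ids)) != n_seq:
            raise ValueError("sequence_ids must be unique, one per row")
        if len(self.snp_ids) != n_snp or len(set(self.snp_ids)) != n_snp:
            raise ValueError("snp_ids must be unique, one per SNP")

    @property
    def n_sequences(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    def take_snps(self, index: np.ndarray) -> "HaplotypeMatrix":
        """Return a copy restricted to the SNP columns in ``index`` (kept in order)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        if np.any(np.diff(index) <= 0):
            raise ValueError("SNP subset must preserve order")
        return HaplotypeMatrix(
            alleles=self.alleles[:, index].copy(),
            positions=self.positions[index].copy(),
            sequence_ids=list(self.sequence_ids),
            snp_ids=[self.snp_ids[i] for i in index],
        )

    def row_index(self, sequence_id: str) -> int:
        return self.sequence_ids.index(sequence_id)


@dataclass
class PopulationMap:
    """Sequence-to-population assignment, plus optional diploid pairing.

    ``pairs`` maps an individual id to the two haplotype row ids forming it;
    it drives the phasing-artifact post-filter.
    """

    populations: Dict[str, str] = field(default_factory=dict)
    pairs: Dict[str, Tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set = set()
        for ind, (a, b) in self.pairs.items():
            if a == b:
                raise ValueError(f"individual {ind!r} pairs a haplotype with itself")
            if a in seen or b in seen:
                raise ValueError("haplotype pairing must be disjoint")
            seen.add(a)
            seen.add(b)

    def validate_against(self, haps: HaplotypeMatrix) -> None:
        ids = set(haps.sequence_ids)
        for sid in self.populations:
            if sid not in ids:
                raise ValueError(f"population map references unknown sequence {sid!r}")
        for ind, (a, b) in self.pairs.items():
            if a not in ids or b not in ids:
                raise ValueError(f"pairing for {ind!r} references unknown sequence")

    @classmethod
    def read(cls, path: str) -> "PopulationMap":
        """Read a TSV of ``sequence_id <tab> population [<tab> individual_id]``."""
        pops: Dict[str, str] = {}
        halves: Dict[str, List[str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                pops[parts[0]] = parts[1]
                if len(parts) > 2 and parts[2]:
                    halves.setdefault(parts[2], []).append(parts[0])
        pairs = {}
        for ind, members in halves.items():
            if len(members) != 2:
                raise ValueError(f"individual {ind!r} must have exactly two haplotypes")
            pairs[ind] = (members[0], members[1])
        return cls(populations=pops, pairs=pairs)


@dataclass
class RecotypeMatrix:
    """Binary presence/absence of each called recombination event per sequence."""

    matrix: np.ndarray  # (n_sequences, n_events) of 0/1
    sequence_ids: List[str]
    event_ids: List[str]
    breakpoints: np.ndarray  # SNP coordinate per event, half-integers allowed
    threshold_intervals: List[Tuple[int, int]]  # SNP index [start, end) per event

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        n_seq, n_ev = self.matrix.shape
        if len(self.sequence_ids) != n_seq:
            raise ValueError("sequence_ids mismatch")
        if len(self.event_ids) != n_ev or len(self.breakpoints) != n_ev:
            raise ValueError("event metadata mismatch")
        if len(self.threshold_intervals) != n_ev:
            raise ValueError("threshold_intervals mismatch")
        if n_ev and not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("recotype entries must be 0/1")
        if n_ev and (self.matrix.sum(axis=0) < 1).any():
            raise ValueError("every event column needs at least one carrier")

    @property
    def n_events(self) -> int:
        return self.matrix.shape[1]


# ---------------------------------------------------------------------------
# TSV haplotype dialect
# ---------------------------------------------------------------------------
#
#   # optional comment lines
#   snp_id      <tab> rs1  <tab> rs2  ...
#   position    <tab> 1000 <tab> 2000 ...
#   sequence_1  <tab> 0    <tab> 1    ...
#   ...


def write_haplotypes(haps: HaplotypeMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\t" + "\t".join(haps.snp_ids) + "\n")
        pos = [
            str(int(p)) if float(p).is_integer() else repr(float(p))
            for p in haps.positions
        ]
        fh.write("position\t" + "\t".join(pos) + "\n")
        for sid, row in zip(haps.sequence_ids, haps.alleles):
            fh.write(sid + "\t" + "\t".join(str(int(a)) for a in row) + "\n")


def _read_haplotypes_tsv(path: str) -> HaplotypeMatrix:
    rows: List[List[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rows.append(line.split("\t"))
    if len(rows) < 4:
        raise ValueError("TSV needs a SNP-id row, a position row and >= 2 haplotypes")
    snp_ids = rows[0][1:]
    positions = np.array([float(x) for x in rows[1][1:]])
    sequence_ids = [r[0] for r in rows[2:]]
    try:
        alleles = np.array([[int(x) for x in r[1:]] for r in rows[2:]], dtype=np.int16)
    except ValueError as exc:
        raise ValueError(f"non-integer or missing allele in {path}: {exc}") from exc
    return HaplotypeMatrix(alleles, positions, sequence_ids, snp_ids)


def _read_haplotypes_vcf(path: str) -> HaplotypeMatrix:
    import pysam

    vf = pysam.VariantFile(path)
    samples = list(vf.header.samples)
    snp_ids: List[str] = []
    positions: List[float] = []
    columns: List[List[int]] = []
    ploidies: Optional[List[int]] = None
    for rec in vf:
        alleles_here: List[int] = []
        ploidies_here: List[int] = []
        for s in samples:
            call = rec.samples[s]
            gt = call["GT"]
            if gt is None or any(a is None for a in gt):
                raise ValueError(
                    f"missing genotype for sample {s} at {rec.chrom}:{rec.pos}"
                )
            if len(gt) > 1 and not call.phased:
                raise ValueError(
                    f"unphased genotype for sample {s} at {rec.chrom}:{rec.pos}"
                )
            alleles_here.extend(int(a) for a in gt)
            ploidies_here.append(len(gt))
        if ploidies is None:
            ploidies = ploidies_here
        elif ploidies != ploidies_here:
            raise ValueError("inconsistent ploidy across records")
        snp_ids.append(rec.id if rec.id else f"{rec.chrom}:{rec.pos}")
        positions.append(float(rec.pos))
        columns.append(alleles_here)
    if not columns:
        raise ValueError(f"no variant records in {path}")
    assert ploidies is not None
    sequence_ids = []
    for s, k in zip(samples, ploidies):
        if k == 1:
            sequence_ids.append(s)
        else:
            sequence_ids.extend(f"{s}|{i}" for i in range(k))
    alleles = np.array(columns, dtype=np.int16).T
    return HaplotypeMatrix(alleles, np.array(positions), sequence_ids, snp_ids)


def read_haplotypes(path: str, format: Optional[str] = None) -> HaplotypeMatrix:
    """Read phased haplotypes from TSV or phased VCF.

    ``format`` is ``"tsv"`` or ``"vcf"``; guessed from the extension when
    omitted. VCF samples are expanded to one row per haplotype
    (``sample|0``, ``sample|1``); haploid samples yield a single row named
    after the sample.
    """
    if format is None:
        format = "vcf" if path.endswith((".vcf", ".vcf.gz", ".bcf")) else "tsv"
    if format == "tsv":
        return _read_haplotypes_tsv(path)
    if format == "vcf":
        return _read_haplotypes_vcf(path)
    raise ValueError(f"unknown haplotype format {format!r}")


# ---------------------------------------------------------------------------
# Result writers
# ---------------------------------------------------------------------------


def _breakpoint_bp(haps: HaplotypeMatrix, coord: float) -> float:
    """Interpolate a SNP-space breakpoint coordinate to bp.

    Integer coordinates map to the SNP's own position; half-integers map to
    the midpoint of the flanking SNP positions.
    """
    lo = int(np.floor(coord))
    hi = int(np.ceil(coord))
    lo = min(max(lo, 0), haps.n_snps - 1)
    hi = min(max(hi, 0), haps.n_snps - 1)
    return float((haps.positions[lo] + haps.positions[hi]) / 2.0)


def write_results(recotypes: RecotypeMatrix, haps: HaplotypeMatrix, out_prefix: str,
                  peak_counts: Optional[Sequence[int]] = None) -> Dict[str, str]:
    """Write recotypes TSV, events TSV, and a BED of threshold intervals.

    Returns the mapping of artifact name to file path. The BED uses the
    flanking-SNP convention: a threshold interval covering SNP indices
    ``[a, b)`` spans ``[positions[a], positions[b-1])`` in bp, 0-based
    half-open.
    """
    paths = {
        "recotypes": f"{out_prefix}.recotypes.tsv",
        "events": f"{out_prefix}.events.tsv",
        "bed": f"{out_prefix}.intervals.bed",
    }
    os.makedirs(os.path.dirname(os.path.abspath(out_prefix)), exist_ok=True)

    with open(paths["recotypes"], "w") as fh:
        fh.write("sequence_id\t" + "\t".join(recotypes.event_ids) + "\n")
        fh.write(
            "breakpoint\t"
            + "\t".join(repr(float(b)) for b in recotypes.breakpoints)
            + "\n"
        )
        for sid, row in zip(recotypes.sequence_ids, recotypes.matrix):
            fh.write(sid + "\t" + "\t".join(str(int(x)) for x in row) + "\n")

    with open(paths["events"], "w") as fh:
        fh.write(
            "event_id\tbreakpoint_snp\tbreakpoint_bp\t"
            "threshold_start\tthreshold_end\tpeak_count\tn_recombinants\n"
        )
        for j, eid in enumerate(recotypes.event_ids):
            a, b = recotypes.threshold_intervals[j]
            if not (0 <= a < b <= haps.n_snps):
                raise ValueError(f"threshold interval {a, b} outside SNP range")
            peak = "" if peak_counts is None else str(int(peak_counts[j]))
            fh.write(
                f"{eid}\t{recotypes.breakpoints[j]!r}\t"
                f"{_breakpoint_bp(haps, recotypes.breakpoints[j])!r}\t"
                f"{a}\t{b}\t{peak}\t{int(recotypes.matrix[:, j].sum())}\n"
            )

    with open(paths["bed"], "w") as fh:
        for j, eid in enumerate(recotypes.event_ids):
            a, b = recotypes.threshold_intervals[j]
            start = int(haps.positions[a])
            end = int(haps.positions[b - 1])
            if end <= start:
                end = start + 1
            fh.write(f"region\t{start}\t{end}\t{eid}\t{int(recotypes.matrix[:, j].sum())}\t+\n")
    return paths


def read_recotypes(path: str) -> RecotypeMatrix:
    """Read back a recotypes TSV written by :func:`write_results`."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    event_ids = header[1:]
    bkp_row = lines[1].split("\t")
    breakpoints = np.array([float(x) for x in bkp_row[1:]])
    sequence_ids = []
    rows = []
    for ln in lines[2:]:
        parts = ln.split("\t")
        sequence_ids.append(parts[0])
        rows.append([int(x) for x in parts[1:]])
    matrix = np.array(rows, dtype=np.int8).reshape(len(sequence_ids), len(event_ids))
    # threshold intervals are not stored in the recotype file; re-read from the
    # events TSV when needed.  Use trivial one-SNP stubs here.
    stubs = [(int(np.floor(b)), int(np.floor(b)) + 1) for b in breakpoints]
    return RecotypeMatrix(matrix, sequence_ids, event_ids, breakpoints, stubs)
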