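"""Coalescent calibration datasets with recorded recombination ground truth.

The generator emulates the calibration conditions: 250 kb regions sampled
from four human-like populations (African n=60, European, East Asian and
admixed African-American n=50 each) under an out-of-Africa-style
demography, with a variable recombination map (regional rate variation
plus discrete hotspots) and finite-sites mutation. Every recombination
event in the sample history is recorded as a :class:`TrueEvent` with its
descendant leaf set, age in generations and breakpoint position, extracted
from the simulator's full ancestral recombination graph.

The demographic parameters follow the published best-fit calibrated human
model commonly used for this kind of benchmark (constant-size epochs,
bottlenecks expressed as inbreeding coefficients, agriculture-era
expansions, low continental migration, recent 80/20 African/European
admixture); exact values are package defaults documented in the methods
note, not measurements.

SNP ascertainment (MAF floor plus greedy pairwise tag-SNP selection at an
r-squared cutoff) reproduces the kind of data found in genotyping panels.
In-silico helpers splice recombinant haplotypes and inject gene
conversion, recurrent mutation and phasing-error artifacts for the
robustness experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, FrozenSet, List, Literal, Optional, Tuple

import numpy as np

from .io import HaplotypeMatrix, PopulationMap

__all__ = [
    "SimParams",
    "TrueEvent",
    "AscertainmentConfig",
    "SimulatedDataset",
    "human_demography",
    "single_population_demography",
    "build_rate_map",
    "simulate_dataset",
    "ascertain",
    "splice_recombinant",
    "select_parents",
    "inject_artifact",
]

GENERATION_YEARS = 20.0  # reporting conversion only; ages stay in generations


@dataclass(frozen=True)
class SimParams:
    """Parameters of one calibration replicate.

    Defaults are the study conditions: 250,000 bp, 210 haplotypes
    (AFR 60, EUR/ASN/AA 50 each), mutation 1.5e-8 /bp/gen, mean
    recombination 1.3e-8 /bp/gen with regional variation and hotspots.
    ``recombination="none"`` produces blank (recombination-free) controls.
    """

    length: int = 250_000
    sample_sizes: Tuple[Tuple[str, int], ...] = (
        ("AFR", 60), ("EUR", 50), ("ASN", 50), ("AA", 50),
    )
    demography: Literal["human_4pop", "single_pop"] = "human_4pop"
    mutation_rate: float = 1.5e-8
    recombination: Literal["variable", "uniform", "none"] = "variable"
    mean_recombination_rate: float = 1.3e-8
    regional_sigma: float = 0.6  # lognormal sd of the regional rate factor
    hotspot_spacing: float = 9_000.0  # mean bp between hotspot centres
    hotspot_width: float = 1_500.0
    hotspot_fraction: float = 0.75  # share of map length inside hotspots
    single_pop_size: float = 12_500.0
    seed: int = 1

    def with_seed(self, seed: int) -> "SimParams":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class TrueEvent:
    """One historical recombination event from the simulated genealogy.

    ``descendants`` are the extant haplotype rows inheriting the junction
    (leaves below the recombinant lineage in the marginal tree at the
    breakpoint). ``left_context`` / ``right_context`` are the nearest
    extant relatives of the two parental lineages on their respective
    sides; they drive the undetectable-event pruning.
    """

    descendants: FrozenSet[int]
    age: float  # generations before present
    breakpoint: float  # bp
    left_context: FrozenSet[int] = frozenset()
    right_context: FrozenSet[int] = frozenset()


@dataclass(frozen=True)
class AscertainmentConfig:
    """SNP filtering: MAF floor then a selection scheme."""

    maf_floor: float = 0.1
    scheme: Literal["all", "density", "tag_pairwise", "tag_aggressive"] = "tag_pairwise"
    r2_cutoff: float = 0.8
    density_bp: float = 2_000.0

    def __post_init__(self) -> None:
        if not (0 <= self.maf_floor < 0.5):
            raise ValueError("MAF floor must be in [0, 0.5)")
        if not (0 < self.r2_cutoff <= 1):
            raise ValueError("r2 cutoff must be in (0, 1]")


@dataclass
class SimulatedDataset:
    """A replicate: haplotypes, ground-truth events and bookkeeping."""

    haplotypes: HaplotypeMatrix
    true_events: List[TrueEvent]
    params: SimParams
    popmap: PopulationMap
    rate_map: Optional[object] = None  # msprime.RateMap
    n_raw_snps: int = 0
    site_times: Optional[np.ndarray] = None  # oldest mutation age per SNP (gen)
    n_arg_recombinations: int = 0  # all ARG recombination events (incl. trapped)

    @property
    def enough_snps(self) -> bool:
        """Replicate-retention flag: more than 80 segregating sites."""
        return self.haplotypes.n_snps > 80

    def __iter__(self):  # allow (haps, truth) unpacking
        yield self.haplotypes
        yield self.true_events


# ---------------------------------------------------------------------------
# demography
# ---------------------------------------------------------------------------


def _bottleneck_strength(n_e: float, inbreeding: float) -> float:
    """Instantaneous-bottleneck strength giving pair-coalescence prob F."""
    return -2.0 * n_e * math.log(1.0 - inbreeding)


def human_demography():
    """Four-population human model: AFR, EUR, ASN and admixed AA.

    Constant-size epochs: present-day sizes 100,000 shrinking to 24,000
    (AFR, 200 gen) and 7,700 (EUR 350 gen, ASN 400 gen); population
    bottlenecks ~2,000 generations ago (inbreeding coefficients 0.008 AFR,
    0.02 EUR, 0.067 ASN), ASN/EUR split 2,000 gen, out-of-Africa split
    3,500 gen with a 0.085 bottleneck, ancestral size 12,500 beyond 17,000
    gen. AA is an 80/20 African/European admixture 7 generations ago.
    Migration AFR-EUR 3.2e-5 and AFR-ASN 0.8e-5 per generation until the
    splits.
    """
    import msprime

    dem = msprime.Demography()
    dem.add_population(name="AFR", initial_size=100_000)
    dem.add_population(name="EUR", initial_size=100_000)
    dem.add_population(name="ASN", initial_size=100_000)
    dem.add_population(name="AA", initial_size=100_000)
    dem.set_symmetric_migration_rate(["AFR", "EUR"], 3.2e-5)
    dem.set_symmetric_migration_rate(["AFR", "ASN"], 0.8e-5)
    # recent admixture: backward in time AA sends 20% to EUR, rest to AFR
    dem.add_mass_migration(time=7, source="AA", dest="EUR", proportion=0.2)
    dem.add_mass_migration(time=7.01, source="AA", dest="AFR", proportion=1.0)
    # agriculture-era expansions (sizes before, looking backward)
    dem.add_population_parameters_change(time=200, population="AFR", initial_size=24_000)
    dem.add_population_parameters_change(time=350, population="EUR", initial_size=7_700)
    dem.add_population_parameters_change(time=400, population="ASN", initial_size=7_700)
    # founder bottlenecks
    dem.add_instantaneous_bottleneck(
        time=1_997, population="AFR", strength=_bottleneck_strength(24_000, 0.008))
    dem.add_instantaneous_bottleneck(
        time=1_998, population="ASN", strength=_bottleneck_strength(7_700, 0.067))
    dem.add_instantaneous_bottleneck(
        time=1_999, population="EUR", strength=_bottleneck_strength(7_700, 0.02))
    # Asian/European split, migration off beyond it
    dem.add_mass_migration(time=2_000, source="ASN", dest="EUR", proportion=1.0)
    dem.add_migration_rate_change(time=2_000, rate=0.0)
    # out of Africa
    dem.add_instantaneous_bottleneck(
        time=3_499, population="EUR", strength=_bottleneck_strength(7_700, 0.085))
    dem.add_mass_migration(time=3_500, source="EUR", dest="AFR", proportion=1.0)
    dem.add_population_parameters_change(time=17_000, population="AFR",
                                         initial_size=12_500)
    dem.sort_events()
    return dem


def single_population_demography(size: float = 12_500.0):
    """Constant-size single population (analytic-check control)."""
    import msprime

    dem = msprime.Demography()
    dem.add_population(name="POP", initial_size=size)
    return dem


# ---------------------------------------------------------------------------
# recombination maps
# ---------------------------------------------------------------------------


def build_rate_map(params: SimParams, rng: np.random.Generator):
    """Variable recombination map: regional factor plus discrete hotspots.

    The region-wide mean rate is drawn lognormally around
    ``mean_recombination_rate``; ``hotspot_fraction`` of the total map
    length is concentrated in hotspots of ``hotspot_width`` bp placed with
    exponential spacing, with exponentially distributed relative
    intensities. Built at 100 bp resolution.
    """
    import msprime

    L = params.length
    if params.recombination == "none":
        return msprime.RateMap(position=[0, L], rate=[0.0])
    if params.recombination == "uniform":
        return msprime.RateMap(position=[0, L],
                               rate=[params.mean_recombination_rate])
    sigma = params.regional_sigma
    regional = params.mean_recombination_rate * rng.lognormal(-0.5 * sigma ** 2, sigma)
    total = regional * L  # expected map length (Morgans-like units)
    n_hs = rng.poisson(L / params.hotspot_spacing)
    res = 100
    n_bins = L // res
    rates = np.full(n_bins, total * (1.0 - params.hotspot_fraction) / L if n_hs else total / L)
    if n_hs:
        centres = rng.uniform(0, L, size=n_hs)
        weights = rng.exponential(1.0, size=n_hs)
        weights /= weights.sum()
        hot_total = total * params.hotspot_fraction
        half = params.hotspot_width / 2.0
        for c, w in zip(centres, weights):
            a = int(max(0, (c - half) // res))
            b = int(min(n_bins, math.ceil((c + half) / res)))
            if b > a:
                rates[a:b] += hot_total * w / ((b - a) * res)
    position = np.arange(n_bins + 1, dtype=float) * res
    position[-1] = L
    return msprime.RateMap(position=position, rate=rates)


# ---------------------------------------------------------------------------
# simulation and ground-truth extraction
# ---------------------------------------------------------------------------


def _sequence_ids(params: SimParams) -> List[str]:
    ids = []
    for pop, n in params.sample_sizes:
        ids.extend(f"{pop}_{i:03d}" for i in range(n))
    return ids


def _extract_true_events(ts) -> Tuple[List[TrueEvent], int]:
    """Recombination events from the full-ARG node table.

    Each event contributes two flagged parent nodes at the same time; the
    breakpoint is where their transmitted intervals abut. Events whose
    recombinant child has no extant descendants spanning the breakpoint
    (trapped ancestral material) are dropped: they cannot leave a trace.
    Descendant sets and parental contexts are gathered in two incremental
    sweeps over the marginal trees (one for each side of the breakpoint).
    """
    import msprime

    nodes_time = ts.tables.nodes.time
    flags = ts.tables.nodes.flags
    re_nodes = np.flatnonzero(flags & msprime.NODE_IS_RE_EVENT)
    edges = ts.tables.edges
    parent_edges: Dict[int, List[Tuple[float, float, int]]] = {}
    for left, right, parent, child in zip(
        edges.left, edges.right, edges.parent, edges.child
    ):
        parent_edges.setdefault(int(parent), []).append((left, right, int(child)))
    candidates: List[Tuple[int, float, float]] = []  # (child, bkpt, age)
    used = set()
    for u in re_nodes:
        u = int(u)
        if u in used:
            continue
        v = u + 1
        if v >= ts.num_nodes or not (flags[v] & msprime.NODE_IS_RE_EVENT):
            continue
        if nodes_time[u] != nodes_time[v]:
            continue
        used.add(u)
        used.add(v)
        eu = parent_edges.get(u, [])
        ev = parent_edges.get(v, [])
        if not eu or not ev:
            continue
        child = eu[0][2]
        bkpt = min(l for (l, _, _) in ev)
        if bkpt <= 0 or bkpt >= ts.sequence_length:
            continue
        candidates.append((child, float(bkpt), float(nodes_time[u])))
    if not candidates:
        return [], 0
    n_samples = ts.num_samples
    breakpoints = ts.breakpoints(as_array=True)
    # tree index holding [bkpt, ...) and the one holding [..., bkpt)
    r_index = np.searchsorted(breakpoints, [b for (_, b, _) in candidates],
                              side="right") - 1
    l_index = np.searchsorted(breakpoints, [b for (_, b, _) in candidates],
                              side="left") - 1
    by_r: Dict[int, List[int]] = {}
    by_l: Dict[int, List[int]] = {}
    for i, (ri, li) in enumerate(zip(r_index, l_index)):
        by_r.setdefault(int(ri), []).append(i)
        by_l.setdefault(int(li), []).append(i)
    desc: List[Optional[FrozenSet[int]]] = [None] * len(candidates)
    left_ok = [False] * len(candidates)
    right_ctx: List[FrozenSet[int]] = [frozenset()] * len(candidates)
    left_ctx: List[FrozenSet[int]] = [frozenset()] * len(candidates)
    for tree in ts.trees():
        idx = tree.index
        for i in by_l.get(idx, ()):
            child = candidates[i][0]
            if tree.parent(child) == -1 and not tree.is_sample(child):
                continue  # trapped on the left side: no extant junction
            left_ok[i] = True
            d_left = _node_samples(tree, child)
            left_ctx[i] = _context_samples(tree, child, d_left)
        for i in by_r.get(idx, ()):
            child = candidates[i][0]
            if tree.parent(child) == -1 and not tree.is_sample(child):
                continue  # trapped material: no extant junction
            d = _node_samples(tree, child)
            if d and len(d) < n_samples:
                desc[i] = d
                right_ctx[i] = _context_samples(tree, child, d)
    events = [
        TrueEvent(
            descendants=desc[i],
            age=candidates[i][2],
            breakpoint=candidates[i][1],
            left_context=left_ctx[i],
            right_context=right_ctx[i],
        )
        for i in range(len(candidates))
        if desc[i] is not None and left_ok[i]
    ]
    events.sort(key=lambda e: (e.breakpoint, e.age))
    return events, len(candidates)


def _node_samples(tree, node: int) -> FrozenSet[int]:
    # msprime assigns sample ids 0..n-1; filtering the subtree node list is
    # much faster than the per-node sample generator
    sub = tree.preorder(node)
    n = tree.tree_sequence.num_samples
    return frozenset(sub[sub < n].tolist())


def _context_samples(tree, child: int, desc: FrozenSet[int]) -> FrozenSet[int]:
    """Nearest extant relatives of the lineage above ``child`` in this tree."""
    base = tree.num_samples(child)
    node = tree.parent(child)
    while node != -1 and tree.num_samples(node) == base:
        node = tree.parent(node)  # skip unary ancestors cheaply
    if node == -1:
        return frozenset()
    return _node_samples(tree, node) - desc


def simulate_dataset(params: SimParams) -> SimulatedDataset:
    """Simulate one replicate with full recombination ground truth.

    Same seed, same params — bit-identical dataset and event list.
    """
    import msprime

    rng = np.random.default_rng(params.seed)
    map_seed, anc_seed, mut_seed = (
        int(x) for x in rng.integers(1, 2 ** 31 - 1, size=3)
    )
    rate_map = build_rate_map(params, np.random.default_rng(map_seed))
    if params.mutation_rate <= 0:
        raise ValueError("mutation rate must be positive to observe SNPs")
    demography = (
        human_demography()
        if params.demography == "human_4pop"
        else single_population_demography(params.single_pop_size)
    )
    pop_names = {p.name for p in demography.populations}
    samples = []
    for pop, n in params.sample_sizes:
        target = pop if pop in pop_names else demography.populations[0].name
        samples.append(msprime.SampleSet(n, population=target, ploidy=1))
    ts = msprime.sim_ancestry(
        samples=samples,
        demography=demography,
        sequence_length=params.length,
        recombination_rate=rate_map,
        record_full_arg=True,
        random_seed=anc_seed,
    )
    mts = msprime.sim_mutations(
        ts, rate=params.mutation_rate, random_seed=mut_seed,
        model=msprime.BinaryMutationModel(),
    )
    events, n_arg_re = _extract_true_events(ts)
    geno = mts.genotype_matrix()  # (sites, samples)
    seg = geno.min(axis=1) != geno.max(axis=1)
    if not seg.any():
        raise RuntimeError("simulation produced no segregating sites")
    positions = mts.tables.sites.position[seg]
    alleles = np.ascontiguousarray(geno[seg].T.astype(np.int16))
    site_times_all = np.zeros(mts.num_sites)
    muts = mts.tables.mutations
    np.maximum.at(site_times_all, muts.site, muts.time)
    site_times = site_times_all[seg]
    seq_ids = _sequence_ids(params)
    haps = HaplotypeMatrix(
        alleles=alleles,
        positions=np.array(positions, dtype=float),
        sequence_ids=seq_ids,
        snp_ids=[f"snp{i}" for i in range(len(positions))],
    )
    pops = {}
    for sid in seq_ids:
        pops[sid] = sid.rsplit("_", 1)[0]
    return SimulatedDataset(
        haplotypes=haps,
        true_events=events,
        params=params,
        popmap=PopulationMap(populations=pops),
        rate_map=rate_map,
        n_raw_snps=len(positions),
        site_times=site_times,
        n_arg_recombinations=n_arg_re,
    )


# ---------------------------------------------------------------------------
# SNP ascertainment
# ---------------------------------------------------------------------------


def _r_squared_matrix(alleles: np.ndarray) -> np.ndarray:
    """Pairwise haplotype r^2 between biallelic SNP columns."""
    x = alleles.astype(float)
    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x /= sd
    r = (x.T @ x) / x.shape[0]
    return r ** 2


def ascertain(haps: HaplotypeMatrix, config: AscertainmentConfig) -> HaplotypeMatrix:
    """Apply the MAF floor then the configured SNP-selection scheme.

    ``tag_pairwise`` mimics a greedy pairwise tagger: repeatedly keep the
    SNP that captures the most not-yet-covered SNPs at r^2 above the
    cutoff (a SNP always captures itself), until every SNP is covered.
    ``density`` keeps the SNP closest to each point of an even grid.
    SNP order and positions are always preserved.
    """
    freqs = haps.alleles.mean(axis=0)
    maf = np.minimum(freqs, 1 - freqs)
    keep = np.flatnonzero(maf >= config.maf_floor)
    if keep.size == 0:
        raise ValueError("no SNPs survive the MAF floor")
    sub = haps.take_snps(keep)
    if config.scheme == "all":
        return sub
    if config.scheme == "density":
        grid = np.arange(sub.positions[0], sub.positions[-1] + config.density_bp,
                         config.density_bp)
        chosen = sorted({int(np.argmin(np.abs(sub.positions - g))) for g in grid})
        return sub.take_snps(np.array(chosen))
    if config.scheme not in ("tag_pairwise", "tag_aggressive"):
        raise ValueError(f"unknown ascertainment scheme {config.scheme!r}")
    r2 = _r_squared_matrix(sub.alleles)
    captures = r2 > config.r2_cutoff
    np.fill_diagonal(captures, True)
    n = sub.n_snps
    covered = np.zeros(n, dtype=bool)
    kept: List[int] = []
    while not covered.all():
        gains = (captures & ~covered[None, :]).sum(axis=1)
        pick = int(np.argmax(gains))
        kept.append(pick)
        covered |= captures[pick]
    kept = sorted(set(kept))
    if config.scheme == "tag_aggressive":
        # peel redundant tags: drop any tag whose taggees are all captured
        # by the remaining tags
        kept_set = list(kept)
        for t in sorted(kept, key=lambda i: -int(captures[i].sum())):
            rest = [k for k in kept_set if k != t]
            if rest and captures[rest].any(axis=0).all():
                kept_set = rest
        kept = sorted(kept_set)
    return sub.take_snps(np.array(kept))


# ---------------------------------------------------------------------------
# in-silico recombination and artifacts
# ---------------------------------------------------------------------------


def splice_recombinant(haps: HaplotypeMatrix, parent1: str, parent2: str,
                       breakpoint_snp: int,
                       new_id: str = "recombinant") -> HaplotypeMatrix:
    """Append parent1[:b] + parent2[b:] as a new haplotype row."""
    if parent1 == parent2:
        raise ValueError("parents must be distinct rows")
    if not (0 < breakpoint_snp < haps.n_snps):
        raise ValueError("breakpoint must be strictly inside the SNP range")
    i1, i2 = haps.row_index(parent1), haps.row_index(parent2)
    new_row = np.concatenate(
        [haps.alleles[i1, :breakpoint_snp], haps.alleles[i2, breakpoint_snp:]]
    )
    return HaplotypeMatrix(
        alleles=np.vstack([haps.alleles, new_row]),
        positions=haps.positions.copy(),
        sequence_ids=list(haps.sequence_ids) + [new_id],
        snp_ids=list(haps.snp_ids),
    )


ParentMode = Literal["random", "one_diff", "two_diff", "unique"]


def select_parents(haps: HaplotypeMatrix, breakpoint_snp: int, mode: ParentMode,
                   rng: np.random.Generator, window: int = 10,
                   max_tries: int = 500) -> Optional[Tuple[str, str]]:
    """Draw a parental pair for an in-silico recombination experiment.

    Modes tighten progressively: ``random`` draws any distinct pair;
    ``one_diff`` requires the parents to differ somewhere within
    ``window`` SNPs of the breakpoint; ``two_diff`` requires a difference
    on each side; ``unique`` additionally requires the spliced recombinant
    to be unique within the breakpoint window. Returns None if no pair
    satisfies the mode within ``max_tries`` draws.
    """
    lo = max(0, breakpoint_snp - window)
    hi = min(haps.n_snps, breakpoint_snp + window)
    for _ in range(max_tries):
        i1, i2 = rng.choice(haps.n_sequences, size=2, replace=False)
        a1 = haps.alleles[i1]
        a2 = haps.alleles[i2]
        if mode == "random":
            pass
        elif mode == "one_diff":
            if not (a1[lo:hi] != a2[lo:hi]).any():
                continue
        else:
            left_diff = (a1[lo:breakpoint_snp] != a2[lo:breakpoint_snp]).any()
            right_diff = (a1[breakpoint_snp:hi] != a2[breakpoint_snp:hi]).any()
            if not (left_diff and right_diff):
                continue
            if mode == "unique":
                rec = np.concatenate([a1[lo:breakpoint_snp], a2[breakpoint_snp:hi]])
                if (haps.alleles[:, lo:hi] == rec).all(axis=1).any():
                    continue
        return haps.sequence_ids[int(i1)], haps.sequence_ids[int(i2)]
    return None


def inject_artifact(haps: HaplotypeMatrix, kind: str, rng: np.random.Generator,
                    tract_length: int = 1) -> Tuple[HaplotypeMatrix, Dict]:
    """Inject one data artifact; returns the new matrix and an audit record.

    ``gene_conversion`` copies a tract of ``tract_length`` SNP alleles from
    a random donor row to a recipient; ``recurrent_mutation`` flips one
    random cell; ``phasing_error`` replaces two random rows by their
    reciprocal splices at a random breakpoint (per-SNP allele counts are
    conserved).
    """
    alleles = haps.alleles.copy()
    n, m = alleles.shape
    if kind == "gene_conversion":
        donor, recipient = rng.choice(n, size=2, replace=False)
        start = int(rng.integers(0, m - tract_length + 1))
        alleles[recipient, start:start + tract_length] = \
            alleles[donor, start:start + tract_length]
        audit = {"kind": kind, "donor": int(donor), "recipient": int(recipient),
                 "start": start, "length": int(tract_length)}
    elif kind == "recurrent_mutation":
        row = int(rng.integers(0, n))
        snp = int(rng.integers(0, m))
        alleles[row, snp] = 1 - alleles[row, snp]
        audit = {"kind": kind, "row": row, "snp": snp}
    elif kind == "phasing_error":
        r1, r2 = (int(x) for x in rng.choice(n, size=2, replace=False))
        b = int(rng.integers(1, m))
        new1 = np.concatenate([alleles[r1, :b], alleles[r2, b:]])
        new2 = np.concatenate([alleles[r2, :b], alleles[r1, b:]])
        alleles[r1] = new1
        alleles[r2] = new2
        audit = {"kind": kind, "rows": (r1, r2), "breakpoint_snp": b}
    else:
        raise ValueError(f"unknown artifact kind {kind!r}")
    return (
        HaplotypeMatrix(alleles, haps.positions.copy(), list(haps.sequence_ids),
                        list(haps.snp_ids)),
        audit,
    )
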