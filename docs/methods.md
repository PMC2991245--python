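# Methods

## Detection model

The detector treats phased haplotypes as sequences of *SNP patterns*
rather than individual alleles. For a grain size `n`, the matrix is cut
into columns of `n` consecutive SNPs (the first column's width varies from
1 to `n` across runs, sliding the boundaries across every possible phase);
within a column, identical allele tuples share an integer pattern code and
patterns private to a single sequence are coded 0 and ignored — they carry
no grouping evidence.

Patterns are modeled as inherited characters on a genealogy. The most
frequent pattern of each column is taken as the ancestral backbone
(*dominant*); every other shared pattern (*subdominant*) is assumed to
have arisen once, on one edge of the genealogy, and to be carried by the
clade below that edge. Two columns are jointly explainable by one rooted
tree when no subdominant block of one column crosses a subdominant block
of the other (crossing = overlapping without nesting); for segmentation,
columns are grouped into maximal runs whose partition-intersection graphs
are pairwise acyclic, the multi-allelic generalization of the four-gamete
test. Within such a run the subdominant blocks form a laminar family, so
the segment's perfect phylogeny is built directly by nesting: one node per
distinct block, each pattern on exactly one edge (no recurrence).

Recombination shows up when two adjacent segments are merged: a
subdominant clade `p` of the left segment crossing a subdominant clade `q`
of the right segment forces the sequences in `p ∩ q` to descend from two
parental nodes at once. Each maximal such intersection is one raw
detection, spanning the two segments' SNP interval. Sub-clades of a
biparental clade cross too; only the maximal intersection is reported,
since nested crossings restate the same junction.

### Aggregation and calling

Raw detections from all runs (grains × offsets × directions; the
calibrated default is 20/10/5, both directions, 70 runs) are pooled into
per-sequence detection distributions: each record credits every member of
its recombinant set over its interval. Aggregating per sequence rather
than per exact recombinant set makes the counts robust to run-to-run
noise in set membership — a descendant whose pattern happens to be unique
in one layout drops out of that run's block without fragmenting the
event's support.

A sequence is called at every local-maximum plateau of its distribution
that reaches the threshold `T` (default 42 of 70 runs, 60%); a sequence
can carry several junctions. Called candidates are grouped into one event
when (a) their threshold regions overlap, (b) their breakpoints lie within
2 SNPs of each other (the method's placement accuracy scale), and (c) the
pair is co-detected in the majority of the raw records covering the locus
— occasional joint membership, as happens when two junctions share a
hotspot, does not merge events. The event takes its breakpoint (argmax
plateau midpoint; half-integers denote inter-SNP slots) from the member
with the highest peak, and its maximum interval is the union of member
plateaus. Events are reported with threshold intervals, peak counts and a
binary sequences-by-events recotype matrix.

`mergepats` (off by default) absorbs patterns at Hamming distance 1 into
more frequent patterns, hierarchically from the most frequent down, which
buys robustness to genotyping error and recurrent mutation at slight
resolution cost. The phasing-artifact post-filter removes pairs of
single-recombinant events sitting on the two homologs of one individual
less than 6 SNPs apart — the signature of a phase switch.

## Calibration harness

### Coalescent generator

Replicates are 250,000 bp regions with 210 haploid samples: 60 African,
50 European, 50 East Asian and 50 from a recently admixed
African/European population (80/20 at 7 generations ago). The demography
is a reconstruction of the published best-fit calibrated human model
commonly used for such benchmarks: present-day effective sizes of 100,000
shrinking (backward) to 24,000 (AFR, at 200 generations) and 7,700
(EUR 350, ASN 400); founder bottlenecks ~2,000 generations ago expressed
as inbreeding coefficients (AFR 0.008, ASN 0.067, EUR 0.02) and converted
to instantaneous-bottleneck strengths `-2N ln(1-F)`; the Asian/European
split at 2,000 generations; the out-of-Africa split at 3,500 generations
behind a 0.085 bottleneck; ancestral size 12,500 beyond 17,000
generations; symmetric migration 3.2e-5 (AFR–EUR) and 0.8e-5 (AFR–ASN)
until the splits. These values are package defaults chosen once from the
published model description, not fitted quantities. Mutation is
finite-sites at 1.5e-8 /bp/generation (recurrent hits possible, as in real
data); the alternate presets (`single_pop`, recombination `uniform` or
`none`) are one flag away.

The recombination map is variable: the region-wide mean rate is drawn
lognormally (σ = 0.6) around 1.3e-8 /bp/generation, and 75% of the total
map length is concentrated in hotspots of 1,500 bp placed with exponential
spacing (mean 9 kb) and exponentially distributed intensities, at 100 bp
resolution. This emulates human-like LD structure — hotspots separated by
cold blocks — without claiming any specific empirical map; the map is
reproducible from the seed and written alongside each simulated dataset.

Every recombination event in the sample history is extracted from the
simulator's full ancestral recombination graph: the two flagged parent
nodes of each event locate the breakpoint, the descendant set is read from
the marginal tree at the breakpoint (events whose material is trapped —
no extant lineage spans the junction — are dropped), the age is the node
time in generations, and the nearest extant relatives of each parental
lineage on its own side of the breakpoint are recorded as that side's
*context*. Ages stay in generations throughout; a years conversion
(default 20 yr/generation) is exposed for reporting only.

### Ascertainment

SNPs below a 10% minor-allele-frequency floor are removed; then a greedy
pairwise tagger keeps, repeatedly, the SNP capturing the most
not-yet-covered SNPs at r² > 0.8 until all are covered (an `aggressive`
variant peels redundant tags afterwards; a `density` scheme keeps the SNP
nearest each point of an even grid). Replicates with 80 or fewer
ascertained SNPs are discarded and redrawn. Blank (recombination-free)
controls skip tag selection: with a single underlying tree all SNPs of a
clade are perfectly correlated and tagging degenerately collapses the
panel to ~10 SNPs.

### Scoring

True events that cannot leave a trace are pruned before computing
sensitivity: an event is undetectable when its breakpoint lies outside
the ascertained span, or when the two parental sequences were identical
over at least one flank *at the time of the event*. Parental flanks are
proxied on realized data — the modal descendant haplotype versus the
modal haplotype of the other parent's context — compared only at SNPs
whose defining mutation is older than the event (younger sites did not
exist then) and only within 20 SNPs of the breakpoint (beyond one grain
the proxies decouple from the parents and the detector reads no pattern
there anyway).

A detection matches a true event when its recombinant set equals the
descendant set — or is a proper subset whose every excluded descendant
carries a younger recorded event overlapping the detection's support
region (the younger junction masks the older trace) — and the true
breakpoint falls inside the detection's argmax plateau (slot semantics: a
plateau covering SNPs `[a, b)` accepts breakpoints between positions
`a-1` and `b`). Matching is one-to-one, preferring exact sets, then the
closest breakpoint. False discovery rate counts detections with no match
against *all* recorded events; sensitivity divides matched surviving
events by all surviving events. Placement distances are measured in SNP
slots; summaries use the nearest-rank 90th percentile. The permuted-truth
control scores each replicate's detections against a different
replicate's truth via a seeded derangement; the parameter sweep ranks
settings by `-2·z(FDR) + z(sensitivity) − z(p90 distance)` across the
grid.

The in-silico splice experiment appends a recombinant built from two
extant haplotypes to a bottlenecked (European-history, strong-LD) sample
of 60 haplotypes over a 60 kb MAF-filtered panel, where parental pairs
drawn at random are often locally identical (~18% within ±10 SNPs of the
breakpoint) — the regime in which the parental-selection modes (random,
one difference near the breakpoint, differences on both sides, unique
recombinant) can separate.

## What the generator does and does not emulate

It reproduces the ingredients that drive detectability: deep population
structure and admixture, variable recombination with hotspots, tag-SNP
ascertainment, finite-sites homoplasy, and complete ground truth with
ages and descendant sets. It does not model gene conversion within the
coalescent, genotyping error (both available as in-silico injections),
phasing (inputs are taken as phased), or any empirically estimated local
recombination map. Passing calibration tests therefore demonstrate the
detector's behavior under a faithful synthetic stand-in for the study
conditions, not performance guarantees on any particular real dataset.

Measured on this generator, the calibrated operating point reproduces the
intended sensitivity regime (mean ~21%) and sub-SNP breakpoint placement
(pooled median distance ~0.5 SNP slots), and the permuted-truth control
degrades both scores by an order of magnitude, while the false discovery
rate and the detected-age distribution run higher/older than the original
study reported — our replicates record on the order of a thousand true
events each (the direct consequence of ρ = 4·N·r·L under the stated
demography and rates), so co-located junctions compete for matching in a
way a sparser event log would not. The numbers the acceptance script
prints are computed, never asserted.

## Numerical choices and degenerate inputs

- Ties in dominant-pattern selection go to the first-appearing code;
  mergepats absorbers are processed by decreasing original frequency with
  first-appearance tie-break; singleton status is re-evaluated after all
  merging in a column (merged former singletons are real evidence).
- Intervals are half-open `[start, end)` in 0-based SNP-index space
  everywhere; bp output uses flanking-SNP positions (BED compatible).
- Even argmax plateaus give half-integer breakpoints (inter-SNP slots).
- Missing or unphased genotypes are rejected at read time, not imputed.
- A column whose patterns are all unique has no dominant code and is
  compatible with everything.
- Detection requires at least `max(grains)` SNPs; the simulator refuses
  zero mutation rates (nothing would be observable).

## Known limitations

- The dominance assumption (most frequent pattern = ancestral) is the
  rooted analogue of the classical major-allele-ancestral heuristic; in
  regions where a derived haplotype has drifted to high frequency the
  backbone may be misassigned locally.
- Saturated regions (many junctions per sequence, e.g. strong hotspots)
  blur event identity: co-located junctions can merge into one called
  event or fragment across overlapping sets, which caps both sensitivity
  and precision — the known saturation behavior of LD-based methods.
- The undetectable-event pruning is an operationalization on realized
  data; the untransmitted half of a parental chromosome is unknowable in
  any coalescent simulation, so parental flank identity is necessarily
  proxied through extant relatives.
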