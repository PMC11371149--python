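# Methods

## Scope and data model

`nrcscape` analyzes the genomic and phylogenetic organization of plant NLR
immune receptor families in which helper (NRC-H) and sensor (NRC-S) clades
coexist, with special attention to a deep-conserved helper ortholog group
("NRC0"-like) that stays genetically clustered with a sensor partner across
species. Inputs are protein FASTA, GFF3 gene coordinates, Newick gene trees
with bootstrap supports, and TSV clade maps. All coordinates are 1-based
inclusive (GFF3 native) and are never converted to half-open form, so the
50 kb linkage rule has a single unambiguous reading. Clade labels form a
small vocabulary (`NRC_H`, `NRC_S`, `NRC0`, `NRC0_S`, `ADR1`, `NRG1`,
`OTHER`); `NRC0` is a subclade of the helpers and `NRC0_S` of the sensors,
so deep-conserved genes also count in all helper/sensor summaries.

## Genetic linkage and clustering

Two genes are genetically linked when they share a scaffold and the number
of bases strictly between their intervals is below the threshold
(`50,000 bp`, strict `<`). Overlapping or nested genes get distance 0 and
are always linked; linkage is never inferred across scaffolds. Both the
distance measure (inter-interval gap vs. start-to-start) and the strictness
of the cutoff are configurable because conventions differ between published
distance scripts; the defaults above are what every test and reported
number uses. Pairs are edges; clusters are connected components
(networkx) and exclude singletons. Pair counts, not component counts, are
the primary summary, and per-species counts must sum to the total while
HH + SS + HS partitions the set of pairs whose members both lie in the NRC
superclade — both identities are asserted on every synthetic run.

The scan is a scaffold-sorted sweep: for a fixed upstream gene the gap to
downstream genes is non-decreasing in their start coordinate, so the inner
loop stops at the first failure. Equivalence with the O(n²) all-pairs
filter is asserted on 100 random gene tables per test run.

## Patristic distances and clade assignment

Patristic distance is the branch-length sum along the unique path between
two leaves, computed via dendropy's phylogenetic distance matrix and
cross-checked in the tests against an independent all-pairs shortest-path
oracle on the weighted node graph. Distances treat the tree as unrooted and
are invariant to rerooting (property-tested).

The closest-neighbor map reports, for every focal-species gene, the
arg-min distance per other species, with ties broken to the
lexicographically smallest gene id. Because it is not stated whether
"shortest distance to orthologs" summaries in the field use the minimum or
the mean over species, both (plus the maximum) are emitted; the
most-conserved flag uses the minimum.

Clade assignment returns the smallest clade containing all reference
leaves whose support strictly exceeds the threshold (default 70; fractional
supports in [0,1] are rescaled to percent on input, logged). If the MRCA is
unsupported the walk proceeds rootward, reporting how many extra leaves
were swept in; exhausting the path yields an explicit unresolved result.
Bootstrap support is a property of a bipartition, not a node, so supports
are attached to edges on read and survive the default midpoint rooting (or
a user-supplied outgroup rooting); the root's inherited edge support is
cleared because a root induces no bipartition. Raising the threshold can
only grow (or unresolve) the returned clade — asserted as a property.

## Iterative ortholog discovery

Desk-scale databases make heuristic seeding unnecessary, so the search
engine is exact Smith–Waterman local alignment (Biopython's
`PairwiseAligner`, BLOSUM62). Gap costs follow the common convention that a
gap of length k costs `11 + k`; in Biopython's parameterization that is
`open_gap_score = −12`, `extend_gap_score = −1`. Percent identity is
identities over alignment columns (gapped columns included); query
coverage is the aligned query span over query length. Both filters are
inclusive (`identity ≥ 40`, `coverage ≥ 95`) and configurable — HSP-based
BLAST statistics can differ slightly from exact local alignment near the
thresholds, so pipelines replicating BLAST runs may need to absorb that
discrepancy via the thresholds. E-values are deliberately absent: the
filters are identity and coverage only. A hook (`confirm` callback) allows
delegating candidate confirmation — normally clade membership on a fixed
background tree — without changing filter semantics.

The loop: seeds query the database; subjects passing both filters for at
least one query are candidates; candidates failing clade confirmation are
quarantined (reported, never silently dropped); confirmed candidates join
the ortholog set and become the next round's queries; iteration stops at a
fixed point or `max_rounds`. The accepted set grows monotonically across
rounds and is invariant to seed/database ordering (all iteration is over
sorted identifiers); both are property-tested. De novo tree inference
never happens inside the loop — the background tree is an input.

## N-terminal motifs

Helper-type NLRs carry a MADA-like alpha1-helix sequence at the very N
terminus; their linked sensors instead retain a degenerate
`MAHAAVVSLxQKLxx` pattern. Detection uses a position-specific log-odds
matrix: column score `log2(((count + pc·bg)/(n + pc))/bg)` with
pseudocount `pc = 1` and uniform background by default, scanned ungapped
over start positions 1..30. An anchored, indel-free motif needs no
insert/delete states, so externally built HMMER3 profiles are loaded as
match-state PSSMs through pyhmmer and served behind the same interface.

The default pass threshold is calibrated on composition-matched shuffles of
the scanned sequence set to a 1 % false-positive rate. This is an operating
point, not a guarantee of zero false calls: a run scanning ~30–40
sensor-clade sequences will occasionally (roughly a third of seeds) produce
a single chance call just above threshold, typically at a placement deep in
the 30-residue window. The default-configuration dataset classifies
cleanly, and planted-motif scores sit far above threshold, so the planting
rate is recovered within binomial error across seeds. The exact bit-score
cutoffs that ship with curated HMMs are preferable when available; the
loader accepts one via its `threshold` argument.

The MAHA call is an exact degenerate-pattern match (x = any residue)
anchored within the same window; its per-sequence false-positive rate is
bounded by the 13 fixed positions (≈ 20⁻¹³ per start) and is asserted to
be below 10⁻⁴ by Monte Carlo.

## Conservation barcodes

Per alignment column the conservation score is `1 − H/log 20`, the
complement of normalized Shannon entropy over the residue distribution;
gaps and X are excluded from the distribution and the gap fraction is
reported separately. Columns where the reference holds a gap are skipped,
so the barcode length always equals the reference's ungapped length.
Entropy is a declared proxy for tree-aware evolutionary-rate estimation
(the ConSurf family of methods): it ignores phylogenetic correlation and
will overstate conservation in clades of near-duplicates. The interface
(scores indexed by reference position) leaves room for a rate-based
backend.

Variable regions are maximal runs, length ≥ 5, of positions whose
10-position centered sliding mean falls strictly below the 0.2 quantile of
the smoothed scores. A flat barcode therefore yields no calls, and raising
the minimum length can only reduce the number of calls.

## Synthetic data generator

The generator is first-class, tested code that defines the study
conditions. Structure: three clades (helper, sensor, outgroup) on one gene
tree; within the helper clade one deep-conserved ortholog group spanning
the first 4 of 6 species (its sensor partner spans and is genetically
linked in the same 4, echoing the real-world situation where a minority of
deep-conserved helpers retain their linked sensor); all other helper and
sensor groups are lineage-specific paralog expansions, which is what makes
the deep group uniquely "most conserved" in cross-species distance.

Sequence evolution is per-site substitution with a uniform exchange
kernel: along a branch of length b each site substitutes with probability
`1 − exp(−b)` to a uniformly chosen different residue. This controls the
identity levels the pipeline consumes without empirical-matrix likelihood
machinery. Default divergences — clade 1.2, ortholog group 0.7, leaf
0.05–0.12 substitutions/site — put within-group identity near 80 %
(comfortably above the 40 % recruitment filter) and between-group local
identity below 30 % with low query coverage (rejected by either filter).
A planted variable region (reference positions 61–90, rate × 6) in the
deep-conserved helper and sensor groups gives the barcode stage a known
low-conservation interval.

Coordinates: each species has 5 scaffolds; the deep helper–sensor pair is
placed as an adjacent unit with a linked gap; paralog groups become tandem
arrays with probability `2 × cluster_fraction` (default cluster_fraction
0.3), occasionally absorbing one unrelated neighbor (producing the rarer
mixed-clade pairs); everything else is placed with unlinked gaps. Linked
gaps are uniform on [0, 50 kb), unlinked on [50 kb, 5 Mb), so the strict
threshold is exercised on both sides; `cluster_fraction = 0` disables all
linkage including the planted pair. Gene lengths are uniform on
1.5–4.5 kb. The truth table's pair set is recomputed from the final
coordinates by an independent O(n²) scan, so incidental linkage through a
tandem array's outer pairs is recorded faithfully.

Motifs: helpers receive a 21-residue MADA-like block (consensus
`MADGEGTRINWEPFDWKQYHR`, a synthetic model of the field's MADA definition,
with 10 % per-position noise) at rate `p_mada_helper = 0.9` — chosen to
echo the ~90 % detection rate reported for real deep-conserved helpers —
and sensors receive the exact MAHA pattern (x positions random) plus a
fixed 6-residue sensor-clade context block at rate `p_maha_sensor = 1.0`.
The context block keeps the two planted signals from overlapping anywhere
except the initiator M–A, which is what lets a shuffle-calibrated
threshold separate helpers from sensors as cleanly as a curated HMM does
on real data.

Supports: planted clades draw support from U(85, 100), background nodes
from U(10, 100), so the deep clade always clears the `> 70` rule while
background clades exercise both sides of it.

Randomness is one numpy Generator per species plus a backbone stream, all
derived from the master seed; adding a species never changes existing
species' data (tested). Outputs are byte-identical across runs with the
same seed (tested).

What the generator does **not** emulate: indels (alignments are the
ungapped equal-length sequences themselves), codon-level or
empirical-matrix substitution, realistic intergenic content or genome
sizes, gene birth–death along a dated species tree, recombination, and
annotation noise (coordinates are exact). Passing tests therefore
demonstrate the correctness of the algorithms under controlled conditions,
not robustness to alignment error or annotation artifacts in real genomes.

## Perturbations

`perturb` produces degraded copies for robustness tests: dropping a
species' coordinates (other species' results must be unaffected), capping
all node supports at a floor (a floor of 0 makes every clade call
unresolved at the default threshold), and shuffling the first 30 residues
of every sequence (motif recovery collapses to the calibrated
false-positive rate while composition is preserved). Every perturbation is
logged on the returned dataset.

## Problem sizes and numerical choices

Default runs use 6 species and ~70 genes of length 140 aa — large enough
that every pair type, linkage boundary and clade-walk branch occurs,
small enough that the full suite (117 tests, including 100-table and
100-tree oracle-equivalence sweeps and a 200-seed motif-rate study) runs
in well under a minute. Ties anywhere (closest neighbor, cluster ids,
recruiting query) break lexicographically and deterministically. Scores
use float64 throughout; the only tolerance-sensitive comparisons are the
inclusive ≥ filters, which are exact at the values the generator produces.
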