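# Methods

## Input model

The unit of input is a typed, directed regulatory interaction:
(regulator_id, regulator_class ∈ {miRNA, TF}, target_id, target_class ∈
{miRNA, TF, gene}, effect ∈ {repression, activation, unspecified},
evidence ∈ {validated, predicted}, source). Tables are validated on
load: self-loops and miRNA→miRNA edges are rejected, identifiers are
whitespace-trimmed but otherwise preserved verbatim (no symbol
normalization — silent renaming would corrupt curated ids; an explicit
column-mapping config absorbs foreign spreadsheet layouts instead), and
exact duplicate rows are dropped with a logged count. A node may hold
several roles at once (a TF that is also a miRNA target); it is always
one node with a role set, never duplicated per role.

## Motif definitions and classification

A feed-forward loop is an ordered triple (m, t, g) with m a miRNA-class
regulator, t a TF-class regulator, g ∉ {m, t}, and both m→g and t→g
present. Classification is exclusive by the regulator-pair edges:
composite-FFL if m→t and t→m both exist, miRNA-FFL if only m→t, TF-FFL
if only t→m, no motif otherwise — so the three classes partition the
qualifying triples and their counts sum to the FFL total. The joint
target may itself be a TF (or a dual-role miRNA node reached through a
TF-class edge); only distinctness from the regulator pair is required.

Membership depends on edge direction and regulator class only, not on
the annotated effect, because curated tables mix effect vocabularies;
`require_mirna_repression=True` restores the strict reading in which
miRNA edges must be repressive.

A feedback loop is a reciprocal miRNA–TF pair, reported once per
unordered pair. Since every composite-FFL contains a reciprocal pair,
each FBL carries a `composite_overlap` flag; `n_fbl_pure` counts the
pairs heading no composite-FFL. Both tallies are always reported —
pipelines that list composite-FFLs and FBLs as separate categories are
counting the pure FBLs, and that is the number the planted-recovery
checks compare.

## Triad census

Significance runs on uncolored topology by default (the conventional
integer edge-list input to motif detectors discards node classes; a
`colored` option stratifies counts by node role). Every weakly
connected induced 3-node subgraph is counted under one of the 13
connected triad isomorphism classes (standard triad nomenclature; the
FFL topology is 030T). Enumeration exploits the fact that any weakly
connected triple has a "center" adjacent to the other two nodes:
iterating neighbour pairs of every node and deduplicating triples visits
each connected triple exactly once, in O(Σᵥ deg(v)²) rather than
O(n³). Each triple's 6-bit edge configuration is mapped to its class by
a 64-entry lookup table frozen from an exhaustive canonicalization over
the six node permutations. The test suite checks the census against
both an independent brute-force enumerator (all node triples, canonical
labeling computed at run time) and networkx's triadic census.

## Switching null model

Replicate networks preserve each node's in- and out-degree and the
reciprocal-pair count. Unidirectional edges and reciprocal pairs form
separate swap pools: a unidirectional exchange (a→b, c→d) ⇒ (a→d, c→b)
is rejected if it would create a self-loop, a duplicate edge, or a new
reciprocal pair; a reciprocal exchange swaps whole pairs
({a,b},{c,d}) ⇒ ({a,d},{c,b}) under the same checks. The schedule
attempts `exchanges_per_edge` (default 3) exchanges per edge of each
pool, each retried up to `tries_per_exchange` (default 3) times on
collision and then skipped, so the attempted count is fixed and the
accepted count varies — a network too constrained to swap comes back
unchanged. Defaults are 10,000 replicates; desk-scale analyses in the
tests and the acceptance script use 500–1,000, which the calibration
test shows is sufficient to separate planted enrichment from noise.

When a typed network is randomized, each moved edge keeps the regulator
class of its source half, so per-node out-degree per class is preserved
as well; the enrichment loop itself operates on pure topology.

## Z-score, p-value, significance call

z = (c − mean)/sd with the *population* standard deviation of the null
counts (the convention of the standard motif tools); sd = 0 maps to
z = ±∞ by the sign of the deviation and 0 on a tie. The empirical
p-value is the fraction of null networks with a *strictly* larger count,
so ties favour the original network. The significance rule is the
conjunction c > 5 ∧ z > 2 ∧ p < 0.05; the frequency clause means rare
motifs are never called significant no matter how extreme z is.
Replicate r draws its RNG from child r of a spawned seed sequence, so
results are bit-reproducible and independent of execution order.

## Network merge, hubs, subnetworks

The co-regulatory network is the union of supporting edges of the
chosen motif instances — by default the miRNA-FFLs and the FBLs; flags
admit TF-FFLs and composite-FFLs — with duplicate nodes and edges
removed and per-edge provenance retained. Hub rule 1 uses the pooled
arithmetic mean of total degree over all miRNA- and TF-role nodes with
a strict ">" (one average over both classes; a per-class mode exists
behind a flag). Rule 2 requires in-degree ≥ 10 over deduplicated edges
plus at least one incoming edge of each regulator class. Subnetworks
are either induced subgraphs or motif closures (union of all instances
touching a seed node), the latter being the natural shape of
single-regulator subnetworks. Joint targets are ranked by the number of
FFL instances they close — incoming miRNA–TF common-edge pairs — not by
raw in-degree.

## Synthetic data

The generator emulates a curated regulatory universe at the scale of
the motivating study — 15 miRNAs, 32 TFs, 157 target genes by default —
with independent Bernoulli background edges per regulation layer
(defaults 0.02–0.05, giving sparse layers of different densities) and a
default validated-evidence fraction of 0.16, the typical composition of
a merged predicted+validated target list. Planted motifs consume fresh
nodes; with `disjoint_planting` (default) background edges are drawn
only among non-planted nodes, so planted counts are exact by
construction — the property the recovery tests rely on. Expression
labels are Bernoulli per gene-role node; miRNAs are down-regulated by
convention.

What the generator does *not* emulate: realistic (heavy-tailed) degree
distributions, correlated targeting between paralogous regulators,
expression magnitudes, or annotation noise in identifiers. Passing
tests therefore demonstrate algorithmic correctness on sparse random
structure with known truth, not robustness to the idiosyncrasies of a
hand-curated table; the headline-count reproduction against a real
curated table is a separate check that activates when such a table is
supplied under `data/`.

## Pipeline conventions

The expression filter removes miRNA→gene rows whose target is not in
the up-regulated set and passes miRNA→TF and TF→* rows through: the
expression criterion applies to the miRNA target-gene list, while the
TF layer comes from regulatory databases rather than expression.
Evidence conflicts for the same target across sources resolve to
validated by default (`predicted_wins` inverts). All stages are
seeded; reports echo thresholds, seed and package version so outputs
are self-describing.

## Problem sizes

Default test and acceptance runs use networks of tens of nodes and a
few hundred edges, 100-seed oracle sweeps, and 500–1,000 null
replicates; the full suite completes in a few minutes on one CPU. The
enumeration and null-model code scale to curated-study inputs (hundreds
of edges, 10,000 replicates) in minutes.

## Known limitations

* Motifs larger than 3 nodes, two-TF or two-miRNA loops, and sampled
  (non-full) enumeration are out of scope.
* The significance machinery assumes a simple directed graph; parallel
  typed edges between the same node pair are collapsed for the census
  and the null model.
* Hub rule 1's "average" is a design choice among defensible readings
  (pooled vs per-class); both are implemented, pooled is the default.
* The empirical p-value has resolution 1/n_random; at 500 replicates
  the smallest nonzero p is 0.002.
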