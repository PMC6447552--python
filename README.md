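# coregnet

Analysis of miRNA–transcription-factor co-regulation in gene regulatory
networks: feed-forward/feedback loop detection, motif significance under
a degree-preserving null model, co-regulatory network assembly, and
hub selection.

## The problem

In many disease contexts — the motivating one is hepatic cancer stem
cells, where a panel of down-regulated miRNAs releases repression of
oncogenic targets — miRNAs and transcription factors (TFs) regulate
shared targets in recurring circuit motifs:

* **feed-forward loop (FFL)** — an ordered triple (miRNA *m*, TF *t*,
  joint target *g*) with both m→g and t→g, classified by the edges
  between the regulator pair:
  * *miRNA-FFL*: m⊣t only (the miRNA is the master regulator),
  * *TF-FFL*: t→m only,
  * *composite-FFL*: both m⊣t and t→m;
* **feedback loop (FBL)** — a reciprocal miRNA–TF pair (m⊣t and t→m).

Given a curated table of typed regulatory interactions (regulator,
regulator class, target, target class, effect, evidence, source), the
package enumerates and classifies every motif instance, asks whether the
feed-forward topology is enriched relative to degree-preserving random
networks, merges the miRNA-FFLs and FBLs into one deduplicated
co-regulatory network, and extracts hubs:

* **regulator hubs** — miRNA/TF nodes whose total degree (in + out)
  exceeds the pooled regulator mean;
* **hub target genes** — common targets with ≥ 10 in-edges, receiving
  at least one miRNA edge and one TF edge.

Motif enrichment uses full enumeration of connected directed 3-node
subgraphs (the 13 triad classes; the FFL topology is class 030T) and a
switching null model: random networks built by repeated pairwise edge
exchanges that preserve every node's in- and out-degree and the number
of reciprocal edge pairs. For an observed count *c* and null counts
*c₁…c_N*:

    Z = (c − mean(cᵢ)) / sd(cᵢ)        (population SD)
    p = #{i : cᵢ > c} / N

and a motif is called significant when c > 5, Z > 2 and p < 0.05.

A seeded synthetic-data module generates tripartite regulatory universes
with planted motifs of exactly known counts, so the whole pipeline is
testable without any external download.

## Worked example

```python
from coregnet import (FFL_TRIAD, NullModelConfig, build_coregulatory_network,
                      find_ffls, test_motif_enrichment)
from coregnet.synthetic import SyntheticSpec, generate

spec = SyntheticSpec(n_mirna=25, n_tf=25, n_gene=40,
                     planted={"miRNA-FFL": 20},
                     edge_prob={"miRNA->TF": 0.02, "miRNA->gene": 0.02,
                                "TF->miRNA": 0.02, "TF->gene": 0.02},
                     seed=4)
table, _ = generate(spec)
network = build_coregulatory_network(find_ffls(table))
result = test_motif_enrichment(network, FFL_TRIAD,
                               NullModelConfig(n_random=500, seed=0))
print(result.original_count, round(result.z_score, 2), result.p_value)
```

prints

```
20 48.22 0.0
```

— the 20 planted feed-forward loops are observed in the merged network,
sit 48 null standard deviations above the null mean (which is 0.17:
degree-preserving rewiring almost never produces a feed-forward triad
here), and no null network had more, so p = 0 and the motif is called
significantly enriched. The scripts in `examples/` walk through each
capability the same way: simulation and exact planted-motif recovery,
expression-based target curation, significance testing, and network/hub
analysis.

A thin CLI mirrors the library
(`coregnet simulate|filter-targets|find-motifs|test-significance|build-network|find-hubs|subnetwork|run`);
`coregnet run --table table.tsv --out-dir out` executes the full
pipeline and writes a self-describing `report.json` plus GraphML/SIF
exports and the integer edge list (`1<TAB>2` per line) that FANMOD-style
motif tools consume.

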