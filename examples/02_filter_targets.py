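"""Curate miRNA targets against condition-specific expression labels.

A down-regulated miRNA releases repression of its targets, so genuine
targets should be up-regulated in the condition.  This example labels
60% of genes up-regulated, intersects the merged target list with that
set, and summarizes the evidence composition of the result.
"""

from coregnet import (
    TargetList,
    count_tfs_in_targets,
    evidence_summary,
    intersect_with_upregulated,
)
from coregnet.synthetic import SyntheticSpec, generate, generate_expression_labels

table, _ = generate(SyntheticSpec(seed=42))
labels = generate_expression_labels(table, frac_upregulated=0.6, seed=43)

targets = TargetList.from_regulation_table(table)
kept = intersect_with_upregulated(targets, labels.upregulated_genes)
print(f"{len(targets)} merged targets, {len(kept)} up-regulated and kept")

s = evidence_summary(kept)
print(f"evidence: {s['n_validated']} validated ({100*s['frac_validated']:.0f}%),"
      f" {s['n_predicted']} predicted ({100*s['frac_predicted']:.0f}%)")

n_tf, tf_ids = count_tfs_in_targets(targets, table.nodes_with_role("TF"))
print(f"{n_tf} of the merged targets are themselves TFs, e.g. {tf_ids[:4]}")
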