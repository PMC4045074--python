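"""Robust MIC association network and seasonal cluster extraction.

OTU pairs are screened in every rarefied table with the maximal
information coefficient; an edge survives only if it is significant in
enough subsampling events with a consistent slope sign.  Connected
components of the positive-edge subgraph are the seasonal clusters.
"""

from aquadyn import (AssociationParams, RarefactionPlan, SyntheticSpec,
                     extract_clusters, generate, network_stats, rarefy,
                     robust_associations)

data = generate(SyntheticSpec(n_otus=300, seed=7))
depth = int(data.table.sample_totals().min())
events = list(rarefy(data.table, RarefactionPlan(depth, 10, base_seed=1)))

params = AssociationParams(min_discoveries=5, n_null=300, seed=0)
net = robust_associations(events, params)
edges = net.edges_dataframe()
print(f"core OTUs (>30% detection in every event): {len(net.core_otus)}")
print(f"edges: {len(edges)} ({int((edges['sign'] > 0).sum())} positive, "
      f"{int((edges['sign'] < 0).sum())} negative)")

assignment = extract_clusters(net)
for label in assignment.cluster_labels():
    print(f"cluster {label}: {len(assignment.members(label))} OTUs")
print(f"isolated: {len(assignment.members('isolated'))}")

stats = network_stats(net, assignment)
print(f"clustering coefficient {stats['clustering_coefficient']:.3f}, "
      f"density {stats['density']:.3f}")
truth = data.truth.cluster_members
hit1 = len(set(assignment.members(1)) & set(truth[1] + truth[2]))
print(f"members of the largest cluster that are planted seasonal OTUs: {hit1}")
# Positive edges join OTUs peaking in the same season; negative edges
# join the winter cluster to the summer cluster.
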