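"""Generate a synthetic monitoring campaign and inspect its artifacts.

The generator emulates a 15-month monthly survey of a treatment plant
(DWTP) and nine distribution-system locations: an OTU count table, the
sample metadata with water chemistry, a rooted phylogeny and a pipe
inventory, plus the ground truth of everything planted.
"""

from aquadyn import SyntheticSpec, generate

data = generate(SyntheticSpec(n_otus=400, seed=7))
table, truth = data.table, data.truth

print(f"samples: {table.n_samples}  OTUs: {table.n_otus}")
print(f"reads per sample: min {table.sample_totals().min()}, "
      f"max {table.sample_totals().max()}")
print(f"pipe network: {truth.n_pipe_sections} sections, "
      f"{truth.pipe_total_length_m / 1000:.1f} km, "
      f"{truth.pipe_total_surface_m2:.0f} m^2 wetted surface")
print(f"planted clusters: {len(truth.cluster_members[1])} winter OTUs, "
      f"{len(truth.cluster_members[2])} summer OTUs")
print(f"occupancy law: {truth.occupancy_model} with alpha = "
      f"{truth.occupancy_alpha:.0f}")
# The cluster member lists, the occupancy alpha and the per-location pipe
# distances in `truth` are what the recovery examples check against.
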