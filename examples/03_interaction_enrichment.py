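"""Cell-cell interaction enrichment on the 15 μm proximity graph.

Edges join cells within 15 μm; observed pairwise phenotype contact
counts are compared against a label-permutation null (positions fixed),
yielding z-scores for attraction between cell types.
"""

from mifspace import (
    GatingConfig, build_proximity_graph, gate_cells, generate_scene,
    interaction_enrichment, make_paper_like_suite,
)

table = gate_cells(generate_scene(make_paper_like_suite("SDUS-like", seed=1)),
                   GatingConfig.from_intensity_model())
graph = build_proximity_graph(table, radius=15.0)
res = interaction_enrichment(graph, table, n_perm=500, seed=0)

print(f"{graph.n_nodes} cells, {graph.n_edges} edges at 15 μm")
for a, b in [("Th", "B"), ("CTL", "Th"), ("Mac", "CTL"), ("B", "Endothelial")]:
    print(f"  {a}-{b}: observed {int(res.counts.loc[a, b])}, "
          f"z = {res.z.loc[a, b]:+.1f}, p = {res.p_perm.loc[a, b]:.4f}")
# The scene plants Th-B and CTL-Th attraction, so those pairs show large
# positive z; un-planted pairs hover near zero.
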