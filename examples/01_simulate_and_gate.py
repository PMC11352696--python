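"""Simulate an immune-high case and recover its phenotypes by gating.

Builds a synthetic SMARCA4-deficient-like scene (lymphoid aggregates,
vascular tiles, a PD-1/PD-L1 invasive margin), gates the cells on
marker-intensity thresholds and compares against the planted truth.
"""

from mifspace import GatingConfig, gate_cells, generate_scene, make_paper_like_suite

spec = make_paper_like_suite("SDUS-like", seed=1)
table = generate_scene(spec)
gated = gate_cells(table, GatingConfig.from_intensity_model())

agree = (gated.data["phenotype"] == gated.data["true_phenotype"]).mean()
print(f"cells: {gated.n_cells}")
print(f"gating agreement with planted phenotypes: {agree:.4f}")
print("\nphenotype counts:")
print(gated.data["phenotype"].value_counts().to_string())
# Agreement near 1.0 means midpoint thresholds on the separable log-normal
# intensity model recover essentially every planted lineage label.
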