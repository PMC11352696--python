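"""Hotspot density quantification and the immune-low vs immune-high gap.

Generates one immune-low (ESS-like) and one immune-high (SDUS-like)
case, finds each case's maximum-density 500 μm window and prints the
per-phenotype densities there, in cells per mm².
"""

import pandas as pd

from mifspace import (
    GatingConfig, find_hotspot, gate_cells, generate_scene,
    hotspot_densities, make_paper_like_suite,
)

gating = GatingConfig.from_intensity_model()
rows = {}
for profile in ("ESS-like", "SDUS-like"):
    table = gate_cells(generate_scene(make_paper_like_suite(profile, seed=1)), gating)
    window = find_hotspot(table, window_side=500.0, stride=250.0)
    rep = hotspot_densities(table, window)
    rows[profile] = rep.densities
    print(f"{profile}: hotspot anchored at ({window.x0:.0f}, {window.y0:.0f}) μm")

dens = pd.DataFrame(rows).fillna(0.0).round(1)
print("\nhotspot densities (cells/mm²):")
print(dens.loc[["CTL", "Th", "B", "Mac"]].to_string())
# The immune-high case carries CTL/Th densities two orders of magnitude
# above the immune-low case — the directional group difference the
# pipeline's statistics quantify.
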