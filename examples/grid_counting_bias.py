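"""Compare automatic area fractions with stereological grid estimates.

Across a set of synthetic scenes, the pixel-count fraction (what image
analysis reports) is compared with grid-vertex counting (what a human with
an overlay grid reports).  Vertex counting is unbiased but noisy; counting
whole grid cells as hits overestimates thin ER on average — the known bias
of manual grid counting.
"""

import numpy as np

from mercquant import (
    SceneSpec,
    area_fractions,
    generate_scene,
    grid_cell_estimate,
    grid_point_estimate,
    pearson_compare,
)

spacing_nm = 16.0  # grid spacing, scaled to the 1 nm/px synthetic scenes
direct_er, vertex_er, cell_er = [], [], []
direct_mito, vertex_mito = [], []
rng = np.random.default_rng(0)
for seed in range(25):
    mask, _ = generate_scene(SceneSpec(seed=seed))
    off = (int(rng.integers(0, 16)), int(rng.integers(0, 16)))
    f = area_fractions(mask)
    gv = grid_point_estimate(mask, spacing_nm, offset_px=off)
    gc = grid_cell_estimate(mask, spacing_nm, offset_px=off)
    direct_er.append(f.er_fraction)
    vertex_er.append(gv.er_fraction)
    cell_er.append(gc.er_fraction)
    direct_mito.append(f.mito_fraction)
    vertex_mito.append(gv.mito_fraction)

r_mito = pearson_compare(direct_mito, vertex_mito)
r_er = pearson_compare(direct_er, vertex_er)
print(f"Pearson r (automatic vs grid-vertex), mitochondria: {r_mito:.2f}")
print(f"Pearson r (automatic vs grid-vertex), ER:           {r_er:.2f}")
print(f"mean ER fraction  — automatic:    {np.mean(direct_er):.4f}")
print(f"                  — grid vertex:  {np.mean(vertex_er):.4f}")
print(f"                  — grid cell:    {np.mean(cell_er):.4f}")
print()
print("Vertex counting is unbiased — its mean agrees with the automatic")
print("fraction — but noisy for thin ER, which few vertices ever hit.")
print("Cell-hit counting inflates the thin-ER fraction several-fold: its")
print("minimal countable unit is a whole grid cell.")
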