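"""From a cell point pattern to an area-density map.

Simulates a Poisson pattern with a density step, renders the cells, detects
them, and maps density with the 8-nearest-neighbor estimator; the two
regions are then compared.
"""

import numpy as np

from stain3d import density as dens
from stain3d.detect import detect_cells
from stain3d.synthetic import PointPatternSpec, generate_point_pattern, render_cells

px = 0.01  # mm/pixel
lam_map = np.full((32, 32), 40.0)
lam_map[:, 16:] = 10.0  # right half is 4x sparser
pattern, _ = generate_point_pattern(
    PointPatternSpec(region=(5.1, 5.1), intensity=lam_map, seed=0)
)
img = render_cells(pattern, (512, 512), px, psf_sigma=0.02, amplitude=1.0)
img.data += np.random.default_rng(0).normal(0, 0.05, img.data.shape)

found = detect_cells(img, sigma=0.02, intensity_threshold=0.25)
grid = dens.knn_density(found, spacing=0.25, origin=(0.5, 0.5), shape=(17, 17),
                        region=(4.1, 4.1), bias_correction=True)

left = grid.values[:, grid.node_x < 2.2]
right = grid.values[:, grid.node_x > 3.0]
print(f"true cells:                {len(pattern)}")
print(f"detected cells:            {len(found)}")
print(f"median density, dense side:  {np.nanmedian(left):7.1f} cells/mm^2 (truth 40)")
print(f"median density, sparse side: {np.nanmedian(right):7.1f} cells/mm^2 (truth 10)")
print()
print("Each grid node's density comes from the mean squared distance to its")
print("8 nearest detected cells (bias-corrected); the map recovers the")
print("density step built into the generating intensity. Close cell pairs")
print("that merge into a single detection pull the dense side below truth —")
print("the same undercounting that affects real crowded tissue.")
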