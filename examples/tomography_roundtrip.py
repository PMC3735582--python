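"""Parallel-beam projection and FBP reconstruction of a phantom slice."""

import numpy as np
from scipy import ndimage

from stain3d import opt_sim
from stain3d.types import ChannelVolume

n = 128
rr, cc = np.mgrid[0:n, 0:n]
img = np.zeros((n, n))
img[(rr - n / 2) ** 2 + (cc - n / 2) ** 2 < (0.35 * n) ** 2] = 1.0
img[(rr - 0.4 * n) ** 2 + (cc - 0.55 * n) ** 2 < (0.08 * n) ** 2] = 3.0
img = ndimage.gaussian_filter(img, 2.0)
slice_ = ChannelVolume(img, pixel_size=0.02)

sino = opt_sim.forward_project(slice_, opt_sim.view_angles(360))
recon = opt_sim.fbp_reconstruct(sino, filter_name="hann")

tissue = img > 0.05
r = np.corrcoef(recon.data[tissue], img[tissue])[0, 1]
print(f"views acquired:            {sino.n_views} over 360 degrees")
print(f"sinogram shape:            {sino.projections.shape} (detector x angle)")
print(f"round-trip correlation:    {r:.4f} (within the tissue mask)")
print()
print("Filtered back-projection from 360 views reproduces the slice almost")
print("exactly, so downstream corrections and detection can be exercised on")
print("reconstructed images just as on directly acquired ones.")
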