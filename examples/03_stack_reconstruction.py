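"""Render a drifted, noisy serial-section stack and reconstruct it.

The rendered stack mimics FIB-SEM acquisition: per-slice drift, noise,
a depthwise brightness gradient, and the flat bright carbon band used
as the alignment template.  The reconstruction chain (align → enhance →
segment) is then scored against the known ground truth.
"""

import numpy as np

from poreflow import (
    MembraneProfile,
    RenderSpec,
    align_stack,
    enhance_and_correct,
    generate_membrane,
    porosity_profile,
    render_stack,
    segment_two_zone,
)
from poreflow.synthetic import substream

membrane = generate_membrane(MembraneProfile.default(thickness_um=48 * 7e-3), (48, 48, 48), seed=5)
rng = substream(11, "drift")
drift = rng.integers(-5, 6, size=(48, 2))
drift[0] = 0
spec = RenderSpec(drift=drift, depth_gradient=np.linspace(1.0, 2.0, 48), noise_sd=6.0)
stack, truth = render_stack(membrane, spec, seed=6)
print(f"rendered {stack.n_slices} slices of {stack.data.shape[1:]} px "
      f"with drift in [-5, 5] px and a 2x depth brightness gradient")

aligned, trace = align_stack(stack)
dx_err = np.abs(trace.dx - truth["drift"][:, 0]).max()
dy_err = np.abs(trace.dy - truth["drift"][:, 1]).max()
print(f"alignment: worst drift error {dx_err} px horizontal, {dy_err} px vertical "
      "(carbon-band template + phase correlation; integer shifts only)")

seg = segment_two_zone(enhance_and_correct(aligned))
miss = (seg.structure.grid != membrane.grid) & seg.valid
print(f"segmentation: {100 * miss.sum() / seg.valid.sum():.2f}% voxel misclassification")

p_true = porosity_profile(membrane)
p_seg = porosity_profile(seg.structure, valid=seg.valid)
err = np.abs(p_true.porosity - p_seg.porosity).max()
print(f"recovered slab porosity within {err:.3f} of ground truth")
print("Sub-pixel-free alignment and two-zone Otsu thresholding recover the 3D pore")
print("structure faithfully enough for quantitative porosity work.")
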