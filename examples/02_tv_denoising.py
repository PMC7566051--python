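"""ROF total-variation denoising: wires vanish, lung boundaries stay.

Adds three bright wires to a phantom, denoises with the PDHG solver, and
compares how much the image changed on the wire support versus on the lung
boundary band — the edge-preserving behavior that motivates TV denoising
over blurring.
"""

import numpy as np
from scipy import ndimage

from tvac import PhantomSpec, add_wires, generate_phantom
from tvac.tv import TVParams, denoise_pdhg

spec = PhantomSpec()
pt = generate_phantom(spec, seed=3)
wired = add_wires(pt, n=3, seed=99, spec=spec)
wire_support = wired.image != pt.image

denoised, trace = denoise_pdhg(wired.image, TVParams())
print(f"PDHG: {trace.iterations_run} iterations, converged={trace.converged}")
print(f"ROF energy: {trace.energies[0]:.1f} -> {trace.energies[-1]:.1f}")

diff = np.abs(denoised - wired.image)
band = ndimage.binary_dilation(pt.lungs, iterations=2) & ~ndimage.binary_erosion(
    pt.lungs, iterations=2
) & ~wire_support
print(f"mean |change| on wires:          {diff[wire_support].mean():.4f}")
print(f"mean |change| on lung boundary:  {diff[band].mean():.4f}")
# The wires are attenuated several times more strongly than the lung
# boundary moves: thin bright structures are diffused, edges survive.
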