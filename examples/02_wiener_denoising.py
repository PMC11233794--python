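"""Denoise a noisy phantom with the pixel-wise adaptive Wiener filter.

The filter estimates a local mean and variance in a 3x3 neighborhood of
each pixel and shrinks the pixel toward its local mean in proportion to
how much of the local variance it attributes to noise.  When no noise
variance is supplied it uses the average of all local variance estimates.
"""

import numpy as np

from tumorgrade.phantom import PhantomSpec, Tissue, make_phantom
from tumorgrade.preprocess import WienerParams, wiener_filter

spec = PhantomSpec(height=300, width=300, tissue=Tissue(noise_std=15.0))
noisy, _ = make_phantom(spec, seed=3)
clean, _ = make_phantom(PhantomSpec(height=300, width=300,
                                    tissue=Tissue(noise_std=0.0)), seed=3)

result = wiener_filter(noisy, WienerParams(3, 3))
rmse_before = float(np.sqrt(np.mean((noisy - clean) ** 2)))
rmse_after = float(np.sqrt(np.mean((result.image - clean) ** 2)))

print(f"estimated noise variance : {result.noise_variance:8.2f} (injected 15^2 = 225)")
print(f"RMSE vs noiseless image  : {rmse_before:8.2f} -> {rmse_after:.2f}")
print()
print("The automatic estimate exceeds the injected noise power because the")
print("average local variance also picks up true structure (skull ring and")
print("tissue edges); the filter nevertheless halves the RMSE against the")
print("noiseless phantom while leaving edges nearly intact.")
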