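"""Simulate a polychromatic CT scan of the bilateral-prostheses phantom.

Builds the material phantom, projects it through the filtered tube spectrum,
and prints the transmission statistics that make projection-domain metal
thresholding possible: every tissue ray stays well above the 0.05-0.07
thresholds while rays through titanium fall far below them.
"""

import numpy as np

from dmar import simulate_case
from dmar.segmentation import transmission_image

case = simulate_case("bilateral_prostheses", size=256, n_views=360, sart_iterations=1)

trans = transmission_image(case.sinogram)
trace = case.metal_trace
print(f"phantom: {case.phantom.name}, {case.phantom.size} px at "
      f"{case.phantom.pixel_size_mm:.3f} mm/px")
print(f"spectrum: {len(case.spectrum.energies)} bins, "
      f"mean energy {case.spectrum.mean_energy:.1f} keV")
print(f"sinogram peak attenuation (normalization constant): {case.sinogram.peak_norm:.2f}")
print(f"non-metal transmission minimum: {trans[~trace].min():.3f}  "
      "(stays above the 0.05/0.07 thresholds)")
print(f"metal-trace transmission minimum: {trans[trace].min():.2e}  "
      "(deep under both thresholds)")
print(f"fraction of the true trace darker than T=0.05: {(trans[trace] <= 0.05).mean():.2f}")
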