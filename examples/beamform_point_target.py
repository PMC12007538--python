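"""Plane-wave beamforming of a point target on the trapezoidal grid.

Channel data for a single scatterer are generated from the analytic
two-way travel-time model for each of the eight tilted plane waves; the
compounded image localizes the target to within one 0.1 mm grid cell and
shows the sidelobe suppression gained by coherent compounding.
"""

import numpy as np

from smsfus import ProbeGeometry, compound, das_beamform, point_scatterer_channels
from smsfus.beamforming import TrapezoidalGrid, default_angles

probe = ProbeGeometry()
elements = probe.element_positions_mm()
grid = TrapezoidalGrid.from_aperture(elements, z_min_mm=2.0, z_max_mm=8.0)
fs = 60e6
x0, z0 = 1.0, 5.0

images = [
    das_beamform(point_scatterer_channels(elements, a, [(x0, z0, 1.0)], fs, int(fs * 16e-6)), a, grid)
    for a in default_angles()
]
img = np.abs(compound(images))
ix, iz = np.unravel_index(img.argmax(), img.shape)


def pslr_db(image):
    a = np.abs(image).copy()
    i, j = np.unravel_index(a.argmax(), a.shape)
    peak = a[i, j]
    a[max(0, i - 2) : i + 3, max(0, j - 2) : j + 3] = 0
    return 20 * np.log10(peak / a.max())


print(f"true target        : x = {x0:.2f} mm, z = {z0:.2f} mm")
print(f"image peak         : x = {grid.x_mm[ix]:.2f} mm, z = {grid.z_mm[iz]:.2f} mm")
print(f"PSLR single angle  : {pslr_db(images[0]):.1f} dB")
print(f"PSLR 8-angle compound: {pslr_db(img):.1f} dB  (higher = cleaner point spread)")
print(f"grid width at 8 mm : {grid.width_mm(8.0):.1f} mm vs aperture {elements.max()-elements.min():.1f} mm")
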