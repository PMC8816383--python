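"""Tomographic reconstruction of a weakly scattering sphere.

Simulates off-axis holograms of a dn = 0.02 sphere under 60 illumination
angles, retrieves the complex fields and reconstructs the RI tomogram with
and without missing-cone regularization.
"""

import numpy as np

from fobtools import AcquisitionGeometry
from fobtools.forward import circle_tilts, simulate_hologram_set
from fobtools.holography import retrieve_fields
from fobtools.odt import reconstruct_tomogram
from fobtools.phantoms import PhantomSpec, Primitive, build_phantom

geometry = AcquisitionGeometry(pixel_pitch_um=0.1, axial_pitch_um=0.1)
spec = PhantomSpec(
    grid_shape=(64, 64, 64), voxel_size_um=(0.1, 0.1, 0.1), n_medium=1.337,
    primitives=(Primitive(center_um=(3.2, 3.2, 3.2), radii_um=(0.8, 0.8, 0.8),
                          n=1.357, shift_ghz=7.8, linewidth_ghz=0.8, label=1),),
)
truth = build_phantom(spec)
tilts = circle_tilts(geometry, n_angles=60, shape=(64, 64))
holograms = simulate_hologram_set(truth, geometry, tilts=tilts)
fields = retrieve_fields(holograms)


def fwhm(profile):
    p = (profile - profile.min()) / np.ptp(profile)
    above = np.where(p >= 0.5)[0]
    return above[-1] - above[0] + 1


mask = truth.labels[32] == 1
for iterations in (0, 50):
    tomo = reconstruct_tomogram(fields, geometry, grid_shape=(64, 64, 64),
                                iterations=iterations)
    mean_ri = tomo.central_slice[mask].mean()
    elong = fwhm(tomo.ri[:, 32, 32]) / fwhm(tomo.ri[32, 32, :])
    print(f"iterations={iterations:3d}: mean RI in sphere {mean_ri:.4f} "
          f"(truth 1.3570), axial/lateral elongation {elong:.2f}")
print("non-negativity iterations recover the contrast the missing cone "
      "removes and shrink the axial elongation")
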