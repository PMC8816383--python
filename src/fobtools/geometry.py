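"""Acquisition geometry shared by all physics operations.

All optical computations in this package are parameterized by a single
:class:`AcquisitionGeometry`: vacuum wavelength, immersion-medium refractive
index, the two numerical apertures of the tomography arm, the deviation of
the Brillouin collection geometry from exact backscattering, and the voxel
pitches of the reconstruction grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AcquisitionGeometry"]


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Optical geometry of the combined microscope.

    Parameters
    ----------
    wavelength_nm:
        Vacuum wavelength of the laser in nanometres (default 532 nm,
        frequency-doubled Nd:YAG).
    n_medium:
        Refractive index of the immersion/mounting medium (default 1.337,
        aqueous buffer).
    na_illumination:
        Numerical aperture of the illumination objective.
    na_detection:
        Numerical aperture of the detection objective.
    theta_deg:
        Deviation of the Brillouin scattering geometry from exact
        backscattering, in degrees.  The instrument collects in
        backscattering, so the default is 0 and the ``cos(theta/2)`` factor
        in the modulus equation is 1.
    pixel_pitch_um:
        Lateral sample-plane pixel pitch in micrometres.
    axial_pitch_um:
        Axial voxel pitch of the tomogram in micrometres.
    """

    wavelength_nm: float = 532.0
    n_medium: float = 1.337
    na_illumination: float = 1.0
    na_detection: float = 1.2
    theta_deg: float = 0.0
    pixel_pitch_um: float = 0.1
    axial_pitch_um: float = 0.1

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if self.n_medium < 1:
            raise ValueError("medium RI must be >= 1")
        for na in (self.na_illumination, self.na_detection):
            if not 0 < na <= self.n_medium:
                raise ValueError("numerical apertures must lie in (0, n_medium]")
        if not 0 <= self.theta_deg < 90:
            raise ValueError("theta must lie in [0, 90) degrees")
        if self.pixel_pitch_um <= 0 or self.axial_pitch_um <= 0:
            raise ValueError("voxel pitches must be positive")

    @property
    def wavelength_um(self) -> float:
        return self.wavelength_nm * 1e-3

    @property
    def k0_um(self) -> float:
        """Vacuum wavenumber in rad/um."""
        return 2.0 * np.pi / self.wavelength_um

    @property
    def km_um(self) -> float:
        """Wavenumber in the medium in rad/um."""
        return self.k0_um * self.n_medium
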