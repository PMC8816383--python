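"""3-D refractive-index reconstruction via the Fourier diffraction theorem.

Under the Rytov approximation the complex phase of the background-normalized
field, ``psi = ln(E/E_bg)``, depends linearly on the scattering potential
``f(r) = k0^2 (n(r)^2 - n_m^2)``.  For each illumination direction the 2-D
Fourier transform of ``psi`` is placed on the Ewald-sphere cap determined by
the illumination wavevector:

    f_hat(k_perp - k_i_perp, kz - k_iz) = (2 kz / i) * psi_hat(k_perp - k_i_perp)
                                          * exp(i (k_iz - kz) z_d)

with ``kz = sqrt(km^2 - |k_perp|^2)`` and ``z_d`` the distance from the
volume center to the plane the field is referenced to.  Because the
transverse scattering vector equals the detector grid frequency exactly, only
the axial component needs gridding, done by nearest-voxel scatter with
fill-count averaging.

The limited illumination cone leaves an unsampled "missing cone" of axial
frequencies, causing axial elongation and contrast underestimation.  This is
regularized by iterative non-negativity (n >= n_m) in real space alternated
with data replacement on the sampled voxels (Gerchberg-Papoulis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import AcquisitionGeometry
from .holography import ComplexField, unwrap_phase

__all__ = [
    "ScatteringPotentialSpectrum",
    "RITomogram",
    "map_field_to_ewald",
    "reconstruct_tomogram",
]


@dataclass
class RITomogram:
    """Reconstructed 3-D refractive-index field."""

    ri: np.ndarray                       # (nz, ny, nx), dimensionless
    voxel_size_um: tuple[float, float, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ri = np.asarray(self.ri, dtype=float)
        if not np.all(np.isfinite(self.ri)):
            raise ValueError("tomogram must be finite")
        if np.any(self.ri < 1.0):
            raise ValueError("refractive index must be >= 1")

    @property
    def central_slice(self) -> np.ndarray:
        return self.ri[self.ri.shape[0] // 2]


def map_field_to_ewald(
    cfield: ComplexField,
    geometry: AcquisitionGeometry,
    grid_shape: tuple[int, int, int],
    axial_pitch_um: float,
    approximation: str = "rytov",
) -> tuple[np.ndarray, np.ndarray]:
    """Map one retrieved field onto its Ewald-sphere cap.

    Returns ``(indices, values)`` where ``indices`` is an (m, 3) array of
    (iz, iy, ix) Fourier-grid voxels (DC-at-corner convention) and
    ``values`` the complex scattering-potential samples placed there.
    """
    if approximation not in ("rytov", "born"):
        raise ValueError("approximation must be 'rytov' or 'born'")
    nz, ny, nx = grid_shape
    if cfield.field.shape != (ny, nx):
        raise ValueError("field shape does not match the grid")
    dy = dx = cfield.pixel_pitch_um
    dz = axial_pitch_um
    km = geometry.km_um
    k0 = geometry.k0_um
    kiy, kix = cfield.tilt_um
    ki_perp2 = kiy**2 + kix**2
    if np.sqrt(ki_perp2) > k0 * geometry.na_illumination * (1 + 1e-9):
        raise ValueError("illumination tilt outside the illumination NA")
    kiz = np.sqrt(km**2 - ki_perp2)

    if approximation == "rytov":
        r = cfield.field
        psi = np.log(np.maximum(np.abs(r), 1e-12)) + 1j * unwrap_phase(np.angle(r))
    else:
        psi = cfield.field - 1.0
    psi_hat = np.fft.fft2(psi) * dy * dx

    qy = 2 * np.pi * np.fft.fftfreq(ny, d=dy)
    qx = 2 * np.pi * np.fft.fftfreq(nx, d=dx)
    QY, QX = np.meshgrid(qy, qx, indexing="ij")
    ky = QY + kiy
    kx = QX + kix
    k_perp2 = ky**2 + kx**2
    k_cut = min(k0 * geometry.na_detection, km)
    valid = k_perp2 <= k_cut**2
    kz = np.sqrt(np.maximum(km**2 - k_perp2, 0.0))
    dkz = 2 * np.pi / (nz * dz)
    kz_rel = kz - kiz
    iz = np.rint(kz_rel / dkz).astype(int)
    valid &= np.abs(iz) <= nz // 2 - 1

    iy_idx, ix_idx = np.nonzero(valid)
    iz_idx = iz[valid] % nz
    vals = (
        (2.0 * kz[valid] / 1j)
        * psi_hat[valid]
        * np.exp(1j * (kiz - kz[valid]) * cfield.detector_offset_um)
    )
    indices = np.stack([iz_idx, iy_idx, ix_idx], axis=1)
    return indices, vals


@dataclass
class ScatteringPotentialSpectrum:
    """Accumulated Fourier coverage of the scattering potential."""

    geometry: AcquisitionGeometry
    grid_shape: tuple[int, int, int]
    voxel_size_um: tuple[float, float, float]
    data: np.ndarray = None          # complex sum
    counts: np.ndarray = None        # fill counts
    n_fields: int = 0

    def __post_init__(self) -> None:
        if self.data is None:
            self.data = np.zeros(self.grid_shape, dtype=complex)
        if self.counts is None:
            self.counts = np.zeros(self.grid_shape, dtype=np.int32)

    def add_field(self, cfield: ComplexField, approximation: str = "rytov") -> None:
        idx, vals = map_field_to_ewald(
            cfield, self.geometry, self.grid_shape, self.voxel_size_um[0], approximation
        )
        np.add.at(self.data, (idx[:, 0], idx[:, 1], idx[:, 2]), vals)
        np.add.at(self.counts, (idx[:, 0], idx[:, 1], idx[:, 2]), 1)
        self.n_fields += 1

    def averaged(self) -> tuple[np.ndarray, np.ndarray]:
        """Fill-count-averaged spectrum and its coverage mask, with
        Hermitian symmetry enforced (the potential is real)."""
        filled = self.counts > 0
        avg = np.zeros_like(self.data)
        avg[filled] = self.data[filled] / self.counts[filled]
        mirror = _index_negate(avg)
        mirror_filled = _index_negate(filled.astype(np.int8)).astype(bool)
        both = filled & mirror_filled
        out = np.where(both, 0.5 * (avg + np.conj(mirror)), 0.0)
        only_f = filled & ~mirror_filled
        only_m = mirror_filled & ~filled
        out[only_f] = avg[only_f]
        out[only_m] = np.conj(mirror)[only_m]
        return out, filled | mirror_filled


def _index_negate(a: np.ndarray) -> np.ndarray:
    """Return b with b[m] = a[-m mod N] on every axis."""
    return np.roll(np.flip(a), shift=(1, 1, 1), axis=(0, 1, 2))


def reconstruct_tomogram(
    fields: list[ComplexField],
    geometry: AcquisitionGeometry,
    grid_shape: tuple[int, int, int] | None = None,
    iterations: int = 100,
    tol: float = 1e-6,
    approximation: str = "rytov",
) -> RITomogram:
    """Reconstruct the RI tomogram from retrieved complex fields.

    After fill-count averaging and inverse transform, ``iterations`` cycles
    of missing-cone regularization are run: enforce ``n >= n_m``
    (non-negative scattering potential) in real space and restore the
    measured values on sampled Fourier voxels.  Iteration stops early when
    the relative real-space update drops below ``tol``.
    """
    if not fields:
        raise ValueError("at least one field is required")
    ny, nx = fields[0].field.shape
    if grid_shape is None:
        grid_shape = (max(ny, nx), ny, nx)
    pitches = (geometry.axial_pitch_um, fields[0].pixel_pitch_um, fields[0].pixel_pitch_um)
    spectrum = ScatteringPotentialSpectrum(geometry, grid_shape, pitches)
    for f in fields:
        spectrum.add_field(f, approximation=approximation)
    data, mask = spectrum.averaged()

    dv = pitches[0] * pitches[1] * pitches[2]
    k0 = geometry.k0_um
    nm = geometry.n_medium

    def to_potential(fhat: np.ndarray) -> np.ndarray:
        return np.real(np.fft.ifftn(fhat)) / dv

    f_cur = data.copy()
    pot = to_potential(f_cur)
    residuals: list[float] = []
    data_norm = np.linalg.norm(data[mask]) or 1.0
    for _ in range(int(iterations)):
        pot_pos = np.maximum(pot, 0.0)
        f_cur = np.fft.fftn(pot_pos) * dv
        residuals.append(float(np.linalg.norm(f_cur[mask] - data[mask]) / data_norm))
        f_cur[mask] = data[mask]
        pot_new = to_potential(f_cur)
        update = np.linalg.norm(pot_new - pot) / (np.linalg.norm(pot) or 1.0)
        pot = pot_new
        if update < tol:
            break
    if iterations > 0:
        pot = np.maximum(pot, 0.0)
    if not np.all(np.isfinite(pot)):
        raise RuntimeError(
            "reconstruction diverged: non-finite scattering potential "
            f"(coverage {mask.mean():.3f}, {len(fields)} fields)"
        )
    n2 = nm**2 + pot / k0**2
    ri = np.sqrt(np.maximum(n2, 1.0))
    # the cap phase factor references z = 0 at the volume center; roll so the
    # center of the object lands on the central slice index
    ri = np.roll(ri, grid_shape[0] // 2, axis=0)
    provenance = {
        "n_angles": len(fields),
        "iterations": int(iterations),
        "iterations_run": len(residuals),
        "approximation": approximation,
        "coverage_fraction": float(mask.mean()),
    }
    tomo = RITomogram(ri=ri, voxel_size_um=pitches, provenance=provenance)
    tomo.residuals = residuals
    return tomo
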