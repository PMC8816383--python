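"""Synthetic raw-data simulators.

Given a voxelized phantom (:class:`~fobtools.phantoms.GroundTruth`) these
routines emulate the instrument's raw outputs:

* angle-resolved off-axis holograms with a tilted-reference carrier, via a
  multi-slice angular-spectrum ("beam propagation") forward model or, for
  closed-form test oracles, a thin accumulated-phase projection;
* two-order VIPA spectra (Stokes / anti-Stokes Lorentzian doublets);
* raster-scanned Brillouin frames sampling the phantom's ground-truth
  shift/linewidth maps, plus calibration doublets at known shifts.

Noise models: additive Gaussian on holograms, Poisson counting noise on
spectra.  All randomness flows through an explicit ``numpy`` generator.
"""

from __future__ import annotations

import numpy as np

from .brillouin import SpectrometerModel, SpectrumFrame
from .geometry import AcquisitionGeometry
from .holography import HologramSet
from .phantoms import GroundTruth
from .phantoms import simulate_fluorescence as simulate_fluorescence_channels

__all__ = [
    "simulate_fluorescence_channels",
    "circle_tilts",
    "simulate_hologram_set",
    "simulate_vipa_spectrum",
    "simulate_brillouin_scan",
    "simulate_calibration_frames",
]

DEFAULT_CARRIER_CPP = (0.28, 0.28)  # cycles/camera-pixel, image diagonal
DEFAULT_OVERSAMPLE = 2              # camera grid relative to reconstruction grid
DEFAULT_CALIBRATION_SHIFTS_GHZ = (5.09, 7.43)


def _snap_tilt(k_target: tuple[float, float], shape: tuple[int, int], pitch: float) -> tuple[float, float]:
    """Snap a transverse illumination wavevector onto the Fourier grid."""
    ny, nx = shape
    my = round(k_target[0] * ny * pitch / (2 * np.pi))
    mx = round(k_target[1] * nx * pitch / (2 * np.pi))
    return (2 * np.pi * my / (ny * pitch), 2 * np.pi * mx / (nx * pitch))


def circle_tilts(
    geometry: AcquisitionGeometry,
    n_angles: int = 60,
    na_fraction: float = 0.8,
    shape: tuple[int, int] = (64, 64),
    include_normal: bool = True,
) -> np.ndarray:
    """Illumination tilts on a circle at a fraction of the illumination NA.

    Returns (n, 2) transverse wavevectors (ky, kx) in rad/um, snapped to the
    detector Fourier grid so the demodulated illumination lands exactly on a
    frequency bin.
    """
    k_r = geometry.k0_um * na_fraction * geometry.na_illumination
    tilts = []
    if include_normal:
        tilts.append((0.0, 0.0))
    for phi in np.linspace(0, 2 * np.pi, n_angles, endpoint=False):
        tilts.append(_snap_tilt((k_r * np.sin(phi), k_r * np.cos(phi)), shape, geometry.pixel_pitch_um))
    return np.array(tilts)


def _propagator(shape: tuple[int, int], pitch: float, km: float, dz: float) -> np.ndarray:
    ky = 2 * np.pi * np.fft.fftfreq(shape[0], d=pitch)
    kx = 2 * np.pi * np.fft.fftfreq(shape[1], d=pitch)
    k2 = ky[:, None] ** 2 + kx[None, :] ** 2
    kz = np.sqrt(np.maximum(km**2 - k2, 0.0))
    prop = np.exp(1j * kz * dz)
    prop[k2 >= km**2] = 0.0  # drop evanescent components
    return prop


def _multislice_fields(
    truth: GroundTruth, geometry: AcquisitionGeometry, tilt: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Propagate a tilted plane wave through the phantom (and without it)."""
    nz, ny, nx = truth.ri.shape
    dz = truth.spec.voxel_size_um[0]
    pitch = truth.spec.voxel_size_um[2]
    km = geometry.km_um
    k0 = geometry.k0_um
    y = np.arange(ny)[:, None] * pitch
    x = np.arange(nx)[None, :] * pitch
    e_s = np.exp(1j * (tilt[0] * y + tilt[1] * x))
    e_b = e_s.copy()
    prop = _propagator((ny, nx), pitch, km, dz)
    dn = truth.ri - truth.spec.n_medium
    # oblique-incidence correction: a tilted ray accrues phase over the
    # slanted path dz / cos(theta_i), not dz
    kiz = np.sqrt(km**2 - tilt[0] ** 2 - tilt[1] ** 2)
    dz_eff = dz * km / kiz
    for j in range(nz):
        e_s = np.fft.ifft2(np.fft.fft2(e_s) * prop)
        e_b = np.fft.ifft2(np.fft.fft2(e_b) * prop)
        if np.any(dn[j]):
            e_s = e_s * np.exp(1j * k0 * dn[j] * dz_eff)
    return e_s, e_b


def _thin_fields(
    truth: GroundTruth, geometry: AcquisitionGeometry, tilt: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Accumulated-phase projection along the tilted ray (no diffraction)."""
    nz, ny, nx = truth.ri.shape
    dz, dy, dx = truth.spec.voxel_size_um
    km = geometry.km_um
    k0 = geometry.k0_um
    kiz = np.sqrt(km**2 - tilt[0] ** 2 - tilt[1] ** 2)
    cos_theta = kiz / km
    ky = 2 * np.pi * np.fft.fftfreq(ny, d=dy)[:, None]
    kx = 2 * np.pi * np.fft.fftfreq(nx, d=dx)[None, :]
    dn = truth.ri - truth.spec.n_medium
    z_c = (nz / 2) * dz
    phase_hat = np.zeros((ny, nx), dtype=complex)
    for j in range(nz):
        if not np.any(dn[j]):
            continue
        # ray through detector pixel r at depth z passes through
        # r - tan * (z_c - z_j); sample the slice there via a Fourier shift
        z_j = (j + 0.5) * dz
        oy = (tilt[0] / kiz) * (z_j - z_c)
        ox = (tilt[1] / kiz) * (z_j - z_c)
        phase_hat += np.fft.fft2(dn[j]) * np.exp(1j * (ky * oy + kx * ox))
    phase = (k0 * dz / cos_theta) * np.real(np.fft.ifft2(phase_hat))
    y = np.arange(ny)[:, None] * dy
    x = np.arange(nx)[None, :] * dx
    e_b = np.exp(1j * (tilt[0] * y + tilt[1] * x))
    return e_b * np.exp(1j * phase), e_b


def _fourier_upsample(e: np.ndarray, factor: int) -> np.ndarray:
    """Band-limited (Fourier zero-padding) upsampling of a periodic field."""
    if factor == 1:
        return e
    ny, nx = e.shape
    spec = np.fft.fftshift(np.fft.fft2(e))
    out = np.zeros((ny * factor, nx * factor), dtype=complex)
    oy = (ny * factor - ny) // 2
    ox = (nx * factor - nx) // 2
    out[oy : oy + ny, ox : ox + nx] = spec
    return np.fft.ifft2(np.fft.ifftshift(out)) * factor * factor


def simulate_hologram_set(
    truth: GroundTruth,
    geometry: AcquisitionGeometry,
    tilts: np.ndarray | None = None,
    carrier_cpp: tuple[float, float] = DEFAULT_CARRIER_CPP,
    noise: float = 0.0,
    mode: str = "multislice",
    oversample: int = DEFAULT_OVERSAMPLE,
    rng: np.random.Generator | None = None,
) -> HologramSet:
    """Simulate off-axis holograms for a list of illumination tilts.

    The camera grid oversamples the reconstruction grid by ``oversample``
    (finer pixels, same field of view), so the carrier can sit at a spatial
    frequency high enough to separate the sideband from the autocorrelation
    term.  The reference beam is tilted by the carrier relative to the
    transmitted illumination, so the +1-order sideband of every hologram
    sits at the configured carrier frequency regardless of the illumination
    angle (equivalent to demodulating at the detected illumination peak).

    ``noise`` is the additive Gaussian standard deviation relative to the
    mean hologram intensity.
    """
    if mode not in ("multislice", "thin"):
        raise ValueError("mode must be 'multislice' or 'thin'")
    if oversample < 1:
        raise ValueError("oversample must be >= 1")
    nz, ny, nx = truth.ri.shape
    pitch = truth.spec.voxel_size_um[2]
    if tilts is None:
        tilts = circle_tilts(geometry, shape=(ny, nx))
    tilts = np.asarray(tilts, dtype=float)
    k_max = geometry.k0_um * geometry.na_illumination
    radii = np.hypot(tilts[:, 0], tilts[:, 1])
    if np.any(radii > k_max * (1 + 1e-9)):
        raise ValueError("illumination tilt exceeds the illumination NA")
    nyc, nxc = ny * oversample, nx * oversample
    cam_pitch = pitch / oversample
    cbins = (round(carrier_cpp[0] * nyc), round(carrier_cpp[1] * nxc))
    hw = min(min(abs(c), n // 2 - abs(c)) for c, n in zip(cbins, (nyc, nxc))) - 1
    if hw < 2:
        raise ValueError("carrier too low: sideband cannot be separated from the DC term")
    if rng is None:
        rng = np.random.default_rng()

    y = np.arange(nyc)[:, None] * cam_pitch
    x = np.arange(nxc)[None, :] * cam_pitch
    k_c = (2 * np.pi * cbins[0] / (nyc * cam_pitch), 2 * np.pi * cbins[1] / (nxc * cam_pitch))
    holos = np.empty((len(tilts), nyc, nxc))
    bgs = np.empty_like(holos)
    for i, tilt in enumerate(tilts):
        if mode == "multislice":
            e_s, e_b = _multislice_fields(truth, geometry, tilt)
        else:
            e_s, e_b = _thin_fields(truth, geometry, tilt)
        e_s = _fourier_upsample(e_s, oversample)
        e_b = _fourier_upsample(e_b, oversample)
        # reference tilted by -carrier so E_obj * conj(E_ref) sits at +carrier
        e_ref = np.exp(1j * ((tilt[0] - k_c[0]) * y + (tilt[1] - k_c[1]) * x))
        holos[i] = np.abs(e_s + e_ref) ** 2
        bgs[i] = np.abs(e_b + e_ref) ** 2
    if noise > 0:
        scale = noise * holos.mean()
        holos = np.clip(holos + rng.normal(0.0, scale, holos.shape), 0.0, None)
        bgs = np.clip(bgs + rng.normal(0.0, scale, bgs.shape), 0.0, None)
    dz = truth.spec.voxel_size_um[0]
    offset = (nz * dz) / 2.0 if mode == "multislice" else 0.0
    return HologramSet(
        holograms=holos,
        backgrounds=bgs,
        tilts_um=tilts,
        carrier_cpp=(cbins[0] / nyc, cbins[1] / nxc),
        pixel_pitch_um=cam_pitch,
        detector_offset_um=offset,
        oversample=oversample,
        meta={"mode": mode, "noise": noise},
    )


def simulate_vipa_spectrum(
    shift_ghz: float,
    linewidth_ghz: float,
    model: SpectrometerModel,
    amplitude: float = 1000.0,
    background: float = 2.0,
    poisson_noise: bool = False,
    rng: np.random.Generator | None = None,
    position_um: tuple[float, float] = (0.0, 0.0),
) -> SpectrumFrame:
    """Simulate one two-order VIPA doublet.

    The anti-Stokes peak of one order sits at ``shift`` on the frequency
    axis and the Stokes peak of the adjacent order at ``FSR - shift``; each
    is a Lorentzian of the sample linewidth convolved with the (Lorentzian)
    instrument response, i.e. of FWHM ``linewidth + instrument_linewidth``.
    With ``poisson_noise`` the trace is Poisson-sampled, so the peak SNR is
    roughly ``sqrt(amplitude)``.
    """
    if not 0 < shift_ghz < model.fsr_ghz / 2:
        raise ValueError("shift must lie in (0, FSR/2): adjacent orders would overlap")
    if linewidth_ghz < 0:
        raise ValueError("linewidth must be >= 0")
    freq = model.frequency_axis()
    w = linewidth_ghz + model.instrument_linewidth_ghz
    w = max(w, 1e-6)
    hw = w / 2.0
    trace = background + amplitude * (
        hw**2 / ((freq - shift_ghz) ** 2 + hw**2)
        + hw**2 / ((freq - (model.fsr_ghz - shift_ghz)) ** 2 + hw**2)
    )
    if poisson_noise:
        if rng is None:
            rng = np.random.default_rng()
        trace = rng.poisson(trace).astype(float)
    return SpectrumFrame(intensity=trace, position_um=position_um)


def simulate_brillouin_scan(
    truth: GroundTruth,
    model: SpectrometerModel,
    raster_shape: tuple[int, int] = (21, 21),
    amplitude: float = 1000.0,
    poisson_noise: bool = True,
    rng: np.random.Generator | None = None,
) -> list[SpectrumFrame]:
    """Raster-scan the phantom's central slice and simulate each spectrum.

    Scan positions cover the full lateral field of view on a
    ``raster_shape`` grid; the ground-truth shift/linewidth at the nearest
    tomogram pixel parameterizes each doublet.
    """
    if rng is None:
        rng = np.random.default_rng()
    ny_r, nx_r = raster_shape
    _, ny, nx = truth.ri.shape
    dy, dx = truth.spec.voxel_size_um[1], truth.spec.voxel_size_um[2]
    ys = np.linspace(0.5 * dy, (ny - 0.5) * dy, ny_r)
    xs = np.linspace(0.5 * dx, (nx - 0.5) * dx, nx_r)
    frames = []
    for yy in ys:
        for xx in xs:
            iy = min(int(yy / dy), ny - 1)
            ix = min(int(xx / dx), nx - 1)
            frames.append(
                simulate_vipa_spectrum(
                    truth.shift_map[iy, ix],
                    truth.linewidth_map[iy, ix],
                    model,
                    amplitude=amplitude,
                    poisson_noise=poisson_noise,
                    rng=rng,
                    position_um=(yy, xx),
                )
            )
    return frames


def simulate_calibration_frames(
    model: SpectrometerModel,
    shifts_ghz: tuple[float, ...] = DEFAULT_CALIBRATION_SHIFTS_GHZ,
    linewidth_ghz: float = 0.3,
    amplitude: float = 5000.0,
    poisson_noise: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[list[SpectrumFrame], list[float]]:
    """Simulate calibration doublets of reference materials with known shifts."""
    frames = [
        simulate_vipa_spectrum(
            s, linewidth_ghz, model, amplitude=amplitude,
            poisson_noise=poisson_noise, rng=rng,
        )
        for s in shifts_ghz
    ]
    return frames, list(shifts_ghz)
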