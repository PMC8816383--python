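"""Off-axis hologram field retrieval and phase unwrapping.

The camera records real-valued interference images with a tilted-reference
carrier.  The complex object field is recovered Fourier-side: transform the
hologram, crop the +1-order sideband around the carrier frequency, recenter
it at DC, transform back, and normalize by the identically processed
background (no-sample) hologram.  The result is the sample/background field
ratio — unit amplitude and zero phase wherever there is no sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import tukey

__all__ = ["HologramSet", "ComplexField", "retrieve_field", "unwrap_phase"]


@dataclass
class HologramSet:
    """Stack of off-axis holograms plus per-angle backgrounds.

    ``tilts_um`` holds the transverse illumination wavevector (ky, kx) in
    rad/um for each hologram.  ``carrier_cpp`` is the reference-carrier
    spatial frequency in cycles/pixel (y, x), measured relative to the
    transmitted illumination beam.  ``detector_offset_um`` is the distance
    from the volume center to the plane the fields are referenced to.
    """

    holograms: np.ndarray            # (n_angles, ny, nx) counts
    backgrounds: np.ndarray          # (n_angles, ny, nx) counts
    tilts_um: np.ndarray             # (n_angles, 2) rad/um
    carrier_cpp: tuple[float, float]
    pixel_pitch_um: float                # camera-grid pitch at the sample
    detector_offset_um: float = 0.0
    oversample: int = 1                  # camera grid / reconstruction grid
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.holograms = np.asarray(self.holograms, dtype=float)
        self.backgrounds = np.asarray(self.backgrounds, dtype=float)
        self.tilts_um = np.asarray(self.tilts_um, dtype=float)
        if self.holograms.shape != self.backgrounds.shape:
            raise ValueError("hologram and background stacks must share a shape")
        if self.holograms.ndim != 3:
            raise ValueError("hologram stack must be (n_angles, ny, nx)")
        if len(self.tilts_um) != len(self.holograms):
            raise ValueError("one illumination tilt per hologram required")
        if np.any(self.holograms < 0) or np.any(self.backgrounds < 0):
            raise ValueError("intensities must be >= 0")

    def __len__(self) -> int:
        return len(self.holograms)


@dataclass
class ComplexField:
    """Background-normalized complex object field for one illumination."""

    field: np.ndarray                # (ny, nx) complex, E_sample / E_background
    tilt_um: tuple[float, float]     # (ky, kx) rad/um of the illumination
    pixel_pitch_um: float
    detector_offset_um: float = 0.0

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=complex)
        if not np.all(np.isfinite(self.field)):
            raise ValueError("complex field must be finite")


def _carrier_bins(carrier_cpp: tuple[float, float], shape: tuple[int, int]) -> tuple[int, int]:
    return (int(round(carrier_cpp[0] * shape[0])), int(round(carrier_cpp[1] * shape[1])))


def _sideband_halfwidth(cbins: tuple[int, int], shape: tuple[int, int]) -> int:
    # largest rectangular half-width keeping the window clear of both the DC
    # term and the Nyquist edge, per axis
    hw = min(
        min(abs(c), n // 2 - abs(c)) for c, n in zip(cbins, shape)
    ) - 1
    return hw


def _extract_sideband(
    img: np.ndarray,
    cbins: tuple[int, int],
    hw: int,
    output_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """FFT, crop a (2hw+1)^2 window at the carrier, recenter at DC, IFFT.

    With ``output_shape`` the window is embedded into a smaller frequency
    frame, demodulating and decimating in one step (the camera grid may
    oversample the reconstruction grid).
    """
    spec = np.fft.fft2(img)
    ny, nx = img.shape
    if output_shape is None:
        output_shape = (ny, nx)
    oy_n, ox_n = output_shape
    if 2 * hw + 1 > min(oy_n, ox_n):
        raise ValueError("sideband window exceeds the output grid's Nyquist range")
    out = np.zeros(output_shape, dtype=complex)
    iy = (np.arange(-hw, hw + 1) + cbins[0]) % ny
    ix = (np.arange(-hw, hw + 1) + cbins[1]) % nx
    oy = np.arange(-hw, hw + 1) % oy_n
    ox = np.arange(-hw, hw + 1) % ox_n
    out[np.ix_(oy, ox)] = spec[np.ix_(iy, ix)]
    # keep amplitudes pitch-independent under decimation
    return np.fft.ifft2(out) * (oy_n * ox_n) / (ny * nx)


def detect_carrier(hologram: np.ndarray) -> tuple[int, int]:
    """Fallback carrier detection: the brightest non-DC spectral peak.

    Only the half-plane with positive x-frequency is searched so the +1
    order is selected deterministically.
    """
    spec = np.abs(np.fft.fft2(hologram))
    ny, nx = spec.shape
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    mask = (np.hypot(fy, fx) > 2.0 / min(ny, nx)) & (fx > 0)
    spec = np.where(mask, spec, 0.0)
    idx = np.unravel_index(np.argmax(spec), spec.shape)
    by = idx[0] if idx[0] <= ny // 2 else idx[0] - ny
    bx = idx[1] if idx[1] <= nx // 2 else idx[1] - nx
    return by, bx


def retrieve_field(
    hologram: np.ndarray,
    background: np.ndarray,
    carrier_cpp: tuple[float, float] | None,
    tilt_um: tuple[float, float] = (0.0, 0.0),
    pixel_pitch_um: float = 0.1,
    detector_offset_um: float = 0.0,
    apodize: bool = True,
    tukey_alpha: float = 0.1,
    output_shape: tuple[int, int] | None = None,
) -> ComplexField:
    """Retrieve the background-normalized complex field from one hologram.

    Parameters
    ----------
    carrier_cpp:
        Carrier spatial frequency in cycles/pixel (y, x); ``None`` enables
        automatic detection from the brightest non-DC sideband peak.
    apodize:
        Apply a 10% Tukey window before the FFT to suppress edge ringing
        (identical for sample and background, so flat-field ratios are
        unaffected).
    """
    hologram = np.asarray(hologram, dtype=float)
    background = np.asarray(background, dtype=float)
    if hologram.shape != background.shape:
        raise ValueError("hologram and background must share a shape")
    if background is None or background.size == 0:
        raise ValueError("missing background hologram")
    shape = hologram.shape
    if carrier_cpp is None:
        cbins = detect_carrier(hologram)
    else:
        cbins = _carrier_bins(carrier_cpp, shape)
    hw = _sideband_halfwidth(cbins, shape)
    if hw < 2:
        raise ValueError(
            f"sideband window overlaps the DC autocorrelation term "
            f"(carrier bins {cbins}, half-width {hw}); increase the carrier frequency"
        )
    if apodize:
        win = np.outer(tukey(shape[0], tukey_alpha), tukey(shape[1], tukey_alpha))
        hologram = hologram * win
        background = background * win
    f_s = _extract_sideband(hologram, cbins, hw, output_shape)
    f_b = _extract_sideband(background, cbins, hw, output_shape)
    small = np.abs(f_b) < 1e-12 * np.abs(f_b).max()
    f_b = np.where(small, 1.0, f_b)
    ratio = np.where(small, 1.0, f_s / f_b)
    if output_shape is not None:
        pixel_pitch_um = pixel_pitch_um * shape[1] / output_shape[1]
    return ComplexField(
        field=ratio,
        tilt_um=tuple(tilt_um),
        pixel_pitch_um=pixel_pitch_um,
        detector_offset_um=detector_offset_um,
    )


def retrieve_fields(hset: HologramSet, **kwargs) -> list[ComplexField]:
    """Retrieve all fields of a :class:`HologramSet`, decimating the camera
    oversampling back to the reconstruction grid."""
    ny, nx = hset.holograms.shape[1:]
    f = hset.oversample
    kwargs.setdefault("output_shape", (ny // f, nx // f) if f > 1 else None)
    return [
        retrieve_field(
            hset.holograms[i],
            hset.backgrounds[i],
            hset.carrier_cpp,
            tilt_um=tuple(hset.tilts_um[i]),
            pixel_pitch_um=hset.pixel_pitch_um,
            detector_offset_um=hset.detector_offset_um,
            **kwargs,
        )
        for i in range(len(hset))
    ]


def unwrap_phase(field: ComplexField | np.ndarray) -> np.ndarray:
    """Unwrap the 2-D phase of a complex field (or a wrapped phase map).

    Uses reliability-sorted (quality-guided) unwrapping.  The output is
    congruent to the wrapped input modulo 2*pi at every pixel; the global
    2*pi offset is anchored so the corner pixel keeps its wrapped value
    (the image border is sample-free background in this instrument).
    """
    from skimage.restoration import unwrap_phase as _unwrap

    if isinstance(field, ComplexField):
        wrapped = np.angle(field.field)
    else:
        wrapped = np.asarray(field, dtype=float)
        if np.iscomplexobj(field):
            wrapped = np.angle(field)
    if not np.all(np.isfinite(wrapped)):
        raise ValueError("phase must be finite")
    unwrapped = np.asarray(_unwrap(wrapped))
    offset = 2 * np.pi * np.round((unwrapped[0, 0] - wrapped[0, 0]) / (2 * np.pi))
    return unwrapped - offset
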