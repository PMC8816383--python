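"""VIPA Brillouin spectrometer: calibration and shift/linewidth extraction.

A two-stage VIPA spectrometer disperses the Brillouin spectrum onto a camera
line.  Within one free spectral range (FSR, 30 GHz here) the visible doublet
consists of the anti-Stokes peak of one diffraction order and the Stokes
peak of the adjacent order, so the doublet separation on the frequency axis
is ``FSR - 2 * shift``.  The Brillouin shift is therefore estimated from the
separation alone, which makes it immune to absolute calibration offsets.

Peaks are Lorentzian; the instrument response (~350 MHz FWHM) is treated as
Lorentzian too, so the measured width is the sum of sample and instrument
widths and the sample linewidth is recovered by simple subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, medfilt

__all__ = [
    "SpectrometerModel",
    "SpectrumFrame",
    "BrillouinPoint",
    "BrillouinMap",
    "calibrate_spectrometer",
    "fit_spectrum",
    "assemble_map",
]


@dataclass(frozen=True)
class SpectrometerModel:
    """Pixel-to-frequency model of the VIPA spectrometer.

    ``dispersion`` are polynomial coefficients (ascending powers) mapping
    pixel index to GHz; the default is mildly quadratic.  The map must be
    strictly monotonic over the valid pixel window ``[0, n_pixels)``.
    """

    fsr_ghz: float = 30.0
    instrument_linewidth_ghz: float = 0.35
    dispersion: tuple[float, ...] = (0.0, 0.072, 1.2e-5)
    n_pixels: int = 400
    calibration_residual_ghz: float | None = None

    def __post_init__(self) -> None:
        if self.fsr_ghz <= 0:
            raise ValueError("FSR must be positive")
        if self.instrument_linewidth_ghz < 0:
            raise ValueError("instrument linewidth must be >= 0")
        if self.n_pixels < 4:
            raise ValueError("pixel window too small")
        if not self._monotonic():
            raise ValueError("dispersion must be strictly monotonic over the pixel window")

    def _monotonic(self) -> bool:
        p = np.arange(self.n_pixels)
        f = self.pixel_to_ghz(p)
        d = np.diff(f)
        return bool(np.all(d > 0) or np.all(d < 0))

    def pixel_to_ghz(self, pixel: np.ndarray | float) -> np.ndarray | float:
        return np.polynomial.polynomial.polyval(pixel, np.asarray(self.dispersion))

    def frequency_axis(self) -> np.ndarray:
        """Frequency (GHz) at each pixel of the valid window."""
        return np.asarray(self.pixel_to_ghz(np.arange(self.n_pixels)), dtype=float)


@dataclass
class SpectrumFrame:
    """One camera readout of the spectrometer at one scan position."""

    intensity: np.ndarray                 # (n_pixels,) counts
    position_um: tuple[float, float] = (0.0, 0.0)   # (y, x)
    exposure_s: float = 0.5
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 1:
            raise ValueError("spectrum must be 1-D")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")


@dataclass
class BrillouinPoint:
    """Fitted Brillouin observables at one scan position."""

    shift_ghz: float
    linewidth_ghz: float
    residual: float
    valid: bool
    position_um: tuple[float, float] = (0.0, 0.0)
    raw_fwhm_ghz: float = float("nan")


@dataclass
class BrillouinMap:
    """Brillouin shift / linewidth gridded on the scan raster."""

    shift_ghz: np.ndarray       # (ny, nx)
    linewidth_ghz: np.ndarray   # (ny, nx)
    valid: np.ndarray           # (ny, nx) bool
    y_um: np.ndarray            # (ny,)
    x_um: np.ndarray            # (nx,)

    @property
    def shape(self) -> tuple[int, int]:
        return self.shift_ghz.shape


def _lorentzian(f, amp, center, fwhm):
    hw = fwhm / 2.0
    return amp * hw**2 / ((f - center) ** 2 + hw**2)


def _doublet(f, a1, c1, w1, a2, c2, w2, offset):
    return _lorentzian(f, a1, c1, w1) + _lorentzian(f, a2, c2, w2) + offset


def _detect_doublet(trace: np.ndarray, prior_sep_px: float | None = None) -> tuple[int, int] | None:
    """Return the pixel indices of the doublet peaks, or None."""
    smooth = medfilt(trace, 3)
    floor = np.median(smooth)
    prom = 0.1 * (smooth.max() - floor)
    if prom <= 0:
        return None
    peaks, props = find_peaks(smooth, prominence=prom)
    if len(peaks) < 2:
        return None
    order = np.argsort(props["prominences"])[::-1]
    if len(peaks) == 2 or prior_sep_px is None:
        chosen = sorted(peaks[order[:2]])
        return chosen[0], chosen[1]
    # more than two candidates: take the pair closest to the expected separation
    cand = peaks[order[: min(len(peaks), 5)]]
    best, best_err = None, np.inf
    for i in range(len(cand)):
        for j in range(i + 1, len(cand)):
            err = abs(abs(cand[j] - cand[i]) - prior_sep_px)
            if err < best_err:
                best, best_err = (min(cand[i], cand[j]), max(cand[i], cand[j])), err
    return best


def fit_spectrum(
    frame: SpectrumFrame,
    model: SpectrometerModel,
    prior_shift_ghz: float = 7.5,
    deconvolve: bool = True,
) -> BrillouinPoint:
    """Fit the Stokes/anti-Stokes doublet of one spectrum frame.

    The doublet is fitted with two Lorentzians plus a constant background on
    the calibrated frequency axis.  The shift is computed from the doublet
    separation, ``(FSR - separation) / 2``; the linewidth is the mean fitted
    FWHM, with the instrument linewidth subtracted when ``deconvolve`` is on
    (floored at zero).  Low-SNR fits are flagged invalid, not raised.
    """
    trace = frame.intensity
    if len(trace) != model.n_pixels:
        raise ValueError("frame length does not match the model's pixel window")
    freq = model.frequency_axis()
    dghz_dpx = abs(np.polynomial.polynomial.polyval(
        model.n_pixels / 2, np.polynomial.polynomial.polyder(np.asarray(model.dispersion))
    ))
    prior_sep_px = (model.fsr_ghz - 2 * prior_shift_ghz) / dghz_dpx

    invalid = BrillouinPoint(
        shift_ghz=float("nan"), linewidth_ghz=float("nan"),
        residual=float("nan"), valid=False, position_um=frame.position_um,
    )
    det = _detect_doublet(trace, prior_sep_px)
    if det is None:
        return invalid
    p1, p2 = det
    f1, f2 = freq[p1], freq[p2]
    off0 = float(np.median(trace))
    w0 = max(2.5 * dghz_dpx, model.instrument_linewidth_ghz)
    p0 = [max(trace[p1] - off0, 1e-6), f1, w0, max(trace[p2] - off0, 1e-6), f2, w0, off0]
    lo = [0, freq.min(), dghz_dpx * 0.2, 0, freq.min(), dghz_dpx * 0.2, 0]
    hi = [np.inf, freq.max(), model.fsr_ghz, np.inf, freq.max(), model.fsr_ghz, np.inf]
    try:
        popt, _ = curve_fit(_doublet, freq, trace, p0=p0, bounds=(lo, hi), maxfev=20000)
    except RuntimeError:
        return invalid
    a1, c1, w1, a2, c2, w2, off = popt
    resid = trace - _doublet(freq, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    separation = abs(c2 - c1)
    shift = (model.fsr_ghz - separation) / 2.0
    raw_fwhm = (w1 + w2) / 2.0
    lw = raw_fwhm - model.instrument_linewidth_ghz if deconvolve else raw_fwhm
    lw = max(lw, 0.0)
    snr_ok = min(a1, a2) >= 5.0 * rms if rms > 0 else True
    valid = bool(snr_ok and 0.0 < shift < model.fsr_ghz / 2.0)
    return BrillouinPoint(
        shift_ghz=float(shift),
        linewidth_ghz=float(lw),
        residual=rms,
        valid=valid,
        position_um=frame.position_um,
        raw_fwhm_ghz=float(raw_fwhm),
    )


def _peak_pixel_subpx(trace: np.ndarray, peak_px: int, half: int = 6) -> float:
    """Subpixel peak position from a local Lorentzian fit in pixel space."""
    lo = max(peak_px - half, 0)
    hi = min(peak_px + half + 1, len(trace))
    x = np.arange(lo, hi, dtype=float)
    y = trace[lo:hi]
    off0 = float(y.min())

    def single(px, amp, center, fwhm, off):
        return _lorentzian(px, amp, center, fwhm) + off

    p0 = [max(y.max() - off0, 1e-6), float(peak_px), 3.0, off0]
    try:
        popt, _ = curve_fit(single, x, y, p0=p0, maxfev=10000)
        center = float(popt[1])
    except RuntimeError:
        center = float(peak_px)
    if not lo <= center <= hi:
        center = float(peak_px)
    return center


def calibrate_spectrometer(
    frames: list[SpectrumFrame],
    known_shifts_ghz: list[float],
    template: SpectrometerModel | None = None,
    degree: int = 2,
    use_fsr_constraint: bool = True,
) -> SpectrometerModel:
    """Fit the pixel-to-frequency dispersion from calibration spectra.

    Each calibration frame is a doublet of a material with known Brillouin
    shift.  The anti-Stokes peak sits at frequency ``shift`` and the Stokes
    peak of the neighbouring order at ``FSR - shift`` (the FSR constraint),
    giving two (pixel, GHz) support points per frame.  A polynomial of the
    requested degree is least-squares fitted through all points.

    Raises ``ValueError`` when the fit is under-determined or the fitted
    dispersion is not monotonic over the pixel window.
    """
    if template is None:
        template = SpectrometerModel()
    if len(frames) != len(known_shifts_ghz):
        raise ValueError("one known shift per calibration frame required")
    px_pts: list[float] = []
    f_pts: list[float] = []
    for frame, shift in zip(frames, known_shifts_ghz):
        if not 0 < shift < template.fsr_ghz / 2:
            raise ValueError("calibration shifts must lie in (0, FSR/2)")
        det = _detect_doublet(frame.intensity)
        if det is None:
            raise ValueError("calibration doublet not detectable")
        p_lo, p_hi = det
        px_pts.append(_peak_pixel_subpx(frame.intensity, p_lo))
        f_pts.append(shift)
        if use_fsr_constraint:
            px_pts.append(_peak_pixel_subpx(frame.intensity, p_hi))
            f_pts.append(template.fsr_ghz - shift)
    if len(px_pts) < degree + 1:
        raise ValueError(
            f"under-determined calibration: {len(px_pts)} support points for "
            f"a degree-{degree} dispersion (need {degree + 1})"
        )
    coeffs = np.polynomial.polynomial.polyfit(px_pts, f_pts, degree)
    fitted = np.polynomial.polynomial.polyval(np.asarray(px_pts), coeffs)
    residual = float(np.sqrt(np.mean((fitted - np.asarray(f_pts)) ** 2)))
    model = SpectrometerModel(
        fsr_ghz=template.fsr_ghz,
        instrument_linewidth_ghz=template.instrument_linewidth_ghz,
        dispersion=tuple(float(c) for c in coeffs),
        n_pixels=template.n_pixels,
        calibration_residual_ghz=residual,
    )
    return model


def assemble_map(points: list[BrillouinPoint], atol_um: float = 1e-6) -> BrillouinMap:
    """Grid fitted points onto their rectilinear scan raster.

    Raster axes are inferred from the unique scan positions.  Missing raster
    cells are marked invalid — never interpolated.  Duplicate positions are
    rejected.
    """
    if not points:
        raise ValueError("no points to assemble")
    pos = np.array([p.position_um for p in points], dtype=float)
    y_ax = np.unique(np.round(pos[:, 0] / atol_um) * atol_um)
    x_ax = np.unique(np.round(pos[:, 1] / atol_um) * atol_um)
    ny, nx = len(y_ax), len(x_ax)
    shift = np.full((ny, nx), np.nan)
    width = np.full((ny, nx), np.nan)
    valid = np.zeros((ny, nx), dtype=bool)
    seen = np.zeros((ny, nx), dtype=bool)
    for p in points:
        iy = int(np.argmin(np.abs(y_ax - p.position_um[0])))
        ix = int(np.argmin(np.abs(x_ax - p.position_um[1])))
        if seen[iy, ix]:
            raise ValueError(f"duplicate scan position {p.position_um}")
        seen[iy, ix] = True
        shift[iy, ix] = p.shift_ghz
        width[iy, ix] = p.linewidth_ghz
        valid[iy, ix] = p.valid
    return BrillouinMap(shift_ghz=shift, linewidth_ghz=width, valid=valid, y_um=y_ax, x_um=x_ax)
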