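"""Co-registration of the Brillouin map with the RI central slice.

The Brillouin raster is coarser than the tomogram pixel grid, so the map is
first resampled (nearest neighbour — values are never interpolated across
invalid cells) onto the RI pixel pitch.  Normalized cross-correlation is
then evaluated over integer shifts within a search radius; the arg-max shift
is refined by quadratic peak interpolation.  A peak correlation below the
floor flags the registration unreliable and falls back to the identity
shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .brillouin import BrillouinMap

__all__ = ["RegistrationResult", "register_maps", "resample_to_grid"]


@dataclass
class RegistrationResult:
    shift_px: tuple[float, float]     # (dy, dx) applied to the moving map
    correlation: float
    reliable: bool
    aligned: np.ndarray               # moving map shifted by the integer part
    aligned_valid: np.ndarray


def resample_to_grid(
    bmap: BrillouinMap,
    grid_shape: tuple[int, int],
    pixel_pitch_um: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-neighbour resampling of a Brillouin map onto a pixel grid.

    Returns (values, valid) on ``grid_shape``.  Pixels whose nearest scan
    point is invalid (or farther than one raster step) stay invalid.
    """
    ny, nx = grid_shape
    yc = (np.arange(ny) + 0.5) * pixel_pitch_um
    xc = (np.arange(nx) + 0.5) * pixel_pitch_um
    iy = np.argmin(np.abs(yc[:, None] - bmap.y_um[None, :]), axis=1)
    ix = np.argmin(np.abs(xc[:, None] - bmap.x_um[None, :]), axis=1)
    vals = bmap.shift_ghz[np.ix_(iy, ix)]
    valid = bmap.valid[np.ix_(iy, ix)]
    step_y = np.median(np.diff(bmap.y_um)) if len(bmap.y_um) > 1 else np.inf
    step_x = np.median(np.diff(bmap.x_um)) if len(bmap.x_um) > 1 else np.inf
    near_y = np.abs(yc - bmap.y_um[iy]) <= step_y
    near_x = np.abs(xc - bmap.x_um[ix]) <= step_x
    valid = valid & near_y[:, None] & near_x[None, :]
    return vals, valid


def _ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Pearson correlation of two images over a common mask."""
    if mask.sum() < 8:
        return -1.0
    av = a[mask] - a[mask].mean()
    bv = b[mask] - b[mask].mean()
    denom = np.sqrt((av**2).sum() * (bv**2).sum())
    if denom == 0:
        return 0.0
    return float((av * bv).sum() / denom)


def register_maps(
    moving: np.ndarray,
    reference: np.ndarray,
    search_radius_px: int = 10,
    moving_valid: np.ndarray | None = None,
    correlation_floor: float = 0.2,
) -> RegistrationResult:
    """Register a (resampled) Brillouin map onto the RI central slice.

    Correlation is computed over all integer shifts within
    ``search_radius_px``; only pixels valid in the (shifted) moving map and
    inside the overlap region contribute.  The best integer shift is refined
    to subpixel precision by fitting a quadratic through the correlation
    peak and its neighbours (skipped when the peak is an exact match).
    """
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape:
        raise ValueError("moving and reference maps must share a shape")
    if moving_valid is None:
        moving_valid = np.isfinite(moving)
    ny, nx = moving.shape
    r = int(search_radius_px)
    if ny <= 2 * r + 2 or nx <= 2 * r + 2:
        raise ValueError("maps too small for the requested search radius")
    shifts = range(-r, r + 1)
    # fixed central comparison region: the same reference pixels enter the
    # correlation at every shift, keeping the correlation curve symmetric
    interior = np.zeros((ny, nx), dtype=bool)
    interior[r:ny - r, r:nx - r] = True
    corr = np.full((2 * r + 1, 2 * r + 1), -np.inf)
    for i, dy in enumerate(shifts):
        for j, dx in enumerate(shifts):
            shifted = np.roll(np.roll(moving, dy, axis=0), dx, axis=1)
            svalid = np.roll(np.roll(moving_valid, dy, axis=0), dx, axis=1)
            corr[i, j] = _ncc(shifted, reference, svalid & interior)
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    peak_corr = float(corr[peak])
    dy_int = peak[0] - r
    dx_int = peak[1] - r

    def _subpx(c_m: float, c_0: float, c_p: float) -> float:
        denom = c_m - 2 * c_0 + c_p
        if denom >= 0 or not np.isfinite(denom):
            return 0.0
        return float(np.clip(0.5 * (c_m - c_p) / denom, -0.5, 0.5))

    frac = (0.0, 0.0)
    if peak_corr < 0.999 and 0 < peak[0] < 2 * r and 0 < peak[1] < 2 * r:
        fy = _subpx(corr[peak[0] - 1, peak[1]], peak_corr, corr[peak[0] + 1, peak[1]])
        fx = _subpx(corr[peak[0], peak[1] - 1], peak_corr, corr[peak[0], peak[1] + 1])
        frac = (fy, fx)

    reliable = peak_corr >= correlation_floor
    if not reliable:
        dy_int, dx_int, frac = 0, 0, (0.0, 0.0)
        import warnings

        warnings.warn(
            f"registration peak correlation {peak_corr:.3f} below floor "
            f"{correlation_floor}; identity shift applied",
            stacklevel=2,
        )
    aligned = np.roll(np.roll(moving, dy_int, axis=0), dx_int, axis=1)
    aligned_valid = np.roll(np.roll(moving_valid, dy_int, axis=0), dx_int, axis=1)
    if dy_int > 0:
        aligned_valid[:dy_int, :] = False
    elif dy_int < 0:
        aligned_valid[dy_int:, :] = False
    if dx_int > 0:
        aligned_valid[:, :dx_int] = False
    elif dx_int < 0:
        aligned_valid[:, dx_int:] = False
    return RegistrationResult(
        shift_px=(dy_int + frac[0], dx_int + frac[1]),
        correlation=peak_corr,
        reliable=reliable,
        aligned=aligned,
        aligned_valid=aligned_valid,
    )
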