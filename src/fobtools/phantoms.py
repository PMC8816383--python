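"""Digital phantoms with known ground truth.

A phantom is a list of geometric primitives (spheres / ellipsoids) carrying a
refractive index, a ground-truth Brillouin shift and linewidth, an integer
compartment label and optionally a fluorescence channel.  Voxelizing a
phantom yields the 3-D RI and label fields plus the central-slice Brillouin
ground truth, which seed every synthetic raw-data simulator in
:mod:`fobtools.forward`.

Preset builders emulate the validation bead phantom (a PDMS bead embedded in
a larger PAA bead) and a simple cell with nucleus, nucleolus and an optional
lipid droplet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Primitive",
    "PhantomSpec",
    "GroundTruth",
    "build_phantom",
    "simulate_fluorescence",
    "bead_phantom_spec",
    "cell_phantom_spec",
]


@dataclass(frozen=True)
class Primitive:
    """One ellipsoidal inclusion of a phantom.

    ``center_um`` and ``radii_um`` are (z, y, x) triplets in micrometres; a
    sphere is an ellipsoid with equal radii.  ``shift_ghz``/``linewidth_ghz``
    are the ground-truth Brillouin observables of the material.
    """

    center_um: tuple[float, float, float]
    radii_um: tuple[float, float, float]
    n: float
    shift_ghz: float
    linewidth_ghz: float
    label: int
    channel: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("refractive index must be >= 1")
        if any(r <= 0 for r in self.radii_um):
            raise ValueError("radii must be positive")
        if self.label <= 0:
            raise ValueError("labels are positive integers")
        if self.linewidth_ghz < 0:
            raise ValueError("linewidth must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative phantom: grid, medium and primitives.

    Later-listed primitives overwrite earlier ones where they overlap, so a
    nucleolus listed after its nucleus carves its own region out of it.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_um: tuple[float, float, float] = (0.1, 0.1, 0.1)
    n_medium: float = 1.337
    medium_shift_ghz: float = 7.46
    medium_linewidth_ghz: float = 0.30
    primitives: tuple[Primitive, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_medium < 1:
            raise ValueError("medium RI must be >= 1")
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid shape must be positive")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel size must be positive")
        labels = [p.label for p in self.primitives]
        if len(set(labels)) != len(labels):
            raise ValueError("compartment labels must be unique")
        extent = tuple(n * v for n, v in zip(self.grid_shape, self.voxel_size_um))
        for p in self.primitives:
            for c, r, ext in zip(p.center_um, p.radii_um, extent):
                if c - r < 0 or c + r > ext:
                    raise ValueError(
                        f"primitive {p.name or p.label} extends outside the grid "
                        f"(center {p.center_um} um, radii {p.radii_um} um, extent {extent} um)"
                    )

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(n * v for n, v in zip(self.grid_shape, self.voxel_size_um))

    def label_table(self) -> dict[int, Primitive]:
        return {p.label: p for p in self.primitives}


@dataclass
class GroundTruth:
    """Voxelized phantom: what the instrument would ideally measure."""

    spec: PhantomSpec
    ri: np.ndarray          # (nz, ny, nx) refractive index
    labels: np.ndarray      # (nz, ny, nx) integer labels, 0 = background
    shift_map: np.ndarray   # (ny, nx) Brillouin shift of the central slice, GHz
    linewidth_map: np.ndarray  # (ny, nx) Brillouin linewidth of the central slice, GHz

    @property
    def central_slice(self) -> np.ndarray:
        """Central-plane RI slice (the Brillouin focal plane)."""
        return self.ri[self.ri.shape[0] // 2]


def build_phantom(spec: PhantomSpec) -> GroundTruth:
    """Voxelize a :class:`PhantomSpec` into RI / label / Brillouin fields.

    A voxel belongs to a primitive when its center lies inside the
    ellipsoid; later primitives overwrite earlier ones.
    """
    nz, ny, nx = spec.grid_shape
    dz, dy, dx = spec.voxel_size_um
    # voxel centers
    z = (np.arange(nz) + 0.5) * dz
    y = (np.arange(ny) + 0.5) * dy
    x = (np.arange(nx) + 0.5) * dx

    ri = np.full(spec.grid_shape, spec.n_medium, dtype=float)
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    shift = np.full((ny, nx), spec.medium_shift_ghz, dtype=float)
    width = np.full((ny, nx), spec.medium_linewidth_ghz, dtype=float)

    zz = z[:, None, None]
    yy = y[None, :, None]
    xx = x[None, None, :]
    z_mid = nz // 2
    for p in spec.primitives:
        cz, cy, cx = p.center_um
        rz, ry, rx = p.radii_um
        mask = (
            ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
        ) <= 1.0
        ri[mask] = p.n
        labels[mask] = p.label
        sl = mask[z_mid]
        shift[sl] = p.shift_ghz
        width[sl] = p.linewidth_ghz

    return GroundTruth(spec=spec, ri=ri, labels=labels, shift_map=shift, linewidth_map=width)


def simulate_fluorescence(
    truth: GroundTruth,
    channels: dict[str, list[int]] | None = None,
    psf_sigma_px: float = 1.5,
    noise: float = 0.02,
    saturation: float = 1.0,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Simulate widefield fluorescence channel images.

    Each channel is the through-stack projection of the indicator of its
    assigned labels, blurred with a Gaussian PSF of ``psf_sigma_px`` and
    degraded with additive Gaussian noise of standard deviation ``noise``
    (relative to the saturation level), clipped to ``[0, saturation]``.

    ``channels`` maps channel name -> list of label ids; by default channels
    are collected from the primitives' ``channel`` attributes.
    """
    from scipy.ndimage import gaussian_filter

    if psf_sigma_px < 0:
        raise ValueError("psf sigma must be >= 0")
    if rng is None:
        rng = np.random.default_rng()
    declared = {p.label for p in truth.spec.primitives}
    if channels is None:
        channels = {}
        for p in truth.spec.primitives:
            if p.channel is not None:
                channels.setdefault(p.channel, []).append(p.label)
    images: dict[str, np.ndarray] = {}
    for name, labs in channels.items():
        unknown = set(labs) - declared
        if unknown:
            raise ValueError(f"channel {name!r} references undeclared labels {sorted(unknown)}")
        indicator = np.isin(truth.labels, labs)
        img = indicator.any(axis=0).astype(float)
        if psf_sigma_px > 0:
            img = gaussian_filter(img, psf_sigma_px)
        if noise > 0:
            img = img + rng.normal(0.0, noise * saturation, size=img.shape)
        images[name] = np.clip(img, 0.0, saturation)
    return images


def bead_phantom_spec(
    grid_shape: tuple[int, int, int] = (64, 64, 64),
    voxel_size_um: tuple[float, float, float] = (0.15, 0.15, 0.15),
    n_medium: float = 1.337,
) -> PhantomSpec:
    """Validation phantom: a stiff silicone (PDMS) bead inside a larger
    polyacrylamide (PAA) bead, fluorescently labeled on the PAA matrix.

    Material values are the measured means of the real phantom: PDMS
    n = 1.3920, shift 7.279 GHz; PAA n = 1.3485, shift 7.574 GHz.
    """
    nz, ny, nx = grid_shape
    dz, dy, dx = voxel_size_um
    center = ((nz / 2) * dz, (ny / 2) * dy, (nx / 2) * dx)
    r_paa = 0.35 * min(nz * dz, ny * dy, nx * dx)
    r_pdms = 0.4 * r_paa
    paa = Primitive(
        center_um=center,
        radii_um=(r_paa,) * 3,
        n=1.3485,
        shift_ghz=7.574,
        linewidth_ghz=0.60,
        label=1,
        channel="alexa488",
        name="paa_bead",
    )
    pdms = Primitive(
        center_um=center,
        radii_um=(r_pdms,) * 3,
        n=1.3920,
        shift_ghz=7.279,
        linewidth_ghz=0.80,
        label=2,
        channel=None,
        name="pdms_bead",
    )
    return PhantomSpec(
        grid_shape=grid_shape,
        voxel_size_um=voxel_size_um,
        n_medium=n_medium,
        primitives=(paa, pdms),
    )


def cell_phantom_spec(
    grid_shape: tuple[int, int, int] = (64, 96, 96),
    voxel_size_um: tuple[float, float, float] = (0.15, 0.15, 0.15),
    n_medium: float = 1.337,
    with_lipid_droplet: bool = False,
) -> PhantomSpec:
    """Cell-like phantom: cytoplasm, nucleus (nucleoplasm), nucleolus and
    optionally a lipid droplet, with RI / Brillouin values set to the
    measured HeLa (and adipocyte droplet) compartment means.
    """
    nz, ny, nx = grid_shape
    dz, dy, dx = voxel_size_um
    cz, cy, cx = (nz / 2) * dz, (ny / 2) * dy, (nx / 2) * dx
    r_cell = 0.40 * min(ny * dy, nx * dx)
    rz_cell = min(0.35 * nz * dz, 0.8 * r_cell)
    prims = [
        Primitive((cz, cy, cx), (rz_cell, r_cell, r_cell), 1.3545, 7.811, 0.85,
                  label=1, channel=None, name="cytoplasm"),
        Primitive((cz, cy - 0.25 * r_cell, cx - 0.2 * r_cell),
                  (0.55 * rz_cell, 0.45 * r_cell, 0.45 * r_cell),
                  1.3522, 7.872, 0.85, label=2, channel="hoechst", name="nucleus"),
        Primitive((cz, cy - 0.25 * r_cell, cx - 0.2 * r_cell),
                  (0.22 * rz_cell, 0.16 * r_cell, 0.16 * r_cell),
                  1.3618, 7.938, 1.00, label=3, channel="gfp", name="nucleolus"),
    ]
    if with_lipid_droplet:
        prims.append(
            Primitive((cz, cy + 0.4 * r_cell, cx + 0.35 * r_cell),
                      (0.3 * rz_cell, 0.2 * r_cell, 0.2 * r_cell),
                      1.409, 8.25, 1.10, label=4, channel="nilered", name="lipid_droplet")
        )
    return PhantomSpec(
        grid_shape=grid_shape,
        voxel_size_um=voxel_size_um,
        n_medium=n_medium,
        primitives=tuple(prims),
    )
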