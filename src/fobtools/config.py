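"""Validated run configuration.

A :class:`RunConfig` describes one simulated acquisition plus all
processing parameters.  It is validated strictly (unknown keys rejected)
before any stage runs, and can be loaded from YAML or JSON.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field

from .geometry import AcquisitionGeometry
from .mechanics import MaterialModel
from .phantoms import PhantomSpec, Primitive
from .segment import SegmentationRule

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    wavelength_nm: float = 532.0
    n_medium: float = 1.337
    na_illumination: float = 1.0
    na_detection: float = 1.2
    theta_deg: float = 0.0
    pixel_pitch_um: float = 0.1
    axial_pitch_um: float = 0.1

    def build(self) -> AcquisitionGeometry:
        return AcquisitionGeometry(**self.model_dump())


class PrimitiveConfig(_Strict):
    center_um: tuple[float, float, float]
    radii_um: tuple[float, float, float]
    n: float
    shift_ghz: float
    linewidth_ghz: float
    label: int
    channel: str | None = None
    name: str = ""

    def build(self) -> Primitive:
        return Primitive(**self.model_dump())


class PhantomConfig(_Strict):
    preset: str | None = None            # "bead" | "cell" | None (explicit)
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_um: tuple[float, float, float] = (0.1, 0.1, 0.1)
    n_medium: float = 1.337
    medium_shift_ghz: float = 7.46
    medium_linewidth_ghz: float = 0.30
    primitives: list[PrimitiveConfig] = Field(default_factory=list)

    def build(self) -> PhantomSpec:
        from . import phantoms

        if self.preset == "bead":
            return phantoms.bead_phantom_spec(
                grid_shape=self.grid_shape,
                voxel_size_um=self.voxel_size_um,
                n_medium=self.n_medium,
            )
        if self.preset == "cell":
            return phantoms.cell_phantom_spec(
                grid_shape=self.grid_shape,
                voxel_size_um=self.voxel_size_um,
                n_medium=self.n_medium,
            )
        if self.preset is not None:
            raise ValueError(f"unknown phantom preset {self.preset!r}")
        return PhantomSpec(
            grid_shape=self.grid_shape,
            voxel_size_um=self.voxel_size_um,
            n_medium=self.n_medium,
            medium_shift_ghz=self.medium_shift_ghz,
            medium_linewidth_ghz=self.medium_linewidth_ghz,
            primitives=tuple(p.build() for p in self.primitives),
        )


class SimulationConfig(_Strict):
    seed: int = 0
    n_angles: int = 60
    na_fraction: float = 0.8
    hologram_mode: str = "multislice"
    hologram_noise: float = 0.0
    carrier_cpp: tuple[float, float] = (0.125, 0.125)
    brillouin_raster: tuple[int, int] = (21, 21)
    spectrum_amplitude: float = 1000.0
    fluorescence_psf_sigma_px: float = 1.5
    fluorescence_noise: float = 0.02


class ReconstructionConfig(_Strict):
    iterations: int = 100
    approximation: str = "rytov"


class BrillouinConfig(_Strict):
    calibration_shifts_ghz: tuple[float, ...] = (5.09, 7.43)
    fsr_ghz: float = 30.0
    instrument_linewidth_ghz: float = 0.35
    n_pixels: int = 400
    prior_shift_ghz: float = 7.5
    deconvolve: bool = True


class RuleConfig(_Strict):
    name: str
    label: int
    source: str
    within: str | None = None
    material: str = "two_substance"

    def build(self) -> SegmentationRule:
        return SegmentationRule(**self.model_dump())


class MaterialConfig(_Strict):
    mode: str = "two_substance_full"
    alpha_ml_g: float = 0.190
    n_fluid: float = 1.337
    rho_fluid_g_ml: float = 1.000
    v_dry_ml_g: float = 0.73
    rho_dry_g_ml: float = 1.35
    rho_lit_g_ml: float | None = None

    def build(self) -> MaterialModel:
        return MaterialModel(**self.model_dump())


class StatsConfig(_Strict):
    bonferroni: bool = False
    remove_outliers: bool = False


class RunConfig(_Strict):
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    reconstruction: ReconstructionConfig = Field(default_factory=ReconstructionConfig)
    brillouin: BrillouinConfig = Field(default_factory=BrillouinConfig)
    segmentation_rules: list[RuleConfig] = Field(default_factory=list)
    registration_search_radius_px: int = 10
    materials: dict[str, MaterialConfig] = Field(default_factory=dict)
    stats: StatsConfig = Field(default_factory=StatsConfig)


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)
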