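"""Pipeline stages operating on the HDF5 container.

Each stage reads one container, computes one derived group and writes it
back with units and provenance.  The stages correspond to the acquisitions
and processing steps of the combined microscope:

``simulate`` -> raw holograms, fluorescence, Brillouin spectra (+ /truth)
``reconstruct`` -> /ri (RI tomogram)
``evaluate_brillouin`` -> /brillouin/{shift, linewidth, valid}
``segment`` -> /labels
``compute_modulus`` -> /maps/{density, concentration, modulus}
``compute_stats`` -> per-compartment summary table (DataFrame / CSV)

All randomness flows from ``config.simulation.seed``; rerunning a stage
with the same config and seed reproduces its outputs bit for bit.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd

from . import container as cio
from .brillouin import SpectrometerModel, assemble_map, calibrate_spectrometer, fit_spectrum
from .config import RunConfig
from .forward import (
    circle_tilts,
    simulate_brillouin_scan,
    simulate_calibration_frames,
    simulate_fluorescence_channels,
    simulate_hologram_set,
)
from .holography import HologramSet, retrieve_fields
from .mechanics import (
    DEFAULT_MATERIALS,
    compartment_stats,
    concentration_from_ri,
    density_from_ri,
    longitudinal_modulus,
)
from .odt import reconstruct_tomogram
from .phantoms import build_phantom
from .register import register_maps, resample_to_grid
from .segment import DEFAULT_RULES, CompartmentLabels, segment_cells, segment_compartments

__all__ = [
    "simulate",
    "reconstruct",
    "evaluate_brillouin",
    "segment",
    "compute_modulus",
    "compute_stats",
    "export_report",
    "run_all",
]

log = logging.getLogger("fobtools")


def _log_stage(name: str, **params) -> None:
    log.info("stage=%s %s", name, json.dumps(params, default=str, sort_keys=True))


def simulate(config: RunConfig, path) -> None:
    """Simulate a full raw acquisition into a new container."""
    geometry = config.geometry.build()
    spec = config.phantom.build()
    sim = config.simulation
    rng = np.random.default_rng(sim.seed)
    truth = build_phantom(spec)
    _log_stage("simulate", seed=sim.seed, grid=spec.grid_shape, n_angles=sim.n_angles)

    nz, ny, nx = spec.grid_shape
    geometry = config.geometry.build()
    tilts = circle_tilts(geometry, n_angles=sim.n_angles, na_fraction=sim.na_fraction,
                         shape=(ny, nx))
    hset = simulate_hologram_set(
        truth, geometry, tilts=tilts, carrier_cpp=sim.carrier_cpp,
        noise=sim.hologram_noise, mode=sim.hologram_mode, rng=rng,
    )
    fluo = simulate_fluorescence_channels(
        truth, psf_sigma_px=sim.fluorescence_psf_sigma_px,
        noise=sim.fluorescence_noise, rng=rng,
    )
    bconf = config.brillouin
    model = SpectrometerModel(
        fsr_ghz=bconf.fsr_ghz,
        instrument_linewidth_ghz=bconf.instrument_linewidth_ghz,
        n_pixels=bconf.n_pixels,
    )
    cal_frames, cal_shifts = simulate_calibration_frames(
        model, shifts_ghz=bconf.calibration_shifts_ghz, rng=rng
    )
    frames = simulate_brillouin_scan(
        truth, model, raster_shape=sim.brillouin_raster,
        amplitude=sim.spectrum_amplitude, poisson_noise=True, rng=rng,
    )

    with cio.create_container(path, geometry, seed=sim.seed) as f:
        f.attrs["config"] = config.model_dump_json()
        cio.write_dataset(f, "holograms/data", hset.holograms, units="counts")
        cio.write_dataset(f, "holograms/background", hset.backgrounds, units="counts")
        cio.write_dataset(f, "holograms/tilts", hset.tilts_um, units="rad/um")
        f["holograms"].attrs["carrier_cpp"] = hset.carrier_cpp
        f["holograms"].attrs["detector_offset_um"] = hset.detector_offset_um
        f["holograms"].attrs["mode"] = sim.hologram_mode
        f["holograms"].attrs["oversample"] = hset.oversample
        f["holograms"].attrs["pixel_pitch_um"] = hset.pixel_pitch_um
        for name, img in fluo.items():
            cio.write_dataset(f, f"fluorescence/{name}", img, units="relative")
        spectra = np.stack([fr.intensity for fr in frames])
        positions = np.array([fr.position_um for fr in frames])
        cio.write_dataset(f, "brillouin/spectra", spectra, units="counts")
        cio.write_dataset(f, "brillouin/positions", positions, units="um")
        cal = np.stack([fr.intensity for fr in cal_frames])
        cio.write_dataset(f, "brillouin/calibration/spectra", cal, units="counts")
        cio.write_dataset(f, "brillouin/calibration/shifts", np.asarray(cal_shifts), units="GHz")
        cio.write_dataset(f, "truth/ri", truth.ri, units="dimensionless")
        cio.write_dataset(f, "truth/labels", truth.labels, units="label")
        cio.write_dataset(f, "truth/shift", truth.shift_map, units="GHz")
        cio.write_dataset(f, "truth/linewidth", truth.linewidth_map, units="GHz")


def _load_config(f) -> RunConfig:
    if "config" in f.attrs:
        return RunConfig.model_validate_json(f.attrs["config"])
    return RunConfig()


def reconstruct(path, iterations: int | None = None, approximation: str | None = None) -> None:
    """Retrieve all fields and reconstruct the RI tomogram into ``/ri``."""
    with cio.open_container(path, "r+") as f:
        cio.require(f, "holograms/data", "holograms/background", "holograms/tilts")
        config = _load_config(f)
        rconf = config.reconstruction
        iterations = rconf.iterations if iterations is None else iterations
        approximation = rconf.approximation if approximation is None else approximation
        geometry = cio.read_geometry(f)
        grp = f["holograms"]
        oversample = int(grp.attrs.get("oversample", 1))
        hset = HologramSet(
            holograms=f["holograms/data"][...],
            backgrounds=f["holograms/background"][...],
            tilts_um=f["holograms/tilts"][...],
            carrier_cpp=tuple(grp.attrs["carrier_cpp"]),
            pixel_pitch_um=float(grp.attrs.get("pixel_pitch_um", geometry.pixel_pitch_um)),
            detector_offset_um=float(grp.attrs.get("detector_offset_um", 0.0)),
            oversample=oversample,
        )
        _log_stage("reconstruct", iterations=iterations, approximation=approximation,
                   n_angles=len(hset))
        fields = retrieve_fields(hset)
        lateral = fields[0].field.shape
        nz = f["truth/ri"].shape[0] if "truth/ri" in f else lateral[0]
        tomo = reconstruct_tomogram(
            fields, geometry, grid_shape=(nz,) + lateral,
            iterations=iterations, approximation=approximation,
        )
        cio.write_dataset(
            f, "ri/volume", tomo.ri, units="dimensionless",
            sources=["holograms/data", "holograms/background"],
            parameters=tomo.provenance,
        )
        cio.write_dataset(f, "ri/voxel_size", np.asarray(tomo.voxel_size_um), units="um")


def evaluate_brillouin(path) -> None:
    """Calibrate the spectrometer and fit every scan spectrum."""
    with cio.open_container(path, "r+") as f:
        cio.require(f, "brillouin/spectra", "brillouin/positions",
                    "brillouin/calibration/spectra", "brillouin/calibration/shifts")
        config = _load_config(f)
        bconf = config.brillouin
        template = SpectrometerModel(
            fsr_ghz=bconf.fsr_ghz,
            instrument_linewidth_ghz=bconf.instrument_linewidth_ghz,
            n_pixels=bconf.n_pixels,
        )
        from .brillouin import SpectrumFrame

        cal_frames = [SpectrumFrame(intensity=row) for row in f["brillouin/calibration/spectra"][...]]
        cal_shifts = list(f["brillouin/calibration/shifts"][...])
        model = calibrate_spectrometer(cal_frames, cal_shifts, template=template)
        _log_stage("evaluate_brillouin", n_frames=f["brillouin/spectra"].shape[0],
                   calibration_residual_ghz=model.calibration_residual_ghz)
        spectra = f["brillouin/spectra"][...]
        positions = f["brillouin/positions"][...]
        points = [
            fit_spectrum(
                SpectrumFrame(intensity=row, position_um=tuple(pos)), model,
                prior_shift_ghz=bconf.prior_shift_ghz, deconvolve=bconf.deconvolve,
            )
            for row, pos in zip(spectra, positions)
        ]
        bmap = assemble_map(points)
        prov = dict(sources=["brillouin/spectra", "brillouin/calibration/spectra"],
                    parameters={"dispersion": list(model.dispersion)})
        cio.write_dataset(f, "brillouin/shift", bmap.shift_ghz, units="GHz", **prov)
        cio.write_dataset(f, "brillouin/linewidth", bmap.linewidth_ghz, units="GHz", **prov)
        cio.write_dataset(f, "brillouin/valid", bmap.valid.astype(np.uint8), units="bool", **prov)
        cio.write_dataset(f, "brillouin/y", bmap.y_um, units="um")
        cio.write_dataset(f, "brillouin/x", bmap.x_um, units="um")


def segment(path) -> CompartmentLabels:
    """Segment cells and compartments on the RI central slice."""
    with cio.open_container(path, "r+") as f:
        cio.require(f, "ri/volume")
        config = _load_config(f)
        geometry = cio.read_geometry(f)
        ri = f["ri/volume"][...]
        ri_slice = ri[ri.shape[0] // 2]
        channels = {}
        if "fluorescence" in f:
            channels = {name: f[f"fluorescence/{name}"][...] for name in f["fluorescence"]}
        rules = tuple(r.build() for r in config.segmentation_rules) or tuple(
            r for r in DEFAULT_RULES if r.source == "ri" or r.source in channels
        )
        cells = segment_cells(ri_slice, geometry.n_medium)
        labels = segment_compartments(cells, ri_slice, channels, rules)
        _log_stage("segment", n_cells=int(cells.max()), labels=list(labels.table))
        cio.write_dataset(
            f, "labels/image", labels.image, units="label",
            sources=["ri/volume"] + [f"fluorescence/{c}" for c in channels],
            parameters={"rules": [r.name for r in rules]},
        )
        tbl = json.dumps({str(k): v for k, v in labels.table.items()})
        cio.write_dataset(f, "labels/table", np.frombuffer(tbl.encode(), dtype=np.uint8),
                          units="json")
        return labels


def compute_modulus(path) -> None:
    """Register the Brillouin map to the RI slice and compute density,
    concentration and longitudinal-modulus maps."""
    with cio.open_container(path, "r+") as f:
        cio.require(f, "ri/volume", "brillouin/shift", "labels/image")
        config = _load_config(f)
        geometry = cio.read_geometry(f)
        ri = f["ri/volume"][...]
        ri_slice = ri[ri.shape[0] // 2]
        from .brillouin import BrillouinMap

        bmap = BrillouinMap(
            shift_ghz=f["brillouin/shift"][...],
            linewidth_ghz=f["brillouin/linewidth"][...],
            valid=f["brillouin/valid"][...].astype(bool),
            y_um=f["brillouin/y"][...],
            x_um=f["brillouin/x"][...],
        )
        shift_img, valid_img = resample_to_grid(bmap, ri_slice.shape, geometry.pixel_pitch_um)
        reg = register_maps(
            shift_img, ri_slice, search_radius_px=config.registration_search_radius_px,
            moving_valid=valid_img,
        )
        label_img = f["labels/image"][...]
        table = json.loads(bytes(f["labels/table"][...]).decode()) if "labels/table" in f else {}
        materials = {k: m.build() for k, m in config.materials.items()} or DEFAULT_MATERIALS
        label_models = {}
        for lab_s, entry in table.items():
            key = entry.get("material", "two_substance")
            if key not in materials:
                raise ValueError(f"material model {key!r} not configured")
            label_models[int(lab_s)] = materials[key]
        density = density_from_ri(ri_slice, label_img, label_models)
        conc, n_clipped = concentration_from_ri(ri_slice, materials.get("two_substance", DEFAULT_MATERIALS["two_substance"]))
        modulus, mvalid = longitudinal_modulus(
            reg.aligned, ri_slice, density, geometry, valid=reg.aligned_valid
        )
        _log_stage("compute_modulus", registration_shift=reg.shift_px,
                   correlation=reg.correlation, clipped_concentration_px=n_clipped)
        prov = dict(sources=["ri/volume", "brillouin/shift", "labels/image"],
                    parameters={"registration_shift_px": list(reg.shift_px),
                                "correlation": reg.correlation})
        cio.write_dataset(f, "maps/density", density, units="g/ml", **prov)
        cio.write_dataset(f, "maps/concentration", conc, units="mg/ml", **prov)
        cio.write_dataset(f, "maps/modulus", modulus, units="GPa", **prov)
        cio.write_dataset(f, "maps/modulus_valid", mvalid.astype(np.uint8), units="bool", **prov)
        cio.write_dataset(f, "maps/shift_registered", reg.aligned, units="GHz", **prov)


def compute_stats(path, csv_path=None) -> pd.DataFrame:
    """Per-compartment summary statistics of all derived maps."""
    with cio.open_container(path, "r") as f:
        cio.require(f, "labels/image", "maps/modulus")
        ri = f["ri/volume"][...]
        ri_slice = ri[ri.shape[0] // 2]
        maps = {
            "ri": ri_slice,
            "density_g_ml": f["maps/density"][...],
            "concentration_mg_ml": f["maps/concentration"][...],
            "shift_ghz": f["maps/shift_registered"][...],
            "modulus_gpa": f["maps/modulus"][...],
        }
        label_img = f["labels/image"][...]
        table = json.loads(bytes(f["labels/table"][...]).decode()) if "labels/table" in f else {}
        labels = CompartmentLabels(
            image=label_img, table={int(k): v for k, v in table.items()}
        )
        valid = f["maps/modulus_valid"][...].astype(bool)
        df = compartment_stats(maps, labels, valid=None)
        # modulus/shift rows should honor the Brillouin validity mask
        df_valid = compartment_stats(
            {"shift_ghz": maps["shift_ghz"], "modulus_gpa": maps["modulus_gpa"]},
            labels, valid=valid,
        )
        df = pd.concat(
            [df[~df.quantity.isin(["shift_ghz", "modulus_gpa"])], df_valid],
            ignore_index=True,
        )
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    return df


def export_report(path, out_dir) -> list:
    """Export derived maps as 32-bit float TIFF, the label image as an
    indexed PNG preview, and the summary table as CSV."""
    import pathlib

    import tifffile
    from PIL import Image

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    with cio.open_container(path, "r") as f:
        cio.require(f, "maps/modulus")
        for name in ("density", "concentration", "modulus", "shift_registered"):
            ds = f[f"maps/{name}"][...]
            target = out / f"{name}.tif"
            tifffile.imwrite(target, ds.astype(np.float32))
            written.append(target)
        ri = f["ri/volume"][...]
        tifffile.imwrite(out / "ri_central_slice.tif",
                         ri[ri.shape[0] // 2].astype(np.float32))
        written.append(out / "ri_central_slice.tif")
        if "labels/image" in f:
            labels = f["labels/image"][...].astype(np.uint8)
            img = Image.fromarray(labels, mode="P")
            # simple categorical palette: background black, labels distinct
            palette = [0, 0, 0, 60, 120, 216, 220, 80, 60, 90, 190, 90, 230, 200, 60]
            img.putpalette(palette + [0] * (768 - len(palette)))
            img.save(out / "labels.png")
            written.append(out / "labels.png")
    compute_stats(path, csv_path=out / "compartment_stats.csv")
    written.append(out / "compartment_stats.csv")
    return written


def run_all(config: RunConfig, path) -> pd.DataFrame:
    """Run the full pipeline on a fresh container and return the stats table."""
    simulate(config, path)
    reconstruct(path)
    evaluate_brillouin(path)
    segment(path)
    compute_modulus(path)
    return compute_stats(path)
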