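# fobtools

Analysis pipeline for combined **f**luorescence, **o**ptical diffraction
tomography and **B**rillouin (FOB) microscopy: from raw measurements —
angle-resolved off-axis holograms, VIPA spectrometer frames and
fluorescence channel images — to refractive-index tomograms, Brillouin
shift/linewidth maps, compartment segmentation, absolute-density maps and
longitudinal-modulus maps.

## Why

Brillouin microscopy maps the GHz-frequency longitudinal modulus

$$M' = \rho \left( \frac{\lambda\,\nu_B}{2 n \cos(\Theta/2)} \right)^{2},$$

where the bracket is the hypersonic phonon velocity obtained from the
Brillouin shift $\nu_B$ (backscattering, $\Theta = 0$ here, so the cosine is
1). Stand-alone Brillouin instruments must *assume* the refractive index
$n$ and density $\rho$. Combining Brillouin mapping with optical
diffraction tomography (which measures $n$ quantitatively) removes that
assumption: for watery compartments the density follows from the RI through
the two-substance mixture model

$$\rho = \rho_\text{fluid} + C\,(1 - \rho_\text{fluid}\,\bar\nu_\text{dry}),
\qquad C = \frac{n - n_\text{fluid}}{\alpha},$$

with refraction increment $\alpha = 0.190\ \mathrm{ml/g}$ for protein and
nucleic acid, while single-substance compartments identified by
fluorescence (lipid droplets, silicone beads) use a literature density.
Getting this right flips qualitative conclusions: a lipid droplet has a
*higher* RI and Brillouin shift than the surrounding cytoplasm but a
*lower* longitudinal modulus.

This package implements the full data path plus physics-faithful
simulators (multi-slice hologram formation, two-order VIPA doublets,
blurred fluorescence channels), so every stage is testable against known
ground truth without any instrument data.

## Worked example

```bash
python examples/worked_modulus.py
```

```
compartment         n       nu_B (GHz)  rho (g/ml)  M' (GPa)
HeLa nucleoplasm  1.3522       7.872      1.0207     2.448
HeLa cytoplasm    1.3545       7.811      1.0234     2.408
PAA bead          1.3485       7.574      1.0190     2.275

polyQ aggregate dry-mass concentration: 255.8 mg/ml
```

The nucleoplasm has a *lower* RI (hence lower density) than the cytoplasm
yet a *higher* longitudinal modulus — the modulus is not just tracking
water content. The concentration line converts the measured aggregate RI
into dry-mass concentration via the refraction increment.

Other examples, one per capability:

| script | shows |
| --- | --- |
| `examples/brillouin_spectrum.py` | VIPA doublet simulation, dispersion calibration, Lorentzian fitting |
| `examples/odt_sphere.py` | hologram simulation, field retrieval, tomographic reconstruction, missing-cone iterations |
| `examples/full_pipeline.py` | raw data to per-compartment statistics on a simulated cell |
| `examples/density_models.py` | two-substance vs literature density, lipid-droplet deviation sign |

## Library layout

| module | contents |
| --- | --- |
| `fobtools.phantoms` | digital phantoms with RI / label / Brillouin ground truth |
| `fobtools.forward` | hologram, VIPA-spectrum and fluorescence simulators |
| `fobtools.holography` | off-axis sideband field retrieval, phase unwrapping |
| `fobtools.odt` | Fourier-diffraction-theorem (Rytov) reconstruction, missing-cone regularization |
| `fobtools.brillouin` | spectrometer calibration, doublet fitting, map assembly |
| `fobtools.register` / `fobtools.segment` | Brillouin-to-RI co-registration; cell / compartment segmentation |
| `fobtools.mechanics` | density and concentration models, modulus maps, group statistics |
| `fobtools.container` / `fobtools.config` / `fobtools.pipeline` | HDF5 container, validated run configs, pipeline stages |

All randomness flows from the seed in the run configuration; rerunning a
stage with the same config reproduces its outputs bit for bit.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the two headline worked values (the longitudinal moduli of the
HeLa nucleoplasm and of the PAA bead of the validation phantom) from their
published compartment means through the package's modulus computation, and
writes them as JSON in GPa.

See `docs/methods.md` for the models, their assumptions, numerical choices
and known limitations.
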