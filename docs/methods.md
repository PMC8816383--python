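# Methods

This note documents the models implemented in `fobtools`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data generator does and does not emulate.

## Instrument model

The simulated instrument matches a combined FOB microscope: a 532 nm
single-frequency laser used both for Mach–Zehnder off-axis holography
(plane-wave illumination tilted through ~150 angles by a galvanometer; here
60 angles by default for desk-scale runtime) and for confocal Brillouin
point scanning through a two-stage VIPA spectrometer (free spectral range
30 GHz, instrument linewidth 350 MHz), plus widefield epifluorescence
sharing the tomography camera. Defaults: medium RI 1.337, illumination NA
1.0, detection NA 1.2, lateral/axial voxel pitch 0.1 µm.

## Synthetic raw data

**Phantoms** are lists of ellipsoids carrying RI, Brillouin shift,
linewidth, a compartment label and optionally a fluorescence channel.
Preset phantoms use the measured compartment means of the real samples:
the PDMS-in-PAA validation bead (inner RI 1.3920 / 7.279 GHz, outer
1.3485 / 7.574 GHz) and a cell with cytoplasm (1.3545 / 7.811 GHz),
nucleus (1.3522 / 7.872 GHz), nucleolus (1.3618 / 7.938 GHz) and
optionally a lipid droplet (1.409 / 8.25 GHz). These values are the
stated world of the generator and are not tuned.

**Holograms.** Two selectable forward models: `thin` accumulates phase
along the tilted illumination ray (closed-form oracle: a slab of contrast
Δn and thickness t retrieves exactly (2π/λ)Δn·t) and `multislice`
propagates the field through the volume with the angular-spectrum method,
applying a per-slice phase screen with an oblique-incidence correction
(dz/cosθᵢ; without it a tilted beam under-accrues phase by cosθ and the
reconstructed contrast integral is ~20% low). The reference beam is tilted
by the carrier relative to the *transmitted* beam, so the sideband of every
hologram sits at the configured carrier — equivalent to demodulating at the
detected illumination peak. The camera grid oversamples the reconstruction
grid 2× with the carrier at 0.28 cycles/pixel on the image diagonal; this
is the smallest configuration for which the sideband window clears both the
DC autocorrelation band and the conjugate order (measured field round-trip
error 2·10⁻³; at 1/4 Nyquist on the coarse grid it is ~3·10⁻²). Hologram
noise is additive Gaussian, scaled to the mean intensity.

**Spectra.** A doublet per frame: the anti-Stokes peak of one order at
ν_B and the Stokes peak of the adjacent order at FSR − ν_B on the frequency
axis, each a Lorentzian of FWHM (sample linewidth + instrument linewidth) —
the Lorentzian⊛Lorentzian convolution is again Lorentzian with summed
widths. The pixel axis maps to frequency through a quadratic dispersion
(mildly nonlinear by default, coefficients configurable); the dispersion
law of a real VIPA is not published for this instrument, so the quadratic
is a declared choice that exercises the calibration fit. Calibration
reference shifts default to 5.09 and 7.43 GHz (two known lines plus the FSR
constraint fix a quadratic). Spectra use Poisson counting noise; peak SNR ≈
√amplitude.

**Fluorescence** channels are label-indicator projections through the
stack, Gaussian-blurred (σ = 1.5 px) with additive Gaussian noise, clipped
to [0, saturation]. No real PSF model, no bleaching, no background
gradients — a green segmentation test establishes correctness of the
thresholding logic, not robustness to realistic stray light.

## Field retrieval and reconstruction

Retrieval crops a rectangular sideband window centered on the carrier
(half-width = the largest value clearing DC and Nyquist, with automatic
carrier detection as fallback), recenters it, inverse-transforms and
divides by the identically processed background; with camera oversampling
the window is embedded in the coarser reconstruction-grid frame,
demodulating and decimating in one step. A 10% Tukey apodization is applied
by default (off in tests that need machine-precision oracles, since the
simulated fields are periodic and the taper is the dominant error there).
Phase unwrapping uses reliability-sorted 2-D unwrapping, anchored so the
corner pixel keeps its wrapped value (the border is sample-free in this
instrument).

Reconstruction follows the Fourier diffraction theorem under the Rytov
approximation (Born selectable): the 2-D spectrum of the complex Rytov
phase is placed on the Ewald cap

f̂(q, k_z − k_iz) = (2 k_z / i) ψ̂(q) · exp(i (k_iz − k_z) z_d),

where q is exactly the detector grid frequency (illumination tilts are
snapped to the Fourier grid, so only the axial component needs gridding —
nearest-voxel scatter with fill-count averaging). Hermitian symmetry is
enforced (the potential is real), multiply-covered voxels are averaged,
and the potential inverts to RI via n = √(n_m² + f/k₀²).

The unsampled **missing cone** is regularized by Gerchberg–Papoulis
iterations: non-negativity of the RI contrast in real space alternated with
data replacement on sampled Fourier voxels (default 100 iterations, early
stop at relative update < 10⁻⁶). Both constraint sets are convex, so the
data-fidelity residual is non-increasing — asserted in tests. No support
constraint is applied; consequently the background can acquire a small
positive bias while the in-object contrast recovers (the 64³ sphere
phantom recovers its mean contrast to ~6% after 50 iterations, against a
~35% underestimate without iterations). Axial elongation decreases with
iterations but does not vanish.

## Brillouin evaluation

Peak detection is prominence-based on a median-filtered trace; with more
than two candidates, the pair whose separation is closest to
FSR − 2·ν_prior (prior 7.5 GHz) is taken. The doublet is fitted jointly —
two Lorentzians plus a constant background — on the calibrated frequency
axis. The shift is computed from the separation, ν_B = (FSR − Δ)/2, which
is immune to calibration offsets (exactly so for linear dispersion; a
quadratic term reintroduces a small sensitivity). The reported linewidth is
the mean fitted FWHM minus the instrument linewidth (valid for
Lorentzian⊛Lorentzian; toggleable off), floored at zero. Fits with peak
amplitude below 5× the residual rms, or shifts outside (0, FSR/2), are
flagged invalid — never interpolated. Whether the real evaluation averages
the Stokes/anti-Stokes widths or fits jointly is not published; the joint
fit is this package's choice.

Calibration fits the dispersion polynomial through the (pixel, frequency)
support points of the reference doublets — two points per reference line
via the FSR constraint — and rejects under-determined or non-monotonic
fits.

## Registration, segmentation, mechanics

The Brillouin map is resampled to the RI pixel grid by nearest neighbour
(invalid scan cells stay invalid), then registered to the RI central slice
by normalized cross-correlation over integer shifts within a search radius,
using a fixed central comparison region so the correlation curve is
symmetric; the peak is refined by quadratic interpolation (skipped for
exact matches, clamped to ±0.5 px). Peak correlation below 0.2 flags the
registration unreliable and applies the identity shift. Registration is
2-D only: the Brillouin focal plane is assumed at the tomogram's central
slice, matching the instrument's confocal geometry.

Cells are segmented by Otsu thresholding of the RI contrast plus a
distance-transform-seeded watershed (minimum object 50 px, holes ≤ 20 px
filled); compartments by per-channel Otsu masks intersected with the cell
mask, nucleoli as the upper Otsu class of RI within the nucleus. Label
precedence is organelle > nucleolus > nucleus > cytoplasm, realized by
application order; an optional erosion margin guards organelle boundaries.
With no channels the output degenerates to {background, cell}.

Densities use the full two-substance model with partial specific volume
ν̄_dry = 0.73 ml/g (protein literature value; the published worked
densities are reproduced with this default, e.g. n = 1.3522 → 1.0216 g/ml
vs the printed 1.0207 from per-cell averaging). The simplified form (drop
the fluid-displacement term) is provided and always overestimates — by
construction equal only at n = n_fluid. Lipid droplets use 0.8932 g/ml
(triacylglyceride), PDMS 1.03 g/ml. Θ is defined as the *deviation from
exact backscattering*, default 0: the printed worked moduli are reproduced
exactly only when the cosine term is 1, consistent with a backscattering
collection geometry.

Group comparison uses the Kruskal–Wallis test with a least-significant-
difference post hoc on pooled ranks (Conover form), significance stars at
0.05/0.01/0.001/0.0001, and ±2.7σ outlier *flagging* (removal is opt-in).
No multiple-testing correction is applied by default, matching the stated
analysis; Bonferroni is a switch.

## Numerical choices and edge cases

- Fourier grids use DC-at-corner indexing internally; the reconstructed
  volume is rolled so the object center lands on the central slice.
- Illumination tilts are snapped to the detector Fourier grid; tilts
  beyond the illumination NA and carriers too low for sideband separation
  are rejected, as are spectra with shift ≥ FSR/2 (order overlap).
- Fit degeneracies (fewer than two detected peaks, saturated or flat
  traces) produce invalid points, not exceptions; empty segmentation
  foregrounds warn and return zero labels.
- The worked value for the PAA bead computes to 2.27450 GPa from the
  printed compartment means — exactly on the three-decimal rounding
  boundary; agreement is asserted at printed precision.

## Limitations

- Weak-scattering (Rytov) reconstruction only; thick or highly scattering
  samples are out of scope, as is any beyond-Rytov multiple-scattering
  inversion.
- No aberration, autofocus, speckle, laser-drift or camera-artifact
  modelling; hologram noise is plain additive Gaussian.
- No viscosity value is derived from the linewidth (no published
  conversion for this instrument); the linewidth itself is reported.
- 2-D compartment segmentation on the central slice only; no tracking of
  mobile condensates.
- The missing-cone iteration can bias the background upward since only
  positivity (no support) constrains the unsampled cone.
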