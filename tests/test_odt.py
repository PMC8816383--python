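"""Fourier-diffraction-theorem reconstruction and missing-cone handling."""

import numpy as np
import pytest

from fobtools.holography import ComplexField, retrieve_fields
from fobtools.odt import (
    ScatteringPotentialSpectrum,
    map_field_to_ewald,
    reconstruct_tomogram,
)


def flat_field(tilt=(0.0, 0.0), shape=(64, 64), pitch=0.1):
    return ComplexField(field=np.ones(shape, complex), tilt_um=tilt,
                        pixel_pitch_um=pitch)


def fwhm_px(profile):
    p = profile - profile.min()
    p = p / p.max()
    above = np.where(p >= 0.5)[0]
    return above[-1] - above[0] + 1


class TestEwaldMapping:
    def test_no_scatterer_contributes_zero(self, geometry):
        idx, vals = map_field_to_ewald(flat_field(), geometry, (64, 64, 64), 0.1)
        assert np.allclose(vals, 0)

    def test_normal_incidence_dc_lands_at_origin(self, geometry):
        # constant nonzero Rytov phase -> single nonzero Fourier sample at DC,
        # which must land on the (0,0,0) voxel of the scattering potential
        f = ComplexField(field=np.exp(1j * 0.1) * np.ones((64, 64)),
                         tilt_um=(0.0, 0.0), pixel_pitch_um=0.1)
        idx, vals = map_field_to_ewald(f, geometry, (64, 64, 64), 0.1)
        nz_entries = idx[np.abs(vals) > 1e-9 * np.abs(vals).max()]
        assert nz_entries.shape[0] == 1
        assert tuple(nz_entries[0]) == (0, 0, 0)

    def test_tilt_outside_na_rejected(self, geometry):
        k_over = 1.05 * geometry.k0_um * geometry.na_illumination
        with pytest.raises(ValueError, match="NA"):
            map_field_to_ewald(flat_field(tilt=(0.0, k_over)), geometry, (64, 64, 64), 0.1)

    @pytest.mark.parametrize("tilt_index", [3, 17])
    def test_cap_geometry_matches_analytic_rasterization(
        self, geometry, sphere_tilts, tilt_index
    ):
        """Voxel placement equals an independent brute-force Ewald-cap
        rasterization from the illumination wavevector."""
        tilt = tuple(sphere_tilts[tilt_index])
        idx, _ = map_field_to_ewald(flat_field(tilt=tilt), geometry, (64, 64, 64), 0.1)

        km = geometry.km_um
        k0 = geometry.k0_um
        kiz = np.sqrt(km**2 - tilt[0] ** 2 - tilt[1] ** 2)
        dkz = 2 * np.pi / (64 * 0.1)
        expected = set()
        for iy in range(64):
            for ix in range(64):
                qy = 2 * np.pi * np.fft.fftfreq(64, 0.1)[iy]
                qx = 2 * np.pi * np.fft.fftfreq(64, 0.1)[ix]
                ky, kx = qy + tilt[0], qx + tilt[1]
                kp2 = ky**2 + kx**2
                if kp2 > min(k0 * geometry.na_detection, km) ** 2:
                    continue
                kz = np.sqrt(km**2 - kp2)
                iz = round((kz - kiz) / dkz)
                if abs(iz) > 64 // 2 - 1:
                    continue
                expected.add((iz % 64, iy, ix))
        assert {tuple(i) for i in idx} == expected

    def test_two_caps_intersect_on_a_circle(self, geometry, sphere_tilts):
        """Two caps share voxels only near the Ewald-geometry intersection
        circle (which always passes through the origin)."""
        caps = []
        for i in (1, 31):
            idx, _ = map_field_to_ewald(flat_field(tilt=tuple(sphere_tilts[i])),
                                        geometry, (64, 64, 64), 0.1)
            caps.append({tuple(j) for j in idx})
        common = caps[0] & caps[1]
        assert (0, 0, 0) in common
        # the intersection is a 1-D voxel set, far smaller than either cap
        assert len(common) < 0.2 * min(len(c) for c in caps)


class TestReconstruction:
    def test_requires_fields(self, geometry):
        with pytest.raises(ValueError, match="at least one"):
            reconstruct_tomogram([], geometry)

    def test_homogeneous_phantom_reconstructs_to_medium(self, geometry, sphere_tilts):
        from fobtools.forward import simulate_hologram_set
        from fobtools.phantoms import PhantomSpec, build_phantom

        truth = build_phantom(PhantomSpec(grid_shape=(64, 64, 64),
                                          voxel_size_um=(0.1, 0.1, 0.1)))
        hset = simulate_hologram_set(truth, geometry, tilts=sphere_tilts)
        tomo = reconstruct_tomogram(retrieve_fields(hset), geometry,
                                    grid_shape=(64, 64, 64), iterations=0)
        rms = np.sqrt(np.mean((tomo.ri - 1.337) ** 2))
        assert rms <= 1e-4

    def test_sphere_contrast_recovered_within_10_percent(
        self, sphere_truth, geometry, sphere_fields
    ):
        tomo = reconstruct_tomogram(sphere_fields, geometry, grid_shape=(64, 64, 64),
                                    iterations=50)
        mask = sphere_truth.labels[32] == 1
        mean_err = abs(tomo.central_slice[mask].mean() - 1.357)
        assert mean_err <= 0.1 * 0.02

    def test_axial_elongation_decreases_with_iterations(
        self, sphere_truth, geometry, sphere_fields
    ):
        elong = []
        for iters in (0, 50):
            tomo = reconstruct_tomogram(sphere_fields, geometry,
                                        grid_shape=(64, 64, 64), iterations=iters)
            axial = fwhm_px(tomo.ri[:, 32, 32])
            lateral = fwhm_px(tomo.ri[32, 32, :])
            elong.append(axial / lateral)
        assert elong[1] < elong[0]

    def test_fidelity_residual_non_increasing(self, geometry, sphere_fields):
        tomo = reconstruct_tomogram(sphere_fields, geometry, grid_shape=(64, 64, 64),
                                    iterations=30)
        r = np.asarray(tomo.residuals)
        assert np.all(np.diff(r) <= 1e-12)

    def test_hermitian_spectrum_yields_real_potential(self, geometry, sphere_fields):
        spectrum = ScatteringPotentialSpectrum(geometry, (64, 64, 64), (0.1, 0.1, 0.1))
        for f in sphere_fields:
            spectrum.add_field(f)
        data, _ = spectrum.averaged()
        pot = np.fft.ifftn(data)
        rms_real = np.sqrt(np.mean(pot.real**2))
        assert np.abs(pot.imag).max() <= 1e-6 * rms_real

    def test_ri_floor_and_provenance(self, geometry, sphere_fields):
        tomo = reconstruct_tomogram(sphere_fields, geometry, grid_shape=(64, 64, 64),
                                    iterations=5)
        assert tomo.ri.min() >= 1.0
        assert tomo.provenance["n_angles"] == len(sphere_fields)
        assert tomo.provenance["approximation"] == "rytov"

    def test_born_approximation_selectable(self, sphere_truth, geometry, sphere_fields):
        """Born inversion of the weak sphere recovers positive contrast in
        the right place (Rytov stays the default for accuracy)."""
        tomo = reconstruct_tomogram(sphere_fields, geometry, grid_shape=(64, 64, 64),
                                    iterations=20, approximation="born")
        mask = sphere_truth.labels[32] == 1
        inside = tomo.central_slice[mask].mean()
        outside = tomo.central_slice[~mask].mean()
        assert inside > outside > 1.0
        assert tomo.provenance["approximation"] == "born"

    def test_two_point_lateral_resolution(self, geometry):
        """Two scatterers 3 voxels apart laterally are resolved."""
        from fobtools.forward import circle_tilts, simulate_hologram_set
        from fobtools.phantoms import PhantomSpec, Primitive, build_phantom

        prim = lambda x_um, lab: Primitive(
            center_um=(3.2, 3.2, x_um), radii_um=(0.1, 0.1, 0.1), n=1.36,
            shift_ghz=7.7, linewidth_ghz=0.8, label=lab,
        )
        spec = PhantomSpec(grid_shape=(64, 64, 64), voxel_size_um=(0.1, 0.1, 0.1),
                           primitives=(prim(3.05, 1), prim(3.35, 2)))
        truth = build_phantom(spec)
        tilts = circle_tilts(geometry, n_angles=60, shape=(64, 64))
        hset = simulate_hologram_set(truth, geometry, tilts=tilts)
        tomo = reconstruct_tomogram(retrieve_fields(hset), geometry,
                                    grid_shape=(64, 64, 64), iterations=20)
        profile = tomo.ri[32, 32, 28:38]
        peaks = np.where(
            (profile[1:-1] > profile[:-2]) & (profile[1:-1] > profile[2:])
        )[0]
        assert len(peaks) >= 2
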