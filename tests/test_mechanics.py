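"""Density model, longitudinal modulus and group statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fobtools import AcquisitionGeometry
from fobtools.mechanics import (
    LIPID_DROPLET_MODEL,
    PDMS_MODEL,
    PROTEIN_MODEL,
    MaterialModel,
    compare_groups,
    compartment_stats,
    concentration_from_ri,
    density_from_ri,
    flag_outliers,
    longitudinal_modulus,
    modulus_point,
)

GEOM = AcquisitionGeometry()


class TestDensity:
    def test_zero_contrast_gives_fluid_density(self):
        for mode in ("two_substance_full", "two_substance_simplified"):
            m = MaterialModel(mode=mode)
            assert m.density(1.337) == pytest.approx(1.000)

    def test_simplified_hand_value(self):
        m = MaterialModel(mode="two_substance_simplified")
        # (1.3522 - 1.337)/0.190 + 1.000
        assert float(m.density(1.3522)) == pytest.approx(1.080, abs=5e-4)

    def test_literature_mode_ignores_ri(self):
        n = np.array([1.30, 1.40, 1.50])
        rho = np.asarray(LIPID_DROPLET_MODEL.density(n))
        assert np.all(rho == 0.8932)
        assert np.all(np.asarray(PDMS_MODEL.density(n)) == 1.03)

    @settings(derandomize=True, max_examples=60)
    @given(st.floats(min_value=1.337, max_value=1.45))
    def test_simplified_at_least_full(self, n):
        """The simplified form overestimates density except at n = n_fluid."""
        full = float(PROTEIN_MODEL.density(n))
        simp = float(MaterialModel(mode="two_substance_simplified").density(n))
        if n == 1.337:
            assert simp == pytest.approx(full)
        else:
            assert simp > full

    def test_label_wise_density_map(self):
        ri = np.array([[1.35, 1.40], [1.337, 1.42]])
        labels = np.array([[1, 2], [0, 2]])
        rho = density_from_ri(ri, labels, {1: PROTEIN_MODEL, 2: LIPID_DROPLET_MODEL})
        assert rho[0, 1] == 0.8932 and rho[1, 1] == 0.8932
        assert rho[1, 0] == pytest.approx(1.000)

    def test_missing_model_rejected(self):
        ri = np.full((2, 2), 1.35)
        labels = np.array([[1, 1], [2, 2]])
        with pytest.raises(ValueError, match="no material model"):
            density_from_ri(ri, labels, {1: PROTEIN_MODEL})


class TestConcentration:
    def test_polyq_aggregate_worked_value(self):
        c, _ = concentration_from_ri(np.array([[1.3856]]), PROTEIN_MODEL)
        assert round(float(c[0, 0]), 1) == 255.8

    def test_zero_at_fluid_ri(self):
        c, _ = concentration_from_ri(np.array([[1.337]]), PROTEIN_MODEL)
        assert c[0, 0] == 0.0

    def test_phospholipid_increment_hand_value(self):
        m = MaterialModel(alpha_ml_g=0.135)
        c, _ = concentration_from_ri(np.array([[1.337 + 0.0135]]), m)
        assert float(c[0, 0]) == pytest.approx(100.0)

    def test_negative_values_clipped_and_counted(self):
        c, n_clipped = concentration_from_ri(np.array([[1.33, 1.35]]), PROTEIN_MODEL)
        assert n_clipped == 1
        assert c.min() == 0.0

    def test_literature_material_has_no_concentration(self):
        with pytest.raises(ValueError, match="undefined"):
            concentration_from_ri(np.array([[1.4]]), LIPID_DROPLET_MODEL)


class TestModulus:
    def test_zero_shift_gives_zero(self):
        m, valid = longitudinal_modulus(np.zeros((2, 2)), np.full((2, 2), 1.35),
                                        np.ones((2, 2)), GEOM)
        assert np.all(m[valid] == 0.0)

    @settings(derandomize=True, max_examples=40)
    @given(
        st.floats(min_value=1.33, max_value=1.45),
        st.floats(min_value=1.0, max_value=12.0),
        st.floats(min_value=0.8, max_value=1.2),
    )
    def test_equals_rho_v_squared(self, n, shift, rho):
        """Unit audit: M' = rho * V^2 with V = lambda*nu/(2 n cos(theta/2))."""
        m = modulus_point(n, shift, rho)
        v = 532e-9 * shift * 1e9 / (2 * n)          # m/s
        expected = rho * 1000 * v**2 / 1e9          # GPa
        assert m == pytest.approx(expected, rel=1e-12)

    def test_scaling_laws(self):
        base = modulus_point(1.35, 7.5, 1.0)
        assert modulus_point(1.35, 7.5, 2.0) == pytest.approx(2 * base)
        assert modulus_point(1.35, 15.0, 1.0) == pytest.approx(4 * base)

    def test_invalid_pixels_propagate(self):
        shift = np.array([[7.5, np.nan]])
        m, valid = longitudinal_modulus(shift, np.full((1, 2), 1.35),
                                        np.ones((1, 2)), GEOM)
        assert valid[0, 0] and not valid[0, 1]
        assert np.isnan(m[0, 1])

    def test_theta_reduces_velocity(self):
        geom_tilted = AcquisitionGeometry(theta_deg=20.0)
        m0 = modulus_point(1.35, 7.5, 1.0)
        m1 = modulus_point(1.35, 7.5, 1.0, geom_tilted)
        assert m1 > m0  # cos < 1 increases the inferred modulus

    @settings(derandomize=True, max_examples=40)
    @given(st.floats(min_value=1.3375, max_value=1.45))
    def test_lipid_homogeneous_assumption_overestimates(self, n):
        """With measured n > 1.337 and a literature density < 1 g/ml, the
        homogeneous assumption (n = 1.337, rho = 1) always overestimates the
        lipid-droplet modulus — the sign of the deviation map."""
        correct = modulus_point(n, 8.25, 0.8932)
        homogeneous = modulus_point(1.337, 8.25, 1.0)
        assert homogeneous > correct


class TestCompartmentStats:
    def test_constant_label(self):
        maps = {"ri": np.full((4, 4), 1.35)}
        labels = np.ones((4, 4), dtype=int)
        df = compartment_stats(maps, labels)
        row = df.iloc[0]
        assert row["mean"] == row["median"] == 1.35
        assert row["sd"] == 0.0

    def test_hand_arithmetic(self):
        maps = {"v": np.array([[1.0, 2.0], [3.0, 4.0]])}
        labels = np.ones((2, 2), dtype=int)
        row = compartment_stats(maps, labels).iloc[0]
        assert row["mean"] == 2.5
        assert row["sem"] == pytest.approx(row["sd"] / 2)

    def test_absent_label_gives_zero_row(self):
        from fobtools.segment import CompartmentLabels

        labels = CompartmentLabels(
            image=np.ones((2, 2), dtype=int),
            table={1: {"name": "cell"}, 9: {"name": "ghost"}},
        )
        df = compartment_stats({"v": np.ones((2, 2))}, labels)
        ghost = df[df.compartment == "ghost"].iloc[0]
        assert ghost["n"] == 0 and np.isnan(ghost["mean"])


def brute_force_kruskal_h(groups):
    """Independent oracle: tie-corrected rank statistic computed from the
    definition (between-group rank variance over total rank variance)."""
    values = np.concatenate(groups)
    from scipy.stats import rankdata

    ranks = rankdata(values)
    n = len(values)
    grand = ranks.mean()
    parts = np.split(ranks, np.cumsum([len(g) for g in groups])[:-1])
    num = sum(len(p) * (p.mean() - grand) ** 2 for p in parts)
    den = np.sum((ranks - grand) ** 2)
    return (n - 1) * num / den


class TestCompareGroups:
    def test_identical_groups_null(self):
        """Three groups with literally identical contents: H ~ 0, p ~ 1."""
        vals = np.arange(20, dtype=float)
        res = compare_groups({"a": vals, "b": vals.copy(), "c": vals.copy()})
        assert res["H"] == pytest.approx(0.0, abs=1e-9)
        assert res["p"] > 0.5

    def test_separated_groups_highly_significant(self):
        rng = np.random.default_rng(5)
        res = compare_groups({"a": rng.normal(0, 1, 30), "b": rng.normal(10, 1, 30)})
        assert res["p"] < 0.0001
        assert res["posthoc"].iloc[0]["stars"] == "****"

    @pytest.mark.parametrize("seed", range(5))
    def test_h_matches_brute_force_small_n(self, seed):
        """Package H equals the definitional rank statistic for all group
        sizes <= 8, including ties."""
        rng = np.random.default_rng(seed)
        sizes = rng.integers(2, 9, size=rng.integers(2, 5))
        groups = [rng.integers(0, 6, size=s).astype(float) for s in sizes]
        res = compare_groups({f"g{i}": g for i, g in enumerate(groups)})
        assert res["H"] == pytest.approx(brute_force_kruskal_h(groups), rel=1e-12)

    def test_outlier_rule(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, 400)
        base = base[np.abs(base) < 2.0]                  # keep the bulk only
        base = (base - base.mean()) / base.std(ddof=1)   # ~mean 0, sd 1
        flagged = flag_outliers(np.append(base, 3.1))
        passed = flag_outliers(np.append(base, 2.5))
        assert flagged[-1]
        assert not passed[-1]
        assert not passed[:-1].any()

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_groups({"a": np.array([1.0]), "b": np.array([1.0, 2.0])})

    def test_posthoc_table_shape_and_bonferroni(self):
        rng = np.random.default_rng(8)
        groups = {k: rng.normal(i, 1, 12) for i, k in enumerate("abc")}
        res = compare_groups(groups)
        assert len(res["posthoc"]) == 3
        res_b = compare_groups(groups, bonferroni=True)
        assert (res_b["posthoc"]["p"] >= res["posthoc"]["p"] - 1e-15).all()
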