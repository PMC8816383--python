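"""Density, concentration, longitudinal modulus and group statistics.

The longitudinal modulus probed by Brillouin scattering is

    M' = rho * (lambda * nu_B / (2 * n * cos(theta / 2)))**2

with vacuum wavelength ``lambda``, Brillouin shift ``nu_B``, refractive
index ``n``, absolute density ``rho`` and ``theta`` the deviation of the
collection geometry from exact backscattering (0 for this instrument, so
the cosine term is 1).  The bracket is the hypersonic phonon velocity, so
``M' = rho * V**2``.

Absolute density follows from the RI through a two-substance mixture model:
dry biomolecular mass dissolved in fluid raises the RI linearly with
concentration via the refraction increment ``alpha = dn/dC``
(0.190 ml/g for proteins and nucleic acids).  With the dry-mass
concentration ``C = (n - n_fluid) / alpha`` the full model reads

    rho = rho_fluid + C * (1 - rho_fluid * v_dry)

where ``v_dry`` is the partial specific volume of the dry fraction
(~0.73 ml/g for protein).  Dropping the fluid-displacement term gives the
simplified form ``rho ~= (n - n_fluid)/alpha + rho_fluid``, which
overestimates the density (by ~10% of the contrast term for cells).
Compartments that are not a watery mixture (lipid droplets, silicone
beads) instead use a literature density, selected per compartment label.

Units: RI dimensionless, ``nu_B`` in GHz, ``lambda`` in nm, ``rho`` in
g/ml, ``C`` in mg/ml, ``M'`` in GPa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import AcquisitionGeometry

__all__ = [
    "MaterialModel",
    "PROTEIN_MODEL",
    "LIPID_DROPLET_MODEL",
    "PDMS_MODEL",
    "density_from_ri",
    "concentration_from_ri",
    "longitudinal_modulus",
    "modulus_point",
    "compartment_stats",
    "compare_groups",
]

SIGNIFICANCE_LEVELS = (0.05, 0.01, 0.001, 0.0001)
OUTLIER_SIGMA = 2.7


@dataclass(frozen=True)
class MaterialModel:
    """Per-compartment rule converting RI to absolute density.

    ``mode`` selects the two-substance mixture (full or simplified) or a
    literature constant.  Defaults are the protein/nucleic-acid constants:
    refraction increment 0.190 ml/g, aqueous fluid (n = 1.337, 1.000 g/ml),
    protein partial specific volume 0.73 ml/g.
    """

    mode: str = "two_substance_full"
    alpha_ml_g: float = 0.190
    n_fluid: float = 1.337
    rho_fluid_g_ml: float = 1.000
    v_dry_ml_g: float = 0.73
    rho_dry_g_ml: float = 1.35
    rho_lit_g_ml: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("two_substance_full", "two_substance_simplified", "literature"):
            raise ValueError(f"unknown material mode {self.mode!r}")
        if self.alpha_ml_g <= 0:
            raise ValueError("refraction increment must be positive")
        if self.n_fluid < 1:
            raise ValueError("fluid RI must be >= 1")
        if self.rho_fluid_g_ml <= 0:
            raise ValueError("fluid density must be positive")
        if self.mode == "literature" and not (self.rho_lit_g_ml and self.rho_lit_g_ml > 0):
            raise ValueError("literature mode requires rho_lit > 0")

    def density(self, n: np.ndarray | float) -> np.ndarray | float:
        """Absolute density (g/ml) for refractive index ``n``."""
        n = np.asarray(n, dtype=float)
        if self.mode == "literature":
            return np.full_like(n, self.rho_lit_g_ml)
        c = (n - self.n_fluid) / self.alpha_ml_g  # g/ml
        if self.mode == "two_substance_simplified":
            return c + self.rho_fluid_g_ml
        return self.rho_fluid_g_ml + c * (1.0 - self.rho_fluid_g_ml * self.v_dry_ml_g)

    def concentration_mg_ml(self, n: np.ndarray | float) -> np.ndarray | float:
        """Dry-mass concentration (mg/ml) for refractive index ``n``."""
        if self.mode == "literature":
            raise ValueError("concentration is undefined for literature-density materials")
        n = np.asarray(n, dtype=float)
        return 1000.0 * (n - self.n_fluid) / self.alpha_ml_g


PROTEIN_MODEL = MaterialModel()
SIMPLIFIED_MODEL = MaterialModel(mode="two_substance_simplified")
LIPID_DROPLET_MODEL = MaterialModel(mode="literature", rho_lit_g_ml=0.8932)
PDMS_MODEL = MaterialModel(mode="literature", rho_lit_g_ml=1.03)

DEFAULT_MATERIALS: dict[str, MaterialModel] = {
    "two_substance": PROTEIN_MODEL,
    "two_substance_simplified": SIMPLIFIED_MODEL,
    "lipid": LIPID_DROPLET_MODEL,
    "pdms": PDMS_MODEL,
}


def density_from_ri(
    ri_map: np.ndarray,
    labels: np.ndarray,
    models: dict[int, MaterialModel],
    background_model: MaterialModel | None = None,
) -> np.ndarray:
    """Per-pixel absolute density map from RI and compartment labels.

    Every nonzero label present in ``labels`` must have a model;
    background (label 0) uses ``background_model`` (default: the protein
    two-substance model, i.e. plain medium evaluates to the fluid density).
    """
    ri_map = np.asarray(ri_map, dtype=float)
    if not np.all(np.isfinite(ri_map)):
        raise ValueError("RI map must be finite")
    labels = np.asarray(labels)
    if labels.shape != ri_map.shape:
        raise ValueError("labels and RI map must share a shape")
    present = set(np.unique(labels)) - {0}
    missing = present - set(models)
    if missing:
        raise ValueError(f"no material model for labels {sorted(missing)}")
    if background_model is None:
        background_model = PROTEIN_MODEL
    rho = np.asarray(background_model.density(ri_map)).copy()
    for lab in present:
        mask = labels == lab
        rho[mask] = np.asarray(models[lab].density(ri_map))[mask]
    return rho


def concentration_from_ri(
    ri_map: np.ndarray,
    model: MaterialModel,
) -> tuple[np.ndarray, int]:
    """Dry-mass concentration map (mg/ml).

    Negative concentrations are clipped to zero; the number of clipped
    pixels is returned alongside the map.
    """
    c = np.asarray(model.concentration_mg_ml(np.asarray(ri_map, dtype=float)))
    n_clipped = int(np.sum(c < 0))
    return np.clip(c, 0.0, None), n_clipped


def modulus_point(
    n: float,
    shift_ghz: float,
    rho_g_ml: float,
    geometry: AcquisitionGeometry | None = None,
) -> float:
    """Longitudinal modulus (GPa) for scalar inputs — the worked-value form."""
    if geometry is None:
        geometry = AcquisitionGeometry()
    return float(
        longitudinal_modulus(
            np.asarray([[shift_ghz]]), np.asarray([[n]]), np.asarray([[rho_g_ml]]), geometry
        )[0][0, 0]
    )


def longitudinal_modulus(
    shift_map_ghz: np.ndarray,
    ri_map: np.ndarray,
    density_map_g_ml: np.ndarray,
    geometry: AcquisitionGeometry,
    valid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel longitudinal modulus map in GPa.

    Evaluates ``M' = rho * (lambda * nu_B / (2 n cos(theta/2)))**2`` in SI
    and reports GPa.  Invalid Brillouin pixels propagate as invalid (NaN in
    the map, False in the returned mask).
    """
    shift = np.asarray(shift_map_ghz, dtype=float)
    ri = np.asarray(ri_map, dtype=float)
    rho = np.asarray(density_map_g_ml, dtype=float)
    if not shift.shape == ri.shape == rho.shape:
        raise ValueError("shift, RI and density maps must share a shape")
    if np.any(ri[np.isfinite(ri)] <= 0):
        raise ValueError("refractive index must be positive")
    if valid is None:
        valid = np.isfinite(shift)
    valid = valid & np.isfinite(shift) & np.isfinite(ri) & np.isfinite(rho)
    lam_m = geometry.wavelength_nm * 1e-9
    nu_hz = shift * 1e9
    theta = np.deg2rad(geometry.theta_deg)
    velocity = lam_m * nu_hz / (2.0 * ri * np.cos(theta / 2.0))   # m/s
    rho_si = rho * 1000.0                                          # kg/m^3
    m_pa = rho_si * velocity**2
    m_gpa = np.where(valid, m_pa / 1e9, np.nan)
    return m_gpa, valid


def compartment_stats(
    maps: dict[str, np.ndarray],
    labels,
    valid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-compartment summary (n, mean, median, SD, SEM) of each map.

    ``labels`` may be a plain integer image or a
    :class:`~fobtools.segment.CompartmentLabels`.  Invalid or non-finite
    pixels are excluded.  Labels without pixels yield an ``n = 0`` row.
    """
    from .segment import CompartmentLabels

    if isinstance(labels, CompartmentLabels):
        label_img = labels.image
        names = {lab: entry["name"] for lab, entry in labels.table.items()}
    else:
        label_img = np.asarray(labels)
        names = {int(lab): str(int(lab)) for lab in np.unique(label_img) if lab != 0}
    rows = []
    for lab, name in sorted(names.items()):
        mask = label_img == lab
        for qty, arr in maps.items():
            arr = np.asarray(arr, dtype=float)
            sel = mask & np.isfinite(arr)
            if valid is not None:
                sel &= valid
            vals = arr[sel]
            n = int(vals.size)
            rows.append(
                {
                    "label": lab,
                    "compartment": name,
                    "quantity": qty,
                    "n": n,
                    "mean": float(vals.mean()) if n else np.nan,
                    "median": float(np.median(vals)) if n else np.nan,
                    "sd": float(vals.std(ddof=1)) if n > 1 else (0.0 if n == 1 else np.nan),
                    "sem": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _stars(p: float) -> str:
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def flag_outliers(values: np.ndarray, sigma: float = OUTLIER_SIGMA) -> np.ndarray:
    """Boolean mask of points outside +-sigma standard deviations of their
    group (flagged, not removed)."""
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return np.zeros(values.shape, dtype=bool)
    z = (values - values.mean()) / sd
    return np.abs(z) > sigma


def compare_groups(
    groups: dict[str, np.ndarray],
    alpha: float = 0.05,
    bonferroni: bool = False,
    remove_outliers: bool = False,
) -> dict:
    """Kruskal-Wallis test across groups with an LSD post hoc on rank means.

    Returns a dict with the omnibus ``H`` and ``p``, a pairwise post-hoc
    table (least-significant-difference t test on pooled ranks, Conover
    form), significance stars, and per-group +-2.7 sigma outlier flags.
    Outliers are flagged, not removed, unless ``remove_outliers`` is set.
    """
    if len(groups) < 2:
        raise ValueError("at least two groups required")
    clean: dict[str, np.ndarray] = {}
    outliers: dict[str, np.ndarray] = {}
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
        flags = flag_outliers(vals)
        outliers[name] = flags
        clean[name] = vals[~flags] if remove_outliers else vals
    names = list(clean)
    samples = [clean[n] for n in names]
    h_stat, p_omni = sps.kruskal(*samples)

    pooled = np.concatenate(samples)
    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    k = len(samples)
    rank_groups = np.split(ranks, np.cumsum([len(s) for s in samples])[:-1])
    rank_means = [r.mean() for r in rank_groups]
    s2 = ranks.var(ddof=1)
    df = n_total - k
    rows = []
    n_pairs = k * (k - 1) // 2
    for i in range(k):
        for j in range(i + 1, k):
            ni, nj = len(samples[i]), len(samples[j])
            se = np.sqrt(s2 * ((n_total - 1 - h_stat) / df) * (1 / ni + 1 / nj))
            t = (rank_means[i] - rank_means[j]) / se if se > 0 else np.inf
            p = 2 * sps.t.sf(abs(t), df)
            if bonferroni:
                p = min(p * n_pairs, 1.0)
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "rank_mean_diff": rank_means[i] - rank_means[j],
                    "t": float(t),
                    "p": float(p),
                    "stars": _stars(float(p)),
                    "significant": bool(p < alpha),
                }
            )
    return {
        "H": float(h_stat),
        "p": float(p_omni),
        "posthoc": pd.DataFrame(rows),
        "outliers": outliers,
    }
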