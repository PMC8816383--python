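"""Cell and compartment segmentation from RI and fluorescence.

Cells are separated from background by Otsu thresholding of the RI contrast
and split into individual objects with a distance-transform-seeded
watershed.  Subcellular compartments are then assigned per rule:

* fluorescence-marked compartments (nucleus, aggregates, lipid droplets)
  are Otsu-thresholded on their channel and intersected with the cell mask;
* nucleoli are the upper Otsu class of the RI restricted to the nucleus
  (they have higher RI than the surrounding nucleoplasm);
* the cytoplasm is the remaining cell area.

Label precedence: organelle > nucleolus > nucleus > cytoplasm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_holes, remove_small_objects
from skimage.segmentation import watershed

__all__ = [
    "CompartmentLabels",
    "SegmentationRule",
    "segment_cells",
    "segment_compartments",
    "crop_roi",
]


@dataclass(frozen=True)
class SegmentationRule:
    """How one compartment is delineated.

    ``source`` is either a fluorescence channel name or the literal
    ``"ri"`` (the nucleolus rule).  ``within`` optionally names the
    compartment the rule is restricted to (e.g. nucleolus within nucleus).
    ``material`` keys into the material-model table of the mechanics stage.
    """

    name: str
    label: int
    source: str
    within: str | None = None
    material: str = "two_substance"


DEFAULT_RULES: tuple[SegmentationRule, ...] = (
    SegmentationRule("nucleus", 2, "hoechst", material="two_substance"),
    SegmentationRule("nucleolus", 3, "ri", within="nucleus", material="two_substance"),
)


@dataclass
class CompartmentLabels:
    """Integer label image aligned to the RI central slice plus its table."""

    image: np.ndarray                       # (ny, nx) int, 0 = background
    table: dict[int, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        missing = set(np.unique(self.image)) - {0} - set(self.table)
        if missing:
            raise ValueError(f"labels {sorted(missing)} lack a table entry")

    def mask(self, name_or_label: str | int) -> np.ndarray:
        if isinstance(name_or_label, str):
            matches = [l for l, e in self.table.items() if e["name"] == name_or_label]
            if not matches:
                raise KeyError(name_or_label)
            return np.isin(self.image, matches)
        return self.image == name_or_label


def segment_cells(
    ri_slice: np.ndarray,
    n_medium: float,
    min_area_px: int = 50,
    max_hole_px: int = 20,
    seed_min_distance_px: int = 10,
) -> np.ndarray:
    """Segment individual cells from the RI central slice.

    Otsu threshold on the RI contrast separates foreground from medium; a
    distance-transform-seeded watershed splits touching cells; objects below
    ``min_area_px`` are discarded and holes up to ``max_hole_px`` filled.

    Returns an integer label image (0 = background).
    """
    ri_slice = np.asarray(ri_slice, dtype=float)
    if not np.all(np.isfinite(ri_slice)):
        raise ValueError("RI slice must be finite")
    contrast = ri_slice - n_medium
    if np.ptp(contrast) == 0:
        import warnings

        warnings.warn("uniform RI slice: no cells found", stacklevel=2)
        return np.zeros(ri_slice.shape, dtype=np.int32)
    thr = threshold_otsu(contrast, nbins=256)
    fg = contrast > thr
    fg = remove_small_holes(fg, max_size=max_hole_px)
    fg = remove_small_objects(fg, max_size=max(min_area_px - 1, 0))
    if not fg.any():
        import warnings

        warnings.warn("empty foreground after Otsu thresholding", stacklevel=2)
        return np.zeros(ri_slice.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(fg)
    # seeds: well-separated local maxima of the distance map, one per cell
    from skimage.feature import peak_local_max

    coords = peak_local_max(
        distance, min_distance=seed_min_distance_px, exclude_border=False, labels=fg
    )
    peak_mask = np.zeros(fg.shape, dtype=bool)
    peak_mask[tuple(coords.T)] = True
    seeds, _ = ndi.label(peak_mask)
    labels = watershed(-distance, markers=seeds, mask=fg)
    # drop undersized objects and renumber consecutively
    sizes = np.bincount(labels.ravel())
    out = np.zeros_like(labels, dtype=np.int32)
    new = 0
    for old in np.unique(labels[labels > 0]):
        if sizes[old] >= min_area_px:
            new += 1
            out[labels == old] = new
    return out


def _otsu_mask(img: np.ndarray, restrict: np.ndarray | None = None) -> np.ndarray:
    """Upper Otsu class of ``img`` (optionally restricted to a mask)."""
    vals = img[restrict] if restrict is not None else img.ravel()
    if vals.size == 0 or np.ptp(vals) == 0:
        return np.zeros(img.shape, dtype=bool)
    thr = threshold_otsu(vals, nbins=256)
    mask = img > thr
    if restrict is not None:
        mask &= restrict
    return mask


def segment_compartments(
    cell_labels: np.ndarray,
    ri_slice: np.ndarray,
    channels: dict[str, np.ndarray] | None = None,
    rules: tuple[SegmentationRule, ...] = DEFAULT_RULES,
    cytoplasm_label: int = 1,
    erosion_px: int = 0,
) -> CompartmentLabels:
    """Assign compartment labels within the segmented cells.

    With no fluorescence channels and no applicable rules the result is
    simply {background, cell}.  ``erosion_px`` optionally erodes organelle
    masks to guard against lipid-rich perinuclear contamination of the
    cytoplasm estimate.
    """
    channels = channels or {}
    cell_mask = np.asarray(cell_labels) > 0
    out = np.where(cell_mask, cytoplasm_label, 0).astype(np.int32)
    table: dict[int, dict] = {}
    if cell_mask.any():
        table[cytoplasm_label] = {"name": "cytoplasm", "source": "ri", "material": "two_substance"}

    masks: dict[str, np.ndarray] = {}
    # precedence: later rules overwrite earlier ones, and organelle rules are
    # applied after the nucleus/nucleolus chain below
    ri_rules = [r for r in rules if r.source == "ri"]
    fluo_rules = [r for r in rules if r.source != "ri"]
    for rule in fluo_rules:
        if rule.source not in channels:
            raise ValueError(f"rule {rule.name!r} references missing channel {rule.source!r}")
        mask = _otsu_mask(np.asarray(channels[rule.source], dtype=float)) & cell_mask
        if erosion_px > 0 and rule.within is None and rule.name not in ("nucleus",):
            mask = ndi.binary_erosion(mask, iterations=erosion_px)
        masks[rule.name] = mask
        out[mask] = rule.label
        table[rule.label] = {"name": rule.name, "source": rule.source, "material": rule.material}
    for rule in ri_rules:
        restrict = masks.get(rule.within) if rule.within else cell_mask
        if restrict is None:
            raise ValueError(f"rule {rule.name!r} is restricted to missing compartment {rule.within!r}")
        mask = _otsu_mask(np.asarray(ri_slice, dtype=float), restrict)
        masks[rule.name] = mask
        out[mask] = rule.label
        table[rule.label] = {"name": rule.name, "source": "ri", "material": rule.material}
    return CompartmentLabels(image=out, table=table)


def crop_roi(img: np.ndarray, center_px: tuple[int, int], size_px: int) -> np.ndarray:
    """Square region-of-interest crop (the manually chosen scan regions
    around stress granules are represented by this utility)."""
    h = size_px // 2
    cy, cx = center_px
    sl = (slice(max(cy - h, 0), cy + h + 1), slice(max(cx - h, 0), cx + h + 1))
    return img[sl]
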