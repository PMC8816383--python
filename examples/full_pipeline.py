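"""Full pipeline on a simulated cell phantom.

Simulates raw data (holograms, fluorescence, Brillouin raster spectra) for
a three-compartment cell, then runs reconstruction, spectrum evaluation,
segmentation, registration and the modulus computation, and prints the
per-compartment summary.
"""

import tempfile
from pathlib import Path

from fobtools.config import RunConfig
from fobtools import pipeline

config = RunConfig.model_validate({
    "phantom": {"preset": "cell", "grid_shape": (48, 96, 96),
                "voxel_size_um": (0.15, 0.15, 0.15)},
    "geometry": {"pixel_pitch_um": 0.15, "axial_pitch_um": 0.15},
    "simulation": {"seed": 1, "n_angles": 40, "brillouin_raster": (21, 21)},
    "reconstruction": {"iterations": 40},
})

with tempfile.TemporaryDirectory() as tmp:
    table = pipeline.run_all(config, Path(tmp) / "cell.h5")

summary = table[table.quantity.isin(["ri", "modulus_gpa"])]
print(summary.to_string(index=False,
                        columns=["compartment", "quantity", "n", "mean", "sem"]))
print("\nphantom ground truth: cytoplasm n=1.3545 / M'~2.41 GPa, "
      "nucleus n=1.3522 / 2.448 GPa, nucleolus n=1.3618 / 2.487 GPa")
print("the nucleus shows lower RI (lower density) than the cytoplasm yet a "
      "higher longitudinal modulus — density and RI must be measured, not assumed")
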