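"""Longitudinal modulus from published compartment means.

Evaluates M' = rho * (lambda * nu_B / (2 n cos(theta/2)))^2 at 532 nm in
backscattering for the HeLa nucleoplasm and the PAA bead of the validation
phantom, plus the dry-mass concentration of polyQ aggregates from their RI.
"""

import numpy as np

from fobtools import modulus_point
from fobtools.mechanics import PROTEIN_MODEL, concentration_from_ri

cases = [
    ("HeLa nucleoplasm", 1.3522, 7.872, 1.0207),
    ("HeLa cytoplasm  ", 1.3545, 7.811, 1.0234),
    ("PAA bead        ", 1.3485, 7.574, 1.019),
]
print("compartment         n       nu_B (GHz)  rho (g/ml)  M' (GPa)")
for name, n, shift, rho in cases:
    m = modulus_point(n, shift, rho)
    print(f"{name}  {n:.4f}  {shift:10.3f}  {rho:10.4f}  {m:8.3f}")

c, _ = concentration_from_ri(np.array([[1.3856]]), PROTEIN_MODEL)
print(f"\npolyQ aggregate dry-mass concentration: {c[0, 0]:.1f} mg/ml")
print("(RI 1.3856 against fluid RI 1.337 with refraction increment 0.190 ml/g)")
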