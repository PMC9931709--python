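"""Mixed exciton states of a strongly coupled chlorophyll dimer.

Diagonalizes a dimer Hamiltonian to show how coupling redistributes
oscillator strength between the upper and lower mixed states, and
evaluates how small the lower state's dipole would have to be to explain
a 12-fold intrinsic emission-intensity ratio by oscillator strengths
alone.
"""

import numpy as np

from frlhc.excitons import (
    ExcitonSystem,
    diagonalize,
    dimer_intensity_ratio_to_dipole_ratio,
)

mu = np.array([0.0, 4.6, 0.0])  # Debye, parallel site dipoles
system = ExcitonSystem(
    pigment_ids=["chl_a", "chl_b"],
    site_energies=np.array([14124.0, 14124.0]),  # ~708 nm in cm^-1
    couplings=np.array([[0.0, 150.0], [150.0, 0.0]]),
)
states = diagonalize(system, [mu, mu])
for label, s in zip(("lower", "upper"), states):
    print(f"{label} state: E = {s.energy:8.1f} cm^-1, "
          f"|mu|^2 = {s.oscillator_weight:6.2f} D^2")
print("-> the in-phase (upper) state carries all the intensity; the "
      "out-of-phase state is dark (H-dimer limit).")

ratio = dimer_intensity_ratio_to_dipole_ratio(12.0)
print(f"\nto explain a 12x intensity ratio by oscillator strength, the "
      f"lower state's dipole must shrink to {100 * ratio:.1f}% of the "
      f"upper's -- a reduction no realistic pair geometry delivered, "
      f"favouring the pigment-number (entropy) explanation instead.")
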