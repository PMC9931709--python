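"""Two-pool Arrhenius analysis of a temperature-dependent emission series.

Generates two-Gaussian fluorescence spectra (F713/F730 bands) between
87 K and 273 K obeying the two-pool equilibrium, fits them with shared
peak positions, and recovers the intrinsic intensity ratio with the
energy gap fixed at 318 cm^-1.
"""

import numpy as np

from frlhc.arrhenius import (
    AreaRatioSeries,
    TwoPoolModel,
    energy_to_temperature,
    fit_intensity_ratio,
)
from frlhc.spectra import fit_shared_peak_series
from frlhc.synthetic import make_temperature_series

model = TwoPoolModel(delta_e=318.0, intensity_ratio=12.0)
temps = np.linspace(87.0, 273.0, 8)
spectra, _ = make_temperature_series(model, temps, noise_sd=0.02, seed=1)

per, peaks, _ = fit_shared_peak_series(spectra, peaks=[713.0, 730.0],
                                       fix_peaks=True)
ratios = np.array([c[0].area / c[1].area for c in per])
print("T (K)   Area_F713/Area_F730")
for t, r in zip(temps, ratios):
    print(f"{t:6.1f}   {r:.3f}")
print("-> the F713 band grows with temperature: uphill transfer into the "
      "larger pool is thermally activated.")

fit = fit_intensity_ratio(AreaRatioSeries(temps, ratios), delta_e_fixed=318.0)
print(f"\ngap fixed at 318 cm^-1 (= {energy_to_temperature(318.0):.0f} K); "
      f"fitted intrinsic ratio I_F713/I_F730 = "
      f"{fit['intensity_ratio']:.2f} (truth 12)")
print("-> a ~12-fold intrinsic ratio matches a ~10:1 pigment-number ratio "
      "between the two far-red pools.")
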