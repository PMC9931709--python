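"""Two-pool Arrhenius analysis of temperature-dependent emission ratios.

Two chlorophyll pools in thermal equilibrium (the F713-emitting and the
F730-emitting long-wavelength pools) share excitation; the ratio of their
band areas follows

    Area_F713 / Area_F730 = (I_F713 / I_F730) * exp(-dE / k_B T),

with dE > 0 the excited-state energy gap of the higher-energy pool above
the lower one and I_F713/I_F730 the intrinsic (infinite-temperature)
intensity ratio, set by the pigment-number ratio of the pools. The same
quantity equals the detailed-balance rate ratio k_up/k_down of the
backward (uphill) over forward (downhill) transfer, with the degeneracy
(pigment-number) factor multiplying the uphill rate.

Fitting is done in log space — ln(ratio) linear in 1/T (an Arrhenius
plot) — with the gap held fixed, leaving a single intercept parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .constants import HC_OVER_KB_CM_K, nm_to_wavenumber


def wavenumber_gap(lambda_hi: float, lambda_lo: float) -> float:
    """Energy gap (cm^-1) between a higher-energy band at ``lambda_hi`` nm
    and a lower-energy band at ``lambda_lo`` nm: 1e7/l_hi - 1e7/l_lo."""
    if lambda_hi <= 0 or lambda_lo <= 0:
        raise ValueError("wavelengths must be positive")
    if lambda_hi > lambda_lo:
        raise ValueError("higher-energy band must have the shorter wavelength")
    return float(nm_to_wavenumber(lambda_hi) - nm_to_wavenumber(lambda_lo))


def energy_to_temperature(delta_e_cm: float) -> float:
    """Express an energy gap (cm^-1) as a temperature (K) via hc/k_B;
    e.g. 318 cm^-1 -> 457.5 K (rounds to 458 K)."""
    return delta_e_cm * HC_OVER_KB_CM_K


#: The fixed gap used in reproduction runs (cm^-1). Note 1e7/713 - 1e7/730
#: = 326.6 cm^-1; both numbers are exposed, this constant is the
#: conventional fixed value.
FIXED_GAP_713_730 = 318.0


@dataclass
class TwoPoolModel:
    """Energy gap + intrinsic intensity ratio + pigment-number ratio."""

    delta_e: float  # cm^-1, E(high pool excited) - E(low pool excited)
    intensity_ratio: float = 12.0  # I_F713 / I_F730
    pigment_ratio: float = 10.0  # N_708 / N_725

    def __post_init__(self):
        if self.delta_e < 0:
            raise ValueError("delta_e must be >= 0")
        if self.intensity_ratio <= 0 or self.pigment_ratio <= 0:
            raise ValueError("ratios must be positive")


@dataclass
class AreaRatioSeries:
    temperatures: np.ndarray  # K
    ratios: np.ndarray  # Area_F713 / Area_F730
    ratio_errors: np.ndarray | None = None

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.temperatures.shape != self.ratios.shape:
            raise ValueError("temperatures and ratios must match")
        if np.any(self.temperatures <= 0):
            raise ValueError("temperatures must be positive")
        if self.ratio_errors is not None:
            self.ratio_errors = np.asarray(self.ratio_errors, dtype=float)
            if self.ratio_errors.shape != self.ratios.shape:
                raise ValueError("ratio_errors must match ratios")

    @classmethod
    def read(cls, path: str | Path) -> "AreaRatioSeries":
        """Delimiter-separated (T_K, ratio[, error]) rows; '#' comments."""
        t, r, e = [], [], []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            t.append(float(parts[0]))
            r.append(float(parts[1]))
            if len(parts) > 2:
                e.append(float(parts[2]))
        err = np.array(e) if len(e) == len(t) else None
        return cls(np.array(t), np.array(r), err)


def predict_ratio(model: TwoPoolModel, temperature_k) -> np.ndarray | float:
    """Band-area ratio at temperature T: I_ratio * exp(-dE * hc/k_B / T)."""
    t = np.asarray(temperature_k, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperature must be positive")
    out = model.intensity_ratio * np.exp(
        -model.delta_e * HC_OVER_KB_CM_K / t
    )
    return float(out) if np.isscalar(temperature_k) else out


def fit_intensity_ratio(
    series: AreaRatioSeries, delta_e_fixed: float = FIXED_GAP_713_730
) -> dict:
    """Weighted least-squares Arrhenius fit with the gap fixed.

    ln(ratio) = ln(I_ratio) - dE*(hc/k_B)/T  with dE fixed leaves a single
    intercept. Weights are 1/sigma_ln^2 with sigma_ln = ratio_error/ratio
    when errors are provided. Returns ``{"intensity_ratio",
    "intensity_ratio_stderr", "delta_e"}``.
    """
    if len(series.temperatures) < 2:
        raise ValueError("need at least two temperatures")
    if np.any(series.ratios <= 0):
        raise ValueError("ratios must be positive for the log-space fit")
    y = np.log(series.ratios) + delta_e_fixed * HC_OVER_KB_CM_K / series.temperatures
    if series.ratio_errors is not None:
        sigma = series.ratio_errors / series.ratios
        w = 1.0 / sigma**2
    else:
        w = np.ones_like(y)
    intercept = float(np.sum(w * y) / np.sum(w))
    n = len(y)
    resid = y - intercept
    var = float(np.sum(w * resid**2) / (np.sum(w) * max(n - 1, 1)))
    ratio = float(np.exp(intercept))
    return {
        "intensity_ratio": ratio,
        "intensity_ratio_stderr": ratio * float(np.sqrt(var)),
        "delta_e": float(delta_e_fixed),
    }


def equilibrium_check(model: TwoPoolModel, temperature_k: float) -> dict:
    """Detailed-balance ratio of the uphill over the downhill transfer rate,
    k_up/k_down = (N_high/N_low) * exp(-dE * hc/k_B / T)."""
    if temperature_k <= 0:
        raise ValueError("temperature must be positive")
    ratio = model.pigment_ratio * np.exp(
        -model.delta_e * HC_OVER_KB_CM_K / temperature_k
    )
    return {"uphill_over_downhill_rate_ratio": float(ratio)}
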