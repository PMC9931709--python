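"""Compartmental kinetics of entropy-driven uphill energy transfer.

Pools of isoenergetic pigments (bulk chlorophylls, a main far-red pool and
a further red-shifted pool) exchange excitation. Downhill transfer rates
are specified; each uphill rate is derived from detailed balance with a
degeneracy (pigment-number) factor,

    k_up / k_down = (N_up_target / N_down_target) * exp(-dE / k_B T),

so the sink-free stationary populations are Boltzmann weighted by pool
size, p_i ~ N_i exp(-E_i / k_B T). Because the uphill destination holds
many more pigments than the far-red pool, the uphill rate is entropically
enhanced: thermal activation alone gives exp(-dE/k_B T) (about 5% for a
708 nm -> 680 nm gap at 278 K) and the ~3:1 pigment abundance lifts the
effective probability to about 15%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .constants import HC_OVER_KB_CM_K, nm_to_wavenumber


def boltzmann_uphill_fraction(
    lambda_low_energy: float, lambda_high_energy: float, temperature_k: float
) -> float:
    """Unnormalized Boltzmann factor exp(-dE / k_B T) for promoting an
    excitation from the band at ``lambda_low_energy`` (nm, longer
    wavelength) up to ``lambda_high_energy`` (nm)."""
    if not (lambda_low_energy >= lambda_high_energy > 0):
        raise ValueError("need lambda_low_energy >= lambda_high_energy > 0")
    if temperature_k <= 0:
        raise ValueError("temperature must be positive")
    de = nm_to_wavenumber(lambda_high_energy) - nm_to_wavenumber(lambda_low_energy)
    return float(np.exp(-de * HC_OVER_KB_CM_K / temperature_k))


def boltzmann_two_level_population(
    lambda_low_energy: float, lambda_high_energy: float, temperature_k: float
) -> float:
    """Normalized upper-level population of the two-level system,
    f/(1+f) with f the unnormalized factor. Exposed alongside the
    unnormalized form; the two differ only in the second decimal here."""
    f = boltzmann_uphill_fraction(lambda_low_energy, lambda_high_energy,
                                  temperature_k)
    return f / (1.0 + f)


def degeneracy_weighted_uphill(fraction: float, degeneracy_ratio: float) -> float:
    """Entropy-corrected uphill probability: min(1, fraction * ratio)."""
    if fraction < 0 or degeneracy_ratio < 0:
        raise ValueError("inputs must be nonnegative")
    return min(1.0, fraction * degeneracy_ratio)


@dataclass
class Pool:
    name: str
    n_pigments: int  # degeneracy
    excited_energy: float  # cm^-1 (absolute wavenumber or relative offset)
    radiative_weight: float = 1.0
    sink_rate: float = 0.0  # ps^-1, total deexcitation (fluorescence, heat, ...)

    def __post_init__(self):
        if self.n_pigments < 1:
            raise ValueError("n_pigments must be >= 1")
        if self.sink_rate < 0 or self.radiative_weight < 0:
            raise ValueError("rates must be nonnegative")

    @classmethod
    def from_wavelength(cls, name, n_pigments, wavelength_nm, **kw) -> "Pool":
        return cls(name, n_pigments, float(nm_to_wavenumber(wavelength_nm)), **kw)


@dataclass
class KineticScheme:
    """Pools + downhill transfer rates; uphill rates derived on demand.

    ``downhill_rates`` maps (from_pool, to_pool) names to rates (ps^-1)
    where the transfer must be downhill or isoenergetic (E_from >= E_to);
    the reverse (uphill) rate for each pair follows from detailed balance
    at ``temperature``.
    """

    pools: list[Pool]
    downhill_rates: dict[tuple[str, str], float]
    temperature: float  # K

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        names = [p.name for p in self.pools]
        if len(names) != len(set(names)):
            raise ValueError("pool names must be unique")
        self._index = {n: i for i, n in enumerate(names)}
        for (src, dst), rate in self.downhill_rates.items():
            if rate < 0:
                raise ValueError("transfer rates must be nonnegative")
            if self.pool(src).excited_energy < self.pool(dst).excited_energy:
                raise ValueError(
                    f"rate {src}->{dst} is uphill; specify the downhill "
                    "direction and let detailed balance derive the reverse"
                )

    def pool(self, name: str) -> Pool:
        return self.pools[self._index[name]]

    def uphill_rate(self, src: str, dst: str) -> float:
        """Detailed-balance uphill rate dst<-src given downhill dst->src."""
        k_down = self.downhill_rates[(dst, src)]
        hi, lo = self.pool(dst), self.pool(src)
        de = hi.excited_energy - lo.excited_energy
        return (
            k_down
            * (hi.n_pigments / lo.n_pigments)
            * np.exp(-de * HC_OVER_KB_CM_K / self.temperature)
        )

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.pools]


def build_rate_matrix(scheme: KineticScheme) -> np.ndarray:
    """Rate matrix K (ps^-1) of dp/dt = K p.

    Off-diagonal K[i, j] is the rate j -> i (downhill as specified, uphill
    from detailed balance with degeneracy); diagonal entries make each
    column sum to -sink_rate of that pool, so with zero sinks columns sum
    to zero exactly (probability conservation).
    """
    n = len(scheme.pools)
    k = np.zeros((n, n))
    idx = scheme._index
    for (src, dst), rate in scheme.downhill_rates.items():
        i, j = idx[dst], idx[src]
        k[i, j] += rate  # downhill src -> dst
        k[j, i] += scheme.uphill_rate(src=dst, dst=src)  # uphill dst -> src
    for j, pool in enumerate(scheme.pools):
        off = k[:, j].sum() - k[j, j]
        k[j, j] = -(off + pool.sink_rate)
    return k


def relaxation_rates(scheme: KineticScheme) -> np.ndarray:
    """Decay rates (ps^-1, ascending) of the kinetic eigenmodes: the
    negated real parts of the rate-matrix eigenvalues."""
    evals = np.linalg.eigvals(build_rate_matrix(scheme))
    return np.sort(-evals.real)


def relax(
    scheme: KineticScheme, initial, t_grid: np.ndarray
) -> np.ndarray:
    """Populations over time: solves dp/dt = K p by eigen-decomposition
    (falls back to the matrix exponential for defective K).

    Returns an array of shape (len(t_grid), n_pools).
    """
    k = build_rate_matrix(scheme)
    p0 = np.asarray(initial, dtype=float)
    if p0.shape != (len(scheme.pools),):
        raise ValueError("initial must give one population per pool")
    t_grid = np.asarray(t_grid, dtype=float)
    connected = (np.abs(k - np.diag(np.diag(k))).sum(axis=0)
                 + np.abs(k - np.diag(np.diag(k))).sum(axis=1)) > 0
    if np.any(~connected & (p0 > 0)) and len(scheme.pools) > 1:
        warnings.warn("initially populated pool is disconnected", stacklevel=2)
    evals, evecs = np.linalg.eig(k)
    try:
        coef = np.linalg.solve(evecs, p0)
        out = np.real(
            (evecs[None, :, :] * np.exp(np.outer(t_grid, evals))[:, None, :])
            @ coef
        )
    except np.linalg.LinAlgError:
        out = np.array([scipy.linalg.expm(k * t) @ p0 for t in t_grid])
    return np.clip(out, 0.0, None)


def pool_fluorescence(populations: np.ndarray, pools: list[Pool]) -> np.ndarray:
    """Per-pool emission traces: emission_i(t) = radiative_weight_i * p_i(t)."""
    weights = np.array([p.radiative_weight for p in pools])
    return populations * weights[None, :]


def stationary_populations(scheme: KineticScheme) -> np.ndarray:
    """Stationary distribution of the sink-free scheme (Boltzmann with
    degeneracy): p_i ~ N_i exp(-E_i / k_B T), normalized."""
    e = np.array([p.excited_energy for p in scheme.pools])
    n = np.array([p.n_pigments for p in scheme.pools])
    w = n * np.exp(-(e - e.min()) * HC_OVER_KB_CM_K / scheme.temperature)
    return w / w.sum()


def pair_rates_from_relaxation(
    relaxation_time_ps: float, uphill_over_downhill: float
) -> tuple[float, float]:
    """Split a two-pool equilibration time 1/(k_up + k_down) into its
    uphill and downhill rates given their detailed-balance ratio."""
    total = 1.0 / relaxation_time_ps
    k_down = total / (1.0 + uphill_over_downhill)
    return total - k_down, k_down


def default_scheme(temperature_k: float = 273.0, psii_drain: float = 0.0
                   ) -> KineticScheme:
    """Three-pool scheme of the far-red antenna.

    Pools: bulk chlorophylls (680 nm, 30 pigments), the main far-red pool
    (708 nm, 10 pigments, emitting F713) and the red-shifted pool (725 nm,
    1 pigment, emitting F730); abundances follow the ~3:1 bulk:far-red
    absorption ratio and the 10:1 pigment-number ratio of the two far-red
    pools. Downhill bulk->708 transfer is set so the bulk/708 pair
    equilibrates in 25 ps at 273 K; 708->725 downhill transfer is 1/250
    ps^-1; terminal sinks are 1/2200 ps^-1 on the bulk and 708 pools and
    1/1900 ps^-1 on the 725 pool. An optional extra PSII drain (ps^-1)
    adds to the bulk-pool sink.
    """
    bulk = Pool.from_wavelength("bulk", 30, 680.0,
                                sink_rate=1.0 / 2200.0 + psii_drain)
    lwc708 = Pool.from_wavelength("lwc708", 10, 708.0, sink_rate=1.0 / 2200.0)
    lwc725 = Pool.from_wavelength("lwc725", 1, 725.0, sink_rate=1.0 / 1900.0)
    # bulk<->708: equilibration time fixed at 25 ps at the reference 273 K
    de = bulk.excited_energy - lwc708.excited_energy
    ratio = (bulk.n_pigments / lwc708.n_pigments) * np.exp(
        -de * HC_OVER_KB_CM_K / 273.0
    )
    _, k_down = pair_rates_from_relaxation(25.0, ratio)
    return KineticScheme(
        pools=[bulk, lwc708, lwc725],
        downhill_rates={("bulk", "lwc708"): k_down,
                        ("lwc708", "lwc725"): 1.0 / 250.0},
        temperature=temperature_k,
    )


def populations_table(t_grid, populations, scheme: KineticScheme) -> pd.DataFrame:
    df = pd.DataFrame(populations, columns=scheme.names)
    df.insert(0, "time_ps", np.asarray(t_grid, dtype=float))
    return df
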