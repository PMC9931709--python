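"""Global reconvolution analysis of time-resolved fluorescence.

Each wavelength channel is modelled as a sum of exponentials gated by the
Heaviside step and convolved with the instrument response function (IRF),

    F_lambda(t) = [ sum_i A_i(lambda) exp(-t/tau_i) H(t) ] (x) I(t),

with the lifetimes tau_i shared by every channel (global fitting). The
per-channel pre-exponential amplitudes A_i(lambda), plotted against
wavelength, are the fluorescence decay-associated spectra (FDAS): a
positive/negative amplitude at a given wavelength means the fluorescence
there decays/rises with that lifetime, so an energy-transfer component
shows a positive lobe on the donor (short-wavelength) side and a negative
lobe on the acceptor (long-wavelength) side.

The fit is solved by variable projection: amplitudes are the exact linear
least-squares solution per channel at fixed lifetimes, and the outer
nonlinear search runs over log-lifetimes and an IRF shift (time zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import fftconvolve


class NonUniformGridError(ValueError):
    """Raised when a time grid is not uniform (resample first)."""


def _check_uniform(times: np.ndarray) -> float:
    dt = np.diff(times)
    if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
        raise NonUniformGridError("time grid must be uniform")
    return float(dt[0])


@dataclass
class TimeResolvedDataset:
    times: np.ndarray  # ps, increasing uniform grid
    wavelengths: np.ndarray  # nm
    counts: np.ndarray  # (n_times, n_wavelengths), >= 0
    irf: np.ndarray  # counts on the same time grid
    temperature: float | None = None  # K

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        self.irf = np.asarray(self.irf, dtype=float)
        if self.counts.shape != (len(self.times), len(self.wavelengths)):
            raise ValueError("counts must be (n_times, n_wavelengths)")
        if self.irf.shape != self.times.shape:
            raise ValueError("irf must live on the time grid")
        if np.any(self.irf < 0) or self.irf.sum() <= 0:
            raise ValueError("irf must be nonnegative with positive sum")

    def write(self, matrix_path: str | Path, irf_path: str | Path) -> None:
        header = "time_ps\t" + "\t".join(f"{w:.2f}" for w in self.wavelengths)
        lines = [header]
        if self.temperature is not None:
            lines.insert(0, f"# temperature {self.temperature}")
        for t, row in zip(self.times, self.counts):
            lines.append("\t".join([f"{t:.4f}"] + [f"{v:.6g}" for v in row]))
        Path(matrix_path).write_text("\n".join(lines) + "\n")
        irf_lines = [f"{t:.4f}\t{v:.6g}" for t, v in zip(self.times, self.irf)]
        Path(irf_path).write_text("\n".join(irf_lines) + "\n")

    @classmethod
    def read(cls, matrix_path: str | Path, irf_path: str | Path
             ) -> "TimeResolvedDataset":
        temperature = None
        rows = []
        header = None
        for line in Path(matrix_path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("temperature"):
                    temperature = float(body.split(None, 1)[1])
                continue
            if header is None:
                header = line.split("\t")
                continue
            rows.append([float(x) for x in line.split("\t")])
        arr = np.array(rows)
        wl = np.array([float(x) for x in header[1:]])
        irf_rows = np.loadtxt(str(irf_path))
        return cls(times=arr[:, 0], wavelengths=wl, counts=arr[:, 1:],
                   irf=irf_rows[:, 1], temperature=temperature)


def gaussian_irf(times: np.ndarray, fwhm: float, center: float) -> np.ndarray:
    """Parametric Gaussian IRF trace on a time grid (area-normalized later)."""
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((np.asarray(times, float) - center) / sigma) ** 2)


def _shifted_kernel(times: np.ndarray, irf: np.ndarray, time_zero: float
                    ) -> np.ndarray:
    """IRF shifted by ``time_zero`` (interpolated) and normalized to unit sum."""
    shifted = np.interp(times - time_zero, times, irf, left=0.0, right=0.0)
    total = shifted.sum()
    if total <= 0:
        raise ValueError("IRF vanished after shifting; time_zero out of range")
    return shifted / total


def _decay_basis(times: np.ndarray, lifetimes: np.ndarray) -> np.ndarray:
    """Step-gated exponentials on the grid, time measured from grid start.

    The sample at the discontinuity uses the trapezoid convention
    H(0) = 1/2, which removes the leading O(dt) bias of the discrete
    convolution against the continuous reconvolution integral.
    """
    t_rel = times - times[0]
    basis = np.exp(-np.outer(t_rel, 1.0 / np.asarray(lifetimes, float)))
    basis[0] *= 0.5
    return basis


def model_trace(
    amplitudes,
    lifetimes,
    times: np.ndarray,
    irf: np.ndarray,
    time_zero: float = 0.0,
) -> np.ndarray:
    """Reconvolved multi-exponential model on the data grid.

    The step-gated exponential sum (per-component amplitudes, lifetimes in
    ps) is discretely convolved with the shifted, sum-normalized IRF. With
    a discrete-delta IRF the model is the bare exponential sum shifted to
    the delta position.
    """
    times = np.asarray(times, dtype=float)
    _check_uniform(times)
    amplitudes = np.asarray(amplitudes, dtype=float)
    lifetimes = np.asarray(lifetimes, dtype=float)
    if np.any(lifetimes <= 0):
        raise ValueError("lifetimes must be positive")
    kernel = _shifted_kernel(times, np.asarray(irf, float), time_zero)
    decay = _decay_basis(times, lifetimes) @ amplitudes
    return fftconvolve(decay, kernel)[: len(times)]


@dataclass
class GlobalFitResult:
    lifetimes: np.ndarray  # ps, ascending
    amplitudes: np.ndarray  # (n_components, n_wavelengths) — the FDAS
    time_zero: float  # ps
    reduced_residual: float  # rms residual per data point
    n_components: int
    wavelengths: np.ndarray | None = None

    def fdas_table(self):
        import pandas as pd

        data = {"wavelength_nm": self.wavelengths}
        for i, tau in enumerate(self.lifetimes):
            data[f"A_tau_{tau:.4g}ps"] = self.amplitudes[i]
        return pd.DataFrame(data)


def _project_amplitudes(basis_conv: np.ndarray, counts: np.ndarray,
                        weights: np.ndarray | None):
    """Per-channel linear least squares at fixed lifetimes (variable
    projection). Returns (amplitudes (n_comp, n_wl), residual matrix)."""
    if weights is None:
        amps, *_ = np.linalg.lstsq(basis_conv, counts, rcond=None)
        resid = basis_conv @ amps - counts
    else:
        n_wl = counts.shape[1]
        amps = np.empty((basis_conv.shape[1], n_wl))
        resid = np.empty_like(counts)
        for j in range(n_wl):
            w = np.sqrt(weights[:, j])
            a, *_ = np.linalg.lstsq(basis_conv * w[:, None],
                                    counts[:, j] * w, rcond=None)
            amps[:, j] = a
            resid[:, j] = (basis_conv @ a - counts[:, j]) * w
    return amps, resid


def global_fit(
    data: TimeResolvedDataset,
    n_components: int,
    init,
    fit_time_zero: bool = True,
    poisson_weights: bool = False,
    max_nfev: int = 400,
) -> GlobalFitResult:
    """Global reconvolution fit with shared lifetimes.

    Parameters
    ----------
    n_components
        Number of exponential components.
    init
        Initial lifetime guesses (ps), length ``n_components``.
    poisson_weights
        If true, channels are weighted by 1/max(counts, 1).

    Raises a warning when two fitted lifetimes converge within 5%
    (over-parameterized model).
    """
    if n_components < 1:
        raise ValueError("need at least one component")
    init = np.asarray(init, dtype=float)
    if init.shape != (n_components,) or np.any(init <= 0):
        raise ValueError("init must give one positive lifetime per component")
    if not np.any(data.counts):
        raise ValueError("counts are all zero")
    dt = _check_uniform(data.times)
    n_t = len(data.times)
    weights = 1.0 / np.maximum(data.counts, 1.0) if poisson_weights else None

    def build_basis(log_taus, t0):
        kernel = _shifted_kernel(data.times, data.irf, t0)
        basis = _decay_basis(data.times, np.exp(log_taus))
        conv = np.empty((n_t, n_components))
        for i in range(n_components):
            conv[:, i] = fftconvolve(basis[:, i], kernel)[:n_t]
        return conv

    span = data.times[-1] - data.times[0]

    def unpack(params):
        log_taus = params[:n_components]
        t0 = params[n_components] if fit_time_zero else 0.0
        return log_taus, t0

    def resid(params):
        log_taus, t0 = unpack(params)
        conv = build_basis(log_taus, t0)
        _, r = _project_amplitudes(conv, data.counts, weights)
        return r.ravel()

    p0 = np.log(init)
    lo = np.full(n_components, np.log(dt * 1e-3))
    hi = np.full(n_components, np.log(span * 100))
    if fit_time_zero:
        p0 = np.append(p0, 0.0)
        lo = np.append(lo, -span / 4)
        hi = np.append(hi, span / 4)

    sol = least_squares(resid, p0, bounds=(lo, hi), method="trf",
                        xtol=1e-13, ftol=1e-13, max_nfev=max_nfev)
    log_taus, t0 = unpack(sol.x)
    taus = np.exp(log_taus)
    conv = build_basis(log_taus, t0)
    amps, r = _project_amplitudes(conv, data.counts, weights)

    order = np.argsort(taus)
    taus = taus[order]
    amps = amps[order]
    close = np.diff(taus) / taus[:-1] < 0.05
    if np.any(close):
        warnings.warn(
            "two lifetimes converged within 5%; the model may have more "
            "components than the data can distinguish",
            stacklevel=2,
        )
    return GlobalFitResult(
        lifetimes=taus,
        amplitudes=amps,
        time_zero=float(t0),
        reduced_residual=float(np.sqrt(np.mean(r**2))),
        n_components=n_components,
        wavelengths=data.wavelengths,
    )


def suggest_n_components(
    data: TimeResolvedDataset,
    init_grid=(25.0, 250.0, 2200.0, 5000.0),
    improvement: float = 0.05,
    max_components: int = 4,
) -> int:
    """Smallest number of components for which adding one more improves the
    reduced residual by less than ``improvement`` (fractional)."""
    prev = None
    for n in range(1, max_components + 1):
        fit = global_fit(data, n, np.asarray(init_grid[:n]))
        if prev is not None and (prev - fit.reduced_residual) / prev < improvement:
            return n - 1
        prev = fit.reduced_residual
    return max_components


def rise_time_constant(k_up: float, k_down: float) -> float:
    """Observed rise/equilibration time constant of a two-pool exchange:
    tau = 1 / (k_up + k_down) (ps for rates in ps^-1)."""
    total = k_up + k_down
    if total <= 0:
        raise ValueError("k_up + k_down must be positive")
    return 1.0 / total
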