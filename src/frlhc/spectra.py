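"""Gaussian decomposition of steady-state spectra.

Workflow mirroring standard band-deconvolution practice on chlorophyll Qy
spectra: single-point baseline zeroing and Qy-peak normalization, peak
seeding from smoothed second/fourth derivatives, then trust-region
least-squares fitting of a Gaussian sum — optionally a simultaneous fit of
a temperature series under the constraint that band peak positions are
shared by every spectrum.

Fitting is done in the wavelength (nm) domain. Gaussians are parameterized
as amplitude * exp(-(x - peak)^2 / (2 width^2)) with width the standard
deviation, so area = amplitude * width * sqrt(2 pi).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import argrelextrema, savgol_filter

SQRT_2PI = float(np.sqrt(2.0 * np.pi))


class FitConvergenceError(RuntimeError):
    def __init__(self, message, last_params=None, residual=None):
        super().__init__(message)
        self.last_params = last_params
        self.residual = residual


@dataclass
class Spectrum:
    wavelengths: np.ndarray  # nm, strictly increasing
    values: np.ndarray  # a.u.
    kind: str = "absorbance"  # absorbance | fluorescence
    temperature: float | None = None  # K

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape:
            raise ValueError("wavelength and value arrays must match")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum values must be finite")

    def value_at(self, wavelength: float) -> float:
        if not (self.wavelengths[0] <= wavelength <= self.wavelengths[-1]):
            raise ValueError(f"{wavelength} nm outside the grid")
        return float(np.interp(wavelength, self.wavelengths, self.values))

    @classmethod
    def read(cls, path: str | Path) -> "Spectrum":
        """Two-column text (wavelength, value); '#' headers may carry
        ``# kind ...`` and ``# temperature ...``."""
        kind, temperature = "absorbance", None
        wl, vals = [], []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("kind"):
                    kind = body.split(None, 1)[1].strip(" :=")
                elif body.lower().startswith("temperature"):
                    temperature = float(body.split(None, 1)[1].strip(" :="))
                continue
            a, b = line.replace(",", " ").split()[:2]
            wl.append(float(a))
            vals.append(float(b))
        return cls(np.array(wl), np.array(vals), kind=kind, temperature=temperature)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# kind {self.kind}\n")
            if self.temperature is not None:
                fh.write(f"# temperature {self.temperature}\n")
            for w, v in zip(self.wavelengths, self.values):
                fh.write(f"{w:.4f} {v:.8e}\n")


@dataclass
class GaussianComponent:
    peak: float  # nm
    width: float  # nm (standard deviation)
    amplitude: float  # a.u.
    area_fraction: float | None = None

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("width must be positive")

    @property
    def area(self) -> float:
        return self.amplitude * self.width * SQRT_2PI

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.amplitude * np.exp(-((x - self.peak) ** 2) / (2 * self.width**2))


def gaussian_sum(x: np.ndarray, components) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    total = np.zeros_like(x)
    for c in components:
        total += c.evaluate(x)
    return total


def normalize_spectrum(
    s: Spectrum, qy_window: tuple[float, float] = (640.0, 730.0),
    zero_wavelength: float = 750.0,
) -> Spectrum:
    """Zero the spectrum at ``zero_wavelength`` and scale the maximum inside
    ``qy_window`` to 1 (the standard Qy-band normalization)."""
    baseline = s.value_at(zero_wavelength)
    shifted = s.values - baseline
    mask = (s.wavelengths >= qy_window[0]) & (s.wavelengths <= qy_window[1])
    if not np.any(mask):
        raise ValueError("qy_window contains no grid points")
    peak = shifted[mask].max()
    if peak <= 1e-12 * max(1.0, np.abs(s.values).max()):
        raise ValueError("flat spectrum: Qy maximum equals the baseline")
    return Spectrum(
        s.wavelengths.copy(), shifted / peak, kind=s.kind, temperature=s.temperature
    )


def seed_peaks(
    s: Spectrum,
    smoothing: int = 11,
    polyorder: int = 6,
    merge_window: float = 3.0,
    min_value: float = 0.0,
    prominence_frac: float = 0.01,
) -> list[float]:
    """Candidate band positions from derivative analysis.

    Candidates are local minima of the smoothed second derivative together
    with local maxima of the smoothed fourth derivative (both computed by
    Savitzky-Golay smoothing-differentiation with window ``smoothing``).
    Candidates closer than ``merge_window`` nm are merged keeping the
    fourth-derivative position. Candidates where the spectrum is below
    ``min_value`` (absolute) or below ``prominence_frac`` of the spectrum
    maximum are discarded.

    The filter is deliberately conservative: only candidates in concave
    regions of the spectrum survive, which rejects the positive
    fourth-derivative side lobes every isolated band produces but also
    means a weak shoulder buried in a convex tail will not be proposed —
    supply such band positions as explicit fit seeds. On noisy spectra
    use a ``smoothing`` window comparable to the band width in grid
    points.
    """
    n = len(s.wavelengths)
    if n < 9:
        raise ValueError("need at least 9 grid points")
    if smoothing > n:
        raise ValueError("smoothing window larger than the grid")
    if smoothing % 2 == 0:
        smoothing += 1
    polyorder = min(polyorder, smoothing - 1)
    if polyorder < 4:
        raise ValueError("smoothing window too small for a 4th derivative")
    dx = float(np.mean(np.diff(s.wavelengths)))
    d2 = savgol_filter(s.values, smoothing, polyorder, deriv=2, delta=dx)
    d4 = savgol_filter(s.values, smoothing, polyorder, deriv=4, delta=dx)

    idx2 = argrelextrema(d2, np.less, order=2)[0]
    idx4 = argrelextrema(d4, np.greater, order=2)[0]
    # keep only candidates in concave regions: the 4th derivative of a
    # single band has positive side lobes ~3 widths out that would
    # otherwise masquerade as extra components
    idx2 = idx2[d2[idx2] < 0]
    idx4 = idx4[d2[idx4] < 0]

    floor = max(min_value, prominence_frac * s.values.max())
    cands = [(s.wavelengths[i], 2) for i in idx2 if s.values[i] >= floor]
    cands += [(s.wavelengths[i], 4) for i in idx4 if s.values[i] >= floor]
    cands.sort()

    merged: list[tuple[float, int]] = []
    for wl, order in cands:
        if merged and abs(wl - merged[-1][0]) <= merge_window:
            prev_wl, prev_order = merged[-1]
            # on disagreement keep the 4th-derivative position
            if order == 4:
                merged[-1] = (wl, 4)
            elif prev_order == 4:
                pass
            else:
                merged[-1] = ((wl + prev_wl) / 2.0, 2)
        else:
            merged.append((wl, order))
    return [wl for wl, _ in merged]


def _pack(components):
    return np.concatenate([[c.peak, c.width, c.amplitude] for c in components])


def _model_and_jac(params, x, n_comp, fixed_peaks=None):
    """Gaussian-sum model and analytic Jacobian wrt free parameters."""
    y = np.zeros_like(x)
    cols = []
    for k in range(n_comp):
        if fixed_peaks is None:
            mu, sig, amp = params[3 * k : 3 * k + 3]
        else:
            mu = fixed_peaks[k]
            sig, amp = params[2 * k : 2 * k + 2]
        z = (x - mu) / sig
        g = np.exp(-0.5 * z**2)
        y += amp * g
        if fixed_peaks is None:
            cols.append(amp * g * z / sig)  # d/dmu
        cols.append(amp * g * z**2 / sig)  # d/dsigma
        cols.append(g)  # d/damp
    return y, np.column_stack(cols)


def fit_gaussians(
    s: Spectrum,
    seeds,
    widths_guess: float = 10.0,
    fix_peaks: bool = False,
    peak_bounds: float = 15.0,
    integration_window: tuple[float, float] | None = None,
    max_nfev: int = 500,
):
    """Fit a sum of Gaussians to a spectrum.

    Parameters
    ----------
    seeds
        Initial peak positions (nm), e.g. from :func:`seed_peaks`.
    fix_peaks
        If true, peak positions are held exactly at the seeds.
    peak_bounds
        Half-width (nm) of the box constraint around each seed when peaks
        are free.
    integration_window
        Wavelength interval over which component area fractions are
        reported; default the full grid. Fractions always sum to 1 over
        the fitted set within the window.

    Returns ``(components, residual_norm)``.
    """
    seeds = list(seeds)
    if not seeds:
        raise ValueError("need at least one seed")
    x, y = s.wavelengths, s.values
    n = len(seeds)
    dx = float(np.mean(np.diff(x)))
    amp0 = [max(s.value_at(min(max(p, x[0]), x[-1])), 1e-3 * y.max()) for p in seeds]

    if fix_peaks:
        p0 = np.concatenate([[widths_guess, a] for a in amp0])
        lo = np.tile([dx / 2, 0.0], n)
        hi = np.tile([np.inf, np.inf], n)
        fixed = np.array(seeds, dtype=float)
    else:
        p0 = np.concatenate([[p, widths_guess, a] for p, a in zip(seeds, amp0)])
        lo = np.concatenate([[p - peak_bounds, dx / 2, 0.0] for p in seeds])
        hi = np.concatenate([[p + peak_bounds, np.inf, np.inf] for p in seeds])
        fixed = None

    def resid(params):
        model, _ = _model_and_jac(params, x, n, fixed)
        return model - y

    def jac(params):
        _, j = _model_and_jac(params, x, n, fixed)
        return j

    sol = least_squares(
        resid, p0, jac=jac, bounds=(lo, hi), method="trf",
        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=max_nfev,
    )
    if not sol.success and sol.status == 0:
        raise FitConvergenceError(
            "Gaussian fit did not converge", last_params=sol.x,
            residual=float(np.linalg.norm(sol.fun)),
        )
    comps = []
    for k in range(n):
        if fix_peaks:
            mu = seeds[k]
            sig, amp = sol.x[2 * k : 2 * k + 2]
        else:
            mu, sig, amp = sol.x[3 * k : 3 * k + 3]
        comps.append(GaussianComponent(peak=float(mu), width=float(sig),
                                       amplitude=float(amp)))
    comps.sort(key=lambda c: c.peak)
    _assign_fractions(comps, integration_window)
    return comps, float(np.linalg.norm(sol.fun))


def _assign_fractions(comps, window):
    from scipy.special import erf

    def window_area(c: GaussianComponent) -> float:
        if window is None:
            return c.area
        a, b = window
        za = (a - c.peak) / (c.width * np.sqrt(2))
        zb = (b - c.peak) / (c.width * np.sqrt(2))
        return c.area * 0.5 * float(erf(zb) - erf(za))

    areas = np.array([window_area(c) for c in comps])
    total = areas.sum()
    for c, a in zip(comps, areas):
        c.area_fraction = float(a / total) if total > 0 else np.nan


def fit_shared_peak_series(
    spectra: list[Spectrum],
    peaks,
    widths_guess: float = 8.0,
    fix_peaks: bool = False,
    peak_bounds: float = 10.0,
    max_nfev: int = 2000,
):
    """Simultaneous Gaussian fit of several spectra with shared peaks.

    Every spectrum is fitted to the same number of Gaussians; peak
    positions are a single shared parameter set (exactly equal across the
    series), while amplitudes and widths are free per spectrum. This is
    the constraint used for a temperature series of two-band fluorescence
    spectra (e.g. F713/F730).

    Returns ``(per_spectrum_components, shared_peaks, residual_norm)``.
    """
    if len(spectra) < 1:
        raise ValueError("need at least one spectrum")
    peaks = np.asarray(peaks, dtype=float)
    n = len(peaks)
    m = len(spectra)

    # parameter layout: [peaks (n, if free)] + per spectrum [sig, amp] * n
    def split(params):
        if fix_peaks:
            mu = peaks
            rest = params
        else:
            mu = params[:n]
            rest = params[n:]
        return mu, rest.reshape(m, n, 2)

    def resid(params):
        mu, rest = split(params)
        out = []
        for i, s in enumerate(spectra):
            model = np.zeros_like(s.wavelengths)
            for k in range(n):
                sig, amp = rest[i, k]
                z = (s.wavelengths - mu[k]) / sig
                model += amp * np.exp(-0.5 * z**2)
            out.append(model - s.values)
        return np.concatenate(out)

    amp0 = [
        [max(s.value_at(min(max(p, s.wavelengths[0]), s.wavelengths[-1])), 1e-6)
         for p in peaks]
        for s in spectra
    ]
    per = np.array([[[widths_guess, a] for a in row] for row in amp0]).ravel()
    if fix_peaks:
        p0 = per
        lo = np.tile([0.1, 0.0], m * n)
        hi = np.full_like(p0, np.inf)
    else:
        p0 = np.concatenate([peaks, per])
        lo = np.concatenate([peaks - peak_bounds, np.tile([0.1, 0.0], m * n)])
        hi = np.concatenate([peaks + peak_bounds, np.full(2 * m * n, np.inf)])

    sol = least_squares(resid, p0, bounds=(lo, hi), method="trf",
                        xtol=1e-12, ftol=1e-12, max_nfev=max_nfev)
    mu, rest = split(sol.x)
    results = []
    for i in range(m):
        comps = [
            GaussianComponent(peak=float(mu[k]), width=float(rest[i, k, 0]),
                              amplitude=float(rest[i, k, 1]))
            for k in range(n)
        ]
        _assign_fractions(comps, None)
        results.append(comps)
    return results, np.asarray(mu, dtype=float), float(np.linalg.norm(sol.fun))
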