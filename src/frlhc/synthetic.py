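"""Synthetic inputs with known ground truth.

Every generator is pure given (spec, seed): an explicit ``numpy`` seeded
RNG is the only randomness, and each generator returns a
:class:`TruthRecord` carrying every parameter of the realization so
downstream recovery tests never need to re-run the generator.

Generated objects emulate the study conditions of a far-red
light-harvesting ring:

* a C11-symmetric ring of pseudo-chlorophylls (Mg + four pyrrole-style
  nitrogens, Qy axis along NB->ND) written as a minimal legal PDB file;
* absorbance spectra that are sums of Gaussian bands (bulk Qy plus far-red
  components at 708/725 nm carrying 22%/2% of the band area);
* temperature series of two-Gaussian emission spectra obeying the two-pool
  Arrhenius equilibrium;
* TCSPC matrices: multi-exponential decays convolved with a Gaussian IRF
  plus Poisson noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import fdas as _fdas
from .arrhenius import TwoPoolModel, predict_ratio
from .kinetics import KineticScheme, pool_fluorescence, relax
from .spectra import GaussianComponent, Spectrum, gaussian_sum
from .structure import Atom, Pigment, PigmentComplex, PSEUDO_CODE

SQRT_2PI = float(np.sqrt(2.0 * np.pi))

CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass
class TruthRecord:
    """Every generated parameter plus the seed that produced the data."""

    params: dict
    seed: int | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))

        text = json.dumps({"seed": self.seed, "params": self.params},
                          indent=2, default=default, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class PigmentSite:
    """One pseudo-chlorophyll in the subunit template (cylindrical frame).

    ``radius_offset`` is added to the ring radius; ``azimuth_deg`` is
    measured within the subunit wedge; ``layer`` picks the z offset.
    The Qy dipole is tangential (along increasing azimuth) unless an
    explicit ``dipole`` 3-vector (in the local tangent/radial/z frame)
    is given.
    """

    resnum: int
    radius_offset: float
    azimuth_deg: float
    layer: str  # stromal | lumenal | mid
    dipole: tuple[float, float, float] | None = None  # (tangent, radial, z)


#: Subunit template mirroring the pigment arrangement of an undecameric
#: far-red LHC ring: a seven-pigment stromal layer whose consecutive chain
#: 601-602-603-609-611'-612'-610' stays below 15 A Mg-Mg, a lumenal
#: 604/613/614 layer, and a mid-layer 708 forming a tight trimer with
#: 603/609 and contacting the neighbouring subunit's 613'/614' dimer
#: (the inter-subunit pentamer).
DEFAULT_SITES = (
    PigmentSite(601, -15.0, 19.0, "stromal"),
    PigmentSite(602, -7.5, 9.8, "stromal"),
    PigmentSite(603, 0.0, 2.0, "stromal"),
    PigmentSite(604, -15.0, -5.0, "lumenal"),
    PigmentSite(609, 6.0, 8.5, "stromal"),
    PigmentSite(610, 14.0, 2.5, "stromal"),
    PigmentSite(611, 8.0, -14.0, "stromal"),
    PigmentSite(612, 12.0, -6.0, "stromal"),
    PigmentSite(613, 2.8, -23.727, "lumenal"),
    PigmentSite(614, 5.8, -19.227, "lumenal"),
    PigmentSite(708, 2.8, 5.0, "mid"),
)

DEFAULT_LAYER_OFFSETS = {"stromal": 9.0, "lumenal": -7.0, "mid": 1.0}


@dataclass
class RingSpec:
    n_subunits: int = 11
    sites: tuple[PigmentSite, ...] = DEFAULT_SITES
    ring_radius: float = 60.0  # Angstrom
    layer_offsets: dict = field(default_factory=lambda: dict(DEFAULT_LAYER_OFFSETS))
    mg_n_distance: float = 2.05  # Angstrom, Mg to pyrrole nitrogen

    def __post_init__(self):
        if self.n_subunits < 3:
            raise ValueError("need at least 3 subunits")
        if self.ring_radius <= 0:
            raise ValueError("ring_radius must be positive")

    @property
    def stromal_resnums(self) -> list[int]:
        return [s.resnum for s in self.sites if s.layer == "stromal"]


def _site_geometry(spec: RingSpec, site: PigmentSite, subunit: int):
    """Mg position and unit Qy axis of one site in the lab frame."""
    wedge = 360.0 / spec.n_subunits
    theta = np.deg2rad(site.azimuth_deg + subunit * wedge)
    r = spec.ring_radius + site.radius_offset
    z = spec.layer_offsets[site.layer]
    mg = np.array([r * np.cos(theta), r * np.sin(theta), z])
    tangent = np.array([-np.sin(theta), np.cos(theta), 0.0])
    radial = np.array([np.cos(theta), np.sin(theta), 0.0])
    zhat = np.array([0.0, 0.0, 1.0])
    if site.dipole is None:
        axis = tangent
    else:
        ct, cr, cz = site.dipole
        axis = ct * tangent + cr * radial + cz * zhat
        axis = axis / np.linalg.norm(axis)
    return mg, axis


def _pseudo_pigment(spec: RingSpec, site: PigmentSite, subunit: int) -> Pigment:
    mg, axis = _site_geometry(spec, site, subunit)
    zhat = np.array([0.0, 0.0, 1.0])
    v = np.cross(zhat, axis)
    if np.linalg.norm(v) < 1e-8:
        v = np.cross(np.array([1.0, 0.0, 0.0]), axis)
    v = v / np.linalg.norm(v)
    d = spec.mg_n_distance
    chain = CHAIN_IDS[subunit]
    names_pos = [
        ("MG", "MG", mg),
        ("NA", "N", mg - d * v),
        ("NB", "N", mg - d * axis),
        ("NC", "N", mg + d * v),
        ("ND", "N", mg + d * axis),
    ]
    atoms = [
        Atom(name=n, element=e, position=p, residue_name=PSEUDO_CODE,
             residue_number=site.resnum, chain_id=chain)
        for n, e, p in names_pos
    ]
    return Pigment(pigment_id=f"{chain}/{site.resnum}", kind="pseudo", atoms=atoms)


def make_ring(spec: RingSpec = RingSpec(), path: str | Path | None = None
              ) -> tuple[PigmentComplex, str]:
    """Build the C11 pseudo-chlorophyll ring.

    Returns the in-memory complex and the PDB-format text (minimal legal
    HETATM records); if ``path`` is given the text is also written there.
    """
    if spec.n_subunits > len(CHAIN_IDS):
        raise ValueError("too many subunits for single-letter chain ids")
    pigments = []
    subunit_map = {}
    for s in range(spec.n_subunits):
        for site in spec.sites:
            pig = _pseudo_pigment(spec, site, s)
            pigments.append(pig)
            subunit_map[pig.pigment_id] = s
    complex_ = PigmentComplex(
        pigments=pigments, n_subunits=spec.n_subunits, subunit_map=subunit_map
    )

    lines = []
    serial = 0
    for pig in pigments:
        for at in pig.atoms:
            serial += 1
            x, y, z = at.position
            lines.append(
                f"HETATM{serial:5d} {at.name:<4s} {PSEUDO_CODE:<3s} "
                f"{at.chain_id}{at.residue_number:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                f"{at.element:>2s}"
            )
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return complex_, text


# ---------------------------------------------------------------------------
# spectra


def make_absorbance(
    components: list[GaussianComponent],
    grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Spectrum, TruthRecord]:
    """Sum-of-Gaussians absorbance spectrum plus seeded Gaussian noise."""
    grid = np.asarray(grid, dtype=float)
    values = gaussian_sum(grid, components)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=grid.shape)
    truth = TruthRecord(
        params={
            "peaks": [c.peak for c in components],
            "widths": [c.width for c in components],
            "amplitudes": [c.amplitude for c in components],
            "areas": [c.area for c in components],
            "area_fractions": [
                c.area / sum(x.area for x in components) for c in components
            ],
            "noise_sd": noise_sd,
        },
        seed=seed,
    )
    return Spectrum(grid, values, kind="absorbance"), truth


def qy_band_components() -> list[GaussianComponent]:
    """Qy-band preset: Chl-b shoulder and bulk Chl-a band plus far-red
    components at 708/725 nm carrying 22%/2% of the total band area."""
    areas = {650.0: 0.08, 671.0: 0.68, 708.0: 0.22, 725.0: 0.02}
    widths = {650.0: 9.0, 671.0: 9.5, 708.0: 8.0, 725.0: 7.0}
    comps = [
        GaussianComponent(peak=p, width=widths[p],
                          amplitude=areas[p] / (widths[p] * SQRT_2PI))
        for p in sorted(areas)
    ]
    # normalize so the spectrum maximum is ~1
    grid = np.arange(600.0, 760.0, 0.25)
    peak = gaussian_sum(grid, comps).max()
    return [
        GaussianComponent(peak=c.peak, width=c.width, amplitude=c.amplitude / peak)
        for c in comps
    ]


def make_temperature_series(
    model: TwoPoolModel,
    temperatures,
    widths: tuple[float, float] = (8.0, 9.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    peaks: tuple[float, float] = (713.0, 730.0),
    grid: np.ndarray | None = None,
) -> tuple[list[Spectrum], TruthRecord]:
    """Two-Gaussian emission spectra whose band-area ratio follows the
    two-pool equilibrium at each temperature."""
    if grid is None:
        grid = np.arange(650.0, 800.0, 0.5)
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    spectra = []
    ratios = []
    for t in temperatures:
        ratio = float(predict_ratio(model, float(t)))
        ratios.append(ratio)
        area730 = 1.0
        area713 = ratio * area730
        comps = [
            GaussianComponent(peak=peaks[0], width=widths[0],
                              amplitude=area713 / (widths[0] * SQRT_2PI)),
            GaussianComponent(peak=peaks[1], width=widths[1],
                              amplitude=area730 / (widths[1] * SQRT_2PI)),
        ]
        values = gaussian_sum(grid, comps)
        if noise_sd > 0:
            values = values + rng.normal(0.0, noise_sd * values.max(),
                                         size=grid.shape)
        spectra.append(Spectrum(grid, values, kind="fluorescence",
                                temperature=float(t)))
    truth = TruthRecord(
        params={
            "delta_e": model.delta_e,
            "intensity_ratio": model.intensity_ratio,
            "peaks": list(peaks),
            "widths": list(widths),
            "temperatures": [float(t) for t in temperatures],
            "ratios": ratios,
            "noise_sd": noise_sd,
        },
        seed=seed,
    )
    return spectra, truth


# ---------------------------------------------------------------------------
# time-resolved fluorescence


def make_tcspc(
    amplitudes: np.ndarray,
    lifetimes,
    wavelengths,
    times: np.ndarray | None = None,
    irf_fwhm: float = 40.0,
    irf_center: float = 100.0,
    peak_counts: float = 1e4,
    noise: bool = True,
    seed: int = 0,
) -> tuple[_fdas.TimeResolvedDataset, TruthRecord]:
    """TCSPC matrix from explicit FDAS amplitudes and lifetimes.

    ``amplitudes`` has shape (n_components, n_wavelengths); negative
    entries encode rise components. Traces are convolved with a Gaussian
    IRF, scaled so the global maximum is ``peak_counts``, and (optionally)
    Poisson-sampled.
    """
    if times is None:
        times = np.arange(0.0, 10000.0, 2.0)
    times = np.asarray(times, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    lifetimes = np.asarray(lifetimes, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    irf = _fdas.gaussian_irf(times, irf_fwhm, irf_center)
    clean = np.column_stack(
        [
            _fdas.model_trace(amplitudes[:, j], lifetimes, times, irf)
            for j in range(len(wavelengths))
        ]
    )
    scale = peak_counts / clean.max()
    clean = np.clip(clean * scale, 0.0, None)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(clean).astype(float) if noise else clean
    data = _fdas.TimeResolvedDataset(
        times=times, wavelengths=wavelengths, counts=counts, irf=irf
    )
    truth = TruthRecord(
        params={
            "lifetimes": lifetimes,
            "amplitudes": amplitudes,
            "irf_fwhm": irf_fwhm,
            "irf_center": irf_center,
            "peak_counts": peak_counts,
            "noise": noise,
        },
        seed=seed,
    )
    return data, truth


def make_tcspc_from_scheme(
    scheme: KineticScheme,
    initial,
    band_centers: dict[str, float],
    band_widths: dict[str, float],
    wavelengths,
    times: np.ndarray | None = None,
    irf_fwhm: float = 40.0,
    irf_center: float = 100.0,
    peak_counts: float = 1e4,
    noise: bool = True,
    seed: int = 0,
) -> tuple[_fdas.TimeResolvedDataset, TruthRecord]:
    """TCSPC matrix simulated from a kinetic scheme.

    Pool emissions (radiative weight x population) are rendered onto the
    wavelength axis as Gaussian emission bands (``band_centers`` /
    ``band_widths`` per pool name; pools absent from ``band_centers`` do
    not emit), convolved with the IRF and Poisson-sampled.
    """
    if times is None:
        times = np.arange(0.0, 10000.0, 2.0)
    times = np.asarray(times, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    pops = relax(scheme, initial, times)
    emis = pool_fluorescence(pops, scheme.pools)
    signal = np.zeros((len(times), len(wavelengths)))
    for i, pool in enumerate(scheme.pools):
        if pool.name not in band_centers:
            continue
        band = np.exp(
            -0.5 * ((wavelengths - band_centers[pool.name])
                    / band_widths[pool.name]) ** 2
        )
        signal += np.outer(emis[:, i], band)
    irf = _fdas.gaussian_irf(times, irf_fwhm, irf_center)
    kernel = irf / irf.sum()
    clean = np.column_stack(
        [np.convolve(signal[:, j], kernel)[: len(times)]
         for j in range(len(wavelengths))]
    )
    scale = peak_counts / clean.max()
    clean = np.clip(clean * scale, 0.0, None)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(clean).astype(float) if noise else clean
    data = _fdas.TimeResolvedDataset(
        times=times, wavelengths=wavelengths, counts=counts, irf=irf,
        temperature=scheme.temperature,
    )
    from .kinetics import relaxation_rates

    truth = TruthRecord(
        params={
            "relaxation_rates": relaxation_rates(scheme),
            "temperature": scheme.temperature,
            "initial": np.asarray(initial, dtype=float),
            "band_centers": band_centers,
            "band_widths": band_widths,
            "irf_fwhm": irf_fwhm,
            "peak_counts": peak_counts,
        },
        seed=seed,
    )
    return data, truth
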