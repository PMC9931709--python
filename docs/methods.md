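# Methods

This note documents the models implemented in `frlhc`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the known limitations.

## Units and constants

Energies and couplings are in cm⁻¹, dipoles in Debye, distances in
Ångström (nm only inside the point-dipole formula), temperatures in K.
All wavelength → wavenumber conversions use the vacuum convention
E = 10⁷/λ(nm); no air refractive-index correction is applied. The
conversion constants live in `frlhc.constants`:

* e²/(4πε₀) = 1.16141×10⁵ cm⁻¹·Å·e⁻²,
* hc/k_B = 1.438777 cm·K,
* 1 e·Å = 4.803205 D,
* point-dipole prefactor 5.04 cm⁻¹·nm³·D⁻².

## Exciton couplings

The coupling between pigments A and B is the screened Coulomb sum over
atomic transition charges (TrEsp),

    V_AB = (1/ε) Σ_I Σ_J q_I^A q_J^B / r_IJ,

with ε = 2.0 by default (a typical effective protein dielectric for this
kind of calculation; overridable everywhere). Transition-charge sets are
required to be monopole-free to 10⁻⁶ e and carry a global `scale`
multiplier. Published full-atom charge sets for chlorophyll *a* are
loaded from a plain-text table (atom name, charge); because no such
table is redistributed here, the package ships a documented minimal
alternative: ±δ charges on the NB/ND nitrogens with δ chosen to
reproduce a reference Qy dipole (default 4.6 D at the 4.1 Å
trans-nitrogen distance of a chlorin). All coupling-level guarantees are
therefore property-based (swap symmetry, 1/ε linearity, rigid-motion
invariance, far-field convergence to the point-dipole formula within 1%
beyond 25× the charge spacing); absolute reproduction of any particular
published coupling table is not attempted.

Pairs with any interatomic distance below 0.5 Å raise an
overlapping-pigments error. Charge-table atoms absent from a pigment
either raise (strict, default) or are dropped with the remaining charges
re-centred to zero monopole (opt-in policy).

The point-dipole oracle is V = (5.04/ε)·μ_A μ_B κ/R³ with R the Mg–Mg
distance in nm and κ = û_A·û_B − 3(û_A·R̂)(û_B·R̂); Qy unit vectors are
the NB→ND axes (standard chlorin convention — the underlying structural
models do not state one).

Exciton states come from `numpy.linalg.eigh` of the site Hamiltonian.
State dipoles are coefficient-weighted sums of site dipoles; the trace
(Σ energies) and oscillator-weight (Σ|μ|²) sum rules are enforced in
tests at 10⁻⁸ relative. The helper
`dimer_intensity_ratio_to_dipole_ratio` inverts I ∝ |μ|²: an intrinsic
intensity ratio r between two mixed states requires a dipole-magnitude
ratio √(1/r) — for r = 12, 28.9%, i.e. "about 30%".

## Pigment network

Edges exist where |V| exceeds a floor (default 10 cm⁻¹) and are classed
strong (> 60), medium (60–30], weak (30–10] cm⁻¹; boundaries belong to
the lower class, and classification uses |V| because the sign of a
coupling depends on arbitrary dipole orientation conventions. The
ring-connectivity report contracts the pigment graph to subunits and
searches (exact backtracking, fine for ≤ a few dozen subunits) for a
simple cycle visiting every subunit; `cycle_spans_ring` is that
subunit-level criterion together with pigment-level connectedness. A
broken ring (one subunit's edges removed) is connected but fails the
cycle test, as it should.

## Spectral deconvolution

Spectra are normalized by subtracting the value at a zero wavelength
(default 750 nm) and scaling the Qy-window maximum to 1. Band seeding
follows the second/fourth-derivative method: Savitzky–Golay
smoothing-differentiation (window 11 points, polyorder 6 by default),
candidates = minima of the 2nd derivative ∪ maxima of the 4th, merged
within 3 nm keeping the 4th-derivative position, discarded where the
spectrum is below 1% of its maximum. Only candidates in concave regions
are kept; this rejects the positive 4th-derivative side lobes of every
isolated band but also means a weak shoulder buried in a convex tail
(e.g. a ~2%-area band on a stronger band's wing) must be supplied as an
explicit seed — which is how such bands are handled in practice once
their positions are established. On noisy spectra the smoothing window
must be comparable to the band width in grid points.

Fitting is nonlinear least squares (scipy trust-region reflective,
analytic Jacobian for the Gaussian sum, ftol/xtol 10⁻¹², ≤ 500
evaluations) in the wavelength domain; Gaussians are parameterized by
peak, standard deviation and amplitude with area = A·σ·√(2π). Area
fractions are reported over a caller-specified integration window
(default the whole fitted set) and always sum to 1 within it. A
temperature series can be fitted simultaneously with peak positions
shared exactly across spectra (single shared parameters) or fixed.
Recovery performance on synthetic data: noiseless areas to 0.1%; with
1% noise the 22%/2% far-red pair is recovered within ±2 percentage
points and their ratio within 11 ± 2 when peaks are held at their
established positions (free-peak fits of the 2% band are substantially
noisier — its amplitude is only ~3.5% of the spectrum maximum).

## Two-pool Arrhenius analysis

Two emitting pools in fast thermal exchange obey

    Area_F713/Area_F730 = (I_F713/I_F730) · exp(−ΔE/k_B T),

with ΔE ≥ 0 the energy of the higher (F713-emitting) pool's excited
state above the lower one's, and the intrinsic ratio I_F713/I_F730 the
infinite-temperature limit, interpreted as the pigment-number ratio of
the pools. The same quantity equals the detailed-balance rate ratio
k_up/k_down with the degeneracy factor on the uphill rate (sign
convention chosen so the ratio grows with temperature, matching the
observed shift of emission from the 730 nm band at 87 K toward 713 nm at
273 K). Fitting is done in log space — ln(ratio) linear in 1/T — with ΔE
fixed, leaving one intercept, weighted by relative ratio errors when
available.

Two numbers coexist for the F713/F730 gap: plain wavelength arithmetic
gives 10⁷/713 − 10⁷/730 = 326.6 cm⁻¹, while the conventional fixed
value for reproduction-style fits is 318 cm⁻¹ (= 457.5 K via hc/k_B).
Both are exposed; `FIXED_GAP_713_730 = 318` is the default for
reproduction runs. Joint fitting of ΔE and the intensity ratio is out of
scope (the gap is fixed by construction in this analysis).

## Global reconvolution fitting (FDAS)

Each wavelength channel is modelled as a step-gated multi-exponential
convolved with the instrument response,

    F_λ(t) = [Σ_i A_i(λ) e^(−t/τ_i) H(t)] ⊗ I(t),

with lifetimes shared across channels. The IRF (measured trace
preferred; a parametric Gaussian is provided for synthetic work) is
sum-normalized and shifted by a fitted time-zero parameter
(interpolated). The discrete convolution uses the trapezoid convention
H(0) = ½ at the gating discontinuity, which removes the leading O(Δt)
bias against the continuous integral — verified against the closed-form
exponentially-modified Gaussian to < 0.03% of peak at a 2 ps step.

The fit is variable projection: per-channel amplitudes are the exact
linear least-squares solution at fixed lifetimes, and the outer search
(trust-region, bounded) runs over log-lifetimes and time zero. Negative
amplitudes are allowed everywhere — they are the rise components. An
optional Poisson weighting (1/max(counts, 1)) is off by default. A
warning is raised when two lifetimes converge within 5%
(over-parameterization); `suggest_n_components` operationalizes "enough
components" as adding one until the rms residual improves by < 5%.

## Compartment kinetics

Pools carry a pigment count (degeneracy), an excited-state energy, a
radiative weight and a sink rate. Downhill transfer rates are inputs;
every uphill rate is derived from detailed balance,
k_up/k_down = (N_hi/N_lo)·exp(−ΔE/k_BT) — the degeneracy factor rides on
the uphill rate, so sink-free stationary populations are
p_i ∝ N_i·exp(−E_i/k_BT). The rate matrix has column sums equal to
−sink_i (exact probability conservation with zero sinks). Relaxation is
solved by eigen-decomposition (matrix-exponential fallback for defective
matrices).

The default three-pool scheme uses pools at 680/708/725 nm with pigment
counts 30:10:1 (the ~3:1 bulk:far-red absorption split and the 10:1
ratio of the two far-red pools), a 25 ps bulk↔708 equilibration (split
into up/down rates by the detailed-balance ratio at the 273 K reference),
a 250 ps 708→725 downhill rate, and terminal sinks of 1/2200 ps⁻¹
(bulk, 708) and 1/1900 ps⁻¹ (725). An optional extra drain on the bulk
pool (default 0) stands for the energy exit toward the photosystem, for
which no rate is established. The "5%" uphill figure is reported as the
unnormalized Boltzmann factor exp(−ΔE/k_BT) = 4.9%; the two-level
normalized population (4.7%) is exposed alongside — both round to 5%.
The entropy weight uses degeneracy ratio 3 ("approximately 3:1"); the
76%/24% absorption split would give 3.17, and callers can pass either.

## Synthetic data

Generators are pure functions of (spec, seed) — a single explicit
`numpy` RNG per call, no hidden state — and every generator returns a
`TruthRecord` with all parameters of the realization.

* **Ring**: a C11 ring of pseudo-chlorophylls (Mg + NA/NB/NC/ND at
  2.05 Å, Qy axis NB→ND, tangential by default) written as minimal legal
  HETATM records. The subunit template places a seven-pigment stromal
  chain (601-602-603-609-611'-612'-610') with consecutive Mg–Mg
  distances of 9–13 Å (< 15 Å), a mid-layer 708 forming a tight trimer
  with 603/609, and a lumenal 613/614 dimer positioned so the
  inter-subunit pentamer contacts are the five shortest distance
  patterns in the structure. Real chlorin geometry (full macrocycles,
  phytol tails, ring deformations) is *not* emulated: couplings computed
  on the ring test the machinery's properties, not any real complex's
  values.
* **Absorbance**: Gaussian sums plus seeded Gaussian noise; the Qy
  preset carries bands at 650/671/708/725 nm with 8/68/22/2% of the
  total area, normalized to unit peak.
* **Temperature series**: two Gaussians at 713/730 nm whose area ratio
  follows the two-pool equilibrium at each temperature (default noise
  2% of peak).
* **TCSPC**: reconvolved exponential sums (explicit FDAS amplitudes, or
  a kinetic scheme rendered through Gaussian emission bands), Gaussian
  IRF (default FWHM 40 ps centred at 100 ps), scaled to 10⁴ peak counts
  and Poisson-sampled. Default grids are 2–10 ps steps over 8–10 ns —
  documented assumptions, since no public raw streak data exist to copy
  binning from. Detector nonlinearity, background, scatter and
  wavelength-dependent IRF shift are not emulated.

Because the study's raw spectra and decays are unpublished, all
quantitative recovery claims here are closure tests against these
generators: they demonstrate that the estimators are correct and
well-conditioned at realistic noise, not that any particular published
number would be re-derived from raw data.

## Problem sizes

The test suite and the acceptance script use 640-point spectra,
8-temperature series, and 20×2000-point TCSPC matrices, with 50–200
seeded replicates for the stochastic recovery studies — sizes chosen to
make the statistical checks sharp while keeping a full run in the order
of seconds on one core.

## Known limitations

* No lineshape theory, vibronic structure or site-energy (CDC)
  calculation — couplings and band fits are treated independently.
* No Förster/Redfield rate computation from couplings; transfer rates in
  the kinetic scheme are empirical inputs.
* The ring-connectivity cycle test is subunit-level; it does not verify
  a pigment-level simple cycle (adequate for ring-vs-broken-ring
  discrimination).
* Gaussian deconvolution assumes a flat (single-point-zeroed) baseline.
* The deposited-structure audit requires downloading the public
  coordinates; it cannot run without network access to the PDB.
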