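# frlhc

Analysis toolkit for far-red light-harvesting chlorophyll-protein
complexes: structure-based exciton-coupling networks, Gaussian band
deconvolution, two-pool Arrhenius equilibrium analysis, global lifetime
fitting of time-resolved fluorescence, and compartmental simulation of
entropy-driven uphill excitation-energy transfer.

## The scientific problem

Some photosynthetic antennas harvest far-red light (700–750 nm) and still
drive photosystem II, which needs ~680 nm excitation — the excitation must
move *uphill* in energy. A C11-symmetric ring antenna with
long-wavelength chlorophyll pools makes this work through two effects:

* **thermal activation** — the Boltzmann factor for promoting an
  excitation across the 708 → 680 nm gap, exp(−ΔE/k_BT) ≈ 5% at 278 K;
* **entropy** — the uphill destination holds ~3× more pigments than the
  far-red pool, so detailed balance multiplies the uphill rate by the
  pigment-number ratio: k_up/k_down = (N_up/N_down)·exp(−ΔE/k_BT),
  lifting the effective uphill probability to ~15%.

The package implements the quantitative chain behind this picture, for
spectroscopists and structural biologists working on such antennas:

1. **structure → couplings** (`frlhc.structure`, `frlhc.excitons`):
   extract chlorophylls (Mg positions, NB→ND Qy axes) from mmCIF/PDB
   files and compute exciton couplings with the transition-charge
   (TrEsp) Coulomb sum V = (1/ε)ΣΣ q_I q_J / r_IJ, with a point-dipole
   far-field oracle and exciton-state diagonalization (mixed-state
   energies, transition dipoles, oscillator strengths).
2. **coupling network** (`frlhc.network`): the energetic chlorophyll
   graph with strength classes (|V| > 60 / 60–30 / 30–10 cm⁻¹) and a
   ring-connectivity test (does an energetically consecutive network
   span all 11 subunits?).
3. **steady-state spectra** (`frlhc.spectra`): derivative-seeded Gaussian
   deconvolution of the Qy band; constrained simultaneous fits of
   temperature series with shared peak positions.
4. **two-pool equilibrium** (`frlhc.arrhenius`): Area_F713/Area_F730 =
   (I_F713/I_F730)·exp(−ΔE/k_BT); Arrhenius fitting with the gap fixed,
   yielding the intrinsic intensity ratio.
5. **time-resolved fluorescence** (`frlhc.fdas`): global reconvolution
   fitting F_λ(t) = [Σ A_i(λ) e^(−t/τ_i) H(t)] ⊗ IRF(t) by variable
   projection; the amplitude spectra A_i(λ) are the fluorescence
   decay-associated spectra (FDAS), negative lobes marking rises.
6. **kinetics** (`frlhc.kinetics`): pools with degeneracies and sinks,
   detailed-balance rate matrices, relaxation eigenmodes, population and
   emission simulation.
7. **synthetic data** (`frlhc.synthetic`): seeded generators for all of
   the above with full ground-truth records.

## Worked example

`examples/` contains one short script per capability. For instance:

```sh
$ python examples/06_uphill_kinetics.py
thermal uphill factor 708 -> 680 nm at 278 K: 4.9%
with the ~3:1 bulk:far-red pigment abundance: 14.8%
...
uphill/downhill ratio bulk <-> far-red pool: 0.140
t =    25 ps: populations bulk=0.071, lwc708=0.838, lwc725=0.080
t =   250 ps: populations bulk=0.076, lwc708=0.538, lwc725=0.275
t =  2500 ps: populations bulk=0.025, lwc708=0.177, lwc725=0.101
```

The 4.9% is the bare Boltzmann factor across the 708→680 nm gap; the
14.8% is the same factor boosted by the 3:1 pigment abundance — the
entropic assist that makes far-red driving of the photosystem viable.
The population rows show far-red excitation feeding the bulk pool within
tens of picoseconds and draining through the ~2 ns terminal decay.

And `examples/04_arrhenius.py` fits a synthetic temperature series:

```
gap fixed at 318 cm^-1 (= 458 K); fitted intrinsic ratio I_F713/I_F730 = 11.85 (truth 12)
```

A command-line interface mirrors the library
(`frlhc couplings|network|fit-spectrum|fit-arrhenius|fit-fdas|kinetics|simulate|demo`);
`frlhc demo` runs the full chain on the synthetic ring.

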