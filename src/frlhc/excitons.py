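"""Exciton couplings and exciton-state analysis.

The coupling between two pigments is the screened Coulomb interaction of
their atomic transition charges (the TrEsp method),

    V_AB = (1/eps) * sum_I sum_J q_I^A q_J^B / r_IJ,

with q in units of the elementary charge, r in Angstrom and the conversion
constant e^2/(4 pi eps0) = 1.16141e5 cm^-1 * Angstrom * e^-2, so V comes out
in cm^-1. A point-dipole formula is provided as the far-field oracle.

Diagonalizing the site Hamiltonian (site energies on the diagonal, couplings
off-diagonal) gives exciton states; their transition dipoles are the
coefficient-weighted sums of the site dipoles, and |mu|^2 ("oscillator
weight") tells whether a mixed state is super-radiative or dark.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .constants import COULOMB_CM_ANGSTROM, DIPOLE_PREFACTOR_CM_NM3_D2, EA_TO_DEBYE
from .structure import Pigment, PigmentComplex, mg_distance


class OverlappingPigmentsError(ValueError):
    """Two pigments approach closer than the hard-core cutoff (0.5 A)."""


@dataclass
class TransitionChargeSet:
    """Atomic transition charges for one pigment kind.

    charges map atom names to transition charges (elementary charge units);
    they must be monopole-free (sum ~ 0). ``reference_dipole`` records the
    Qy dipole magnitude (Debye) the set reproduces on its reference
    geometry; ``scale`` is a global multiplier applied to every charge.
    """

    charges: dict[str, float]
    kind: str = "chlorophyll-a"
    reference_dipole: float = 4.6  # Debye
    scale: float = 1.0

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        total = sum(self.charges.values())
        if abs(total) > 1e-6:
            raise ValueError(
                f"transition charges must sum to zero (got {total:.3e} e)"
            )

    def scaled(self) -> dict[str, float]:
        return {k: v * self.scale for k, v in self.charges.items()}

    @classmethod
    def two_point(
        cls,
        reference_dipole: float = 4.6,
        nb_nd_distance: float = 4.1,
        kind: str = "chlorophyll-a",
    ) -> "TransitionChargeSet":
        """Minimal +-delta charge set on the NB/ND nitrogens.

        delta is chosen so the charge pair reproduces ``reference_dipole``
        (Debye) at the reference NB-ND separation (Angstrom; 4.1 A is the
        trans-nitrogen distance of a chlorin with Mg-N ~ 2.05 A).
        """
        delta = reference_dipole / (EA_TO_DEBYE * nb_nd_distance)
        return cls(
            charges={"NB": -delta, "ND": +delta},
            kind=kind,
            reference_dipole=reference_dipole,
        )

    @classmethod
    def from_table(cls, path: str | Path) -> "TransitionChargeSet":
        """Read a charge table: comment header (# kind, # reference_dipole)
        followed by whitespace/comma separated ``atom_name charge_e`` rows."""
        kind, ref = "chlorophyll-a", 4.6
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("kind"):
                    kind = body.split(None, 1)[1].strip(" :=")
                elif body.lower().startswith("reference_dipole"):
                    ref = float(body.split(None, 1)[1].strip(" :="))
                continue
            parts = line.replace(",", " ").split()
            rows.append((parts[0], float(parts[1])))
        return cls(charges=dict(rows), kind=kind, reference_dipole=ref)

    def to_table(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# kind {self.kind}\n")
            fh.write(f"# reference_dipole {self.reference_dipole}\n")
            for name, q in self.charges.items():
                fh.write(f"{name} {q:.8f}\n")


def tresp_coupling(
    a: Pigment,
    b: Pigment,
    qa: TransitionChargeSet,
    qb: TransitionChargeSet,
    epsilon: float = 2.0,
    missing_atom_policy: str = "strict",
) -> float:
    """TrEsp exciton coupling between pigments a and b, in cm^-1.

    missing_atom_policy: "strict" raises if a charged atom name is absent
    from the pigment; "drop" drops missing atoms and renormalizes the
    remaining charges to zero monopole (with a warning).
    """
    if a is b or a.pigment_id == b.pigment_id:
        raise ValueError("coupling requires two distinct pigments")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")

    def resolve(pig: Pigment, qset: TransitionChargeSet):
        charges = qset.scaled()
        names = [n for n in charges if pig.has_atom(n)]
        missing = [n for n in charges if n not in names]
        if missing:
            if missing_atom_policy == "strict":
                raise ValueError(
                    f"{pig.pigment_id}: charge-table atoms missing: {missing}"
                )
            warnings.warn(
                f"{pig.pigment_id}: dropping charges on missing atoms {missing}",
                stacklevel=3,
            )
            kept = np.array([charges[n] for n in names])
            kept -= kept.mean()  # restore zero monopole
            q = kept
        else:
            q = np.array([charges[n] for n in names])
        pos = pig.positions_for(names)
        return q, pos

    q1, p1 = resolve(a, qa)
    q2, p2 = resolve(b, qb)
    r = cdist(p1, p2)
    if np.any(r < 0.5):
        raise OverlappingPigmentsError(
            f"{a.pigment_id} and {b.pigment_id} have atoms closer than 0.5 A"
        )
    return float(COULOMB_CM_ANGSTROM / epsilon * (np.outer(q1, q2) / r).sum())


def transition_dipole(pigment: Pigment, qset: TransitionChargeSet) -> np.ndarray:
    """Transition dipole (Debye 3-vector) of the charge distribution."""
    charges = qset.scaled()
    names = [n for n in charges if pigment.has_atom(n)]
    q = np.array([charges[n] for n in names])
    pos = pigment.positions_for(names)
    return EA_TO_DEBYE * (q[:, None] * pos).sum(axis=0)


def point_dipole_coupling(
    a: Pigment,
    b: Pigment,
    mu_a: float,
    mu_b: float,
    epsilon: float = 2.0,
) -> float:
    """Point-dipole coupling (cm^-1): V = 5.04 mu_a mu_b kappa / (eps R^3).

    mu in Debye, R (Mg-Mg) in nm, kappa the orientation factor from the Qy
    axes. Serves as the far-field oracle for the TrEsp sum.
    """
    r_ang = mg_distance(a, b)
    if r_ang == 0:
        raise ValueError("coincident pigments")
    r_nm = r_ang / 10.0
    ua, ub = a.qy_axis, b.qy_axis
    rhat = (b.mg_position - a.mg_position) / r_ang
    kappa = float(ua @ ub - 3.0 * (ua @ rhat) * (ub @ rhat))
    return DIPOLE_PREFACTOR_CM_NM3_D2 / epsilon * mu_a * mu_b * kappa / r_nm**3


@dataclass
class ExcitonSystem:
    """Site basis of an exciton Hamiltonian: energies + couplings (cm^-1)."""

    pigment_ids: list[str]
    site_energies: np.ndarray  # cm^-1, shape (N,)
    couplings: np.ndarray  # cm^-1, symmetric, zero diagonal
    epsilon: float = 2.0

    def __post_init__(self):
        self.site_energies = np.asarray(self.site_energies, dtype=float)
        self.couplings = np.asarray(self.couplings, dtype=float)
        n = len(self.pigment_ids)
        if self.site_energies.shape != (n,) or self.couplings.shape != (n, n):
            raise ValueError("inconsistent dimensions")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not np.allclose(self.couplings, self.couplings.T, atol=1e-9):
            raise ValueError("coupling matrix must be symmetric")
        if np.any(np.diag(self.couplings) != 0):
            raise ValueError("coupling diagonal must be zero")

    @property
    def hamiltonian(self) -> np.ndarray:
        return np.diag(self.site_energies) + self.couplings

    def coupling(self, id_a: str, id_b: str) -> float:
        i, j = self.pigment_ids.index(id_a), self.pigment_ids.index(id_b)
        return float(self.couplings[i, j])

    def coupling_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.couplings, index=self.pigment_ids, columns=self.pigment_ids
        )


def coupling_matrix(
    complex_: PigmentComplex,
    charge_sets: dict[str, TransitionChargeSet] | TransitionChargeSet,
    epsilon: float = 2.0,
    site_energies: np.ndarray | float = 0.0,
    pigments: list[Pigment] | None = None,
) -> ExcitonSystem:
    """All-pairs TrEsp couplings over the chlorophyll-like pigments.

    ``charge_sets`` is either one set used for every pigment or a mapping
    from pigment kind to set (unlisted kinds fall back to "chlorophyll-a",
    mirroring modelling every chlorin with the Chl-a table).
    """
    pigs = pigments if pigments is not None else complex_.chlorophylls
    ids = [p.pigment_id for p in pigs]
    if isinstance(charge_sets, TransitionChargeSet):
        charge_sets = {"*": charge_sets}

    def qset_for(p: Pigment) -> TransitionChargeSet:
        if p.kind in charge_sets:
            return charge_sets[p.kind]
        if "*" in charge_sets:
            return charge_sets["*"]
        return charge_sets["chlorophyll-a"]

    n = len(pigs)
    v = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v[i, j] = v[j, i] = tresp_coupling(
                pigs[i], pigs[j], qset_for(pigs[i]), qset_for(pigs[j]), epsilon
            )
    energies = np.broadcast_to(np.asarray(site_energies, dtype=float), (n,)).copy()
    return ExcitonSystem(
        pigment_ids=ids, site_energies=energies, couplings=v, epsilon=epsilon
    )


@dataclass
class ExcitonState:
    energy: float  # cm^-1
    coefficients: np.ndarray  # site coefficients, normalized
    transition_dipole: np.ndarray  # Debye 3-vector
    oscillator_weight: float  # Debye^2 = |transition_dipole|^2


def diagonalize(
    system: ExcitonSystem, site_dipoles: list[np.ndarray]
) -> list[ExcitonState]:
    """Eigen-decompose the exciton Hamiltonian.

    Returns states sorted by ascending energy. The k-th state's transition
    dipole is sum_i c_ki mu_i; the oscillator weights obey the sum rule
    sum_k |mu_k|^2 = sum_i |mu_i|^2.
    """
    mus = np.asarray(site_dipoles, dtype=float)
    n = len(system.pigment_ids)
    if mus.shape != (n, 3):
        raise ValueError("site_dipoles must be N Debye 3-vectors")
    h = system.hamiltonian
    if not np.allclose(h, h.T, atol=1e-9):
        raise ValueError("Hamiltonian must be symmetric")
    evals, evecs = np.linalg.eigh(h)
    states = []
    for k in range(n):
        c = evecs[:, k]
        mu = c @ mus
        states.append(
            ExcitonState(
                energy=float(evals[k]),
                coefficients=c,
                transition_dipole=mu,
                oscillator_weight=float(mu @ mu),
            )
        )
    return states


def dimer_intensity_ratio_to_dipole_ratio(intensity_ratio: float) -> float:
    """Lower/higher mixed-state dipole-magnitude ratio implied by an
    emission intensity ratio.

    Emission intensity scales with |mu|^2, so explaining an intrinsic
    intensity ratio I_high/I_low = r by oscillator-strength redistribution
    alone requires |mu_low|/|mu_high| = sqrt(1/r) (e.g. r = 12 -> 0.289,
    i.e. the weaker state's dipole must shrink to ~30%).
    """
    if intensity_ratio <= 0:
        raise ValueError("intensity ratio must be positive")
    return float(np.sqrt(1.0 / intensity_ratio))
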