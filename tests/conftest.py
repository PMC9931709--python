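import numpy as np
import pytest

from frlhc.structure import Atom, Pigment
from frlhc.synthetic import RingSpec, make_ring


def make_point_pigment(pid, charges_positions, residue_number=1, chain="A"):
    """A bare pigment whose atoms are named points (for coupling oracles).

    ``charges_positions`` maps atom name -> position; Qy-axis/Mg queries
    work only if the corresponding atoms are provided.
    """
    atoms = [
        Atom(name=n, element=n[:1], position=np.asarray(p, dtype=float),
             residue_name="PSD", residue_number=residue_number, chain_id=chain)
        for n, p in charges_positions.items()
    ]
    return Pigment(pigment_id=pid, kind="pseudo", atoms=atoms)


def make_dipole_pigment(pid, mg, axis, half_length=2.05, chain="A", resnum=1):
    """Pseudo-chlorin: Mg at ``mg``, NB/ND straddling it along ``axis``."""
    mg = np.asarray(mg, dtype=float)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return make_point_pigment(
        pid,
        {
            "MG": mg,
            "NB": mg - half_length * axis,
            "ND": mg + half_length * axis,
        },
        residue_number=resnum,
        chain=chain,
    )


@pytest.fixture(scope="session")
def ring():
    """Default C11 synthetic ring (121 pseudo-chlorophylls)."""
    complex_, text = make_ring(RingSpec())
    return complex_


@pytest.fixture(scope="session")
def ring_file(tmp_path_factory):
    path = tmp_path_factory.mktemp("ring") / "ring11.pdb"
    complex_, _ = make_ring(RingSpec(), path=path)
    return path, complex_
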