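"""Pigment extraction from macromolecular structures.

Reads mmCIF or PDB coordinate files (via gemmi), pulls out pigment cofactors
(chlorophylls, carotenoids, or generated pseudo-chlorophylls) and exposes the
geometry the excitonic pipeline needs: Mg positions, Qy transition-dipole
axes and macrocycle plane normals.

Conventions
-----------
* The Qy axis of a chlorin is the unit vector from the NB nitrogen to the ND
  nitrogen (standard chlorin axis convention).
* Chains are mapped to subunits in order of first appearance in the file; in
  a C11 ring the "prime" neighbour of subunit *i* is subunit *(i+1) mod n*
  under that ordering, overridable through ``chain_order``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Residue codes treated as chlorophyll-like (must contain a central Mg).
CHLOROPHYLL_CODES = {"CLA": "chlorophyll-a", "CHL": "chlorophyll-b"}
#: Residue codes treated as carotenoids (inventory only).
CAROTENOID_CODES = {"XAT", "LUT", "VIO", "LOR", "NEX", "BCR"}
#: Residue code emitted by the synthetic ring generator.
PSEUDO_CODE = "PSD"

DEFAULT_PIGMENT_CODES = frozenset(
    set(CHLOROPHYLL_CODES) | CAROTENOID_CODES | {PSEUDO_CODE}
)


class StructureFormatError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class PigmentGeometryError(ValueError):
    """Raised when a pigment lacks the atoms a geometric query needs."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    position: np.ndarray  # Angstrom, shape (3,)
    residue_name: str
    residue_number: int
    chain_id: str
    symmetry_copy_id: str = ""

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be nonempty")
        object.__setattr__(self, "position", pos)


@dataclass
class Pigment:
    """A pigment cofactor with the geometry used by the exciton engine."""

    pigment_id: str  # "chain/resnum"
    kind: str  # chlorophyll-a | chlorophyll-b | carotenoid | pseudo
    atoms: list[Atom]

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise PigmentGeometryError(f"{self.pigment_id}: no atom named {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def chain_id(self) -> str:
        return self.atoms[0].chain_id

    @property
    def residue_number(self) -> int:
        return self.atoms[0].residue_number

    @property
    def mg_position(self) -> np.ndarray:
        """Position of the central Mg atom (Angstrom)."""
        if not self.has_atom("MG"):
            raise PigmentGeometryError(f"{self.pigment_id}: no Mg atom")
        return self.atom("MG").position

    @property
    def qy_axis(self) -> np.ndarray:
        return qy_axis(self)

    @property
    def plane_normal(self) -> np.ndarray:
        """Unit normal of the macrocycle plane from the pyrrole nitrogens."""
        names = [n for n in ("NA", "NB", "NC", "ND") if self.has_atom(n)]
        if len(names) < 3:
            raise PigmentGeometryError(
                f"{self.pigment_id}: need >=3 pyrrole nitrogens for a plane"
            )
        pts = np.array([self.atom(n).position for n in names])
        centered = pts - pts.mean(axis=0)
        # smallest principal axis of the nitrogen cloud
        _, _, vt = np.linalg.svd(centered)
        normal = vt[-1]
        return normal / np.linalg.norm(normal)

    def positions_for(self, names: Iterable[str]) -> np.ndarray:
        return np.array([self.atom(n).position for n in names])


def qy_axis(pigment: Pigment) -> np.ndarray:
    """Unit Qy axis: NB -> ND direction of the chlorin nitrogens."""
    if not (pigment.has_atom("NB") and pigment.has_atom("ND")):
        raise PigmentGeometryError(
            f"{pigment.pigment_id}: NB/ND atoms required for the Qy axis"
        )
    v = pigment.atom("ND").position - pigment.atom("NB").position
    norm = np.linalg.norm(v)
    if norm < 1e-6:
        raise PigmentGeometryError(
            f"{pigment.pigment_id}: NB and ND coincide; Qy axis undefined"
        )
    return v / norm


def mg_distance(a: Pigment, b: Pigment) -> float:
    """Mg-Mg distance between two chlorophyll-like pigments (Angstrom)."""
    return float(np.linalg.norm(a.mg_position - b.mg_position))


@dataclass
class PigmentComplex:
    """All pigments of one structure plus the subunit (chain) bookkeeping."""

    pigments: list[Pigment]
    n_subunits: int
    subunit_map: dict[str, int]  # pigment_id -> subunit index
    prime_convention: bool = True

    def __post_init__(self):
        ids = [p.pigment_id for p in self.pigments]
        if len(ids) != len(set(ids)):
            raise ValueError("pigment_ids must be unique")
        for pid, s in self.subunit_map.items():
            if not (0 <= s < max(self.n_subunits, 1)):
                raise ValueError(f"subunit index of {pid} out of range")

    def __len__(self) -> int:
        return len(self.pigments)

    def get(self, pigment_id: str) -> Pigment:
        for p in self.pigments:
            if p.pigment_id == pigment_id:
                return p
        raise KeyError(pigment_id)

    @property
    def chlorophylls(self) -> list[Pigment]:
        return [p for p in self.pigments if p.kind != "carotenoid"]

    def subunit_of(self, pigment_id: str) -> int:
        return self.subunit_map[pigment_id]

    def resolve(self, name: str, subunit: int) -> Pigment:
        """Resolve a residue-number name like ``"611'"`` relative to a subunit.

        A trailing prime refers to the same residue number in the next
        subunit (counter-clockwise viewed from the stromal side, i.e. the
        next chain in file order, wrapping around the ring).
        """
        name = name.strip()
        primes = len(name) - len(name.rstrip("'′"))
        resnum = int(name.rstrip("'′"))
        target = (subunit + primes) % self.n_subunits
        for p in self.pigments:
            if p.residue_number == resnum and self.subunit_map[p.pigment_id] == target:
                return p
        raise KeyError(f"residue {resnum} not found in subunit {target}")

    def inventory(self) -> pd.DataFrame:
        """Pigment inventory table (one row per pigment)."""
        rows = []
        for p in self.pigments:
            try:
                mg = p.mg_position
            except PigmentGeometryError:
                mg = np.full(3, np.nan)
            rows.append(
                {
                    "pigment_id": p.pigment_id,
                    "kind": p.kind,
                    "chain": p.chain_id,
                    "resnum": p.residue_number,
                    "subunit": self.subunit_map[p.pigment_id],
                    "mg_x": mg[0],
                    "mg_y": mg[1],
                    "mg_z": mg[2],
                }
            )
        return pd.DataFrame(rows)


def _classify(residue_name: str) -> str:
    if residue_name in CHLOROPHYLL_CODES:
        return CHLOROPHYLL_CODES[residue_name]
    if residue_name in CAROTENOID_CODES:
        return "carotenoid"
    return "pseudo"


def read_structure(
    path: str | Path,
    pigment_residue_names: Iterable[str] = DEFAULT_PIGMENT_CODES,
    chain_order: Sequence[str] | None = None,
) -> PigmentComplex:
    """Read an mmCIF/PDB file and extract pigment cofactors.

    Parameters
    ----------
    path
        Coordinate file; format detected by gemmi from the extension/content.
    pigment_residue_names
        Residue codes to extract (default: chlorophyll, carotenoid and
        pseudo-chlorophyll codes).
    chain_order
        Optional explicit chain -> subunit ordering overriding file order
        (sets the ring adjacency used by the prime convention).

    Chlorophyll-kind residues lacking a central Mg are skipped with a
    warning. A file with zero matching residues yields an empty complex
    (with a warning).
    """
    import gemmi

    codes = set(pigment_residue_names)
    if not codes:
        raise ValueError("pigment_residue_names must be nonempty")
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise StructureFormatError(f"{path}: no coordinate model found")
    model = st[0]
    chains_seen: list[str] = []
    pigments: list[Pigment] = []
    for chain in model:
        for residue in chain:
            if residue.name not in codes:
                continue
            if chain.name not in chains_seen:
                chains_seen.append(chain.name)
            atoms = [
                Atom(
                    name=at.name,
                    element=at.element.name,
                    position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    residue_name=residue.name,
                    residue_number=residue.seqid.num,
                    chain_id=chain.name,
                )
                for at in residue
            ]
            kind = _classify(residue.name)
            pid = f"{chain.name}/{residue.seqid.num}"
            pig = Pigment(pigment_id=pid, kind=kind, atoms=atoms)
            if kind.startswith("chlorophyll") or kind == "pseudo":
                if not pig.has_atom("MG"):
                    warnings.warn(
                        f"{pid} ({residue.name}): no Mg atom, residue skipped",
                        stacklevel=2,
                    )
                    logger.warning("skipped %s: chlorophyll-like without Mg", pid)
                    continue
            pigments.append(pig)

    if not pigments:
        warnings.warn(f"{path}: no pigment residues matching {sorted(codes)}",
                      stacklevel=2)

    order = list(chain_order) if chain_order is not None else chains_seen
    chain_index = {c: i for i, c in enumerate(order)}
    subunit_map = {}
    for p in pigments:
        if p.chain_id not in chain_index:
            raise ValueError(f"chain {p.chain_id} missing from chain_order")
        subunit_map[p.pigment_id] = chain_index[p.chain_id]
    return PigmentComplex(
        pigments=pigments,
        n_subunits=max(len(order), 1),
        subunit_map=subunit_map,
    )


def chain_distance_audit(
    complex_: PigmentComplex,
    chain_names: Sequence[str],
    start_subunit: int = 0,
    cutoff: float = 15.0,
) -> pd.DataFrame:
    """Audit consecutive Mg-Mg distances along a named pigment path.

    ``chain_names`` is a list of residue-number names, primes allowed
    (e.g. ``["601", "602", "603", "609", "611'", "612'", "610'"]``); each
    name is resolved relative to ``start_subunit``. Returns one row per
    consecutive pair with the distance and whether it is below ``cutoff``.
    """
    pigs = [complex_.resolve(name, start_subunit) for name in chain_names]
    rows = []
    for (na, a), (nb, b) in zip(
        zip(chain_names, pigs), zip(chain_names[1:], pigs[1:])
    ):
        d = mg_distance(a, b)
        rows.append(
            {"from": na, "to": nb, "mg_distance": d, "within_cutoff": d < cutoff}
        )
    return pd.DataFrame(rows)
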