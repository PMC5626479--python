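"""Discrete rotamer library and internal-coordinate side-chain construction.

Side chains are realized on a fixed backbone frame (N/CA/C of the residue)
by sequential torsion-chain (NeRF) placement using the packaged ideal
internal-coordinate table.  Chi dihedrals recomputed from the built atoms
match the requested values to well under half a degree, which the test
suite asserts for every residue type.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Sequence

import numpy as np

from .constants import AA1_TO_3, N_CHI
from .geometry import place_atom
from .structures import Atom, BackboneFrame

__all__ = [
    "Rotamer",
    "RotamerPlacement",
    "RotamerError",
    "available_libraries",
    "load_rotamer_library",
    "build_sidechain",
    "enumerate_placements",
    "residue_bonds",
    "CHI_ATOMS",
]

_LIBRARIES = {"compact-v1": "rotamers_compact_v1.tsv"}
DEFAULT_LIBRARY = "compact-v1"


class RotamerError(ValueError):
    pass


@dataclass(frozen=True)
class Rotamer:
    """A discrete side-chain conformation: residue type + chi angles."""

    residue_type: str  # 1-letter code
    chi: tuple[float, ...]
    prior_weight: float

    def __post_init__(self):
        if self.residue_type not in AA1_TO_3:
            raise RotamerError(f"unknown residue type {self.residue_type!r}")
        if len(self.chi) != N_CHI[self.residue_type]:
            raise RotamerError(
                f"{self.residue_type} takes {N_CHI[self.residue_type]} chi angles, "
                f"got {len(self.chi)}"
            )
        if not self.prior_weight > 0:
            raise RotamerError("prior_weight must be positive")


@dataclass(frozen=True)
class RotamerPlacement:
    """A rotamer realized as side-chain heavy atoms at a specific site."""

    site: tuple[str, int]  # (chain_id, residue_number)
    rotamer: Rotamer
    atoms: tuple[Atom, ...]


def _read_data(name: str) -> str:
    return resources.files("bumphole.data").joinpath(name).read_text()


def available_libraries() -> list[str]:
    return sorted(_LIBRARIES)


@lru_cache(maxsize=4)
def load_rotamer_library(source_id: str = DEFAULT_LIBRARY) -> dict[str, tuple[Rotamer, ...]]:
    """Load a packaged rotamer library, weights normalized per residue type."""
    if source_id not in _LIBRARIES:
        raise RotamerError(
            f"unknown rotamer library {source_id!r}; available: {available_libraries()}"
        )
    raw: dict[str, list[tuple[tuple[float, ...], float]]] = {}
    for line in _read_data(_LIBRARIES[source_id]).splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        res, *chis, weight = line.split("\t")
        chi = tuple(float(c) for c in chis if c != ".")
        raw.setdefault(res, []).append((chi, float(weight)))
    lib: dict[str, tuple[Rotamer, ...]] = {}
    for res, rows in raw.items():
        total = sum(w for _, w in rows)
        lib[res] = tuple(
            Rotamer(residue_type=res, chi=chi, prior_weight=w / total)
            for chi, w in rows
        )
    return lib


# ---------------------------------------------------------------------------
# Topology table

_CHI_RE = re.compile(r"^chi(\d)([+-]\d+(?:\.\d+)?)?$")


@dataclass(frozen=True)
class _TopoRow:
    atom: str
    refs: tuple[str, str, str]  # a1 (bonded parent), a2, a3
    bond: float
    angle: float
    chi_index: int | None  # 0-based; None for fixed torsion
    offset: float  # added to chi, or the fixed torsion itself


@lru_cache(maxsize=1)
def _topology() -> dict[str, tuple[_TopoRow, ...]]:
    table: dict[str, list[_TopoRow]] = {}
    for line in _read_data("topology.tsv").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        res, atom, a1, a2, a3, bond, angle, torsion = line.split("\t")
        m = _CHI_RE.match(torsion)
        if m:
            chi_index = int(m.group(1)) - 1
            offset = float(m.group(2) or 0.0)
        else:
            chi_index, offset = None, float(torsion)
        table.setdefault(res, []).append(
            _TopoRow(atom, (a1, a2, a3), float(bond), float(angle), chi_index, offset)
        )
    table["G"] = []
    return {r: tuple(rows) for r, rows in table.items()}


# Atoms defining chi_k for each residue type: chi_k = torsion over CHI_ATOMS[res][k].
@lru_cache(maxsize=1)
def _chi_atoms() -> dict[str, tuple[tuple[str, str, str, str], ...]]:
    out: dict[str, list[tuple[str, str, str, str]]] = {}
    for res, rows in _topology().items():
        chains: dict[int, tuple[str, str, str, str]] = {}
        for row in rows:
            if row.chi_index is not None and abs(row.offset) < 1e-9:
                a1, a2, a3 = row.refs
                chains[row.chi_index] = (a3, a2, a1, row.atom)
        out[res] = [chains[k] for k in sorted(chains)]
    return {r: tuple(v) for r, v in out.items()}


def CHI_ATOMS(residue_type: str) -> tuple[tuple[str, str, str, str], ...]:
    """Atom-name quadruples defining each chi dihedral of a residue type."""
    return _chi_atoms()[residue_type]


# Ring-closure bonds not expressible in the build tree (for bond graphs).
_RING_CLOSURES = {
    "P": [("CD", "N")],
    "H": [("NE2", "CD2")],
    "F": [("CZ", "CE2")],
    "Y": [("CZ", "CE2")],
    "W": [("NE1", "CE2"), ("CZ3", "CH2")],
}


@lru_cache(maxsize=32)
def residue_bonds(residue_type: str) -> frozenset[tuple[str, str]]:
    """Covalent bonds among the heavy atoms of one residue (both orders)."""
    bonds = {("N", "CA"), ("CA", "C"), ("C", "O"), ("C", "OXT")}
    for row in _topology().get(residue_type, ()):
        bonds.add((row.refs[0], row.atom))
    for a, b in _RING_CLOSURES.get(residue_type, ()):
        bonds.add((a, b))
    return frozenset(bonds | {(b, a) for a, b in bonds})


# ---------------------------------------------------------------------------
# Construction

_ELEMENT_OF = {"C": "C", "N": "N", "O": "O", "S": "S"}


def _element(atom_name: str) -> str:
    return _ELEMENT_OF[atom_name[0]]


def build_sidechain(
    frame: BackboneFrame, residue_type: str, chi: Sequence[float]
) -> list[tuple[str, np.ndarray]]:
    """Build side-chain heavy atoms for one residue on a backbone frame.

    Returns ``(atom_name, coord)`` pairs in topology order.  CB is placed
    tetrahedrally off N/CA/C; subsequent atoms follow the torsion chain with
    the requested chi values substituted for the chi-labelled torsions.
    """
    if residue_type not in AA1_TO_3:
        raise RotamerError(f"unknown residue type {residue_type!r}")
    chi = tuple(float(c) for c in chi)
    if len(chi) != N_CHI[residue_type]:
        raise RotamerError(
            f"{residue_type} takes {N_CHI[residue_type]} chi angles, got {len(chi)}"
        )
    known: dict[str, np.ndarray] = {"N": frame.N, "CA": frame.CA, "C": frame.C}
    out: list[tuple[str, np.ndarray]] = []
    for row in _topology()[residue_type]:
        torsion = row.offset if row.chi_index is None else chi[row.chi_index] + row.offset
        a1, a2, a3 = (known[r] for r in row.refs)
        coord = place_atom(a3, a2, a1, row.bond, row.angle, torsion)
        known[row.atom] = coord
        out.append((row.atom, coord))
    return out


def enumerate_placements(
    library: dict[str, tuple[Rotamer, ...]],
    site: tuple[str, int],
    frame: BackboneFrame,
    residue_type: str,
    expansion: Sequence[float] = (),
) -> list[RotamerPlacement]:
    """One placement per library rotamer, times optional chi1 perturbations.

    ``expansion`` lists additional chi1 offsets in degrees (e.g. ``(-10, 10)``)
    applied as sub-rotamers after the unperturbed one; order is deterministic:
    library order, then perturbation order.
    """
    if residue_type not in library:
        raise RotamerError(f"library has no rotamers for {residue_type!r}")
    placements: list[RotamerPlacement] = []
    offsets = (0.0, *[float(e) for e in expansion])
    for rot in library[residue_type]:
        for k, off in enumerate(offsets):
            if rot.chi:
                chi = (rot.chi[0] + off, *rot.chi[1:])
            else:
                chi = ()
                if k > 0:
                    continue  # no rotatable bond to perturb
            built = build_sidechain(frame, residue_type, chi)
            atoms = tuple(
                Atom(
                    name=nm,
                    element=_element(nm),
                    coord=xyz,
                    residue_number=site[1],
                    residue_name=AA1_TO_3[residue_type],
                    chain_id=site[0],
                )
                for nm, xyz in built
            )
            sub = rot if off == 0.0 else Rotamer(residue_type, chi, rot.prior_weight)
            placements.append(RotamerPlacement(site=site, rotamer=sub, atoms=atoms))
    return placements
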