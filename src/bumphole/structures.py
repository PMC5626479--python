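"""Structure I/O, mutation threading, design-region extraction and fixtures.

The in-memory model is deliberately small: a :class:`Structure` is an ordered
list of heavy :class:`Atom` records with author residue numbering, which is
all a fixed-backbone steric design needs.  Parsing of PDB text is delegated
to biotite (first model, highest-occupancy altloc, hydrogens/HETATM/waters
dropped); writing uses an in-house fixed-column formatter so that
write -> read -> write is byte-idempotent.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .constants import AA1_TO_3, AA3_TO_1, BACKBONE_ATOMS, STANDARD_AA
from .geometry import place_atom

__all__ = [
    "Atom",
    "Structure",
    "Mutation",
    "InterfaceSpec",
    "BackboneFrame",
    "DesignSite",
    "DesignRegion",
    "StructureError",
    "FormatError",
    "MutationError",
    "read_structure",
    "write_structure",
    "apply_mutations",
    "parse_mutation",
    "extract_design_region",
    "make_synthetic_bundle",
    "make_synthetic_interface",
    "core_facing_positions",
]


class StructureError(ValueError):
    """Base error for structure handling."""


class FormatError(StructureError):
    """Unparsable or unwritable PDB content."""


class MutationError(StructureError):
    """Mutation does not apply to the structure."""


@dataclass(frozen=True)
class Atom:
    """One heavy atom with author numbering."""

    name: str
    element: str
    coord: np.ndarray  # (3,) float, Angstrom
    residue_number: int
    residue_name: str  # 3-letter code
    chain_id: str

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS

    def __post_init__(self):
        c = np.asarray(self.coord, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise StructureError(f"bad coordinate for atom {self.name}: {self.coord}")
        object.__setattr__(self, "coord", c)


@dataclass
class Structure:
    """Ordered collection of atoms from one model."""

    atoms: list[Atom]
    model_id: int = 1

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms]) if self.atoms else np.zeros((0, 3))

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def chain(self, chain_id: str) -> list[Atom]:
        return [a for a in self.atoms if a.chain_id == chain_id]

    def residue(self, chain_id: str, residue_number: int) -> list[Atom]:
        return [
            a
            for a in self.atoms
            if a.chain_id == chain_id and a.residue_number == residue_number
        ]

    def residue_name(self, chain_id: str, residue_number: int) -> str:
        res = self.residue(chain_id, residue_number)
        if not res:
            raise StructureError(f"no residue {residue_number} on chain {chain_id!r}")
        return res[0].residue_name

    def residue_numbers(self, chain_id: str) -> list[int]:
        seen: dict[int, None] = {}
        for a in self.atoms:
            if a.chain_id == chain_id:
                seen.setdefault(a.residue_number, None)
        return list(seen)

    def get_atom(self, chain_id: str, residue_number: int, name: str) -> Atom:
        for a in self.atoms:
            if (
                a.chain_id == chain_id
                and a.residue_number == residue_number
                and a.name == name
            ):
                return a
        raise StructureError(
            f"atom {name} of residue {residue_number} chain {chain_id!r} not found"
        )

    def validate(self) -> None:
        seen = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_number, a.name)
            if key in seen:
                raise StructureError(f"duplicate atom {key}")
            seen.add(key)


@dataclass(frozen=True)
class Mutation:
    """Point substitution in wt/position/mut notation, e.g. L126A."""

    wt: str
    position: int
    mut: str

    def __post_init__(self):
        if self.wt not in AA1_TO_3 or self.mut not in AA1_TO_3:
            raise MutationError(f"unknown residue code in {self}")
        if self.wt == self.mut:
            raise MutationError(f"mutation {self} is a no-op")
        if self.position <= 0:
            raise MutationError(f"non-positive position in {self}")

    def __str__(self) -> str:
        return f"{self.wt}{self.position}{self.mut}"


def parse_mutation(token: str) -> Mutation:
    """Parse a token like ``L126A`` into a :class:`Mutation`."""
    token = token.strip().upper()
    if len(token) < 3 or not token[1:-1].isdigit():
        raise MutationError(
            f"malformed mutation token {token!r} (expected e.g. 'L126A')"
        )
    return Mutation(wt=token[0], position=int(token[1:-1]), mut=token[-1])


@dataclass(frozen=True)
class InterfaceSpec:
    """Names the two protomer chains and the shared design positions."""

    chain_x: str
    chain_y: str
    design_positions: tuple[int, ...]
    environment_cutoff: float = 8.0

    def __post_init__(self):
        if self.chain_x == self.chain_y:
            raise StructureError("chain_x and chain_y must differ")
        if not self.design_positions:
            raise StructureError("design_positions must be nonempty")
        if self.environment_cutoff < 0:
            raise StructureError("environment_cutoff must be >= 0")
        object.__setattr__(
            self, "design_positions", tuple(sorted(set(self.design_positions)))
        )


@dataclass(frozen=True)
class BackboneFrame:
    """N/CA/C coordinates of one residue; the anchor for side-chain building."""

    N: np.ndarray
    CA: np.ndarray
    C: np.ndarray

    def __post_init__(self):
        for nm in ("N", "CA", "C"):
            object.__setattr__(self, nm, np.asarray(getattr(self, nm), float))
        for a, b, label in ((self.N, self.CA, "N-CA"), (self.CA, self.C, "CA-C")):
            d = float(np.linalg.norm(a - b))
            if not 1.2 <= d <= 1.8:
                raise StructureError(f"implausible {label} bond length {d:.2f} A")


@dataclass(frozen=True)
class DesignSite:
    chain_id: str
    residue_number: int
    wt_name: str  # 3-letter code of the residue currently threaded
    frame: BackboneFrame


@dataclass
class DesignRegion:
    """Design sites on both protomers plus their fixed template environment."""

    spec: InterfaceSpec
    design_sites: list[DesignSite]
    template_atoms: list[Atom]

    def site_index(self, chain_id: str, residue_number: int) -> int:
        for i, s in enumerate(self.design_sites):
            if s.chain_id == chain_id and s.residue_number == residue_number:
                return i
        raise StructureError(f"no design site {chain_id}/{residue_number}")


# ---------------------------------------------------------------------------
# PDB I/O


def _as_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    if isinstance(source, (str, os.PathLike)):
        s = os.fspath(source)
        if "\n" in s or s.lstrip().startswith(("ATOM", "HETATM", "HEADER", "MODEL", "REMARK", "CRYST")):
            return s
        with open(s) as fh:
            return fh.read()
    raise FormatError(f"cannot interpret source of type {type(source)!r}")


def _find_bad_line(text: str) -> int | None:
    for i, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            try:
                int(line[22:26])
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except (ValueError, IndexError):
                return i
    return None


def read_structure(source, model: int = 1) -> Structure:
    """Read protein heavy atoms from PDB-format text, a path, or a file object.

    The first model is used by default; hydrogens, HETATM records (waters,
    ligands, the nucleosomal DNA of entries like 1KX3), and all but the
    highest-occupancy altloc are dropped.  Author residue numbering is kept.
    """
    import biotite.structure.io.pdb as biotite_pdb

    text = _as_text(source)
    try:
        pdb_file = biotite_pdb.PDBFile.read(io.StringIO(text))
        arr = pdb_file.get_structure(model=model, altloc="occupancy")
    except Exception as exc:
        bad = _find_bad_line(text)
        where = f" at line {bad}" if bad is not None else ""
        raise FormatError(f"unparsable PDB record{where}: {exc}") from exc

    atoms: list[Atom] = []
    for i in range(arr.array_length()):
        if arr.hetero[i]:
            continue
        res_name = str(arr.res_name[i])
        if res_name not in STANDARD_AA:
            continue
        element = str(arr.element[i]).upper()
        if element in ("H", "D"):
            continue
        atoms.append(
            Atom(
                name=str(arr.atom_name[i]),
                element=element,
                coord=arr.coord[i].astype(float),
                residue_number=int(arr.res_id[i]),
                residue_name=res_name,
                chain_id=str(arr.chain_id[i]),
            )
        )
    if not atoms:
        raise FormatError("no protein ATOM records found in input")
    s = Structure(atoms=atoms, model_id=model)
    s.validate()
    return s


def _format_atom_name(name: str, element: str) -> str:
    # Standard PDB convention: 1-letter elements start in column 14.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_structure(structure: Structure, path: str | os.PathLike | None = None) -> str:
    """Serialize to fixed-column PDB ATOM records (3-decimal coordinates)."""
    if not structure.atoms:
        raise StructureError("refusing to write an empty structure")
    lines = []
    serial = 0
    prev_chain = None
    for a in structure.atoms:
        if prev_chain is not None and a.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = a.chain_id
        serial += 1
        x, y, z = a.coord
        for v in (x, y, z):
            if not -999.999 <= v <= 9999.999:
                raise FormatError(f"coordinate {v:.3f} overflows PDB fixed-width field")
        lines.append(
            f"ATOM  {serial:5d} {_format_atom_name(a.name, a.element)} "
            f"{a.residue_name:>3s} {a.chain_id[:1]}{a.residue_number:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {a.element:>2s}"
        )
    lines.append("TER")
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Mutation threading


def apply_mutations(
    structure: Structure, chain_id: str, mutations: Sequence[Mutation]
) -> Structure:
    """Thread point mutations onto a chain without moving any backbone atom.

    Side-chain atoms of mutated residues are removed (they are rebuilt from
    rotamers downstream); backbone atoms are carried over bit-identically.
    """
    by_pos = {}
    for m in mutations:
        if m.position in by_pos:
            raise MutationError(f"duplicate mutation at position {m.position}")
        by_pos[m.position] = m

    present = set(structure.residue_numbers(chain_id))
    for m in by_pos.values():
        if m.position not in present:
            raise MutationError(
                f"position {m.position} does not exist on chain {chain_id!r}"
            )
        found = AA3_TO_1[structure.residue_name(chain_id, m.position)]
        if found != m.wt:
            raise MutationError(
                f"wild-type mismatch at {chain_id}/{m.position}: "
                f"mutation expects {m.wt}, structure has {found}"
            )

    new_atoms: list[Atom] = []
    for a in structure.atoms:
        if a.chain_id == chain_id and a.residue_number in by_pos:
            if not a.is_backbone:
                continue
            m = by_pos[a.residue_number]
            new_atoms.append(replace(a, residue_name=AA1_TO_3[m.mut]))
        else:
            new_atoms.append(a)
    return Structure(atoms=new_atoms, model_id=structure.model_id)


# ---------------------------------------------------------------------------
# Design-region extraction


def _frame_for(structure: Structure, chain_id: str, pos: int) -> BackboneFrame:
    try:
        n = structure.get_atom(chain_id, pos, "N").coord
        ca = structure.get_atom(chain_id, pos, "CA").coord
        c = structure.get_atom(chain_id, pos, "C").coord
    except StructureError as exc:
        raise StructureError(
            f"design site {chain_id}/{pos} is missing a backbone atom: {exc}"
        ) from exc
    return BackboneFrame(N=n, CA=ca, C=c)


def extract_design_region(structure: Structure, spec: InterfaceSpec) -> DesignRegion:
    """Carve out design sites (both protomers) and the fixed template shell.

    Template = every non-design atom within ``environment_cutoff`` of any
    design-site CA or CB (brute-force distance criterion), plus the backbone
    atoms of the design sites themselves.  The crystallographic side chains
    of the design sites are discarded; they are re-represented as rotamers.
    """
    chains = set(structure.chains())
    for c in (spec.chain_x, spec.chain_y):
        if c not in chains:
            raise StructureError(f"chain {c!r} not present in structure")

    design_keys = set()
    design_sites: list[DesignSite] = []
    for chain in (spec.chain_x, spec.chain_y):
        for pos in spec.design_positions:
            if pos not in set(structure.residue_numbers(chain)):
                raise StructureError(f"design position {pos} missing on chain {chain!r}")
            design_keys.add((chain, pos))
            design_sites.append(
                DesignSite(
                    chain_id=chain,
                    residue_number=pos,
                    wt_name=structure.residue_name(chain, pos),
                    frame=_frame_for(structure, chain, pos),
                )
            )

    probe = []
    for chain, pos in design_keys:
        for name in ("CA", "CB"):
            try:
                probe.append(structure.get_atom(chain, pos, name).coord)
            except StructureError:
                pass  # e.g. GLY has no CB
    probe = np.array(probe)

    template: list[Atom] = []
    for a in structure.atoms:
        key = (a.chain_id, a.residue_number)
        if key in design_keys:
            if a.is_backbone:
                template.append(a)
            continue
        if probe.size and spec.environment_cutoff > 0:
            d = np.linalg.norm(probe - a.coord, axis=1)
            if float(d.min()) <= spec.environment_cutoff:
                template.append(a)
    return DesignRegion(spec=spec, design_sites=design_sites, template_atoms=template)


# ---------------------------------------------------------------------------
# Synthetic fixtures

_HELIX_PHI, _HELIX_PSI, _HELIX_OMEGA = -57.0, -47.0, 180.0
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_B_C_O, _A_CA_C_O = 1.231, 120.8
_B_CA_CB, _A_N_CA_CB, _T_CB = 1.530, 110.4, -122.5  # improper torsion(CB,CA,N,C)


def _ideal_helix_backbone(n_res: int) -> list[dict[str, np.ndarray]]:
    """Poly-ALA ideal alpha helix built by torsion propagation (phi/psi -57/-47)."""
    res: list[dict[str, np.ndarray]] = []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_B_N_CA, 0.0, 0.0])
    th = np.radians(180.0 - _A_N_CA_C)
    c = ca + _B_CA_C * np.array([np.cos(th), np.sin(th), 0.0])
    for i in range(n_res):
        res.append({"N": n, "CA": ca, "C": c})
        if i + 1 < n_res:
            n2 = place_atom(n, ca, c, _B_C_N, _A_CA_C_N, _HELIX_PSI)
            ca2 = place_atom(ca, c, n2, _B_N_CA, _A_C_N_CA, _HELIX_OMEGA)
            c2 = place_atom(c, n2, ca2, _B_CA_C, _A_N_CA_C, _HELIX_PHI)
            n, ca, c = n2, ca2, c2
    # carbonyl O and CB from the completed trace
    for i, r in enumerate(res):
        psi = _HELIX_PSI if i + 1 < n_res else _HELIX_PSI  # C-terminal O kept helical
        r["O"] = place_atom(r["N"], r["CA"], r["C"], _B_C_O, _A_CA_C_O, psi + 180.0)
        r["CB"] = place_atom(r["C"], r["N"], r["CA"], _B_CA_CB, _A_N_CA_CB, _T_CB)
    return res


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    if np.dot(coords[-1] - coords[0], axis) < 0:
        axis = -axis
    return axis


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(np.dot(u, v))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # 180 degrees about any axis perpendicular to u
        p = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            p = np.array([0.0, 1.0, 0.0])
        k = np.cross(u, p)
        k /= np.linalg.norm(k)
        return 2.0 * np.outer(k, k) - np.eye(3)
    k = np.cross(u, v)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + kx + kx @ kx / (1 + c)


def make_synthetic_bundle(
    n_helices: int = 2,
    residues_per_helix: int = 12,
    inter_axis_spacing: float = 10.0,
    seed: int = 0,
    phase_deg: float | Sequence[float] = 0.0,
    jitter_sd: float = 0.0,
    first_residue_number: int = 1,
) -> Structure:
    """Generate an idealized antiparallel poly-alanine helix bundle.

    Helices are ideal alpha helices (1.5 A rise, 100 deg/residue; phi/psi
    -57/-47) with axes along z, antiparallel in alternation, spaced
    ``inter_axis_spacing`` apart (two helices: side by side; three or more:
    a regular polygon with that edge length).  ``phase_deg`` rotates each
    helix about its own axis and so selects which face points at the core.
    Optional Gaussian coordinate jitter (``jitter_sd``, A) is driven by
    ``seed``; with the default jitter of 0 the output is fully deterministic.
    """
    if n_helices < 1:
        raise StructureError("n_helices must be >= 1")
    if residues_per_helix < 4:
        raise StructureError("residues_per_helix must be >= 4")
    if inter_axis_spacing < 4.0:
        raise StructureError(
            f"inter_axis_spacing {inter_axis_spacing} A is non-physical (< 4 A)"
        )
    phases = (
        [float(phase_deg)] * n_helices
        if np.isscalar(phase_deg)
        else [float(p) for p in phase_deg]
    )
    if len(phases) != n_helices:
        raise StructureError("phase_deg must be scalar or one value per helix")

    if n_helices == 1:
        centers = [np.zeros(2)]
    elif n_helices == 2:
        centers = [np.array([-inter_axis_spacing / 2, 0.0]), np.array([inter_axis_spacing / 2, 0.0])]
    else:
        r = inter_axis_spacing / (2 * np.sin(np.pi / n_helices))
        centers = [
            r * np.array([np.cos(2 * np.pi * k / n_helices), np.sin(2 * np.pi * k / n_helices)])
            for k in range(n_helices)
        ]

    proto = _ideal_helix_backbone(residues_per_helix)
    proto_coords = np.array([a for r in proto for a in (r["N"], r["CA"], r["C"], r["O"], r["CB"])])
    ca_coords = np.array([r["CA"] for r in proto])
    axis = _principal_axis(ca_coords)
    rot_to_z = _rotation_between(axis, np.array([0.0, 0.0, 1.0]))
    aligned = (proto_coords - ca_coords.mean(axis=0)) @ rot_to_z.T

    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    chain_ids = [chr(ord("A") + k) for k in range(n_helices)]
    atom_names = ["N", "CA", "C", "O", "CB"]
    elements = ["N", "C", "C", "O", "C"]
    for k in range(n_helices):
        coords = aligned.copy()
        if k % 2 == 1:  # antiparallel: rotate 180 deg about y, so that for
            # n = 2 the second helix is the exact C2 image of the first
            flip = np.diag([-1.0, 1.0, -1.0])
            coords = coords @ flip.T
        ph = np.radians(phases[k])
        rz = np.array(
            [[np.cos(ph), -np.sin(ph), 0], [np.sin(ph), np.cos(ph), 0], [0, 0, 1]]
        )
        coords = coords @ rz.T
        coords[:, 0] += centers[k][0]
        coords[:, 1] += centers[k][1]
        if jitter_sd > 0:
            coords = coords + rng.normal(0.0, jitter_sd, coords.shape)
        for i in range(residues_per_helix):
            for j, (nm, el) in enumerate(zip(atom_names, elements)):
                atoms.append(
                    Atom(
                        name=nm,
                        element=el,
                        coord=coords[5 * i + j],
                        residue_number=first_residue_number + i,
                        residue_name="ALA",
                        chain_id=chain_ids[k],
                    )
                )
    return Structure(atoms=atoms)


def make_synthetic_interface(
    residues_per_helix: int = 13,
    inter_axis_spacing: float = 10.5,
    seed: int = 0,
) -> tuple[Structure, InterfaceSpec]:
    """SYNTHETIC stand-in for a homodimeric four-helix-bundle interface.

    Two protomer chains (A and B), each contributing an antiparallel pair of
    ideal poly-alanine helices (residues 101.. and 201..), assembled with
    exact two-fold symmetry about z on a square of edge ``inter_axis_spacing``.
    This is an idealized geometric analogue of a histone-fold dimerization
    bundle — NOT experimental coordinates — built so the full design pipeline
    (threading, packing, specificity ranking, clash/void diagnosis) can run
    without any downloaded structure.

    Returns the structure and an :class:`InterfaceSpec` whose design
    positions are the two most core-facing interior residues of each helix.
    """
    if inter_axis_spacing < 4.0:
        raise StructureError(
            f"inter_axis_spacing {inter_axis_spacing} A is non-physical (< 4 A)"
        )
    proto = _ideal_helix_backbone(residues_per_helix)
    proto_coords = np.array(
        [a for r in proto for a in (r["N"], r["CA"], r["C"], r["O"], r["CB"])]
    )
    ca = np.array([r["CA"] for r in proto])
    axis = _principal_axis(ca)
    rot_to_z = _rotation_between(axis, np.array([0.0, 0.0, 1.0]))
    aligned = (proto_coords - ca.mean(axis=0)) @ rot_to_z.T

    half = inter_axis_spacing / 2.0
    corners = [np.array([half, half]), np.array([half, -half])]  # chain A helices
    flip = np.diag([-1.0, 1.0, -1.0])
    central = residues_per_helix // 2

    chain_a_coords = []
    for h, corner in enumerate(corners):
        coords = aligned.copy()
        if h == 1:  # second helix of the hairpin runs antiparallel
            coords = coords @ flip.T
        # phase the helix so the central residue's CB points at the bundle axis
        cb = coords[5 * central + 4]
        ca_c = coords[5 * central + 1]
        v = cb - ca_c
        current = np.arctan2(v[1], v[0])
        target = np.arctan2(-corner[1], -corner[0])
        ph = target - current
        rz = np.array(
            [[np.cos(ph), -np.sin(ph), 0], [np.sin(ph), np.cos(ph), 0], [0, 0, 1]]
        )
        coords = coords @ rz.T
        coords[:, 0] += corner[0]
        coords[:, 1] += corner[1]
        chain_a_coords.append(coords)

    c2 = np.diag([-1.0, -1.0, 1.0])  # two-fold about z maps chain A onto chain B
    atom_names = ["N", "CA", "C", "O", "CB"]
    elements = ["N", "C", "C", "O", "C"]
    atoms: list[Atom] = []
    for chain_id, transform in (("A", np.eye(3)), ("B", c2)):
        for h, coords in enumerate(chain_a_coords):
            placed = coords @ transform.T
            base = 101 if h == 0 else 201
            for i in range(residues_per_helix):
                for j, (nm, el) in enumerate(zip(atom_names, elements)):
                    atoms.append(
                        Atom(
                            name=nm,
                            element=el,
                            coord=placed[5 * i + j],
                            residue_number=base + i,
                            residue_name="ALA",
                            chain_id=chain_id,
                        )
                    )
    structure = Structure(atoms=atoms)

    # design positions: the four interior residues (two per helix) whose CB
    # atoms across BOTH protomers form the tightest shared cluster — the
    # synthetic analogue of a hydrophobic cluster at a dimer interface
    interior = [
        p
        for base in (101, 201)
        for p in range(base + 2, base + residues_per_helix - 2)
    ]
    cb = {
        (ch, p): structure.get_atom(ch, p, "CB").coord
        for ch in ("A", "B")
        for p in interior
    }
    h1 = [p for p in interior if p < 200]
    h2 = [p for p in interior if p > 200]
    import itertools as _it

    best: tuple[float, tuple[int, ...]] | None = None
    for pa in _it.combinations(h1, 2):
        for pb in _it.combinations(h2, 2):
            pts = [cb[(ch, p)] for ch in ("A", "B") for p in pa + pb]
            dmax = max(
                float(np.linalg.norm(u - v))
                for i, u in enumerate(pts)
                for v in pts[i + 1 :]
            )
            if best is None or dmax < best[0] - 1e-9:
                best = (dmax, pa + pb)
    flat = tuple(sorted(best[1]))
    return structure, InterfaceSpec(
        chain_x="A", chain_y="B", design_positions=flat, environment_cutoff=8.0
    )


def core_facing_positions(
    structure: Structure, chain_id: str, n_best: int = 4, center: np.ndarray | None = None
) -> list[int]:
    """Rank residues of a chain by how directly their CA->CB vector points
    at the bundle core (centroid of all CA atoms by default).

    A convenience for choosing design positions on synthetic fixtures; returns
    the ``n_best`` most core-facing residue numbers in ascending order.
    """
    all_ca = np.array([a.coord for a in structure.atoms if a.name == "CA"])
    core = all_ca.mean(axis=0) if center is None else np.asarray(center, float)
    scores = []
    for pos in structure.residue_numbers(chain_id):
        try:
            ca = structure.get_atom(chain_id, pos, "CA").coord
            cb = structure.get_atom(chain_id, pos, "CB").coord
        except StructureError:
            continue
        v = cb - ca
        to_core = core - ca
        to_core[2] = 0.0  # judge facing in the bundle cross-section
        if np.linalg.norm(to_core) < 1e-9:
            continue
        cosang = float(
            np.dot(v, to_core) / (np.linalg.norm(v) * np.linalg.norm(to_core))
        )
        scores.append((cosang, pos))
    scores.sort(reverse=True)
    return sorted(pos for _, pos in scores[:n_best])
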