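"""Steric scoring: united-atom 12-6 Lennard-Jones and the pairwise matrix.

The scoring model is purely van der Waals — the bump-hole design logic is
steric, so a soft-capped 12-6 potential over united heavy atoms is the whole
force field.  Radii are scaled (default 0.9) and each atom-pair term is
capped (default +10 kcal/mol) so that clashing geometries stay finite and a
single bad pair cannot dominate a ranking.

The packing problem over design sites is compiled once into a pairwise
energy matrix: a template constant (fixed atoms with themselves), per-
placement self energies (placement vs template), and placement-pair
energies between distinct sites.  Any total over the matrix equals the
direct all-atom energy of the assembled model; the test suite asserts this
to 1e-6 kcal/mol.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .constants import AA3_TO_1
from .rotamers import (
    DEFAULT_LIBRARY,
    RotamerPlacement,
    enumerate_placements,
    load_rotamer_library,
    residue_bonds,
)
from .structures import Atom, DesignRegion

__all__ = [
    "LJParams",
    "EnergyOptions",
    "EnergyMatrix",
    "Assignment",
    "EnergyError",
    "atom_params",
    "pair_energy",
    "compute_energy_matrix",
    "total_energy",
    "structure_energy",
]


class EnergyError(ValueError):
    pass


@dataclass(frozen=True)
class LJParams:
    atom_class: str
    sigma: float  # Angstrom
    epsilon: float  # kcal/mol

    def __post_init__(self):
        if not (self.sigma > 0 and self.epsilon > 0):
            raise EnergyError(f"non-physical LJ parameters {self}")


@dataclass(frozen=True)
class EnergyOptions:
    """Knobs of the steric score; defaults are conventional fixed-backbone
    choices and all of them are exposed in run configuration."""

    radius_scale: float = 0.9
    repulsion_cap: float = 10.0  # kcal/mol per atom pair
    cutoff: float = 8.0  # Angstrom
    clash_cut: float = 3.0  # kcal/mol per atom pair
    void_cut: float = 1.0  # kcal/mol state-level deficit

    def __post_init__(self):
        if not 0 < self.radius_scale <= 1:
            raise EnergyError("radius_scale must be in (0, 1]")
        if not self.repulsion_cap > self.clash_cut > 0:
            raise EnergyError("need repulsion_cap > clash_cut > 0")
        if not self.cutoff > 0:
            raise EnergyError("cutoff must be positive")


# ---------------------------------------------------------------------------
# Parameter tables


@lru_cache(maxsize=1)
def _lj_table() -> dict[str, LJParams]:
    out = {}
    text = resources.files("bumphole.data").joinpath("lj_params.tsv").read_text()
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cls, sigma, eps = line.split("\t")
        out[cls] = LJParams(atom_class=cls, sigma=float(sigma), epsilon=float(eps))
    return out


@lru_cache(maxsize=1)
def _class_map() -> dict[tuple[str, str], str]:
    out = {}
    text = resources.files("bumphole.data").joinpath("atom_classes.tsv").read_text()
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        res, atom, cls = line.split("\t")
        out[(res, atom)] = cls
    return out


def atom_params(atom: Atom) -> LJParams:
    """United-atom LJ parameters for one protein heavy atom."""
    res1 = AA3_TO_1.get(atom.residue_name)
    if res1 is None:
        raise EnergyError(f"nonstandard residue {atom.residue_name!r}")
    cmap = _class_map()
    cls = cmap.get((res1, atom.name)) or cmap.get(("*", atom.name))
    if cls is None:
        raise EnergyError(
            f"no LJ class for atom {atom.name!r} of residue {atom.residue_name}"
        )
    return _lj_table()[cls]


def _params_arrays(atoms: Sequence[Atom]) -> tuple[np.ndarray, np.ndarray]:
    p = [atom_params(a) for a in atoms]
    return np.array([q.sigma for q in p]), np.array([q.epsilon for q in p])


# ---------------------------------------------------------------------------
# Pair potential


def _lj_matrix(
    coords_a: np.ndarray,
    sig_a: np.ndarray,
    eps_a: np.ndarray,
    coords_b: np.ndarray,
    sig_b: np.ndarray,
    eps_b: np.ndarray,
    options: EnergyOptions,
) -> np.ndarray:
    """Per-pair capped 12-6 terms (Lorentz-Berthelot, scaled radii, cutoff)."""
    r = cdist(coords_a, coords_b)
    sig = options.radius_scale * 0.5 * (sig_a[:, None] + sig_b[None, :])
    eps = np.sqrt(eps_a[:, None] * eps_b[None, :])
    with np.errstate(divide="ignore", over="ignore"):
        x6 = (sig / np.maximum(r, 1e-9)) ** 6
        e = 4.0 * eps * (x6 * x6 - x6)
    e = np.minimum(e, options.repulsion_cap)
    e[r >= options.cutoff] = 0.0
    return e


@lru_cache(maxsize=64)
def _excluded_pairs(residue_type: str) -> frozenset[frozenset[str]]:
    """Atom-name pairs within one residue separated by <= 3 bonds (1-2/1-3/1-4)."""
    bonds = residue_bonds(residue_type)
    adj: dict[str, set[str]] = {}
    for a, b in bonds:
        adj.setdefault(a, set()).add(b)
    excluded = set()
    for start in adj:
        dist = {start: 0}
        q = deque([start])
        while q:
            u = q.popleft()
            if dist[u] >= 3:
                continue
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    q.append(v)
        for other, d in dist.items():
            if other != start and d <= 3:
                excluded.add(frozenset((start, other)))
    return frozenset(excluded)


def _exclusion_mask(atoms_a: Sequence[Atom], atoms_b: Sequence[Atom]) -> np.ndarray:
    """True where an atom pair must not be scored (same residue, <= 3 bonds)."""
    mask = np.zeros((len(atoms_a), len(atoms_b)), dtype=bool)
    for i, a in enumerate(atoms_a):
        for j, b in enumerate(atoms_b):
            if a.chain_id == b.chain_id and a.residue_number == b.residue_number:
                # residue_name may legitimately differ between a threaded
                # placement and the template backbone of the same site;
                # bonded separation is judged by atom names under either type
                if a.name == b.name:
                    mask[i, j] = True
                    continue
                pair = frozenset((a.name, b.name))
                if pair in _excluded_pairs(AA3_TO_1[a.residue_name]) or pair in _excluded_pairs(
                    AA3_TO_1[b.residue_name]
                ):
                    mask[i, j] = True
    return mask


def pair_energy(
    atoms_a: Sequence[Atom],
    atoms_b: Sequence[Atom],
    options: EnergyOptions | None = None,
) -> float:
    """Summed capped LJ energy over all cross pairs of two disjoint atom sets.

    Pairs inside the same residue at 1-2/1-3/1-4 bonded separation are never
    scored; inter-residue pairs always are.  Symmetric in its arguments and
    zero for empty sets.
    """
    if not atoms_a or not atoms_b:
        return 0.0
    options = options or EnergyOptions()
    ca, cb = np.array([a.coord for a in atoms_a]), np.array([b.coord for b in atoms_b])
    sa, ea = _params_arrays(atoms_a)
    sb, eb = _params_arrays(atoms_b)
    e = _lj_matrix(ca, sa, ea, cb, sb, eb, options)
    e[_exclusion_mask(atoms_a, atoms_b)] = 0.0
    return float(e.sum())


def _self_energy(atoms: Sequence[Atom], options: EnergyOptions) -> float:
    """Energy of a set with itself (unordered pairs, exclusions applied)."""
    if len(atoms) < 2:
        return 0.0
    c = np.array([a.coord for a in atoms])
    s, e = _params_arrays(atoms)
    m = _lj_matrix(c, s, e, c, s, e, options)
    m[_exclusion_mask(atoms, atoms)] = 0.0
    np.fill_diagonal(m, 0.0)
    return float(m.sum()) / 2.0


def structure_energy(atoms: Sequence[Atom], options: EnergyOptions | None = None) -> float:
    """Total capped-LJ energy of a full atom collection (diagnostics/oracle)."""
    return _self_energy(list(atoms), options or EnergyOptions())


# ---------------------------------------------------------------------------
# Pairwise energy matrix


@dataclass(frozen=True)
class Assignment:
    """One chosen placement index per design site, in matrix site order."""

    indices: tuple[int, ...]


@dataclass
class EnergyMatrix:
    """Template constant + self energies + pair energies over design sites."""

    sites: list  # list[DesignSite]
    placements: list[list[RotamerPlacement]]  # per site
    E_template: float
    E_self: list[np.ndarray]  # per site, (n_i,)
    E_pair: dict[tuple[int, int], np.ndarray]  # i < j -> (n_i, n_j)
    options: EnergyOptions
    library_id: str = DEFAULT_LIBRARY

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def n_placements(self, i: int) -> int:
        return len(self.placements[i])

    def pair(self, i: int, ri: int, j: int, rj: int) -> float:
        if i == j:
            raise EnergyError("no pair energy within a single site")
        if i < j:
            return float(self.E_pair[(i, j)][ri, rj])
        return float(self.E_pair[(j, i)][rj, ri])

    def residue_of(self, i: int, ri: int) -> str:
        return self.placements[i][ri].rotamer.residue_type

    def allowed(self, i: int, residue_type: str) -> np.ndarray:
        """Placement indices at site i carrying the given residue type."""
        idx = [
            k
            for k, p in enumerate(self.placements[i])
            if p.rotamer.residue_type == residue_type
        ]
        return np.array(idx, dtype=int)

    def to_json(self) -> str:
        """Documented cache layout: sites, per-placement residue/chi, energies."""
        payload = {
            "library_id": self.library_id,
            "options": vars(self.options).copy()
            if not hasattr(self.options, "__dataclass_fields__")
            else {k: getattr(self.options, k) for k in self.options.__dataclass_fields__},
            "E_template": self.E_template,
            "sites": [
                {"chain": s.chain_id, "residue_number": s.residue_number, "wt": s.wt_name}
                for s in self.sites
            ],
            "placements": [
                [
                    {"residue": p.rotamer.residue_type, "chi": list(p.rotamer.chi)}
                    for p in site_pl
                ]
                for site_pl in self.placements
            ],
            "E_self": [list(map(float, e)) for e in self.E_self],
            "E_pair": {
                f"{i},{j}": [[float(v) for v in row] for row in m]
                for (i, j), m in self.E_pair.items()
            },
        }
        return json.dumps(payload)


def compute_energy_matrix(
    region: DesignRegion,
    alphabet: Iterable[str],
    library: Mapping[str, tuple] | None = None,
    options: EnergyOptions | None = None,
    expansion: Sequence[float] = (),
    library_id: str = DEFAULT_LIBRARY,
) -> EnergyMatrix:
    """Compile the design region into template/self/pair energies.

    ``alphabet`` is a set of 1-letter residue types allowed at every design
    site; placements are enumerated in alphabetical residue order, library
    order within a residue.  Pair energies are symmetric by construction and
    same-site placements are never paired.
    """
    options = options or EnergyOptions()
    library = library or load_rotamer_library(library_id)
    alphabet = sorted(set(alphabet))
    if not alphabet:
        raise EnergyError("alphabet must be nonempty")

    placements: list[list[RotamerPlacement]] = []
    for site in region.design_sites:
        site_pl: list[RotamerPlacement] = []
        for res in alphabet:
            site_pl.extend(
                enumerate_placements(
                    library,
                    (site.chain_id, site.residue_number),
                    site.frame,
                    res,
                    expansion=expansion,
                )
            )
        if not site_pl:
            raise EnergyError(
                f"no placements possible at site {site.chain_id}/{site.residue_number}"
            )
        placements.append(site_pl)

    template = list(region.template_atoms)
    E_template = _self_energy(template, options)

    t_coords = np.array([a.coord for a in template]) if template else np.zeros((0, 3))
    if template:
        t_sig, t_eps = _params_arrays(template)

    E_self: list[np.ndarray] = []
    for site_pl in placements:
        e_site = np.zeros(len(site_pl))
        for k, p in enumerate(site_pl):
            if not template:
                continue
            atoms = list(p.atoms)
            c = np.array([a.coord for a in atoms])
            s, e = _params_arrays(atoms)
            m = _lj_matrix(c, s, e, t_coords, t_sig, t_eps, options)
            m[_exclusion_mask(atoms, template)] = 0.0
            e_site[k] = m.sum()
        E_self.append(e_site)

    E_pair: dict[tuple[int, int], np.ndarray] = {}
    n_sites = len(placements)
    flat: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
    for site_pl in placements:
        atoms = [a for p in site_pl for a in p.atoms]
        counts = np.array([len(p.atoms) for p in site_pl])
        if atoms:
            coords = np.array([a.coord for a in atoms])
            sig, eps = _params_arrays(atoms)
        else:
            coords = np.zeros((0, 3))
            sig = eps = np.zeros(0)
        flat.append((coords, sig, eps, counts))
    for i in range(n_sites):
        ci, si, ei, ni = flat[i]
        starts_i = np.concatenate([[0], np.cumsum(ni)[:-1]])
        for j in range(i + 1, n_sites):
            cj, sj, ej, nj = flat[j]
            if ci.shape[0] == 0 or cj.shape[0] == 0:
                E_pair[(i, j)] = np.zeros((len(ni), len(nj)))
                continue
            starts_j = np.concatenate([[0], np.cumsum(nj)[:-1]])
            m = _lj_matrix(ci, si, ei, cj, sj, ej, options)
            # sum atom-pair terms into placement-pair blocks
            m = np.add.reduceat(m, starts_i, axis=0)
            m = np.add.reduceat(m, starts_j, axis=1)
            E_pair[(i, j)] = m
    return EnergyMatrix(
        sites=list(region.design_sites),
        placements=placements,
        E_template=E_template,
        E_self=E_self,
        E_pair=E_pair,
        options=options,
        library_id=library_id,
    )


def total_energy(matrix: EnergyMatrix, assignment: Assignment) -> float:
    """E_template + sum of self energies + sum of pair energies (i < j)."""
    idx = assignment.indices
    if len(idx) != matrix.n_sites:
        raise EnergyError(
            f"assignment covers {len(idx)} sites, matrix has {matrix.n_sites}"
        )
    for i, ri in enumerate(idx):
        if not 0 <= ri < matrix.n_placements(i):
            raise EnergyError(f"placement index {ri} out of range at site {i}")
    e = matrix.E_template
    for i, ri in enumerate(idx):
        e += float(matrix.E_self[i][ri])
    for i in range(matrix.n_sites):
        for j in range(i + 1, matrix.n_sites):
            e += float(matrix.E_pair[(i, j)][idx[i], idx[j]])
    return e
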