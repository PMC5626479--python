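"""Multistate heterodimer design on a fixed backbone.

For a candidate sequence pair (X, Y) threaded onto a homodimeric interface,
four states are scored on the same backbone: the heterodimer X/Y, the two
homodimers X/X and Y/Y, and wild type.  Each state's energy is the global
minimum-energy conformation (GMEC) of the rotamer packing problem under the
state's sequence constraint; homodimers may adopt asymmetric rotamers.  The
design objective is the specificity gap

    gap = min(E_XX, E_YY) - E_XY

(positive when the heterodimer is preferred over both homodimers), subject
to a stability filter E_XY - E_WT <= delta_stab so that specificity is not
bought by ruining the heterodimer itself.  Homodimer failure is diagnosed
sterically: a "clash" when some cross-protomer atom pair in the homodimer
GMEC is strongly repulsive, a "void" when the homodimer is under-packed
relative to wild type without any single clashing pair.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .constants import AA3_TO_1
from .energetics import (
    Assignment,
    EnergyMatrix,
    EnergyOptions,
    _lj_matrix,
    _params_arrays,
    compute_energy_matrix,
    total_energy,
)
from .structures import Atom, DesignRegion

__all__ = [
    "DesignError",
    "SequenceAssignment",
    "StateSolution",
    "SpecificityScore",
    "ContactTerm",
    "FailureMode",
    "DesignCandidate",
    "DesignResult",
    "gmec",
    "score_states",
    "classify_failure_mode",
    "heterodimer_fraction",
    "enumerate_designs",
]

GAS_CONSTANT = 1.9872041e-3  # kcal/(mol K)


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceAssignment:
    """Residue types for protomers X and Y at the shared design positions."""

    positions: tuple[int, ...]
    x: tuple[str, ...]
    y: tuple[str, ...]

    def __post_init__(self):
        if not len(self.positions) == len(self.x) == len(self.y):
            raise DesignError("positions, x and y must have equal length")

    @property
    def x_str(self) -> str:
        return "".join(self.x)

    @property
    def y_str(self) -> str:
        return "".join(self.y)

    @classmethod
    def from_mutations(cls, region: DesignRegion, x_mutations, y_mutations):
        """Build X/Y sequences by applying mutation lists to the region's
        wild type (chain_x's residue identities at the design positions)."""
        positions = tuple(region.spec.design_positions)
        wt = {
            s.residue_number: AA3_TO_1[s.wt_name]
            for s in region.design_sites
            if s.chain_id == region.spec.chain_x
        }
        seqs = []
        for muts in (x_mutations, y_mutations):
            cur = dict(wt)
            for m in muts:
                if m.position not in cur:
                    raise DesignError(f"{m} is not at a design position {positions}")
                if cur[m.position] != m.wt:
                    raise DesignError(
                        f"{m}: design position {m.position} is {cur[m.position]}, "
                        f"not {m.wt}"
                    )
                cur[m.position] = m.mut
            seqs.append(tuple(cur[p] for p in positions))
        return cls(positions=positions, x=seqs[0], y=seqs[1])


@dataclass(frozen=True)
class ContactTerm:
    """One cross-protomer atom-pair LJ term, for clash/void diagnostics."""

    atom_a: tuple[str, int, str]  # (chain, residue_number, atom name)
    atom_b: tuple[str, int, str]
    distance: float
    energy: float


@dataclass
class StateSolution:
    """GMEC packing of one dimeric state."""

    state_label: str
    assignment: Assignment
    energy: float
    per_contact: list[ContactTerm] | None = None
    placed_atoms: tuple[Atom, ...] | None = None


@dataclass
class SpecificityScore:
    """Per-state best energies and the derived specificity gap."""

    E_XY: float
    E_XX: float
    E_YY: float
    E_WT: float
    solutions: dict[str, StateSolution] | None = None

    @property
    def gap(self) -> float:
        return min(self.E_XX, self.E_YY) - self.E_XY

    @property
    def stability(self) -> float:
        return self.E_XY - self.E_WT


@dataclass
class FailureMode:
    mode: str  # "clash" | "void" | "none"
    deficit: float  # homodimer energy - WT energy
    contacts: list[ContactTerm]  # offending (repulsive) cross-protomer pairs


@dataclass
class DesignCandidate:
    seq_x: str
    seq_y: str
    score: SpecificityScore
    rank: int
    failure_mode_xx: str | None = None
    failure_mode_yy: str | None = None


# ---------------------------------------------------------------------------
# GMEC search


def _goldstein_prune(
    matrix: EnergyMatrix,
    allowed: list[np.ndarray],
    partner_allowed: Mapping[int, np.ndarray] | None = None,
) -> list[np.ndarray]:
    """Iterated Goldstein singles elimination.

    ``allowed[i]`` are the candidate placement indices at site i.  If
    ``partner_allowed`` maps a site to a wider index set, minima over that
    site use the wider set — this keeps pruning sound when the rotamers of a
    partner chain are not yet fixed (multistate enumeration).
    """
    allowed = [np.asarray(a, dtype=int) for a in allowed]
    n = matrix.n_sites
    changed = True
    while changed:
        changed = False
        for i in range(n):
            cand = allowed[i]
            if len(cand) <= 1:
                continue
            self_i = matrix.E_self[i][cand]
            # D[r, r'] = sum_j min_s (pair(i,r,j,s) - pair(i,r',j,s))
            D = self_i[:, None] - self_i[None, :]
            for j in range(n):
                if j == i:
                    continue
                js = (partner_allowed or {}).get(j, allowed[j])
                if i < j:
                    block = matrix.E_pair[(i, j)][np.ix_(cand, js)]
                else:
                    block = matrix.E_pair[(j, i)][np.ix_(js, cand)].T
                D += (block[:, None, :] - block[None, :, :]).min(axis=2)
            prunable = (D > 1e-9).any(axis=1)
            if prunable.any():
                allowed[i] = cand[~prunable]
                changed = True
    return allowed


def _exhaustive_min(
    matrix: EnergyMatrix, allowed: list[np.ndarray]
) -> tuple[tuple[int, ...], float]:
    """Brute-force minimum over the product of allowed placement sets.

    Enumeration is lexicographic in site order, so argmin ties resolve to
    the lexicographically smallest placement-index vector.
    """
    sizes = [len(a) for a in allowed]
    n = matrix.n_sites
    shape = tuple(sizes)
    E = np.full(shape, matrix.E_template)
    for i in range(n):
        sh = [1] * n
        sh[i] = sizes[i]
        E = E + matrix.E_self[i][allowed[i]].reshape(sh)
    for i in range(n):
        for j in range(i + 1, n):
            block = matrix.E_pair[(i, j)][np.ix_(allowed[i], allowed[j])]
            sh = [1] * n
            sh[i], sh[j] = sizes[i], sizes[j]
            E = E + block.reshape(sh)
    flat = int(np.argmin(E))
    local = np.unravel_index(flat, shape)
    idx = tuple(int(allowed[i][local[i]]) for i in range(n))
    return idx, float(E[local])


def gmec(
    matrix: EnergyMatrix,
    sequence_constraint: Sequence[str],
    exhaustive_bound: int = 300_000,
    hard_bound: int = 3_000_000,
    state_label: str = "",
) -> StateSolution:
    """Global minimum-energy rotamer packing under a fixed sequence.

    Exhaustive enumeration when the conformation space is small; otherwise
    Goldstein singles dead-end elimination followed by exhaustive search
    over the survivors.  Ties break lexicographically by placement index.
    """
    if len(sequence_constraint) != matrix.n_sites:
        raise DesignError(
            f"constraint names {len(sequence_constraint)} sites, "
            f"matrix has {matrix.n_sites}"
        )
    if matrix.n_sites == 0:
        return StateSolution(state_label, Assignment(()), matrix.E_template)
    allowed = []
    for i, res in enumerate(sequence_constraint):
        a = matrix.allowed(i, res)
        if len(a) == 0:
            raise DesignError(
                f"no placements of residue {res!r} at site {i} "
                f"({matrix.sites[i].chain_id}/{matrix.sites[i].residue_number})"
            )
        allowed.append(a)
    space = math.prod(len(a) for a in allowed)
    if space > exhaustive_bound:
        allowed = _goldstein_prune(matrix, allowed)
        space = math.prod(len(a) for a in allowed)
        if space > hard_bound:
            raise DesignError(
                f"{space} conformations survive dead-end elimination "
                "(above the hard bound); reduce the chi expansion or the alphabet"
            )
    idx, energy = _exhaustive_min(matrix, allowed)
    return StateSolution(state_label, Assignment(idx), energy)


# ---------------------------------------------------------------------------
# State scoring


def _half_indices(region: DesignRegion) -> tuple[list[int], list[int]]:
    cx = region.spec.chain_x
    xs = [i for i, s in enumerate(region.design_sites) if s.chain_id == cx]
    ys = [i for i, s in enumerate(region.design_sites) if s.chain_id != cx]
    return xs, ys


def _state_constraint(
    region: DesignRegion, seq_pair: SequenceAssignment, on_x: Sequence[str], on_y: Sequence[str]
) -> list[str]:
    by_pos_x = dict(zip(seq_pair.positions, on_x))
    by_pos_y = dict(zip(seq_pair.positions, on_y))
    out = []
    cx = region.spec.chain_x
    for s in region.design_sites:
        table = by_pos_x if s.chain_id == cx else by_pos_y
        out.append(table[s.residue_number])
    return out


def _wt_constraint(region: DesignRegion) -> list[str]:
    return [AA3_TO_1[s.wt_name] for s in region.design_sites]


def cross_protomer_contacts(
    region: DesignRegion,
    matrix: EnergyMatrix,
    assignment: Assignment,
    options: EnergyOptions,
    energy_floor: float = 0.01,
) -> list[ContactTerm]:
    """Cross-protomer atom-pair LJ terms of an assembled state.

    Only pairs involving at least one designed side-chain atom are reported
    (template-template terms are identical in every state); pairs with
    |energy| below ``energy_floor`` are dropped.  Sorted by descending energy
    so clashes come first.
    """
    cx = region.spec.chain_x
    sides: dict[bool, list[tuple[Atom, bool]]] = {True: [], False: []}
    for a in region.template_atoms:
        sides[a.chain_id == cx].append((a, False))
    for i, ri in enumerate(assignment.indices):
        for a in matrix.placements[i][ri].atoms:
            sides[a.chain_id == cx].append((a, True))
    atoms_x = [a for a, _ in sides[True]]
    atoms_y = [a for a, _ in sides[False]]
    if not atoms_x or not atoms_y:
        return []
    design_x = np.array([d for _, d in sides[True]])
    design_y = np.array([d for _, d in sides[False]])
    coords_x = np.array([a.coord for a in atoms_x])
    coords_y = np.array([a.coord for a in atoms_y])
    sx, ex = _params_arrays(atoms_x)
    sy, ey = _params_arrays(atoms_y)
    e = _lj_matrix(coords_x, sx, ex, coords_y, sy, ey, options)
    e[~(design_x[:, None] | design_y[None, :])] = 0.0
    out: list[ContactTerm] = []
    ii, jj = np.nonzero(np.abs(e) >= energy_floor)
    for i, j in zip(ii, jj):
        a, b = atoms_x[i], atoms_y[j]
        out.append(
            ContactTerm(
                atom_a=(a.chain_id, a.residue_number, a.name),
                atom_b=(b.chain_id, b.residue_number, b.name),
                distance=float(np.linalg.norm(a.coord - b.coord)),
                energy=float(e[i, j]),
            )
        )
    out.sort(key=lambda t: (-t.energy, t.atom_a, t.atom_b))
    return out


def score_states(
    region: DesignRegion,
    seq_pair: SequenceAssignment,
    library=None,
    options: EnergyOptions | None = None,
    matrix: EnergyMatrix | None = None,
    expansion: Sequence[float] = (),
) -> SpecificityScore:
    """Score the four dimeric states of a sequence pair on one backbone.

    The heterodimer is evaluated in both protomer-to-chain orientations and
    takes the better one (they are the same complex), which makes the score
    exactly invariant under relabeling X <-> Y.
    """
    options = options or EnergyOptions()
    if tuple(seq_pair.positions) != tuple(region.spec.design_positions):
        raise DesignError("sequence pair positions do not match the design region")
    wt = _wt_constraint(region)
    if matrix is None:
        alphabet = set(seq_pair.x) | set(seq_pair.y) | set(wt)
        matrix = compute_energy_matrix(
            region, alphabet, library=library, options=options, expansion=expansion
        )

    def solve(label, on_x, on_y):
        sol = gmec(matrix, _state_constraint(region, seq_pair, on_x, on_y), state_label=label)
        sol.per_contact = cross_protomer_contacts(region, matrix, sol.assignment, options)
        sol.placed_atoms = tuple(
            a
            for i, ri in enumerate(sol.assignment.indices)
            for a in matrix.placements[i][ri].atoms
        )
        return sol

    xy1 = solve("XY", seq_pair.x, seq_pair.y)
    xy2 = solve("XY", seq_pair.y, seq_pair.x)
    xy = xy1 if xy1.energy <= xy2.energy else xy2
    xx = solve("XX", seq_pair.x, seq_pair.x)
    yy = solve("YY", seq_pair.y, seq_pair.y)
    wt_sol = solve("WT", tuple(wt[: len(seq_pair.positions)]), tuple(wt[len(seq_pair.positions):]))
    return SpecificityScore(
        E_XY=xy.energy,
        E_XX=xx.energy,
        E_YY=yy.energy,
        E_WT=wt_sol.energy,
        solutions={"XY": xy, "XX": xx, "YY": yy, "WT": wt_sol},
    )


def assemble_state(region: DesignRegion, solution: StateSolution):
    """Assemble template atoms + packed side chains into a writable Structure."""
    from .structures import Structure

    if solution.placed_atoms is None:
        return None
    atoms = list(region.template_atoms) + list(solution.placed_atoms)
    atoms.sort(
        key=lambda a: (a.chain_id, a.residue_number, 0 if a.is_backbone else 1, a.name)
    )
    return Structure(atoms=atoms)


def classify_failure_mode(
    homodimer: StateSolution,
    wt: StateSolution,
    options: EnergyOptions | None = None,
) -> FailureMode:
    """Diagnose why a designed homodimer fails: clash, void, or neither.

    "clash": some cross-protomer atom pair in the homodimer GMEC is repulsive
    beyond ``clash_cut``.  "void": no such pair, but the state is under-packed
    by at least ``void_cut`` relative to wild type.
    """
    options = options or EnergyOptions()
    if homodimer.per_contact is None:
        raise DesignError("homodimer solution carries no contact report")
    offenders = [t for t in homodimer.per_contact if t.energy >= options.clash_cut]
    deficit = homodimer.energy - wt.energy
    if offenders:
        return FailureMode(mode="clash", deficit=deficit, contacts=offenders)
    if deficit >= options.void_cut:
        return FailureMode(mode="void", deficit=deficit, contacts=[])
    return FailureMode(mode="none", deficit=deficit, contacts=[])


def heterodimer_fraction(
    gap_xx: float, gap_yy: float, temperature: float = 303.0
) -> float:
    """Expected heterodimer fraction under equimolar mass-action mixing.

    With both protomers fully dimerized, the four equally likely pairings
    (XY, YX, XX, YY) are Boltzmann-reweighted by the homodimer gaps
    gap_ss = E_ss - E_XY, giving 2 / (2 + exp(-gap_XX/RT) + exp(-gap_YY/RT)).
    Monotone nondecreasing in each gap; 0.5 at (0, 0); -> 1 as both gaps grow.
    """
    if temperature <= 0:
        raise DesignError("temperature must be positive (K)")
    rt = GAS_CONSTANT * temperature
    return float(2.0 / (2.0 + np.exp(-gap_xx / rt) + np.exp(-gap_yy / rt)))


# ---------------------------------------------------------------------------
# Design enumeration


@dataclass
class DesignResult:
    """Outcome of a design run over sequence-pair space."""

    positions: tuple[int, ...]
    sequences: list[str]  # protomer sequences, lexicographic order
    E_WT: float
    candidates: list[DesignCandidate]
    n_positive_gap: int
    mode: str
    seed: int
    dimer_energy: np.ndarray | None = None  # G[x, y]: x on chain_x, y on chain_y

    def index(self, seq: str) -> int:
        try:
            return self.sequences.index(seq)
        except ValueError:
            raise DesignError(f"sequence {seq!r} not in the enumerated space")

    def pair_score(self, seq_x: str, seq_y: str) -> SpecificityScore:
        if self.dimer_energy is None:
            raise DesignError("full dimer-energy grid only available in exhaustive mode")
        i, j = self.index(seq_x), self.index(seq_y)
        g = self.dimer_energy
        e_xy = float(min(g[i, j], g[j, i]))
        return SpecificityScore(
            E_XY=e_xy, E_XX=float(g[i, i]), E_YY=float(g[j, j]), E_WT=self.E_WT
        )

    def is_positive(self, seq_x: str, seq_y: str) -> bool:
        return self.pair_score(seq_x, seq_y).gap > 0

    def to_rows(self) -> list[dict]:
        rows = []
        for c in self.candidates:
            rows.append(
                {
                    "sequence_X": c.seq_x,
                    "sequence_Y": c.seq_y,
                    "E_XY": c.score.E_XY,
                    "E_XX": c.score.E_XX,
                    "E_YY": c.score.E_YY,
                    "E_WT": c.score.E_WT,
                    "gap": c.score.gap,
                    "stability": c.score.stability,
                    "failure_mode_XX": c.failure_mode_xx or "",
                    "failure_mode_YY": c.failure_mode_yy or "",
                    "rank": c.rank,
                }
            )
        return rows


def _per_sequence_configs(
    matrix: EnergyMatrix,
    half_sites: list[int],
    other_sites: list[int],
    seqs: list[tuple[str, ...]],
    partner_allowed: dict[int, np.ndarray],
):
    """Surviving rotamer configurations and internal energies per sequence.

    For each protomer sequence, per-site candidates are pruned with
    Goldstein singles that stay sound against ANY partner-chain rotamer,
    then the surviving product space is enumerated with internal energy
    self + intra-chain pairs.
    """
    k = len(half_sites)
    cross = {
        (p, j): (
            matrix.E_pair[(site, j)] if site < j else matrix.E_pair[(j, site)].T
        )
        for p, site in enumerate(half_sites)
        for j in partner_allowed
    }
    cfg_idx_parts: list[np.ndarray] = []
    cfg_e_parts: list[np.ndarray] = []
    starts = [0]
    for seq in seqs:
        allowed = [matrix.allowed(site, seq[p]) for p, site in enumerate(half_sites)]
        if any(len(a) == 0 for a in allowed):
            raise DesignError(f"sequence {''.join(seq)} has an empty placement set")
        pruned = _restricted_goldstein(matrix, half_sites, allowed, partner_allowed)
        sizes = [len(a) for a in pruned]
        ncfg = math.prod(sizes)
        grids = np.meshgrid(*pruned, indexing="ij")
        idx = np.stack([g.ravel() for g in grids], axis=1)  # (ncfg, k)
        e = np.zeros(ncfg)
        for p, site in enumerate(half_sites):
            e += matrix.E_self[site][idx[:, p]]
        for p in range(k):
            for q in range(p + 1, k):
                i, j = half_sites[p], half_sites[q]
                block = matrix.E_pair[(i, j)] if i < j else matrix.E_pair[(j, i)].T
                e += block[idx[:, p], idx[:, q]]
        # config-level domination: drop configs that can never beat another
        # config of the same sequence, whatever the partner chain does
        if len(e) > 1:
            Vs = []
            for j, js in partner_allowed.items():
                V = np.zeros((len(e), len(js)))
                for p in range(k):
                    V += cross[(p, j)][np.ix_(idx[:, p], js)]
                Vs.append(V)
            # cheap interval filter: lower bound vs best upper bound
            lb = e + sum(V.min(axis=1) for V in Vs)
            ub = e + sum(V.max(axis=1) for V in Vs)
            keep = lb <= ub.min() + 1e-9
            idx, e = idx[keep], e[keep]
            Vs = [V[keep] for V in Vs]
            if 1 < len(e) <= 256:
                # exact pairwise Goldstein on the survivors
                D = e[:, None] - e[None, :]
                for V in Vs:
                    D += (V[:, None, :] - V[None, :, :]).min(axis=2)
                keep = ~(D > 1e-9).any(axis=1)
                idx, e = idx[keep], e[keep]
        cfg_idx_parts.append(idx)
        cfg_e_parts.append(e)
        starts.append(starts[-1] + len(e))
    return (
        np.concatenate(cfg_idx_parts, axis=0),
        np.concatenate(cfg_e_parts),
        np.array(starts),
    )


def _restricted_goldstein(
    matrix: EnergyMatrix,
    half_sites: list[int],
    allowed: list[np.ndarray],
    partner_allowed: dict[int, np.ndarray],
) -> list[np.ndarray]:
    """Goldstein singles on a chain half; partner-chain minima range over the
    union of all partner candidates, which keeps elimination exact for every
    partner sequence simultaneously."""
    k = len(half_sites)
    allowed = [np.asarray(a, int) for a in allowed]
    changed = True
    while changed:
        changed = False
        for p in range(k):
            cand = allowed[p]
            if len(cand) <= 1:
                continue
            i = half_sites[p]
            D = matrix.E_self[i][cand][:, None] - matrix.E_self[i][cand][None, :]
            for q in range(k):
                if q == p:
                    continue
                j = half_sites[q]
                js = allowed[q]
                block = (
                    matrix.E_pair[(i, j)][np.ix_(cand, js)]
                    if i < j
                    else matrix.E_pair[(j, i)][np.ix_(js, cand)].T
                )
                D += (block[:, None, :] - block[None, :, :]).min(axis=2)
            for j, js in partner_allowed.items():
                block = (
                    matrix.E_pair[(i, j)][np.ix_(cand, js)]
                    if i < j
                    else matrix.E_pair[(j, i)][np.ix_(js, cand)].T
                )
                D += (block[:, None, :] - block[None, :, :]).min(axis=2)
            prunable = (D > 1e-9).any(axis=1)
            if prunable.any():
                allowed[p] = cand[~prunable]
                changed = True
    return allowed


def _pair_grid(
    matrix: EnergyMatrix,
    xs: list[int],
    ys: list[int],
    seqs: list[tuple[str, ...]],
    letters_per_pos: list[list[str]],
    chunk_target: int = 1280,
) -> np.ndarray:
    """Exact dimer energies G[x, y] for every ordered sequence pair.

    G[x, y] = E_template + min over rotamer configs of (internal_x +
    internal_y + cross interaction); the minimization is exact because the
    per-sequence config sets were pruned with partner-agnostic DEE only.
    """
    k = len(xs)
    union_allowed_x = {
        site: np.sort(np.concatenate([matrix.allowed(site, l) for l in letters_per_pos[p]]))
        for p, site in enumerate(xs)
    }
    union_allowed_y = {
        site: np.sort(np.concatenate([matrix.allowed(site, l) for l in letters_per_pos[p]]))
        for p, site in enumerate(ys)
    }
    IA, EA, startsA = _per_sequence_configs(matrix, xs, ys, seqs, union_allowed_y)
    IB, EB, startsB = _per_sequence_configs(matrix, ys, xs, seqs, union_allowed_x)
    S = len(seqs)
    P = {
        (p, q): (matrix.E_pair[(xs[p], ys[q])] if xs[p] < ys[q] else matrix.E_pair[(ys[q], xs[p])].T)
        for p in range(k)
        for q in range(k)
    }

    def chunks(starts):
        lo = 0
        while lo < S:
            hi = lo + 1
            while hi < S and starts[hi + 1] - starts[lo] <= chunk_target:
                hi += 1
            yield lo, hi
            lo = hi

    G = np.empty((S, S))
    for a_lo, a_hi in chunks(startsA):
        arows = slice(startsA[a_lo], startsA[a_hi])
        ia = IA[arows]
        ea = EA[arows]
        a_starts = startsA[a_lo:a_hi] - startsA[a_lo]
        # for each partner site q, pre-sum this A-chunk's interactions with
        # every placement at q, so each B-chunk needs one gather per site
        RQ = []
        for q in range(k):
            acc = P[(0, q)][ia[:, 0], :].copy()
            for p in range(1, k):
                acc += P[(p, q)][ia[:, p], :]
            RQ.append(acc)
        for b_lo, b_hi in chunks(startsB):
            brows = slice(startsB[b_lo], startsB[b_hi])
            ib = IB[brows]
            X = ea[:, None] + EB[brows][None, :]
            for q in range(k):
                X += RQ[q][:, ib[:, q]]
            R1 = np.minimum.reduceat(X, a_starts, axis=0)
            b_starts = startsB[b_lo:b_hi] - startsB[b_lo]
            G[a_lo:a_hi, b_lo:b_hi] = np.minimum.reduceat(R1, b_starts, axis=1)
    return G + matrix.E_template


def enumerate_designs(
    region: DesignRegion,
    alphabet: Iterable[str],
    constraints: Mapping[int, Iterable[str]] | None = None,
    options: EnergyOptions | None = None,
    library=None,
    mode: str = "exhaustive",
    seed: int = 0,
    delta_stab: float = 2.0,
    budget: int = 20_000_000,
    diagnose_top: int = 20,
    max_candidates: int = 1000,
    expansion: Sequence[float] = (),
    n_restarts: int = 8,
) -> DesignResult:
    """Rank sequence-pair space by specificity gap.

    Exhaustive mode scores every (X, Y) pair up to relabeling symmetry
    (exactly); heuristic mode runs seeded greedy hill-climbing with restarts.
    Candidates violating the stability filter (E_XY - E_WT > delta_stab) are
    excluded; the rest are ranked by descending gap, ties alphabetical.
    Deterministic given the seed; exhaustive output is independent of the
    input ordering of the alphabet.
    """
    options = options or EnergyOptions()
    alphabet = sorted(set(alphabet))
    positions = tuple(region.spec.design_positions)
    constraints = constraints or {}
    letters_per_pos = [
        sorted(set(constraints.get(p, alphabet)) & set(alphabet) or set(alphabet))
        if p in constraints
        else list(alphabet)
        for p in positions
    ]
    seqs = [tuple(s) for s in itertools.product(*letters_per_pos)]
    S = len(seqs)
    n_pairs = S * (S + 1) // 2
    if mode == "exhaustive" and n_pairs > budget:
        raise DesignError(
            f"{n_pairs} sequence pairs exceed the exhaustive budget {budget}; "
            "use heuristic mode"
        )

    wt = _wt_constraint(region)
    matrix_alphabet = set(alphabet) | set(wt)
    matrix = compute_energy_matrix(
        region, matrix_alphabet, library=library, options=options, expansion=expansion
    )
    xs, ys = _half_indices(region)
    wt_sol = gmec(matrix, wt, state_label="WT")
    wt_sol.per_contact = cross_protomer_contacts(region, matrix, wt_sol.assignment, options)
    E_WT = wt_sol.energy

    if mode == "exhaustive":
        G = _pair_grid(matrix, xs, ys, seqs, letters_per_pos)
        het = np.minimum(G, G.T)
        homo = np.diag(G)
        gap = np.minimum.outer(homo, homo) - het
        stability = het - E_WT
        iu, ju = np.triu_indices(S)
        ok = stability[iu, ju] <= delta_stab
        iu, ju = iu[ok], ju[ok]
        n_positive = int((gap[iu, ju] > 0).sum())
        order = np.lexsort((ju, iu, -gap[iu, ju]))
        top = order[:max_candidates]
        candidates = []
        for rank, t in enumerate(top, start=1):
            i, j = int(iu[t]), int(ju[t])
            sc = SpecificityScore(
                E_XY=float(het[i, j]),
                E_XX=float(G[i, i]),
                E_YY=float(G[j, j]),
                E_WT=E_WT,
            )
            candidates.append(
                DesignCandidate(
                    seq_x="".join(seqs[i]), seq_y="".join(seqs[j]), score=sc, rank=rank
                )
            )
        result = DesignResult(
            positions=positions,
            sequences=["".join(s) for s in seqs],
            E_WT=E_WT,
            candidates=candidates,
            n_positive_gap=n_positive,
            mode=mode,
            seed=seed,
            dimer_energy=G,
        )
    elif mode == "heuristic":
        result = _heuristic_search(
            region, matrix, seqs, letters_per_pos, E_WT, options,
            seed=seed, delta_stab=delta_stab, n_restarts=n_restarts,
            max_candidates=max_candidates, positions=positions,
        )
    else:
        raise DesignError(f"unknown mode {mode!r}")

    _diagnose_candidates(region, matrix, result, wt_sol, options, diagnose_top)
    return result


def _diagnose_candidates(region, matrix, result, wt_sol, options, diagnose_top):
    positions = result.positions
    for c in result.candidates[:diagnose_top]:
        for attr, seq in (("failure_mode_xx", c.seq_x), ("failure_mode_yy", c.seq_y)):
            pair = SequenceAssignment(positions, tuple(seq), tuple(seq))
            sol = gmec(matrix, _state_constraint(region, pair, tuple(seq), tuple(seq)))
            sol.per_contact = cross_protomer_contacts(region, matrix, sol.assignment, options)
            setattr(c, attr, classify_failure_mode(sol, wt_sol, options).mode)


def _heuristic_search(
    region, matrix, seqs, letters_per_pos, E_WT, options,
    seed, delta_stab, n_restarts, max_candidates, positions,
):
    """Greedy single-substitution hill climbing on the gap, seeded restarts."""
    rng = np.random.default_rng(seed)
    homo_cache: dict[tuple[str, ...], float] = {}
    het_cache: dict[tuple, float] = {}

    def homo(seq):
        if seq not in homo_cache:
            pair = SequenceAssignment(positions, seq, seq)
            homo_cache[seq] = gmec(
                matrix, _state_constraint(region, pair, seq, seq)
            ).energy
        return homo_cache[seq]

    def het(x, y):
        key = (min(x, y), max(x, y))
        if key not in het_cache:
            pair = SequenceAssignment(positions, x, y)
            e1 = gmec(matrix, _state_constraint(region, pair, x, y)).energy
            e2 = gmec(matrix, _state_constraint(region, pair, y, x)).energy
            het_cache[key] = min(e1, e2)
        return het_cache[key]

    def objective(x, y):
        e_xy = het(x, y)
        if e_xy - E_WT > delta_stab:
            return -np.inf, e_xy
        return min(homo(x), homo(y)) - e_xy, e_xy

    k = len(positions)
    seen: dict[tuple, SpecificityScore] = {}
    for _ in range(n_restarts):
        x = tuple(l[rng.integers(len(l))] for l in letters_per_pos)
        y = tuple(l[rng.integers(len(l))] for l in letters_per_pos)
        cur, _ = objective(x, y)
        improved = True
        while improved:
            improved = False
            best_move, best_val = None, cur
            for which in (0, 1):
                base = x if which == 0 else y
                for p in range(k):
                    for letter in letters_per_pos[p]:
                        if letter == base[p]:
                            continue
                        cand = base[:p] + (letter,) + base[p + 1 :]
                        nx, ny = (cand, y) if which == 0 else (x, cand)
                        val, _ = objective(nx, ny)
                        if val > best_val + 1e-12:
                            best_val, best_move = val, (nx, ny)
            if best_move is not None:
                x, y = best_move
                cur = best_val
                improved = True
        if np.isfinite(cur):
            key = (min(x, y), max(x, y))
            seen[key] = SpecificityScore(
                E_XY=het(x, y), E_XX=homo(key[0]), E_YY=homo(key[1]), E_WT=E_WT
            )
    ranked = sorted(
        seen.items(), key=lambda kv: (-kv[1].gap, kv[0][0], kv[0][1])
    )[:max_candidates]
    candidates = [
        DesignCandidate(
            seq_x="".join(x), seq_y="".join(y), score=sc, rank=r
        )
        for r, ((x, y), sc) in enumerate(ranked, start=1)
    ]
    n_positive = sum(1 for _, sc in ranked if sc.gap > 0)
    return DesignResult(
        positions=positions,
        sequences=["".join(s) for s in seqs],
        E_WT=E_WT,
        candidates=candidates,
        n_positive_gap=n_positive,
        mode="heuristic",
        seed=seed,
        dimer_energy=None,
    )
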