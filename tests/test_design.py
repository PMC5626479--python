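import itertools
import math

import numpy as np
import pytest

from bumphole.energetics import (
    Assignment,
    EnergyMatrix,
    EnergyOptions,
    compute_energy_matrix,
    total_energy,
)
from bumphole.design import (
    DesignError,
    GAS_CONSTANT,
    SequenceAssignment,
    classify_failure_mode,
    enumerate_designs,
    gmec,
    heterodimer_fraction,
    score_states,
    _goldstein_prune,
    _state_constraint,
)
from bumphole.structures import InterfaceSpec, extract_design_region, make_synthetic_bundle


def _random_matrix(rng, n_sites, n_rot, residue="L"):
    """Seeded random pairwise matrix over synthetic placements of one type."""

    class _FakeRot:
        def __init__(self):
            self.residue_type = residue
            self.chi = ()

    class _FakePlacement:
        def __init__(self):
            self.rotamer = _FakeRot()
            self.atoms = ()

    class _FakeSite:
        chain_id = "A"
        residue_number = 1
        wt_name = "LEU"

    placements = [[_FakePlacement() for _ in range(n_rot)] for _ in range(n_sites)]
    E_self = [rng.normal(0, 2, n_rot) for _ in range(n_sites)]
    E_pair = {
        (i, j): rng.normal(0, 1, (n_rot, n_rot))
        for i in range(n_sites)
        for j in range(i + 1, n_sites)
    }
    return EnergyMatrix(
        sites=[_FakeSite() for _ in range(n_sites)],
        placements=placements,
        E_template=float(rng.normal()),
        E_self=E_self,
        E_pair=E_pair,
        options=EnergyOptions(),
    )


def _brute_force(matrix, constraint):
    spaces = [list(matrix.allowed(i, r)) for i, r in enumerate(constraint)]
    best = None
    for idx in itertools.product(*spaces):
        e = total_energy(matrix, Assignment(tuple(idx)))
        if best is None or e < best[1] - 1e-15:
            best = (idx, e)
    return best


class TestGmec:
    def test_single_rotamer_forced(self):
        rng = np.random.default_rng(0)
        m = _random_matrix(rng, 1, 1)
        sol = gmec(m, ["L"])
        assert sol.assignment.indices == (0,)
        assert sol.energy == pytest.approx(m.E_template + m.E_self[0][0])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_3x4(self, seed):
        rng = np.random.default_rng(seed)
        m = _random_matrix(rng, 3, 4)
        sol = gmec(m, ["L"] * 3)
        _, best = _brute_force(m, ["L"] * 3)
        assert sol.energy == pytest.approx(best, abs=1e-12)

    @pytest.mark.parametrize("seed", range(100))
    def test_dee_path_equals_exhaustive_on_random_instances(self, seed):
        """DEE-pruned search agrees exactly with brute force on seeded random
        matrices up to 4 sites x 6 rotamers."""
        rng = np.random.default_rng(1000 + seed)
        n_sites = int(rng.integers(2, 5))
        n_rot = int(rng.integers(2, 7))
        m = _random_matrix(rng, n_sites, n_rot)
        constraint = ["L"] * n_sites
        # force the DEE path by setting the exhaustive bound to zero
        sol_dee = gmec(m, constraint, exhaustive_bound=0)
        _, best = _brute_force(m, constraint)
        assert sol_dee.energy == pytest.approx(best, abs=1e-12)

    def test_dee_on_fixture_matrix(self, small_region):
        m = compute_energy_matrix(small_region, {"A", "L", "V"})
        constraint = ["L"] * m.n_sites
        assert gmec(m, constraint, exhaustive_bound=0).energy == pytest.approx(
            gmec(m, constraint).energy, abs=1e-12
        )

    def test_goldstein_never_prunes_the_optimum(self):
        for seed in range(30):
            rng = np.random.default_rng(2000 + seed)
            m = _random_matrix(rng, 3, 5)
            allowed = [m.allowed(i, "L") for i in range(3)]
            pruned = _goldstein_prune(m, allowed)
            best_idx, _ = _brute_force(m, ["L"] * 3)
            for i, ri in enumerate(best_idx):
                assert ri in pruned[i]

    def test_hard_bound_error_mentions_expansion(self):
        rng = np.random.default_rng(5)
        # degenerate equal energies defeat pruning
        m = _random_matrix(rng, 4, 6)
        for i in range(4):
            m.E_self[i][:] = 0.0
        for key in m.E_pair:
            m.E_pair[key][:, :] = 0.0
        with pytest.raises(DesignError, match="expansion|alphabet"):
            gmec(m, ["L"] * 4, exhaustive_bound=0, hard_bound=1)


class TestScoreStates:
    def test_identical_sequences_null(self, interface_region):
        positions = interface_region.spec.design_positions
        seq = ("L", "A", "L", "L")
        sc = score_states(interface_region, SequenceAssignment(positions, seq, seq))
        assert sc.gap == 0.0
        assert sc.E_XX == sc.E_YY == sc.E_XY
        assert sc.stability == pytest.approx(0.0, abs=1e-9)

    def test_toy_energies_arithmetic(self):
        sc_vals = dict(E_XY=-10.0, E_XX=-8.0, E_YY=-7.0, E_WT=-9.0)
        from bumphole.design import SpecificityScore

        sc = SpecificityScore(**sc_vals)
        assert sc.gap == pytest.approx(2.0)
        assert sc.stability == pytest.approx(-1.0)

    def test_relabeling_symmetry(self, interface_region):
        positions = interface_region.spec.design_positions
        x = ("L", "A", "A", "V")
        y = ("I", "W", "L", "I")
        sc1 = score_states(interface_region, SequenceAssignment(positions, x, y))
        sc2 = score_states(interface_region, SequenceAssignment(positions, y, x))
        assert sc1.E_XY == pytest.approx(sc2.E_XY, abs=1e-9)
        assert sc1.E_XX == pytest.approx(sc2.E_YY, abs=1e-9)
        assert sc1.E_YY == pytest.approx(sc2.E_XX, abs=1e-9)
        assert sc1.gap == pytest.approx(sc2.gap, abs=1e-9)

    def test_state_energies_match_direct_gmec(self, interface_region):
        positions = interface_region.spec.design_positions
        x = ("L", "A", "A", "V")
        y = ("I", "W", "L", "I")
        pair = SequenceAssignment(positions, x, y)
        sc = score_states(interface_region, pair)
        alphabet = set(x) | set(y) | {"L", "A"}
        m = compute_energy_matrix(interface_region, alphabet)
        e_xx = gmec(m, _state_constraint(interface_region, pair, x, x)).energy
        assert sc.E_XX == pytest.approx(e_xx, abs=1e-9)


class TestFailureModes:
    def test_wt_vs_itself_is_none(self, interface_region):
        positions = interface_region.spec.design_positions
        seq = ("L", "A", "L", "L")
        sc = score_states(interface_region, SequenceAssignment(positions, seq, seq))
        fm = classify_failure_mode(sc.solutions["XX"], sc.solutions["WT"])
        assert fm.mode == "none"
        assert fm.deficit == pytest.approx(0.0, abs=1e-9)

    def test_bump_homodimer_clashes(self, interface_region):
        """A tryptophan bump threaded on both protomers produces a
        cross-protomer clash in the homodimer GMEC."""
        positions = interface_region.spec.design_positions
        y = ("I", "W", "L", "I")
        sc = score_states(
            interface_region, SequenceAssignment(positions, ("L", "A", "L", "L"), y)
        )
        fm = classify_failure_mode(sc.solutions["YY"], sc.solutions["WT"])
        assert fm.mode == "clash"
        assert fm.contacts
        assert fm.contacts[0].energy >= EnergyOptions().clash_cut

    def test_hole_homodimer_voids(self, interface_region):
        """Carving the core (L->A, L->V holes) under-packs the homodimer
        without any single clashing pair: a void."""
        positions = interface_region.spec.design_positions
        x = ("L", "A", "A", "V")
        sc = score_states(
            interface_region, SequenceAssignment(positions, x, ("L", "A", "L", "L"))
        )
        fm = classify_failure_mode(sc.solutions["XX"], sc.solutions["WT"])
        assert fm.mode == "void"
        assert fm.deficit >= EnergyOptions().void_cut


class TestFraction:
    def test_zero_gaps_give_half(self):
        assert heterodimer_fraction(0.0, 0.0) == pytest.approx(0.5)

    def test_rt_ln2_closed_form(self):
        rt = GAS_CONSTANT * 303.0
        g = rt * math.log(2.0)
        assert heterodimer_fraction(g, g, temperature=303.0) == pytest.approx(2 / 3)

    def test_limit_is_one(self):
        assert heterodimer_fraction(1e6, 1e6) == pytest.approx(1.0)

    def test_monotone_and_bounded(self):
        gaps = np.linspace(-5, 5, 21)
        prev = 0.0
        for g in gaps:
            f = heterodimer_fraction(g, 1.0)
            assert 0.0 < f <= 1.0
            assert f >= prev - 1e-12
            prev = f

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(DesignError):
            heterodimer_fraction(0.0, 0.0, temperature=0.0)


@pytest.fixture(scope="module")
def small_design(small_region):
    return enumerate_designs(
        small_region, alphabet="AVLW", seed=0, max_candidates=50, diagnose_top=2
    )


class TestEnumerate:

    def test_wt_only_alphabet_single_null_candidate(self, small_region):
        res = enumerate_designs(small_region, alphabet="A", seed=0)
        assert len(res.candidates) == 1
        assert res.candidates[0].score.gap == pytest.approx(0.0)
        assert res.n_positive_gap == 0

    def test_grid_matches_per_pair_gmec_oracle(self, small_region, small_design):
        """Exhaustive-mode dimer energies equal a naive per-pair GMEC."""
        res = small_design
        m = compute_energy_matrix(small_region, set("AVLW"))
        letters = sorted("AVLW")
        seqs = [tuple(t) for t in itertools.product(letters, repeat=2)]
        positions = small_region.spec.design_positions
        rng = np.random.default_rng(0)
        picks = rng.integers(0, len(seqs), size=(20, 2))
        for i, j in picks:
            x, y = seqs[i], seqs[j]
            direct = gmec(
                m, _state_constraint(small_region, SequenceAssignment(positions, x, y), x, y)
            ).energy
            assert res.dimer_energy[i, j] == pytest.approx(direct, abs=1e-9)

    def test_top_gap_equals_brute_force_maximum(self, small_region, small_design):
        res = small_design
        G = res.dimer_energy
        het = np.minimum(G, G.T)
        homo = np.diag(G)
        gap = np.minimum.outer(homo, homo) - het
        stab = het - res.E_WT
        iu, ju = np.triu_indices(len(res.sequences))
        ok = stab[iu, ju] <= 2.0
        best = gap[iu, ju][ok].max()
        assert res.candidates[0].score.gap == pytest.approx(best, abs=1e-12)

    def test_alphabet_order_invariance(self, small_region, small_design):
        res2 = enumerate_designs(
            small_region, alphabet="WLVA", seed=0, max_candidates=50, diagnose_top=0
        )
        a = [(c.seq_x, c.seq_y, c.score.gap) for c in small_design.candidates]
        b = [(c.seq_x, c.seq_y, c.score.gap) for c in res2.candidates]
        assert a == b

    def test_diagonal_gap_exactly_zero(self, small_design):
        for s in small_design.sequences[:10]:
            assert small_design.pair_score(s, s).gap == 0.0

    def test_budget_error_suggests_heuristic(self, small_region):
        with pytest.raises(DesignError, match="heuristic"):
            enumerate_designs(small_region, alphabet="AVLW", budget=10)

    def test_heuristic_deterministic_given_seed(self, small_region):
        r1 = enumerate_designs(
            small_region, alphabet="AVLW", mode="heuristic", seed=11, diagnose_top=0
        )
        r2 = enumerate_designs(
            small_region, alphabet="AVLW", mode="heuristic", seed=11, diagnose_top=0
        )
        assert [(c.seq_x, c.seq_y) for c in r1.candidates] == [
            (c.seq_x, c.seq_y) for c in r2.candidates
        ]

    def test_heuristic_finds_candidates_within_exhaustive_space(self, small_region, small_design):
        r = enumerate_designs(
            small_region, alphabet="AVLW", mode="heuristic", seed=3, diagnose_top=0
        )
        for c in r.candidates:
            ref = small_design.pair_score(c.seq_x, c.seq_y)
            assert c.score.gap == pytest.approx(ref.gap, abs=1e-9)
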