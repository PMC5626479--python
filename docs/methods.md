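# Methods

## Scope and model

`bumphole` performs fixed-backbone, multistate side-chain design at a small
set of interface positions of a homodimeric protein–protein interface. The
backbone never moves; residue identity and side-chain conformation at the
design positions are the only degrees of freedom. The method has five
stages: (1) structure handling and mutation threading, (2) rotamer
enumeration and internal-coordinate side-chain construction, (3) compilation
of a pairwise van der Waals energy matrix, (4) GMEC packing per dimeric
state and specificity-gap ranking of sequence pairs, (5) steric diagnosis of
designed homodimer failure (clash vs void) and a mass-action interpretation
of the gaps.

## Energy function

The score is a united-heavy-atom 12-6 Lennard-Jones potential and nothing
else — no electrostatics, solvation, hydrogen bonding, or entropy terms.
The design objective here is steric complementarity (bumps and holes), and
every quantity consumed downstream (gap, stability, clash, void) is a
*difference* of packings on the same backbone, where non-steric terms
largely cancel. Parameters (`data/lj_params.tsv`) are OPLS-UA-like sigma and
epsilon values over nine united-atom classes; the mapping from
(residue, atom name) to class is `data/atom_classes.tsv`. Combining is
Lorentz–Berthelot. Three numerical guards, all exposed in `EnergyOptions`:

- `radius_scale` (default 0.9): combined sigmas are scaled down, the
  standard softening that compensates for discrete rotamers on a rigid
  backbone;
- `repulsion_cap` (default +10 kcal/mol per atom pair): caps each pair term
  so a single overlap cannot dominate a ranking and every stored energy is
  finite even at grossly clashing geometries;
- `cutoff` (default 8 Å): pair terms are zero at and beyond the cutoff.

Atom pairs within one residue at 1-2/1-3/1-4 bonded separation are never
scored (bond graphs include the ring-closure bonds of His/Phe/Tyr/Trp/Pro);
inter-residue pairs are always scored. Consequently absolute state energies
include a large constant from bonded inter-residue backbone contacts — this
is deliberate: the constant is identical across states of the same region
and cancels in every reported difference. Only differences are meaningful.

## Rotamers and side-chain construction

A compact backbone-independent rotamer library
(`data/rotamers_compact_v1.tsv`) ships canonical gauche−/gauche+/trans chi
combinations with approximate populations (1–5 rotamers per residue type,
weights renormalized at load). Side chains are built by sequential NeRF
placement from an ideal internal-coordinate table (`data/topology.tsv`):
CB is placed tetrahedrally off N/CA/C with the L-amino-acid improper
(torsion CB–CA–N–C = −122.5°), then each atom follows bond/angle/torsion
rows where torsions are chi labels (with offsets for branches, e.g. Leu CD2
at chi2+122°) or fixed ring values. Build-then-measure identity (recomputed
chi within 0.5° of the request) is asserted for every residue type and
rotamer in the test suite; ring closures land at ~1.4 Å bond lengths.
Optional ±chi1 sub-rotamer expansion exists but is off by default (cost
multiplies; the hydrophobic 4-position cores targeted here do not need it).
Proline and glycine are buildable but excluded from design alphabets by
default (their conformations are backbone-coupled, which a fixed-backbone
treatment cannot honor).

## The pairwise matrix and its contracts

For a design region (design sites on both protomers plus all non-design
atoms within `environment_cutoff` = 8 Å of any design-site CA/CB, and the
design-site backbones), the matrix stores E_template (template atoms with
themselves), E_self per placement (placement against the whole template)
and E_pair per placement pair at distinct sites. Two properties are load-
bearing and tested: E_pair symmetry under argument swap, and exact
reconstruction — for any complete assignment, the matrix total equals a
direct all-atom recomputation of the assembled model within 1e-6 kcal/mol.

## Search

`gmec` solves the packing under a per-site residue constraint: exhaustive
enumeration when the conformation count is below a bound (default 3×10⁵),
otherwise iterated Goldstein singles dead-end elimination followed by
exhaustive search over the survivors; ties break lexicographically by
placement index, so results are bit-reproducible. DEE-pruned and exhaustive
paths agree exactly on 100 seeded random instances in the suite.

`enumerate_designs` exhaustive mode scores *every* ordered sequence pair
over the alphabet exactly, via a config-grid formulation: per protomer
sequence, per-site candidates are pruned with Goldstein singles whose
partner-chain minima range over the union of all partner rotamers (sound
for every partner simultaneously), surviving rotamer configurations get
internal energies, and a blocked min-plus reduction over the cross-chain
interaction produces the full dimer-energy grid G[x, y]. The heterodimer
energy of a pair is min(G[x,y], G[y,x]) — the two protomer-to-chain
orientations are the same complex — which also makes relabeling symmetry
(swap X and Y) exact on asymmetric real backbones. Homodimer energies are
the grid diagonal; homodimers may adopt asymmetric rotamers (sequence
symmetry does not imply conformational symmetry). The grid is verified
against naive per-pair GMEC in the tests. Heuristic mode is seeded greedy
hill-climbing over single substitutions with restarts, for spaces beyond
the exhaustive budget; it is deterministic given the seed.

Ranking: candidates failing the stability filter E_XY − E_WT > δ_stab
(default +2 kcal/mol) are excluded; the rest sort by descending gap, ties
alphabetical. Clash/void diagnosis is computed for the top `diagnose_top`
(default 20) candidates — per-contact reports for millions of pairs would
be noise.

## Failure-mode diagnosis and the fraction model

For a homodimer GMEC, cross-protomer atom-pair terms involving at least one
designed side-chain atom are collected. "Clash": some pair ≥ `clash_cut`
(3.0 kcal/mol). "Void": no clashing pair but state energy exceeds wild type
by ≥ `void_cut` (1.0 kcal/mol). Otherwise "none". The expected heterodimer
fraction under equimolar, fully dimerized mass-action mixing is
2 / (2 + exp(−gap_XX/RT) + exp(−gap_YY/RT)) at temperature 303 K by
default — an interpretive summary, not a fitted binding model.

## Synthetic fixtures: what they emulate and what they do not

`make_synthetic_bundle` produces ideal α-helices (φ/ψ = −57/−47, 1.5 Å
rise, 100°/residue) as poly-alanine, antiparallel in alternation, axes
spaced as requested; for two helices the second is the exact C2 image of
the first. Note that facing CA atoms of two ideal helices with axes d apart
approach d − 2×2.3 Å (the CA ring radius), not d.

`make_synthetic_interface` is the stand-in for a homodimeric four-helix-
bundle interface: two protomer chains of two antiparallel helices each,
assembled with exact two-fold symmetry on a square of edge 10.5 Å. Design
positions are the four interior residues (two per helix) whose CB atoms
across both protomers form the tightest shared cluster — the synthetic
analogue of a hydrophobic cluster at a dimer interface. The axis spacing
was fixed once by a physical prior: the smallest half-Å spacing at which
the threaded Leu/Ala pseudo-wild-type core packs with no clashing pair and
the most favorable cross-interface energy. These are idealized geometric
coordinates, NOT experimental ones: passing tests on this fixture
demonstrate that the machinery (threading, packing, exact search, gap
ranking, clash/void classification) behaves correctly and that the
bump-hole logic emerges from the physics — they do not certify energies or
sequence choices on any real structure. Accordingly, the specific designed
sequences found on the fixture differ from the published H3 pair, whose
geometry is that of the nucleosome crystal structure; on the fixture, the
threaded analogues of those mutations still reproduce the qualitative
failure modes (bump homodimer → clash, hole homodimer → void).

## Problem sizes

The shipped analyses use the 5-letter hydrophobic alphabet A/V/I/L/W at
four positions (625 protomer sequences, 195 625 unordered pairs, all scored
exactly; ~15 s on one CPU). The 7-letter alphabet A/V/I/L/W/T/Q (2 401
sequences, ~2.9 M pairs) runs through the same exact engine in a few
minutes and is used for the structure-anchored reproduction when 1KX3 is
available.

## Known limitations

- LJ-only scoring cannot rank designs that differ mainly in polarity; Thr
  and Gln in the default design alphabet are treated purely sterically.
- Fixed backbone: no accommodation of strain; the repulsion cap and radius
  scaling absorb some of this, at the cost of flattening extreme clashes
  (all capped pairs look equally bad).
- Rotamer discreteness: a near-fit rejected by 0.3 Å may be buildable in
  reality; the optional chi1 expansion softens but does not remove this.
- The heterodimer-fraction model assumes complete dimerization and
  equimolar expression; it ignores monomer states, chaperones, and
  concentration effects.
- mmCIF input is not supported (PDB-format text only).
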