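import numpy as np
import pytest

from bumphole.structures import (
    InterfaceSpec,
    apply_mutations,
    extract_design_region,
    make_synthetic_bundle,
    make_synthetic_interface,
    parse_mutation,
)


@pytest.fixture(scope="session")
def two_helix_bundle():
    """Small antiparallel two-helix poly-alanine fixture."""
    return make_synthetic_bundle(
        n_helices=2, residues_per_helix=12, inter_axis_spacing=9.5, seed=0
    )


@pytest.fixture(scope="session")
def small_region(two_helix_bundle):
    """Two design positions per chain on the two-helix fixture."""
    spec = InterfaceSpec(chain_x="A", chain_y="B", design_positions=(5, 8))
    return extract_design_region(two_helix_bundle, spec)


@pytest.fixture(scope="session")
def interface_fixture():
    """Synthetic two-protomer four-helix interface with an L/A/L/L pseudo-WT
    threaded at the design positions (analogous to a histone-fold core of
    three leucines and one alanine)."""
    structure, spec = make_synthetic_interface()
    p1, p2, p3, p4 = spec.design_positions
    wt_muts = [
        parse_mutation(f"A{p1}L"),
        parse_mutation(f"A{p3}L"),
        parse_mutation(f"A{p4}L"),
    ]
    threaded = apply_mutations(
        apply_mutations(structure, "A", wt_muts), "B", wt_muts
    )
    return threaded, spec


@pytest.fixture(scope="session")
def interface_region(interface_fixture):
    structure, spec = interface_fixture
    return extract_design_region(structure, spec)


@pytest.fixture(scope="session")
def backbone_frame(two_helix_bundle):
    from bumphole.structures import BackboneFrame

    s = two_helix_bundle
    return BackboneFrame(
        N=s.get_atom("A", 6, "N").coord,
        CA=s.get_atom("A", 6, "CA").coord,
        C=s.get_atom("A", 6, "C").coord,
    )
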