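import numpy as np
import pytest

from torsionfold import geometry as geom
from torsionfold import restraints as rst
from torsionfold import synthetic as syn


@pytest.fixture(scope="session")
def helix12():
    """Ideal 12-residue polyalanine alpha helix."""
    return geom.build_coordinates(
        "A" * 12, np.full(12, -57.0), np.full(12, -47.0)
    )


@pytest.fixture(scope="session")
def extended12():
    return geom.build_coordinates(
        "A" * 12, np.full(12, -120.0), np.full(12, 120.0)
    )


@pytest.fixture(scope="session")
def hairpin20():
    spec = syn.FixtureSpec(length=20, fold_type="hairpin", seed=0)
    return syn.make_toy_protein(spec)


@pytest.fixture(scope="session")
def hairpin20_restraints(hairpin20):
    spec = syn.FixtureSpec(length=20, fold_type="hairpin", seed=0)
    return syn.restraints_from_structure(hairpin20, spec)


@pytest.fixture(scope="session")
def hairpin20_potentials(hairpin20, hairpin20_restraints):
    sel = rst.select_restraints(hairpin20_restraints, ("prob_cutoff", 0.55))
    return rst.fit_splines(
        hairpin20_restraints, sel, sequence=hairpin20.sequence
    )


@pytest.fixture(scope="session")
def bundle30():
    spec = syn.FixtureSpec(length=30, fold_type="helix_bundle", seed=3)
    native = syn.make_toy_protein(spec)
    restraints = syn.restraints_from_structure(native, spec)
    return spec, native, restraints
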