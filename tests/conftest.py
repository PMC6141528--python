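import numpy as np
import pytest

from complexome.model import BindingRule, MolecularSpecies, ReactionModel
from complexome.simulator import SimulatedComplex


@pytest.fixture
def ab_model_factory():
    """Minimal two-species model A + B with one binding rule."""

    def make(kon=1.0, koff=1.0, n_a=1, n_b=1, sites=1, max_partners=10):
        species = [
            MolecularSpecies(id="A", domains=[("dA", sites)], abundance=n_a,
                             max_partners=max_partners),
            MolecularSpecies(id="B", domains=[("dB", sites)], abundance=n_b,
                             max_partners=max_partners),
        ]
        rules = [BindingRule("A", "B", "dA", "dB", kon=kon, koff=koff)]
        return ReactionModel(species=species, rules=rules)

    return make


@pytest.fixture
def barbell_sc():
    """Two 4-cliques joined by a single bridging bond."""
    members = [f"A{i}" for i in range(4)] + [f"B{i}" for i in range(4)]
    bonds = (
        [(i, j) for i in range(4) for j in range(i + 1, 4)]
        + [(i, j) for i in range(4, 8) for j in range(i + 1, 8)]
        + [(0, 4)]
    )
    return SimulatedComplex(id="barbell", members=members, bonds=bonds)


def make_sc(members, bonds=None, id="sc", run=0, sample=0):
    if bonds is None:  # chain is enough to make the complex connected
        bonds = [(i, i + 1) for i in range(len(members) - 1)]
    return SimulatedComplex(id=id, members=list(members), bonds=bonds,
                            run=run, sample=sample)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
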