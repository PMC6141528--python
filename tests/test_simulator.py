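"""Spatial simulation: placement, SSA, diffusion, conservation, sampling."""

import numpy as np
import pytest

from complexome.model import BindingRule, MolecularSpecies, ReactionModel
from complexome.simulator import (
    SpatialConfig,
    diffusion_cycle,
    extract_complexes,
    initialize_state,
    run_simulation,
    ssa_cycle,
)


def two_compartment_config(**kwargs):
    cmap = [["n", "n", "c", "c"] for _ in range(4)]
    return SpatialConfig(rows=4, cols=4, compartment_map=cmap, **kwargs)


# -- initialization ---------------------------------------------------------


def test_molecules_placed_only_in_their_compartment():
    model = ReactionModel(
        species=[MolecularSpecies(id="N", abundance=10, compartments={"n"})],
        rules=[],
    )
    state = initialize_state(model, two_compartment_config(sv_capacity=5), seed=1)
    for uid in range(state.n_molecules):
        assert state.labels[state.mol_sv[uid]] == "n"


def test_placement_at_exact_capacity_succeeds():
    model = ReactionModel(
        species=[MolecularSpecies(id="X", abundance=16)], rules=[],
    )
    spatial = SpatialConfig(rows=4, cols=4, sv_capacity=1)
    state = initialize_state(model, spatial, seed=0)
    assert (state.occupancy_counts() == 1).all()


def test_placement_over_capacity_errors():
    model = ReactionModel(
        species=[MolecularSpecies(id="X", abundance=17)], rules=[],
    )
    spatial = SpatialConfig(rows=4, cols=4, sv_capacity=1)
    with pytest.raises(ValueError, match="full"):
        initialize_state(model, spatial, seed=0)


# -- SSA --------------------------------------------------------------------


def test_two_state_equilibrium_kon_equals_koff(ab_model_factory):
    model = ab_model_factory(kon=1.0, koff=1.0)
    state = initialize_state(model, SpatialConfig(rows=1, cols=1, sv_capacity=5), seed=9)
    bound = 0
    n, burn = 4000, 500
    for i in range(n + burn):
        ssa_cycle(state)
        if i >= burn and state.total_bonds():
            bound += 1
    # P(bound) = kon/(kon+koff) = 0.5; 3 sigma of ~2000 effective samples
    assert bound / n == pytest.approx(0.5, abs=0.05)


def test_absorbing_state_with_zero_unbinding_propensity(ab_model_factory):
    model = ab_model_factory(kon=5.0, koff=1e-12, n_a=5, n_b=5)
    state = initialize_state(model, SpatialConfig(rows=1, cols=1, sv_capacity=20), seed=4)
    for _ in range(50):
        ssa_cycle(state)
    assert state.total_bonds() == 5  # all possible A-B pairs formed


def test_max_partners_and_site_exclusivity_hold(ab_model_factory):
    model = ab_model_factory(kon=10.0, koff=0.1, n_a=6, n_b=6, sites=3, max_partners=2)
    state = initialize_state(model, SpatialConfig(rows=1, cols=1, sv_capacity=20), seed=2)
    for _ in range(60):
        ssa_cycle(state)
        for uid in range(state.n_molecules):
            assert state.n_bonds[uid] <= 2
            occupied = [s for s in state.site_bond[uid] if s is not None]
            assert len(occupied) == state.n_bonds[uid]


def test_species_counts_unchanged_by_reactions(ab_model_factory):
    model = ab_model_factory(kon=2.0, koff=1.0, n_a=4, n_b=3)
    state = initialize_state(model, SpatialConfig(rows=2, cols=2, sv_capacity=10), seed=5)
    before = state.species_counts()
    for _ in range(30):
        ssa_cycle(state)
    assert state.species_counts() == before


# -- diffusion --------------------------------------------------------------


def test_diffusion_conserves_species_counts():
    model = ReactionModel(
        species=[MolecularSpecies(id="X", abundance=50, diffusion_rate=1.0)],
        rules=[],
    )
    state = initialize_state(model, SpatialConfig(rows=8, cols=8, sv_capacity=10), seed=3)
    before = state.species_counts()
    for _ in range(40):
        diffusion_cycle(state)
        assert state.species_counts() == before
        assert int(state.occupancy_counts().sum()) == 50


def test_molecules_never_leave_their_compartment():
    model = ReactionModel(
        species=[MolecularSpecies(id="N", abundance=12, compartments={"n"})],
        rules=[],
    )
    state = initialize_state(model, two_compartment_config(sv_capacity=10), seed=7)
    for _ in range(50):
        diffusion_cycle(state)
        for uid in range(state.n_molecules):
            assert state.labels[state.mol_sv[uid]] == "n"


def test_bound_complex_moves_as_one_unit(ab_model_factory):
    model = ab_model_factory(kon=50.0, koff=1e-12)
    state = initialize_state(model, SpatialConfig(rows=6, cols=6, sv_capacity=5), seed=11)
    # co-locate and bind the only two molecules
    for _ in range(200):
        diffusion_cycle(state)
        if state.mol_sv[0] == state.mol_sv[1]:
            ssa_cycle(state)
        if state.total_bonds():
            break
    assert state.total_bonds() == 1
    for _ in range(30):
        diffusion_cycle(state)
        assert state.mol_sv[0] == state.mol_sv[1]


def test_zero_diffusion_rate_molecules_stay_put():
    model = ReactionModel(
        species=[MolecularSpecies(id="X", abundance=20, diffusion_rate=0.0)],
        rules=[],
    )
    state = initialize_state(model, SpatialConfig(rows=4, cols=4, sv_capacity=10), seed=8)
    before = list(state.mol_sv)
    for _ in range(10):
        diffusion_cycle(state)
    assert state.mol_sv == before


# -- sampling and full runs -------------------------------------------------


def test_model_without_rules_yields_no_complexes():
    model = ReactionModel(
        species=[MolecularSpecies(id="X", abundance=30)], rules=[],
    )
    spatial = SpatialConfig(rows=4, cols=4, sv_capacity=20, n_cycles=6)
    assert run_simulation(model, spatial, n_runs=1, samples_per_run=2, seed=0) == []


def test_same_seed_reproduces_sc_list(ab_model_factory):
    model = ab_model_factory(kon=5.0, koff=0.5, n_a=10, n_b=10)
    spatial = SpatialConfig(rows=4, cols=4, sv_capacity=20, n_cycles=10)
    a = run_simulation(model, spatial, n_runs=2, samples_per_run=2, seed=42)
    b = run_simulation(model, spatial, n_runs=2, samples_per_run=2, seed=42)
    assert [(sc.id, sc.members, sc.bonds) for sc in a] == [
        (sc.id, sc.members, sc.bonds) for sc in b
    ]
    c = run_simulation(model, spatial, n_runs=2, samples_per_run=2, seed=43)
    assert [(sc.id, sc.members) for sc in a] != [(sc.id, sc.members) for sc in c]


def test_planted_cliques_recovered_in_near_absorbing_regime():
    # two disjoint 3-protein cliques, strong binding, negligible unbinding:
    # nearly every sampled complex is exactly one of the planted member sets
    proteins = ("A1", "A2", "A3", "B1", "B2", "B3")
    doms = {p: [] for p in proteins}
    rules = []
    for names in (proteins[:3], proteins[3:]):
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                da, db = f"d{a}{b}a", f"d{a}{b}b"
                rules.append(BindingRule(a, b, da, db, kon=50.0, koff=1e-9))
                doms[a].append((da, 1))
                doms[b].append((db, 1))
    species = [MolecularSpecies(id=p, domains=doms[p], abundance=15) for p in proteins]
    model = ReactionModel(species=species, rules=rules)
    spatial = SpatialConfig(rows=4, cols=4, sv_capacity=50, n_cycles=40)
    scs = run_simulation(model, spatial, n_runs=2, samples_per_run=2, seed=6)
    planted = {frozenset({"A1", "A2", "A3"}), frozenset({"B1", "B2", "B3"})}
    assert scs
    hits = sum(1 for sc in scs if sc.member_set in planted)
    assert hits / len(scs) >= 0.95


def test_extract_complexes_reports_connected_components(ab_model_factory):
    model = ab_model_factory(kon=100.0, koff=1e-12, n_a=2, n_b=2)
    state = initialize_state(model, SpatialConfig(rows=1, cols=1, sv_capacity=10), seed=1)
    ssa_cycle(state, dt=5.0)
    scs = extract_complexes(state)
    assert len(scs) == 2
    assert all(sorted(sc.members) == ["A", "B"] for sc in scs)


def test_sample_cycles_are_after_burn_in():
    spatial = SpatialConfig(rows=2, cols=2, n_cycles=60, burn_in_fraction=0.5)
    cycles = spatial.sample_cycles(2)
    assert cycles == [45, 60]
    assert all(c > 30 for c in cycles)
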