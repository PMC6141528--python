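"""Spatial stochastic simulation of complexation, decomplexation and diffusion.

Space is a 2D grid of well-mixed subvolumes (SVs), optionally partitioned
into labelled compartments.  Each simulation cycle alternates

1. an exact Gillespie SSA within every subvolume over the local reaction
   channels — complexation (per binding rule and eligible molecule pair,
   propensity ``kon``) and decomplexation (per existing bond, propensity
   ``koff``) — run for ``dt`` time units, and
2. a diffusion step in which unbound molecules hop to a uniformly chosen
   4-neighbor SV with probability ``min(1, D * dt)`` and bound complexes
   move as a single unit at the slowest member's rate; hops are rejected
   at grid borders, compartment boundaries, and full subvolumes.

Molecules are tracked individually: every molecule carries its binding
sites (one per domain copy, fictitious domains included) and a site holds
at most one bond; a species-level ``max_partners`` additionally caps the
number of simultaneous bonds per molecule.  Binding between molecules in
two *different adjacent* compartments is allowed across the shared SV
face; such cross-compartment complexes stay anchored until the cross
bond breaks.

Connected components of the bond graph with at least two members are the
simulated complexes (SCs) sampled at the configured timepoints.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, deque
from dataclasses import dataclass, field

import numpy as np

from .iofmt import DEFAULT_COMPARTMENT
from .model import ReactionModel

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialConfig",
    "MoleculeInstance",
    "SimulatedComplex",
    "SimState",
    "initialize_state",
    "ssa_cycle",
    "diffusion_cycle",
    "extract_complexes",
    "run_simulation",
]


@dataclass
class SpatialConfig:
    """Grid geometry, capacity and schedule of one simulation run."""

    rows: int = 64
    cols: int = 64
    compartment_map: list[list[str]] | None = None  # None -> single compartment
    sv_capacity: int = 150
    dt: float = 1.0
    n_cycles: int = 40
    burn_in_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one subvolume")
        if self.sv_capacity < 1:
            raise ValueError("sv_capacity must be >= 1")
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must lie in [0, 1)")
        if self.compartment_map is not None:
            if len(self.compartment_map) != self.rows or any(
                len(r) != self.cols for r in self.compartment_map
            ):
                raise ValueError("compartment map shape does not match grid")

    @property
    def n_sv(self) -> int:
        return self.rows * self.cols

    def labels(self) -> list[str]:
        if self.compartment_map is None:
            return [DEFAULT_COMPARTMENT] * self.n_sv
        return [lab for row in self.compartment_map for lab in row]

    def sample_cycles(self, samples_per_run: int) -> list[int]:
        """Evenly spaced sampling cycles strictly after the burn-in window."""
        burn = int(math.ceil(self.n_cycles * self.burn_in_fraction))
        span = self.n_cycles - burn
        if samples_per_run > span:
            raise ValueError(
                f"cannot place {samples_per_run} samples in {span} post-burn-in cycles"
            )
        return [burn + round((k + 1) * span / samples_per_run) for k in range(samples_per_run)]


@dataclass
class MoleculeInstance:
    """Read-only snapshot of one tracked molecule (for inspection and tests)."""

    uid: int
    species: str
    subvolume: int
    bonds: list[tuple[int, int, int]]  # (site on self, peer uid, peer site)


@dataclass
class SimulatedComplex:
    """A connected set of bound molecules sampled from one snapshot."""

    id: str
    members: list[str]  # species id per member molecule (multiset)
    bonds: list[tuple[int, int]]  # local member indices, one entry per bond
    run: int = 0
    sample: int = 0

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)

    @property
    def stoichiometry(self) -> Counter:
        return Counter(self.members)

    def __len__(self) -> int:
        return len(self.members)


class SimState:
    """Mutable per-run simulation state with model lookups compiled in."""

    def __init__(self, model: ReactionModel, spatial: SpatialConfig, rng: np.random.Generator):
        self.model = model
        self.spatial = spatial
        self.rng = rng

        self.sp_ids = [s.id for s in model.species]
        sp_index = {sid: i for i, sid in enumerate(self.sp_ids)}
        dom_index: dict[str, int] = {}
        for s in model.species:
            for d, _ in s.domains:
                dom_index.setdefault(d, len(dom_index))

        self.site_template: list[list[int]] = []
        self.free_template: list[dict[int, int]] = []
        self.sp_maxp: list[int] = []
        self.sp_diff: list[float] = []
        self.sp_labels: list[frozenset[str]] = []
        for s in model.species:
            sites = []
            free: dict[int, int] = {}
            for d, n in s.domains:
                di = dom_index[d]
                sites.extend([di] * n)
                free[di] = free.get(di, 0) + n
            self.site_template.append(sites)
            self.free_template.append(free)
            self.sp_maxp.append(s.max_partners)
            self.sp_diff.append(s.diffusion_rate)
            self.sp_labels.append(frozenset(s.compartments))

        # oriented rule lookup: (species i, species j) -> [(dom_i, dom_j, kon, koff)]
        self.rules_by_pair: dict[tuple[int, int], list[tuple[int, int, float, float]]] = {}
        for r in model.rules:
            ia, ib = sp_index[r.species_a], sp_index[r.species_b]
            da, db = dom_index[r.domain_a], dom_index[r.domain_b]
            self.rules_by_pair.setdefault((ia, ib), [])
            self.rules_by_pair.setdefault((ib, ia), [])
            if (da, db, r.kon, r.koff) not in self.rules_by_pair[(ia, ib)]:
                self.rules_by_pair[(ia, ib)].append((da, db, r.kon, r.koff))
            if (db, da, r.kon, r.koff) not in self.rules_by_pair[(ib, ia)]:
                self.rules_by_pair[(ib, ia)].append((db, da, r.kon, r.koff))

        # grid geometry
        rows, cols = spatial.rows, spatial.cols
        self.labels = spatial.labels()
        self.neighbors: list[list[int]] = []
        self.cross_owned: list[list[int]] = []  # east/south neighbors in a different compartment
        for sv in range(spatial.n_sv):
            r, c = divmod(sv, cols)
            nbs = []
            if r > 0:
                nbs.append(sv - cols)
            if r < rows - 1:
                nbs.append(sv + cols)
            if c > 0:
                nbs.append(sv - 1)
            if c < cols - 1:
                nbs.append(sv + 1)
            self.neighbors.append(nbs)
            owned = []
            for nb in ((sv + 1) if c < cols - 1 else None, (sv + cols) if r < rows - 1 else None):
                if nb is not None and self.labels[nb] != self.labels[sv]:
                    owned.append(nb)
            self.cross_owned.append(owned)

        # molecule arrays (filled by initialize_state)
        self.mol_species: list[int] = []
        self.mol_sv: list[int] = []
        self.site_bond: list[list] = []  # per molecule: per site None | (peer, peer_site, koff)
        self.free_count: list[dict[int, int]] = []
        self.n_bonds: list[int] = []
        self.occupants: list[set[int]] = [set() for _ in range(spatial.n_sv)]
        self.occ = np.zeros(spatial.n_sv, dtype=np.int64)

    # -- introspection ------------------------------------------------------

    @property
    def n_molecules(self) -> int:
        return len(self.mol_species)

    def molecule(self, uid: int) -> MoleculeInstance:
        bonds = [
            (site, peer, psite)
            for site, entry in enumerate(self.site_bond[uid])
            if entry is not None
            for peer, psite, _ in [entry]
        ]
        return MoleculeInstance(
            uid=uid,
            species=self.sp_ids[self.mol_species[uid]],
            subvolume=self.mol_sv[uid],
            bonds=bonds,
        )

    def species_counts(self) -> Counter:
        return Counter(self.sp_ids[si] for si in self.mol_species)

    def total_bonds(self) -> int:
        return sum(self.n_bonds) // 2

    def occupancy_counts(self) -> np.ndarray:
        return self.occ.copy()

    def components(self) -> list[list[int]]:
        """Connected components of the bond graph (singletons included)."""
        seen = [False] * self.n_molecules
        out = []
        for start in range(self.n_molecules):
            if seen[start]:
                continue
            comp = [start]
            seen[start] = True
            queue = deque([start])
            while queue:
                m = queue.popleft()
                for entry in self.site_bond[m]:
                    if entry is None:
                        continue
                    peer = entry[0]
                    if not seen[peer]:
                        seen[peer] = True
                        comp.append(peer)
                        queue.append(peer)
            out.append(comp)
        return out

    # -- bond bookkeeping ---------------------------------------------------

    def _add_molecule(self, spi: int, sv: int) -> int:
        uid = len(self.mol_species)
        self.mol_species.append(spi)
        self.mol_sv.append(sv)
        self.site_bond.append([None] * len(self.site_template[spi]))
        self.free_count.append(dict(self.free_template[spi]))
        self.n_bonds.append(0)
        self.occupants[sv].add(uid)
        self.occ[sv] += 1
        return uid

    def _free_site_for(self, m: int, dom: int) -> int:
        sites = self.site_template[self.mol_species[m]]
        taken = self.site_bond[m]
        for idx, d in enumerate(sites):
            if d == dom and taken[idx] is None:
                return idx
        raise RuntimeError("no free site despite positive free count")  # pragma: no cover

    def bind(self, m1: int, dom1: int, m2: int, dom2: int, koff: float) -> None:
        s1 = self._free_site_for(m1, dom1)
        s2 = self._free_site_for(m2, dom2)
        self.site_bond[m1][s1] = (m2, s2, koff)
        self.site_bond[m2][s2] = (m1, s1, koff)
        self.free_count[m1][dom1] -= 1
        self.free_count[m2][dom2] -= 1
        self.n_bonds[m1] += 1
        self.n_bonds[m2] += 1

    def unbind(self, m1: int, site1: int) -> None:
        peer, psite, _ = self.site_bond[m1][site1]
        dom1 = self.site_template[self.mol_species[m1]][site1]
        dom2 = self.site_template[self.mol_species[peer]][psite]
        self.site_bond[m1][site1] = None
        self.site_bond[peer][psite] = None
        self.free_count[m1][dom1] += 1
        self.free_count[peer][dom2] += 1
        self.n_bonds[m1] -= 1
        self.n_bonds[peer] -= 1


def initialize_state(
    model: ReactionModel, spatial: SpatialConfig, seed: int | np.random.Generator = 0
) -> SimState:
    """Place every molecule uniformly at random within its compartment(s).

    Placement respects ``sv_capacity``; a compartment that cannot hold the
    molecules assigned to it raises an error naming the compartment.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = SimState(model, spatial, rng)

    label_arr = state.labels
    sv_by_label: dict[str, list[int]] = {}
    for sv, lab in enumerate(label_arr):
        sv_by_label.setdefault(lab, []).append(sv)

    # feasibility per compartment-set before any placement
    demand: Counter = Counter()
    for s in model.species:
        key = frozenset(s.compartments)
        demand[key] += s.abundance
    for key, n in demand.items():
        candidates = [sv for lab in key for sv in sv_by_label.get(lab, [])]
        if not candidates:
            raise ValueError(f"no subvolume carries any of the compartments {sorted(key)}")
    # shared capacity check: greedy placement below will fail loudly otherwise

    for spi, s in enumerate(model.species):
        candidates = [sv for lab in s.compartments for sv in sv_by_label.get(lab, [])]
        open_svs = [sv for sv in candidates if state.occ[sv] < spatial.sv_capacity]
        for _ in range(s.abundance):
            if not open_svs:
                raise ValueError(
                    f"compartment(s) {sorted(s.compartments)} are full: cannot place "
                    f"all {s.abundance} copies of {s.id!r}"
                )
            k = int(rng.integers(len(open_svs)))
            sv = open_svs[k]
            state._add_molecule(spi, sv)
            if state.occ[sv] >= spatial.sv_capacity:
                open_svs[k] = open_svs[-1]
                open_svs.pop()
    return state


def _sv_channels(state: SimState, sv: int) -> list[tuple[float, int, tuple]]:
    """Reaction channels owned by one subvolume.

    Complexation channels cover unordered molecule pairs co-located in
    ``sv`` plus pairs with the east/south neighbor when that neighbor
    lies in a different compartment; decomplexation channels cover bonds
    whose lower-uid endpoint sits in ``sv``.
    """
    channels: list[tuple[float, int, tuple]] = []
    mols = list(state.occupants[sv])
    rules = state.rules_by_pair
    maxp = state.sp_maxp
    nb_mols: list[int] = []
    for nb in state.cross_owned[sv]:
        nb_mols.extend(state.occupants[nb])

    def pair_channels(m1: int, m2: int) -> None:
        s1, s2 = state.mol_species[m1], state.mol_species[m2]
        entries = rules.get((s1, s2))
        if not entries:
            return
        if state.n_bonds[m1] >= maxp[s1] or state.n_bonds[m2] >= maxp[s2]:
            return
        f1, f2 = state.free_count[m1], state.free_count[m2]
        for da, db, kon, koff in entries:
            if f1.get(da, 0) > 0 and f2.get(db, 0) > 0:
                channels.append((kon, 0, (m1, da, m2, db, koff)))

    n = len(mols)
    for i in range(n):
        for j in range(i + 1, n):
            pair_channels(mols[i], mols[j])
        for m2 in nb_mols:
            pair_channels(mols[i], m2)
    for m in mols:
        if state.n_bonds[m]:
            for site, entry in enumerate(state.site_bond[m]):
                if entry is not None and m < entry[0]:
                    channels.append((entry[2], 1, (m, site)))
    return channels


def ssa_cycle(state: SimState, dt: float | None = None) -> SimState:
    """Run an exact Gillespie SSA for ``dt`` time units in every subvolume."""
    dt = state.spatial.dt if dt is None else dt
    rng = state.rng
    for sv in range(state.spatial.n_sv):
        if not state.occupants[sv] and not state.cross_owned[sv]:
            continue
        t = 0.0
        while True:
            channels = _sv_channels(state, sv)
            if not channels:
                break
            a0 = 0.0
            for prop, _, _ in channels:
                a0 += prop
            t += rng.exponential() / a0
            if t >= dt:
                break
            pick = rng.random() * a0
            acc = 0.0
            chosen = channels[-1]
            for ch in channels:
                acc += ch[0]
                if pick < acc:
                    chosen = ch
                    break
            if chosen[1] == 0:
                m1, da, m2, db, koff = chosen[2]
                state.bind(m1, da, m2, db, koff)
            else:
                m, site = chosen[2]
                state.unbind(m, site)
    return state


_OFFSETS = ((-1, 0), (1, 0), (0, -1), (0, 1))


def diffusion_cycle(state: SimState, dt: float | None = None) -> SimState:
    """One Fickian diffusion step: unbiased random hops with rejection.

    Unbound molecules hop independently; each bound complex without a
    cross-compartment bond moves as a rigid unit at the minimum member
    diffusion rate; complexes holding a cross-compartment bond stay put.
    Rejected moves (off-grid, wrong compartment, full target) leave the
    molecule in place, so per-species counts are conserved exactly.
    """
    dt = state.spatial.dt if dt is None else dt
    rng = state.rng
    spatial = state.spatial
    cols = spatial.cols
    cap = spatial.sv_capacity
    labels = state.labels
    comps = state.components()
    order = rng.permutation(len(comps))

    for ci in order:
        comp = comps[ci]
        if len(comp) == 1:
            m = comp[0]
            if state.n_bonds[m]:
                continue  # bound molecule moves with its complex
            spi = state.mol_species[m]
            p = min(1.0, state.sp_diff[spi] * dt)
            if p <= 0.0 or rng.random() >= p:
                continue
            dr, dc = _OFFSETS[int(rng.integers(4))]
            sv = state.mol_sv[m]
            r, c = divmod(sv, cols)
            nr, nc = r + dr, c + dc
            if not (0 <= nr < spatial.rows and 0 <= nc < cols):
                continue
            target = nr * cols + nc
            if labels[target] not in state.sp_labels[spi] or state.occ[target] >= cap:
                continue
            state.occupants[sv].discard(m)
            state.occupants[target].add(m)
            state.occ[sv] -= 1
            state.occ[target] += 1
            state.mol_sv[m] = target
        else:
            # a cross-compartment bond anchors the whole complex
            anchored = False
            for m in comp:
                lab = labels[state.mol_sv[m]]
                for entry in state.site_bond[m]:
                    if entry is not None and labels[state.mol_sv[entry[0]]] != lab:
                        anchored = True
                        break
                if anchored:
                    break
            if anchored:
                continue
            d = min(state.sp_diff[state.mol_species[m]] for m in comp)
            p = min(1.0, d * dt)
            if p <= 0.0 or rng.random() >= p:
                continue
            dr, dc = _OFFSETS[int(rng.integers(4))]
            for m in comp:
                state.occ[state.mol_sv[m]] -= 1
            targets = []
            incoming: Counter = Counter()
            ok = True
            for m in comp:
                sv = state.mol_sv[m]
                r, c = divmod(sv, cols)
                nr, nc = r + dr, c + dc
                if not (0 <= nr < spatial.rows and 0 <= nc < cols):
                    ok = False
                    break
                target = nr * cols + nc
                spi = state.mol_species[m]
                if labels[target] not in state.sp_labels[spi]:
                    ok = False
                    break
                incoming[target] += 1
                if state.occ[target] + incoming[target] > cap:
                    ok = False
                    break
                targets.append(target)
            if ok:
                for m, target in zip(comp, targets):
                    sv = state.mol_sv[m]
                    state.occupants[sv].discard(m)
                    state.occupants[target].add(m)
                    state.mol_sv[m] = target
                    state.occ[target] += 1
            else:
                for m in comp:
                    state.occ[state.mol_sv[m]] += 1
    return state


def extract_complexes(state: SimState, run: int = 0, sample: int = 0) -> list[SimulatedComplex]:
    """Connected bound components with >= 2 members, as simulated complexes."""
    out = []
    k = 0
    for comp in state.components():
        if len(comp) < 2:
            continue
        comp = sorted(comp)
        local = {uid: i for i, uid in enumerate(comp)}
        members = [state.sp_ids[state.mol_species[uid]] for uid in comp]
        bonds = []
        for uid in comp:
            for entry in state.site_bond[uid]:
                if entry is not None and uid < entry[0]:
                    bonds.append((local[uid], local[entry[0]]))
        out.append(
            SimulatedComplex(
                id=f"r{run}s{sample}c{k}", members=members, bonds=sorted(bonds),
                run=run, sample=sample,
            )
        )
        k += 1
    return out


def run_simulation(
    model: ReactionModel,
    spatial: SpatialConfig,
    n_runs: int = 3,
    samples_per_run: int = 2,
    seed: int = 0,
) -> list[SimulatedComplex]:
    """Run ``n_runs`` independent replicates and pool the sampled complexes.

    Each run alternates SSA and diffusion cycles for
    ``spatial.n_cycles`` cycles and samples the bond graph at
    ``samples_per_run`` evenly spaced post-burn-in cycles.  Replicate RNG
    streams are derived deterministically from (seed, run index), so the
    pooled list is fully reproducible.
    """
    sample_at = set(spatial.sample_cycles(samples_per_run))
    pooled: list[SimulatedComplex] = []
    for run in range(n_runs):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(run,)))
        state = initialize_state(model, spatial, rng)
        sample_idx = 0
        for cycle in range(1, spatial.n_cycles + 1):
            ssa_cycle(state)
            diffusion_cycle(state)
            if cycle in sample_at:
                pooled.extend(extract_complexes(state, run=run, sample=sample_idx))
                sample_idx += 1
        logger.info(
            "run %d: %d molecules, %d bonds at end",
            run, state.n_molecules, state.total_bonds(),
        )
    return pooled
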