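"""Post-processing of simulated complexes into refined complexes.

The refinement pipeline has three steps:

1. **split** — Markov Clustering (MCL) on each simulated complex's bond
   graph separates strongly connected subnetworks that are linked only by
   one or a few bonds (typically artefacts of missing steric
   constraints);
2. **merge** — simulated complexes that differ in only a few proteins
   (overlap score above a similarity threshold, default 0.5) are
   agglomerated greedily, most-similar pair first, into refined
   complexes (RCs) whose member set is the union;
3. **quantify** — every post-split simulated complex is assigned to the
   refined complex it overlaps most; the number of assigned SCs is the
   predicted abundance of the RC.

Two refined complexes may both match the same reference complex above
the evaluation threshold without being merged; these are alternative
forms of one biological complex and are deliberately kept apart.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .metrics import overlap_score
from .simulator import SimulatedComplex

logger = logging.getLogger(__name__)

__all__ = [
    "RefinementConfig",
    "RefinedComplex",
    "mcl",
    "mcl_split",
    "merge_similar",
    "assign_quantities",
    "refine_pipeline",
]


@dataclass
class RefinementConfig:
    mcl_inflation: float = 2.0
    mcl_expansion: int = 2
    mcl_prune_threshold: float = 1e-5
    mcl_max_iter: int = 100
    merge_threshold: float = 0.5  # pairwise overlap above which SCs merge
    per_sample: bool = False
    n_samples: int = 1  # divisor for per-sample normalization

    def __post_init__(self) -> None:
        if not 0.0 < self.merge_threshold <= 1.0:
            raise ValueError("merge_threshold must lie in (0, 1]")
        if self.mcl_inflation <= 1.0:
            raise ValueError("mcl_inflation must be > 1")


@dataclass
class RefinedComplex:
    id: str
    members: frozenset[str]
    abundance: float = 0.0
    mean_stoichiometry: dict[str, float] = field(default_factory=dict)
    assigned_sc_ids: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)


def mcl(
    adjacency: np.ndarray,
    inflation: float = 2.0,
    expansion: int = 2,
    prune: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> list[list[int]] | None:
    """Markov Clustering on a weighted adjacency matrix.

    Self-loops of weight 1 are added, columns are normalized to a column-
    stochastic matrix, and expansion (matrix power) alternates with
    inflation (elementwise power + renormalization) until the matrix is
    stable.  Clusters are read off the rows of the limit matrix
    (attractor rows and the columns they serve); nodes claimed by several
    attractor rows go to the first.  Returns ``None`` on non-convergence.
    """
    n = adjacency.shape[0]
    m = adjacency.astype(float) + np.eye(n)
    m /= m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = m**inflation
        m[m < prune] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0.0] = 1.0
        m /= colsum
        if np.abs(m - prev).max() < tol:
            break
    else:
        return None

    clusters: list[list[int]] = []
    assigned = [False] * n
    for i in range(n):
        if m[i, i] <= prune:  # not an attractor row
            continue
        members = [j for j in range(n) if m[i, j] > prune and not assigned[j]]
        if members:
            for j in members:
                assigned[j] = True
            clusters.append(members)
    for j in range(n):  # isolated numerical leftovers become singletons
        if not assigned[j]:
            clusters.append([j])
    return clusters


def _bond_weight_matrix(sc: SimulatedComplex) -> np.ndarray:
    n = len(sc.members)
    w = np.zeros((n, n))
    for i, j in sc.bonds:
        w[i, j] += 1.0
        w[j, i] += 1.0
    return w


def mcl_split(sc: SimulatedComplex, config: RefinementConfig | None = None) -> list[SimulatedComplex]:
    """Split one simulated complex with MCL; singleton clusters are discarded.

    The clustering runs on the molecule-level bond graph with edge weight
    equal to the number of bonds between the two molecules.  If MCL
    leaves the graph in one cluster (or fails to converge) the complex is
    returned unchanged.
    """
    config = config or RefinementConfig()
    if len(sc.members) <= 2:
        return [sc]
    clusters = mcl(
        _bond_weight_matrix(sc),
        inflation=config.mcl_inflation,
        expansion=config.mcl_expansion,
        prune=config.mcl_prune_threshold,
        max_iter=config.mcl_max_iter,
    )
    if clusters is None:
        logger.warning("MCL did not converge on complex %s; kept unsplit", sc.id)
        return [sc]
    clusters = [sorted(c) for c in clusters]
    if sum(1 for c in clusters if c) <= 1 or max(len(c) for c in clusters) == len(sc.members):
        return [sc]
    out = []
    for k, cluster in enumerate(sorted(clusters, key=lambda c: (-len(c), c))):
        if len(cluster) < 2:
            continue
        local = {uid: i for i, uid in enumerate(cluster)}
        in_cluster = set(cluster)
        bonds = [
            (local[i], local[j]) for i, j in sc.bonds if i in in_cluster and j in in_cluster
        ]
        out.append(
            SimulatedComplex(
                id=f"{sc.id}.{k}",
                members=[sc.members[i] for i in cluster],
                bonds=sorted(bonds),
                run=sc.run,
                sample=sc.sample,
            )
        )
    return out if out else [sc]


def merge_similar(
    scs: list[SimulatedComplex], config: RefinementConfig | None = None
) -> list[RefinedComplex]:
    """Agglomerate similar member sets into refined complexes.

    Identical member sets collapse first; then the most-overlapping pair
    is merged (union of members) repeatedly until no pair exceeds the
    merge threshold.  Ties on the maximal overlap are broken by the
    lexicographically smallest pair of sorted member tuples, so the
    result is deterministic.
    """
    config = config or RefinementConfig()
    sets = sorted({frozenset(sc.members) for sc in scs}, key=lambda s: (-len(s), sorted(s)))
    if not sets:
        return []

    def key_of(s: frozenset) -> tuple:
        return tuple(sorted(s))

    while len(sets) > 1:
        best = None
        best_o = config.merge_threshold
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                o = overlap_score(sets[i], sets[j])
                if o > best_o or (
                    best is not None
                    and o == best_o
                    and (key_of(sets[i]), key_of(sets[j])) < best[2]
                ):
                    best = (i, j, (key_of(sets[i]), key_of(sets[j])))
                    best_o = o
        if best is None:
            break
        i, j, _ = best
        merged = sets[i] | sets[j]
        rest = [s for k, s in enumerate(sets) if k not in (i, j)]
        rest.append(merged)
        sets = sorted(set(rest), key=lambda s: (-len(s), sorted(s)))

    return [
        RefinedComplex(id=f"rc{k:04d}", members=s)
        for k, s in enumerate(sorted(sets, key=lambda s: (-len(s), sorted(s))))
    ]


def assign_quantities(
    scs: list[SimulatedComplex],
    rcs: list[RefinedComplex],
    config: RefinementConfig | None = None,
) -> list[RefinedComplex]:
    """Assign every simulated complex to its best-overlapping refined complex.

    Ties go to the larger RC, then to the lexicographically smallest RC
    id.  An SC overlapping no RC at all founds a new RC of its own member
    set.  Abundances count assigned SCs (total over all runs and
    samples, or per sample when ``config.per_sample``); they always sum
    to the number of input SCs, and mean stoichiometries are averaged
    over the SCs assigned to each RC.
    """
    config = config or RefinementConfig()
    rcs = [
        RefinedComplex(id=rc.id, members=rc.members) for rc in rcs
    ]  # fresh copies: membership frozen, quantities recomputed
    extra: dict[frozenset, RefinedComplex] = {}
    counts: dict[str, int] = {}
    stoich: dict[str, Counter] = {}

    for sc in scs:
        mset = sc.member_set
        best = None
        best_key = None
        for rc in rcs:
            o = overlap_score(mset, rc.members)
            if o <= 0.0:
                continue
            key = (o, rc.size, _neg_id(rc.id))
            if best_key is None or key > best_key:
                best, best_key = rc, key
        if best is None:
            if mset in extra:
                best = extra[mset]
            else:
                best = RefinedComplex(id=f"rc-orphan{len(extra):04d}", members=mset)
                extra[mset] = best
                logger.warning(
                    "SC %s overlaps no refined complex; kept as singleton RC", sc.id
                )
        counts[best.id] = counts.get(best.id, 0) + 1
        stoich.setdefault(best.id, Counter()).update(sc.stoichiometry)
        best.assigned_sc_ids.append(sc.id)

    out = rcs + list(extra.values())
    divisor = max(1, config.n_samples) if config.per_sample else 1
    for rc in out:
        n = counts.get(rc.id, 0)
        rc.abundance = n / divisor
        if n:
            rc.mean_stoichiometry = {
                sp: c / n for sp, c in sorted(stoich[rc.id].items())
            }
    return out


class _neg_id(str):
    """String wrapper whose ordering is reversed (smallest id wins in a max)."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def refine_pipeline(
    raw_scs: list[SimulatedComplex], config: RefinementConfig | None = None
) -> list[RefinedComplex]:
    """Full split → merge → quantify pipeline (deterministic given inputs)."""
    config = config or RefinementConfig()
    split: list[SimulatedComplex] = []
    for sc in raw_scs:
        split.extend(mcl_split(sc, config))
    if not split:
        return []
    rcs = merge_similar(split, config)
    return assign_quantities(split, rcs, config)
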