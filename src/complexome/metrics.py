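"""Evaluation metrics for predicted protein complexes.

A prediction is a collection of protein sets P, evaluated against a
reference catalog B (CYC2008/CORUM style).  All scores are built on the
overlap score

    Overlap(p, r) = |p ∩ r|^2 / (|p| * |r|),

which is 1 exactly when the two sets coincide and 0 exactly when they are
disjoint.  A predicted complex *matches* a reference complex when their
overlap strictly exceeds a threshold ``omega`` (default 0.25).

The module provides:

* ``recall`` — fraction of reference complexes matched by some prediction;
* ``sensitivity_ppv_accuracy`` — clustering-wise Sn, PPV and their
  geometric mean, computed from the protein-sharing contingency table;
* ``mmr`` — maximum matching ratio: the weight of a maximum-weight
  bipartite matching between predictions and references (edge weight =
  overlap), divided by |B|;
* ``composite_score`` — recall + MMR + accuracy, the headline score used
  to compare complex-prediction tools (range [0, 3]);
* ``filter_location_consistent`` — drop complexes whose members have no
  common subcellular compartment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)

__all__ = [
    "MatchConfig",
    "ContingencyTable",
    "MetricsReport",
    "overlap_score",
    "recall",
    "contingency_table",
    "sensitivity_ppv_accuracy",
    "mmr",
    "composite_score",
    "filter_location_consistent",
]


@dataclass(frozen=True)
class MatchConfig:
    """Matching threshold for a successful prediction (strict inequality)."""

    omega: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 < self.omega < 1.0:
            raise ValueError(f"omega must lie in (0, 1), got {self.omega}")


@dataclass
class ContingencyTable:
    """Protein-sharing counts between reference and predicted complexes.

    ``t[i, j]`` is the number of proteins shared by reference complex *i*
    (of size ``ref_sizes[i]``) and predicted complex *j*.
    """

    t: np.ndarray
    ref_sizes: np.ndarray
    pred_sizes: np.ndarray

    @property
    def column_sums(self) -> np.ndarray:
        return self.t.sum(axis=0)


@dataclass
class MetricsReport:
    recall: float
    sn: float
    ppv: float
    accuracy: float
    mmr: float
    composite: float
    matched_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "recall": self.recall,
            "sn": self.sn,
            "ppv": self.ppv,
            "accuracy": self.accuracy,
            "mmr": self.mmr,
            "composite": self.composite,
            "matched_pairs": [list(m) for m in self.matched_pairs],
        }


def overlap_score(p: Iterable[str], r: Iterable[str]) -> float:
    """``|p ∩ r|² / (|p|·|r|)`` — symmetric set similarity in [0, 1]."""
    ps, rs = set(p), set(r)
    if not ps or not rs:
        raise ValueError("overlap_score requires two non-empty sets")
    inter = len(ps & rs)
    return inter * inter / (len(ps) * len(rs))


def _as_sets(complexes) -> list[frozenset]:
    out = []
    for c in complexes:
        members = getattr(c, "members", c)
        out.append(frozenset(members))
    return out


def recall(predicted, reference, omega: float = 0.25) -> float:
    """Fraction of reference complexes matched (overlap > omega) by a prediction."""
    preds = _as_sets(predicted)
    refs = _as_sets(reference)
    if not refs:
        raise ValueError("reference complex set is empty")
    hit = 0
    for b in refs:
        if any(overlap_score(p, b) > omega for p in preds if p):
            hit += 1
    return hit / len(refs)


def contingency_table(predicted, reference) -> ContingencyTable:
    preds = _as_sets(predicted)
    refs = _as_sets(reference)
    t = np.zeros((len(refs), len(preds)), dtype=np.int64)
    for i, b in enumerate(refs):
        for j, p in enumerate(preds):
            t[i, j] = len(b & p)
    return ContingencyTable(
        t=t,
        ref_sizes=np.array([len(b) for b in refs], dtype=np.int64),
        pred_sizes=np.array([len(p) for p in preds], dtype=np.int64),
    )


def sensitivity_ppv_accuracy(table: ContingencyTable) -> tuple[float, float, float]:
    """Clustering-wise sensitivity, positive predictive value, and accuracy.

    Sn weights each reference complex's best per-complex sensitivity
    ``max_j T_ij / N_i`` by its size ``N_i``; PPV weights each predicted
    complex's best column fraction ``max_i T_ij / T_.j`` by its column sum
    ``T_.j`` (columns with ``T_.j = 0`` — predictions sharing no protein
    with any reference complex — contribute nothing).  Accuracy is the
    geometric mean ``sqrt(Sn * PPV)``.
    """
    t = table.t
    if t.size == 0 or not np.any(t):
        raise ValueError("contingency table has no nonzero entry")
    sn = float(t.max(axis=1).sum() / table.ref_sizes.sum())
    col = table.column_sums
    nz = col > 0
    ppv = float(t[:, nz].max(axis=0).sum() / col[nz].sum())
    return sn, ppv, float(np.sqrt(sn * ppv))


def mmr(predicted, reference) -> float:
    """Maximum matching ratio.

    Maximum-weight bipartite matching between predicted and reference
    complexes, with the overlap score as edge weight; each node is used at
    most once.  The total matched weight is divided by the number of
    reference complexes.  Solved exactly as an assignment problem.
    """
    preds = _as_sets(predicted)
    refs = _as_sets(reference)
    if not refs:
        raise ValueError("reference complex set is empty")
    if not preds:
        return 0.0
    w = np.zeros((len(preds), len(refs)))
    for i, p in enumerate(preds):
        for j, b in enumerate(refs):
            w[i, j] = overlap_score(p, b)
    rows, cols = linear_sum_assignment(w, maximize=True)
    return float(w[rows, cols].sum() / len(refs))


def composite_score(
    predicted,
    reference,
    omega: float = 0.25,
    predicted_ids: Sequence[str] | None = None,
    reference_ids: Sequence[str] | None = None,
) -> MetricsReport:
    """Full evaluation report: recall + MMR + accuracy (composite in [0, 3]).

    A degenerate contingency table (no protein shared between any
    prediction and any reference complex) yields Sn = PPV = accuracy = 0
    so the composite stays well defined.
    """
    preds = _as_sets(predicted)
    refs = _as_sets(reference)
    rec = recall(preds, refs, omega)
    table = contingency_table(preds, refs)
    if preds and np.any(table.t):
        sn, ppv, acc = sensitivity_ppv_accuracy(table)
    else:
        sn = ppv = acc = 0.0
    m = mmr(preds, refs)

    pid = list(predicted_ids) if predicted_ids is not None else [f"p{j}" for j in range(len(preds))]
    rid = list(reference_ids) if reference_ids is not None else [f"b{i}" for i in range(len(refs))]
    pairs: list[tuple[str, str, float]] = []
    for i, b in enumerate(refs):
        best, best_o = None, 0.0
        for j, p in enumerate(preds):
            o = overlap_score(p, b)
            if o > best_o:
                best, best_o = j, o
        if best is not None and best_o > omega:
            pairs.append((pid[best], rid[i], best_o))

    return MetricsReport(
        recall=rec,
        sn=sn,
        ppv=ppv,
        accuracy=acc,
        mmr=m,
        composite=rec + m + acc,
        matched_pairs=pairs,
    )


def filter_location_consistent(
    complexes,
    compartments: Mapping[str, set],
) -> tuple[list, list]:
    """Split complexes into location-consistent and inconsistent ones.

    A complex is kept iff the intersection of its members' compartment
    sets is non-empty.  Members without a compartment annotation are
    treated as ubiquitous (they never cause removal).
    """
    kept, removed = [], []
    for c in complexes:
        members = getattr(c, "members", c)
        common: set | None = None
        for m in set(members):
            comp = compartments.get(m)
            if not comp:
                continue
            common = set(comp) if common is None else common & set(comp)
        if common is not None and not common:
            removed.append(c)
        else:
            kept.append(c)
    if removed:
        logger.info("location filter removed %d of %d complexes", len(removed), len(removed) + len(kept))
    return kept, removed
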