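"""Context-dependent complexome analytics.

Tools for comparing complexome predictions across conditions (tissues,
drug treatments, perturbed abundances), for computing the specificity of
a protein for a complex, and for ranking complex members as candidate
pull-down baits.

Specificity of protein *i* in complex *c* is ``S_i^c = A_i^c / A_i``:
the fraction of the protein's total copies found in simulated complexes
assigned to refined complex *c*.  Highly specific, reasonably abundant
members are the best bait candidates for co-IP / TAP experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .metrics import overlap_score
from .refine import RefinedComplex

logger = logging.getLogger(__name__)

__all__ = [
    "ConditionComparison",
    "SpecificityRecord",
    "compare_conditions",
    "protein_specificity",
    "rank_baits",
    "roc_curve",
]


@dataclass
class ConditionComparison:
    """Cross-condition clusters of structurally similar refined complexes."""

    conditions: list[str]
    table: pd.DataFrame  # one row per cluster, sorted by cv descending
    clusters: list[dict]  # cluster id -> per-condition member RCs

    def condition_specific(self) -> pd.DataFrame:
        return self.table[self.table["condition_specific"]]


@dataclass
class SpecificityRecord:
    protein: str
    complex_id: str
    abundance_in_complex: float  # A_i^c
    total_abundance: float  # A_i
    specificity: float  # S_i^c = A_i^c / A_i


def compare_conditions(
    results: list[tuple[str, list[RefinedComplex]]],
    match_threshold: float = 0.5,
    min_mean_abundance: float = 25.0,
) -> ConditionComparison:
    """Cluster refined complexes across conditions and rank by variability.

    Single-linkage clustering joins any two RCs (within or across
    conditions) whose overlap exceeds ``match_threshold``.  Each
    cluster's abundance vector over conditions (absent condition = 0) is
    summarized by its coefficient of variation (population std / mean)
    and clusters are sorted by cv descending.

    The cv of a cluster counted from only a handful of simulated
    complexes is dominated by counting noise (a Poisson count of mean n
    fluctuates with relative error ~ 1/sqrt(n), which already mimics a
    2-fold change near n ≈ 10), so clusters whose mean abundance falls
    below ``min_mean_abundance`` are kept in the table but flagged
    ``low_abundance`` and ranked after the substantial clusters.
    """
    if len(results) < 2:
        raise ValueError("compare_conditions needs at least two conditions")
    labels = [lab for lab, _ in results]
    if len(set(labels)) != len(labels):
        raise ValueError("condition labels must be unique")

    flat: list[tuple[int, RefinedComplex]] = []
    for ci, (_, rcs) in enumerate(results):
        flat.extend((ci, rc) for rc in rcs)
    n = len(flat)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if overlap_score(flat[i][1].members, flat[j][1].members) > match_threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    rows = []
    clusters = []
    for k, idxs in enumerate(sorted(groups.values(), key=lambda g: min(g))):
        abundance = np.zeros(len(labels))
        member_union: set[str] = set()
        member_sets: list[frozenset] = []
        per_condition: dict[str, list[str]] = {lab: [] for lab in labels}
        for i in idxs:
            ci, rc = flat[i]
            abundance[ci] += rc.abundance
            member_union |= rc.members
            member_sets.append(rc.members)
            per_condition[labels[ci]].append(rc.id)
        mean = abundance.mean()
        cv = float(abundance.std() / mean) if mean > 0 else 0.0
        common = frozenset.intersection(*member_sets) if member_sets else frozenset()
        rows.append(
            {
                "cluster": k,
                "members": ";".join(sorted(member_union)),
                **{f"abundance[{lab}]": abundance[ci] for ci, lab in enumerate(labels)},
                "cv": cv,
                "low_abundance": bool(mean < min_mean_abundance),
                "condition_specific": bool((abundance == 0).any()),
                "structural_difference": ";".join(sorted(member_union - common)),
            }
        )
        clusters.append({"cluster": k, "rcs": per_condition, "members": sorted(member_union)})

    table = (
        pd.DataFrame(rows)
        .sort_values(["low_abundance", "cv", "cluster"], ascending=[True, False, True])
        .reset_index(drop=True)
    )
    return ConditionComparison(conditions=labels, table=table, clusters=clusters)


def protein_specificity(
    rcs: list[RefinedComplex],
    scs,
    model,
    n_samples: int = 1,
) -> list[SpecificityRecord]:
    """Per-(protein, complex) specificity records from quantified predictions.

    ``A_i^c`` counts copies of protein *i* over all simulated complexes
    assigned to RC *c*, divided by ``n_samples`` (so that it is on the
    same per-snapshot scale as the model's copy numbers ``A_i``).
    Proteins with zero total abundance are skipped with a warning.
    """
    abundances = model.abundances() if hasattr(model, "abundances") else dict(model)
    sc_by_id = {sc.id: sc for sc in scs}
    records = []
    for rc in rcs:
        counts: dict[str, float] = {}
        for scid in rc.assigned_sc_ids:
            for sp, k in sc_by_id[scid].stoichiometry.items():
                counts[sp] = counts.get(sp, 0.0) + k
        for prot in sorted(counts):
            a_ic = counts[prot] / max(1, n_samples)
            a_i = float(abundances.get(prot, 0.0))
            if a_i <= 0:
                logger.warning(
                    "protein %r has zero total abundance; specificity for %s skipped",
                    prot, rc.id,
                )
                continue
            records.append(
                SpecificityRecord(
                    protein=prot,
                    complex_id=rc.id,
                    abundance_in_complex=a_ic,
                    total_abundance=a_i,
                    specificity=a_ic / a_i,
                )
            )
    return records


def rank_baits(
    rc: RefinedComplex,
    specificity_records: list[SpecificityRecord],
    model,
    ppi,
) -> pd.DataFrame:
    """Rank the members of one refined complex as candidate baits.

    Sorted by specificity descending; ties broken by higher abundance,
    then by lower PPI degree (hub proteins make unspecific baits).
    """
    spec = {
        r.protein: r.specificity
        for r in specificity_records
        if r.complex_id == rc.id
    }
    if not spec:
        raise ValueError(f"no specificity record for any member of {rc.id}")
    abundances = model.abundances() if hasattr(model, "abundances") else dict(model)
    degree = ppi.degree() if hasattr(ppi, "degree") else dict(ppi)
    rows = [
        {
            "protein": p,
            "specificity": spec.get(p, 0.0),
            "abundance": float(abundances.get(p, 0.0)),
            "degree": int(degree.get(p, 0)),
        }
        for p in sorted(rc.members)
    ]
    df = pd.DataFrame(rows).sort_values(
        ["specificity", "abundance", "degree", "protein"],
        ascending=[False, False, True, True],
    )
    df.insert(0, "rank", range(1, len(df) + 1))
    return df.reset_index(drop=True)


def roc_curve(scores, labels) -> tuple[np.ndarray, float]:
    """ROC points (fpr, tpr) by descending score and the trapezoidal AUC.

    Tied scores move the threshold simultaneously.  Both classes must be
    present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("roc_curve needs both positive and negative labels")
    fpr, tpr, _ = _skm.roc_curve(labels, scores)
    auc = float(_skm.auc(fpr, tpr))
    return np.column_stack([fpr, tpr]), auc
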