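"""Evaluation-metric unit and property tests.

The exact values asserted here were computed independently by hand or by
the brute-force oracles defined below (naive double-loop Sn/PPV,
exhaustive matching enumeration for MMR).
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from complexome.metrics import (
    MatchConfig,
    composite_score,
    contingency_table,
    filter_location_consistent,
    mmr,
    overlap_score,
    recall,
    sensitivity_ppv_accuracy,
)

# -- brute-force oracles ----------------------------------------------------


def naive_sn_ppv(refs, preds):
    """Direct double-loop evaluation of the clustering-wise Sn and PPV."""
    t = [[len(b & p) for p in preds] for b in refs]
    sn_num = sum(len(b) * max(t[i][j] / len(b) for j in range(len(preds)))
                 for i, b in enumerate(refs))
    sn = sn_num / sum(len(b) for b in refs)
    ppv_num = ppv_den = 0.0
    for j in range(len(preds)):
        col = sum(t[i][j] for i in range(len(refs)))
        if col == 0:
            continue
        ppv_num += col * max(t[i][j] / col for i in range(len(refs)))
        ppv_den += col
    ppv = ppv_num / ppv_den if ppv_den else 0.0
    return sn, ppv


def brute_force_mmr(preds, refs):
    """Exhaustive enumeration of all injective prediction→reference matchings."""
    w = [[overlap_score(p, b) for b in refs] for p in preds]
    k = min(len(preds), len(refs))
    best = 0.0
    for rows in itertools.permutations(range(len(preds)), k):
        for cols in itertools.permutations(range(len(refs)), k):
            best = max(best, sum(w[r][c] for r, c in zip(rows, cols)))
    return best / len(refs)


def random_sets(rng, n, universe=10, max_size=5):
    out = []
    for _ in range(n):
        size = int(rng.integers(1, max_size + 1))
        out.append(frozenset(f"p{k}" for k in rng.choice(universe, size, replace=False)))
    return out


# -- overlap ----------------------------------------------------------------


@pytest.mark.parametrize(
    "p, r, expected",
    [
        ({"A", "B", "C"}, {"A", "B", "C"}, 1.0),
        ({"A", "B"}, {"C", "D"}, 0.0),
        ({"A", "B", "C"}, {"A", "B", "D"}, 4 / 9),
        ({"A", "B", "C", "D"}, {"A", "B", "C", "E"}, 9 / 16),
        ({"A", "B", "C"}, {"A", "D", "E"}, 1 / 9),
    ],
)
def test_overlap_examples(p, r, expected):
    assert overlap_score(p, r) == pytest.approx(expected)


def test_overlap_rejects_empty_sets():
    with pytest.raises(ValueError):
        overlap_score(set(), {"A"})


@given(
    p=st.sets(st.integers(0, 12), min_size=1, max_size=6),
    r=st.sets(st.integers(0, 12), min_size=1, max_size=6),
)
@settings(deadline=None, derandomize=True)
def test_overlap_symmetry_range_identity(p, r):
    p = frozenset(map(str, p))
    r = frozenset(map(str, r))
    o = overlap_score(p, r)
    assert o == pytest.approx(overlap_score(r, p))
    assert 0.0 <= o <= 1.0
    assert (o == 1.0) == (p == r)
    assert (o == 0.0) == (not p & r)


# -- recall -----------------------------------------------------------------


def test_recall_counts_strict_matches():
    refs = [{"A", "B", "C", "D"}, {"E", "F", "G"}, {"H", "I", "J", "K"}]
    preds = [{"A", "B", "C", "D", "X", "Y", "Z", "W"},  # overlap 16/32 = 0.5 to refs[0]
             {"E", "X"},                                # 1/6 to refs[1]
             {"H", "X", "Y", "Z"}]                      # 1/16 to refs[2]
    assert recall(preds, refs, omega=0.25) == pytest.approx(1 / 3)


def test_recall_perfect_prediction():
    refs = [{"A", "B"}, {"C", "D", "E"}]
    assert recall(refs, refs, omega=0.25) == 1.0


def test_recall_boundary_is_strict():
    # overlap exactly 0.25: |p ∩ r| = 1, |p| = 2, |r| = 2
    refs = [{"A", "B"}]
    preds = [{"A", "C"}]
    assert overlap_score(preds[0], refs[0]) == pytest.approx(0.25)
    assert recall(preds, refs, omega=0.25) == 0.0


def test_recall_monotone_in_omega(rng):
    preds = random_sets(rng, 8)
    refs = random_sets(rng, 6)
    values = [recall(preds, refs, omega=w) for w in np.linspace(0.05, 0.95, 10)]
    assert all(a >= b for a, b in zip(values, values[1:]))


# -- Sn / PPV / accuracy ----------------------------------------------------


def test_worked_toy_sn_ppv_accuracy():
    refs = [{"A", "B", "C"}, {"D", "E"}]
    preds = [{"A", "B"}, {"D", "E", "F"}]
    sn, ppv, acc = sensitivity_ppv_accuracy(contingency_table(preds, refs))
    assert sn == pytest.approx(0.8)
    assert ppv == pytest.approx(1.0)
    assert acc == pytest.approx(np.sqrt(0.8))


def test_identity_prediction_scores_one():
    refs = [{"A", "B", "C"}, {"D", "E"}]
    sn, ppv, acc = sensitivity_ppv_accuracy(contingency_table(refs, refs))
    assert (sn, ppv, acc) == (1.0, 1.0, 1.0)


def test_lumped_prediction_penalized_by_ppv():
    refs = [{"A", "B", "C"}, {"D", "E"}]
    preds = [{"A", "B", "C", "D", "E"}]
    sn, ppv, _ = sensitivity_ppv_accuracy(contingency_table(preds, refs))
    assert sn == 1.0
    assert ppv < 1.0


def test_all_zero_table_raises():
    refs = [{"A", "B"}]
    preds = [{"X", "Y"}]
    with pytest.raises(ValueError):
        sensitivity_ppv_accuracy(contingency_table(preds, refs))


def test_sn_ppv_match_naive_double_loop(rng):
    for _ in range(300):
        refs = random_sets(rng, int(rng.integers(1, 6)))
        preds = random_sets(rng, int(rng.integers(1, 6)))
        table = contingency_table(preds, refs)
        if not np.any(table.t):
            continue
        sn, ppv, acc = sensitivity_ppv_accuracy(table)
        sn0, ppv0 = naive_sn_ppv(refs, preds)
        assert sn == pytest.approx(sn0)
        assert ppv == pytest.approx(ppv0)
        assert acc == pytest.approx(np.sqrt(sn0 * ppv0))


# -- MMR --------------------------------------------------------------------


def test_mmr_beats_greedy_on_crossing_instance():
    # o(p1,b1) = 9/15 = 0.6 is the single largest overlap, but the optimal
    # matching crosses: p1-b2 (4/10) + p2-b1 (4/9) = 0.844 > 0.6 + 0
    b1, b2 = {"1", "2", "3"}, {"4", "5"}
    p1, p2 = {"1", "2", "3", "4", "5"}, {"1", "2", "x"}
    assert overlap_score(p1, b1) == pytest.approx(0.6)
    expected = (4 / 10 + 4 / 9) / 2
    assert mmr([p1, p2], [b1, b2]) == pytest.approx(expected)
    assert brute_force_mmr([p1, p2], [b1, b2]) == pytest.approx(expected)


def test_mmr_identity_and_disjoint():
    refs = [{"A", "B"}, {"C", "D", "E"}]
    assert mmr(refs, refs) == 1.0
    assert mmr([{"X", "Y"}], refs) == 0.0


def test_mmr_equals_exhaustive_enumeration(rng):
    for _ in range(300):
        refs = random_sets(rng, int(rng.integers(1, 5)))
        preds = random_sets(rng, int(rng.integers(1, 5)))
        assert mmr(preds, refs) == pytest.approx(brute_force_mmr(preds, refs))


# -- composite --------------------------------------------------------------


def test_composite_of_worked_toy():
    refs = [{"A", "B", "C"}, {"D", "E"}]
    preds = [{"A", "B"}, {"D", "E", "F"}]
    rep = composite_score(preds, refs, omega=0.25)
    assert rep.recall == 1.0
    assert rep.mmr == pytest.approx(2 / 3)
    assert rep.accuracy == pytest.approx(np.sqrt(0.8))
    assert rep.composite == pytest.approx(1.0 + 2 / 3 + np.sqrt(0.8))


def test_composite_perfect_and_disjoint():
    refs = [{"A", "B"}, {"C", "D", "E"}]
    assert composite_score(refs, refs).composite == pytest.approx(3.0)
    rep = composite_score([{"X", "Y"}], refs)
    assert rep.composite == 0.0
    assert rep.accuracy == 0.0


def test_match_config_validates_omega():
    with pytest.raises(ValueError):
        MatchConfig(omega=1.5)


# -- location filter --------------------------------------------------------


def test_location_filter_rules():
    comp = {
        "N1": {"nucleus"},
        "NC": {"nucleus", "cytoplasm"},
        "M1": {"mitochondrion"},
    }
    kept, removed = filter_location_consistent(
        [{"N1", "NC"}, {"N1", "M1"}, {"N1", "unknown"}], comp
    )
    assert {frozenset(c) for c in kept} == {
        frozenset({"N1", "NC"}),
        frozenset({"N1", "unknown"}),  # unannotated member treated as ubiquitous
    }
    assert [set(c) for c in removed] == [{"N1", "M1"}]
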