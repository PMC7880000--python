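"""The dependency statistic against hand arithmetic and a brute-force oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import trials_from_matrix
from eventdep.dependency import (
    COMMON_CUE,
    COMMON_TARGET,
    TABLE_COLUMNS,
    TABLE_SPECS,
    ContingencyTable,
    DependencyError,
    TableSpec,
    build_contingency_tables,
    dependency_from_matrix,
    dependency_score,
    independent_joint,
    joint_proportion,
    score_participants,
)
from eventdep.design import DIRECTIONS


def naive_dependency(correct):
    """Independent re-implementation: loop over tables and events with
    plain Python arithmetic. Kept deliberately naive as the oracle."""
    correct = [[bool(v) for v in row] for row in correct]
    n = len(correct)
    data_props, indep_props = [], []
    for spec in TABLE_SPECS:
        i, j = TABLE_COLUMNS[(spec.kind, spec.anchor_role)]
        both = sum(1 for row in correct if row[i] == row[j])
        p1 = sum(1 for row in correct if row[i]) / n
        p2 = sum(1 for row in correct if row[j]) / n
        data_props.append(both / n)
        indep_props.append(p1 * p2 + (1 - p1) * (1 - p2))
    return sum(data_props) / 6 - sum(indep_props) / 6


# Hand-enumerated 4-event toy pattern (columns ordered as DIRECTIONS:
# a>o, a>l, o>a, o>l, l>a, l>o); expected cells worked out on paper.
TOY_MATRIX = [
    [1, 1, 1, 1, 1, 1],
    [1, 0, 0, 1, 0, 1],
    [0, 0, 1, 0, 1, 0],
    [0, 1, 1, 0, 0, 0],
]
TOY_EXPECTED_CELLS = {
    (COMMON_CUE, "animal"): (1, 1, 1, 1),
    (COMMON_CUE, "object"): (1, 2, 1, 0),
    (COMMON_CUE, "location"): (1, 1, 1, 1),
    (COMMON_TARGET, "animal"): (2, 1, 0, 1),
    (COMMON_TARGET, "object"): (2, 0, 0, 2),
    (COMMON_TARGET, "location"): (1, 1, 1, 1),
}


def make_table(n11, n10, n01, n00, spec=None):
    return ContingencyTable(spec or TABLE_SPECS[0], n11, n10, n01, n00)


class TestTableStatistics:
    @pytest.mark.parametrize(
        "cells,expected",
        [((8, 2, 1, 4), 12 / 15), ((15, 0, 0, 0), 1.0), ((3, 3, 3, 3), 0.5)],
    )
    def test_joint_proportion(self, cells, expected):
        assert joint_proportion(make_table(*cells)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((8, 2, 1, 4), (2 / 3) * (3 / 5) + (1 / 3) * (2 / 5)),
            ((15, 0, 0, 0), 1.0),  # P_AB = P_AC = 1
            ((5, 5, 5, 5), 0.5),  # symmetry point P = 0.5
        ],
    )
    def test_independent_joint(self, cells, expected):
        assert independent_joint(make_table(*cells)) == pytest.approx(expected)

    def test_empty_table_is_undefined(self):
        with pytest.raises(DependencyError):
            joint_proportion(make_table(0, 0, 0, 0))
        with pytest.raises(DependencyError):
            independent_joint(make_table(0, 0, 0, 0))

    def test_dependency_score_toy_table(self):
        tables = [ContingencyTable(spec, 8, 2, 1, 4) for spec in TABLE_SPECS]
        result = dependency_score(tables)
        assert result.joint_data == pytest.approx(0.8)
        assert result.joint_independent == pytest.approx(0.5333333333)
        assert result.dependency == pytest.approx(0.8 - 0.5333333333)

    def test_dependency_score_requires_all_six_specs(self):
        tables = [ContingencyTable(TABLE_SPECS[0], 8, 2, 1, 4)] * 6
        with pytest.raises(DependencyError):
            dependency_score(tables)


class TestContingencyTables:
    def test_toy_pattern_matches_hand_enumeration(self):
        trials = trials_from_matrix(TOY_MATRIX)
        tables = build_contingency_tables(trials)
        by_spec = {(t.spec.kind, t.spec.anchor_role): t for t in tables}
        for key, (n11, n10, n01, n00) in TOY_EXPECTED_CELLS.items():
            t = by_spec[key]
            assert (t.n11, t.n10, t.n01, t.n00) == (n11, n10, n01, n00)

    def test_cells_sum_to_event_count(self, rng):
        mat = rng.random((15, 6)) < 0.6
        tables = build_contingency_tables(trials_from_matrix(mat))
        assert all(t.included_events == 15 for t in tables)
        assert len(tables) == 6

    def test_all_correct_gives_degenerate_tables(self):
        tables = build_contingency_tables(trials_from_matrix(np.ones((15, 6))))
        assert all((t.n11, t.n10, t.n01, t.n00) == (15, 0, 0, 0) for t in tables)

    def test_event_exclusion_drops_event_from_all_tables(self, rng):
        mat = rng.random((15, 6)) < 0.6
        tables = build_contingency_tables(trials_from_matrix(mat), included_event_ids=range(1, 14))
        assert all(t.included_events == 13 for t in tables)

    def test_missing_direction_is_named(self):
        trials = trials_from_matrix(np.ones((2, 6)))
        trials = trials.drop(trials.index[3])  # event 1, object>location
        with pytest.raises(DependencyError, match="event 1.*object->location"):
            build_contingency_tables(trials)

    def test_unresolved_missing_correctness_refused(self):
        mat = np.ones((2, 6))
        mat[0, 0] = np.nan
        with pytest.raises(DependencyError, match="missing correctness"):
            build_contingency_tables(trials_from_matrix(mat))


class TestDependencyEquivalence:
    def test_degenerate_participants_have_zero_dependency(self):
        for mat in (np.ones((15, 6)), np.zeros((15, 6))):
            result = dependency_score(build_contingency_tables(trials_from_matrix(mat)))
            assert result.dependency == 0.0

    def test_matrix_path_equals_table_path(self, rng):
        for _ in range(20):
            mat = rng.random((9, 6)) < rng.uniform(0.2, 0.9)
            via_tables = dependency_score(build_contingency_tables(trials_from_matrix(mat)))
            _, _, d = dependency_from_matrix(mat)
            assert float(d) == pytest.approx(via_tables.dependency, abs=1e-12)

    def test_exhaustive_two_event_oracle(self):
        # all 2^12 correctness assignments of a 2-event participant
        patterns = np.array(list(itertools.product([0, 1], repeat=12)), dtype=bool)
        mats = patterns.reshape(-1, 2, 6)
        _, _, d = dependency_from_matrix(mats)
        expected = np.array([naive_dependency(m) for m in mats])
        np.testing.assert_allclose(d, expected, atol=1e-12)

    def test_joint_proportions_stay_in_unit_interval(self, rng):
        mats = rng.random((200, 12, 6)) < rng.uniform(0.05, 0.95, size=(200, 1, 1))
        jd, ji, d = dependency_from_matrix(mats)
        assert np.all((jd >= 0) & (jd <= 1))
        assert np.all((ji >= 0) & (ji <= 1))
        # per-table lower bound: pq + (1-p)(1-q) >= 2*min(p,1-p)*min(q,1-q)
        for mat in mats[:10]:
            for t in build_contingency_tables(trials_from_matrix(mat)):
                p, q = t.p_first, t.p_second
                assert independent_joint(t) >= 2 * min(p, 1 - p) * min(q, 1 - q) - 1e-12
                # Frechet bounds on the both-correct cell given the marginals
                n, n11 = t.included_events, t.n11
                assert max(0, (p + q - 1) * n) - 1e-9 <= n11 <= min(p, q) * n + 1e-9

    def test_joint_row_permutation_invariance(self, rng):
        mat = rng.random((12, 6)) < 0.6
        _, _, d0 = dependency_from_matrix(mat)
        perm = rng.permutation(12)
        _, _, d1 = dependency_from_matrix(mat[perm])
        assert float(d1) == pytest.approx(float(d0))

    def test_shuffling_one_direction_destroys_dependency(self, rng):
        # strong dependency: events succeed or fail wholesale
        bound = rng.random(600) < 0.5
        mat = np.repeat(bound[:, None], 6, axis=1) | (rng.random((600, 6)) < 0.05)
        _, _, d_orig = dependency_from_matrix(mat)
        assert float(d_orig) > 0.2
        shuffled_ds = []
        for _ in range(50):
            m = np.column_stack([mat[rng.permutation(600), j] for j in range(6)])
            _, _, d = dependency_from_matrix(m)
            shuffled_ds.append(float(d))
        # breaking the event pairing leaves only sampling noise around 0
        assert abs(np.mean(shuffled_ds)) < 0.01
        assert np.mean(shuffled_ds) < float(d_orig) / 10


class TestScoreParticipants:
    def test_scores_two_participants(self, rng):
        frames = []
        for pid in ("p1", "p2"):
            mat = rng.random((15, 6)) < 0.6
            frames.append(trials_from_matrix(mat, participant_id=pid))
        scores = score_participants(pd.concat(frames, ignore_index=True))
        assert len(scores) == 2
        assert set(scores["participant_id"]) == {"p1", "p2"}
        assert scores["included_events"].eq(15).all()
        assert {"joint_data", "joint_independent", "dependency"} <= set(scores.columns)
        assert (scores["dependency"] == scores["joint_data"] - scores["joint_independent"]).all()
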