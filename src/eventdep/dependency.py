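"""The retrieval-dependency statistic.

For one participant and condition, every event contributes six retrieval
trials (each pairwise association tested in both directions). Trials are
grouped into six 2x2 contingency tables — one per role used as a *common
cue* (e.g. cued by the animal, retrieve the object / retrieve the location)
and one per role used as a *common target* (e.g. retrieve the animal when
cued by the object / by the location). Each table cross-classifies, over
events, the correctness of its two retrieval directions.

Per table, the proportion of *contingent* responses (both correct or both
incorrect) is compared with the proportion expected under independence
given the table's marginal accuracies P_AB and P_AC:

    independent joint = P_AB * P_AC + (1 - P_AB) * (1 - P_AC)

The dependency score D is the mean contingent proportion minus the mean
independent-model proportion, averaged over the six tables. Positive D
indicates that within-event associations succeed and fail together beyond
what overall accuracy predicts — the behavioural signature of holistic
retrieval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import DIRECTIONS, ROLES

COMMON_CUE = "common_cue"
COMMON_TARGET = "common_target"


class DependencyError(ValueError):
    """Input violates the contracts of the dependency computation."""


@dataclass(frozen=True)
class TableSpec:
    """Identity of one of the six contingency tables."""

    kind: str  # COMMON_CUE or COMMON_TARGET
    anchor_role: str

    def __post_init__(self) -> None:
        if self.kind not in (COMMON_CUE, COMMON_TARGET):
            raise DependencyError(f"unknown table kind {self.kind!r}")
        if self.anchor_role not in ROLES:
            raise DependencyError(f"unknown role {self.anchor_role!r}")

    @property
    def label(self) -> str:
        return f"{self.kind}_{self.anchor_role}"


#: The six table specs in canonical order (3 common-cue, then 3 common-target).
TABLE_SPECS: tuple[TableSpec, ...] = tuple(
    TableSpec(kind, role) for kind in (COMMON_CUE, COMMON_TARGET) for role in ROLES
)

#: Direction-column indices (into DIRECTIONS) of each table's two trials.
#: Columns: 0 animal>object, 1 animal>location, 2 object>animal,
#: 3 object>location, 4 location>animal, 5 location>object.
TABLE_COLUMNS: dict[tuple[str, str], tuple[int, int]] = {
    (COMMON_CUE, "animal"): (0, 1),
    (COMMON_CUE, "object"): (2, 3),
    (COMMON_CUE, "location"): (4, 5),
    (COMMON_TARGET, "animal"): (2, 4),
    (COMMON_TARGET, "object"): (0, 5),
    (COMMON_TARGET, "location"): (1, 3),
}

_DIRECTION_INDEX = {d: i for i, d in enumerate(DIRECTIONS)}


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 cross-classification over events of two retrieval directions.

    ``n11`` counts events where both directions were correct, ``n10`` where
    only the first was, ``n01`` only the second, ``n00`` neither.
    """

    spec: TableSpec
    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise DependencyError("cell counts must be non-negative")

    @property
    def included_events(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def p_first(self) -> float:
        """Marginal accuracy of the first direction (P_AB)."""
        return (self.n11 + self.n10) / self.included_events

    @property
    def p_second(self) -> float:
        """Marginal accuracy of the second direction (P_AC)."""
        return (self.n11 + self.n01) / self.included_events


@dataclass(frozen=True)
class DependencyResult:
    """Per-participant-condition dependency and its components.

    ``dependency = joint_data - joint_independent``, each side the mean of
    the six per-table proportions.
    """

    joint_data: float
    joint_independent: float
    dependency: float
    per_table: tuple[tuple[TableSpec, float, float], ...]


def correctness_matrix(
    trials: pd.DataFrame, included_event_ids: Iterable[int] | None = None
) -> tuple[np.ndarray, list[int]]:
    """Pivot one participant-condition's retrieval trials to an events x 6
    boolean matrix, columns ordered as :data:`~eventdep.design.DIRECTIONS`.

    ``trials`` needs columns event_id, cue_role, target_role, correct, with
    correctness already resolved to 0/1 (screening's job).
    """
    if trials["correct"].isna().any():
        raise DependencyError(
            "unresolved missing correctness; run screening.resolve_timeouts first"
        )
    event_ids = sorted(
        set(trials["event_id"])
        if included_event_ids is None
        else set(included_event_ids)
    )
    index = {eid: i for i, eid in enumerate(event_ids)}
    mat = np.full((len(event_ids), 6), -1, dtype=np.int8)
    for row in trials.itertuples(index=False):
        if row.event_id not in index:
            continue  # excluded event
        col = _DIRECTION_INDEX.get((row.cue_role, row.target_role))
        if col is None:
            raise DependencyError(
                f"unknown direction ({row.cue_role!r}, {row.target_role!r})"
            )
        mat[index[row.event_id], col] = int(row.correct)
    if (mat < 0).any():
        eid_idx, col = np.argwhere(mat < 0)[0]
        raise DependencyError(
            f"event {event_ids[eid_idx]} is missing direction "
            f"{DIRECTIONS[col][0]}->{DIRECTIONS[col][1]}"
        )
    return mat.astype(bool), event_ids


def build_contingency_tables(
    trials: pd.DataFrame, included_event_ids: Iterable[int] | None = None
) -> list[ContingencyTable]:
    """The six contingency tables for one participant-condition.

    Every retrieval trial contributes to exactly one common-cue table (that
    of its cue role) and one common-target table (that of its target role).
    Events outside ``included_event_ids`` (when given) are dropped from all
    six tables alike.
    """
    mat, _ = correctness_matrix(trials, included_event_ids)
    tables = []
    for spec in TABLE_SPECS:
        i, j = TABLE_COLUMNS[(spec.kind, spec.anchor_role)]
        a, b = mat[:, i], mat[:, j]
        tables.append(
            ContingencyTable(
                spec=spec,
                n11=int(np.sum(a & b)),
                n10=int(np.sum(a & ~b)),
                n01=int(np.sum(~a & b)),
                n00=int(np.sum(~a & ~b)),
            )
        )
    return tables


def joint_proportion(table: ContingencyTable) -> float:
    """Observed proportion of contingent (both-correct or both-incorrect)
    events in one table."""
    if table.included_events == 0:
        raise DependencyError("joint proportion undefined for an empty table")
    return (table.n11 + table.n00) / table.included_events


def independent_joint(table: ContingencyTable) -> float:
    """Contingent proportion predicted from the table's marginals if the
    two retrievals were independent: P_AB*P_AC + (1-P_AB)*(1-P_AC)."""
    if table.included_events == 0:
        raise DependencyError("independent model undefined for an empty table")
    p, q = table.p_first, table.p_second
    return p * q + (1.0 - p) * (1.0 - q)


def dependency_score(tables: Sequence[ContingencyTable]) -> DependencyResult:
    """Average the data and independent-model joint proportions over the six
    tables and take their difference."""
    specs = sorted(t.spec.label for t in tables)
    if specs != sorted(s.label for s in TABLE_SPECS):
        raise DependencyError(
            f"expected exactly the six canonical tables, got {specs}"
        )
    per_table = tuple(
        (t.spec, joint_proportion(t), independent_joint(t)) for t in tables
    )
    joint_data = float(np.mean([jd for _, jd, _ in per_table]))
    joint_indep = float(np.mean([ji for _, _, ji in per_table]))
    return DependencyResult(
        joint_data=joint_data,
        joint_independent=joint_indep,
        dependency=joint_data - joint_indep,
        per_table=per_table,
    )


def dependency_from_matrix(correct: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised dependency over stacked participants.

    Parameters
    ----------
    correct : ndarray of bool, shape (..., n_events, 6)
        Correctness matrices with direction columns ordered as
        :data:`~eventdep.design.DIRECTIONS`; leading axes index
        participants/replicates.

    Returns
    -------
    joint_data, joint_independent, dependency : ndarray, shape (...)

    Identical to :func:`dependency_score` on the equivalent tables; this is
    the fast path used by the simulator-calibration and power machinery.
    """
    c = np.asarray(correct, dtype=bool)
    if c.shape[-1] != 6:
        raise DependencyError(f"last axis must have 6 directions, got {c.shape[-1]}")
    jd = np.zeros(c.shape[:-2])
    ji = np.zeros(c.shape[:-2])
    for spec in TABLE_SPECS:
        i, j = TABLE_COLUMNS[(spec.kind, spec.anchor_role)]
        a, b = c[..., i], c[..., j]
        jd += np.mean(a == b, axis=-1)
        p, q = np.mean(a, axis=-1), np.mean(b, axis=-1)
        ji += p * q + (1.0 - p) * (1.0 - q)
    jd /= len(TABLE_SPECS)
    ji /= len(TABLE_SPECS)
    return jd, ji, jd - ji


def score_participants(
    retrieval: pd.DataFrame,
    included_events: dict[tuple[str, str], Iterable[int]] | None = None,
) -> pd.DataFrame:
    """Dependency scores for every participant-condition in a trial table.

    Parameters
    ----------
    retrieval : DataFrame
        Long-format retrieval trials (resolved correctness) for any number
        of participants; columns participant_id, age_group, condition,
        event_id, cue_role, target_role, correct.
    included_events : dict, optional
        (participant_id, condition) -> event ids to keep, as produced by
        screening. Cells absent from the dict keep all their events; cells
        mapped to None are skipped (condition excluded).

    Returns
    -------
    DataFrame with one row per participant-condition: identifiers, number
    of included events, overall accuracy, joint proportions, dependency,
    and the six per-table dependency differences (diagnostics).
    """
    rows = []
    for (pid, cond), cell in retrieval.groupby(["participant_id", "condition"], sort=True):
        keep = None
        if included_events is not None and (pid, cond) in included_events:
            keep = included_events[(pid, cond)]
            if keep is None:
                continue
        tables = build_contingency_tables(cell, keep)
        result = dependency_score(tables)
        mat, event_ids = correctness_matrix(cell, keep)
        row = {
            "participant_id": pid,
            "age_group": cell["age_group"].iloc[0],
            "condition": cond,
            "included_events": len(event_ids),
            "accuracy": float(mat.mean()),
            "joint_data": result.joint_data,
            "joint_independent": result.joint_independent,
            "dependency": result.dependency,
        }
        for spec, jd, ji in result.per_table:
            row[f"dep_{spec.label}"] = jd - ji
        rows.append(row)
    if not rows:
        raise DependencyError("no participant-conditions to score")
    return pd.DataFrame(rows)
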