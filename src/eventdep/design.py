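"""Experimental design: events, encoding schedules, retrieval schedules.

The design this package models is a three-element event-memory experiment:
each *event* binds an animal, an object, and a location. Events are studied
either *simultaneously* (all three pictures at once) or *separated* (the
three pairwise associations shown in three different blocks), and every
within-event association is later tested in both cue-target directions with
a four-alternative forced choice, giving six retrieval trials per event.

Schedules are counterbalanced: in the separated encoding phase and in each
retrieval set, every block contains one trial per event and an equal number
of trials of each pair type (animal-object, animal-location,
object-location). With the default 15 events that is the familiar
3-blocks-of-15 layout with 5 trials of each pair type per block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: The three element roles, in canonical order.
ROLES: tuple[str, str, str] = ("animal", "object", "location")

#: The three unordered pair types, in canonical order.
PAIR_TYPES: tuple[tuple[str, str], ...] = (
    ("animal", "object"),
    ("animal", "location"),
    ("object", "location"),
)

#: All six ordered cue->target directions, in canonical order.
DIRECTIONS: tuple[tuple[str, str], ...] = (
    ("animal", "object"),
    ("animal", "location"),
    ("object", "animal"),
    ("object", "location"),
    ("location", "animal"),
    ("location", "object"),
)

SIMULTANEOUS = "simultaneous"
SEPARATED = "separated"
CONDITIONS = (SIMULTANEOUS, SEPARATED)


class DesignError(ValueError):
    """A schedule request violates the design's structural constraints."""


@dataclass(frozen=True)
class EventTriplet:
    """One event: an animal, an object and a location bound together.

    Parameters
    ----------
    event_id : int
        1-based identifier, unique within a list.
    list_id : int
        Which stimulus list (1 or 2) the event belongs to.
    elements : mapping
        Role -> element label, with exactly the three roles present.
    """

    event_id: int
    list_id: int
    elements: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.event_id < 1:
            raise DesignError(f"event_id must be >= 1, got {self.event_id}")
        if self.list_id not in (1, 2):
            raise DesignError(f"list_id must be 1 or 2, got {self.list_id}")
        if set(self.elements) != set(ROLES):
            raise DesignError(
                f"event {self.event_id}: elements must cover roles {ROLES}, "
                f"got {sorted(self.elements)}"
            )


@dataclass(frozen=True)
class DesignSpec:
    """Structural parameters of the experiment.

    ``n_events_per_condition`` must be divisible by 3 so that pair types can
    be split evenly across the three blocks of the separated encoding phase
    and of each retrieval set.
    """

    n_events_per_condition: int = 15
    n_foils: int = 3
    conditions: tuple[str, ...] = CONDITIONS

    def __post_init__(self) -> None:
        if self.n_events_per_condition < 0:
            raise DesignError("n_events_per_condition must be >= 0")
        if self.n_events_per_condition % 3 != 0:
            raise DesignError(
                "n_events_per_condition must be divisible by 3 for balanced "
                f"blocks, got {self.n_events_per_condition}"
            )
        if self.n_foils < 1:
            raise DesignError("n_foils must be >= 1")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise DesignError(f"unknown conditions: {sorted(unknown)}")

    @property
    def guess_floor(self) -> float:
        """Chance accuracy of the forced choice (0.25 for 4AFC)."""
        return 1.0 / (self.n_foils + 1)


@dataclass(frozen=True)
class EncodingTrialPlan:
    """One planned encoding trial.

    ``roles_shown`` has all three roles for simultaneous encoding and the
    two roles of one pairwise association for separated encoding.
    """

    event_id: int
    condition: str
    roles_shown: tuple[str, ...]
    block_index: int
    within_block_position: int

    def __post_init__(self) -> None:
        if self.condition == SIMULTANEOUS:
            if len(self.roles_shown) != 3 or self.block_index != 1:
                raise DesignError("simultaneous encoding shows all 3 roles in block 1")
        elif self.condition == SEPARATED:
            if len(self.roles_shown) != 2:
                raise DesignError("separated encoding shows exactly 2 roles")
        else:
            raise DesignError(f"unknown condition {self.condition!r}")


@dataclass(frozen=True)
class RetrievalTrialPlan:
    """One planned 4AFC retrieval trial (cue one role, choose the target)."""

    event_id: int
    cue_role: str
    target_role: str
    set_index: int
    block_index: int
    within_block_position: int

    def __post_init__(self) -> None:
        if self.cue_role == self.target_role:
            raise DesignError("cue_role and target_role must differ")
        if self.set_index not in (1, 2):
            raise DesignError("set_index must be 1 or 2")
        if self.block_index not in (1, 2, 3):
            raise DesignError("block_index must be in 1..3")


def default_vocabulary(design: DesignSpec, list_id: int) -> dict[str, list[str]]:
    """Generated element labels, one pool per role, sized to the design."""
    n = design.n_events_per_condition
    return {
        role: [f"{role}{list_id}_{i:02d}" for i in range(1, n + 1)] for role in ROLES
    }


def build_events(
    design: DesignSpec,
    list_id: int,
    rng_seed: int,
    vocabulary: Mapping[str, Sequence[str]] | None = None,
) -> list[EventTriplet]:
    """Randomly pair elements into fixed events.

    Each role's pool is shuffled independently and the pools are zipped, so
    every element is used exactly once. Deterministic for a fixed seed.

    Raises
    ------
    DesignError
        If any role's vocabulary is smaller than the number of events,
        naming the deficient role.
    """
    n = design.n_events_per_condition
    vocab = dict(vocabulary) if vocabulary is not None else default_vocabulary(design, list_id)
    for role in ROLES:
        pool = vocab.get(role, [])
        if len(pool) < n:
            raise DesignError(
                f"vocabulary for role {role!r} has {len(pool)} elements, "
                f"need {n}"
            )
    rng = np.random.default_rng(rng_seed)
    shuffled = {role: [vocab[role][i] for i in rng.permutation(len(vocab[role]))[:n]] for role in ROLES}
    return [
        EventTriplet(
            event_id=i + 1,
            list_id=list_id,
            elements={role: shuffled[role][i] for role in ROLES},
        )
        for i in range(n)
    ]


def _random_latin_square(rng: np.random.Generator) -> np.ndarray:
    """A uniformly random 3x3 Latin square over symbols {0, 1, 2}.

    Row, column and symbol permutations of the cyclic square reach all 12
    order-3 Latin squares.
    """
    row = rng.permutation(3)
    col = rng.permutation(3)
    sym = rng.permutation(3)
    return np.array([[sym[(row[g] + col[b]) % 3] for b in range(3)] for g in range(3)])


def _balanced_block_assignment(
    event_ids: Sequence[int], rng: np.random.Generator
) -> dict[tuple[int, int], tuple[str, str]]:
    """Assign one pair type per (event, block) so that every event covers all
    three pair types across the three blocks and every block holds an equal
    number of each pair type.

    Events are split into three equal groups; each group follows one row of
    a random 3x3 Latin square mapping block -> pair type.

    Returns a map (event_id, block_index 1..3) -> unordered pair type.
    """
    n = len(event_ids)
    if n % 3 != 0:
        raise DesignError(f"need a multiple of 3 events for balanced blocks, got {n}")
    order = [event_ids[i] for i in rng.permutation(n)]
    square = _random_latin_square(rng)
    assignment: dict[tuple[int, int], tuple[str, str]] = {}
    group_size = n // 3
    for g in range(3):
        for event_id in order[g * group_size : (g + 1) * group_size]:
            for b in range(3):
                assignment[(event_id, b + 1)] = PAIR_TYPES[square[g, b]]
    return assignment


def build_encoding_schedule(
    events: Sequence[EventTriplet], condition: str, rng_seed: int
) -> list[EncodingTrialPlan]:
    """Plan the encoding phase for one condition.

    Simultaneous: one trial per event (all three pictures), randomised
    order, a single block. Separated: three blocks, each containing one
    pairwise association per event, with pair types balanced within blocks
    and each event covering all three pair types across blocks.
    """
    if condition not in CONDITIONS:
        raise DesignError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(rng_seed)
    ids = [e.event_id for e in events]
    if condition == SIMULTANEOUS:
        order = [ids[i] for i in rng.permutation(len(ids))]
        return [
            EncodingTrialPlan(
                event_id=eid,
                condition=condition,
                roles_shown=ROLES,
                block_index=1,
                within_block_position=pos + 1,
            )
            for pos, eid in enumerate(order)
        ]
    assignment = _balanced_block_assignment(ids, rng)
    plans: list[EncodingTrialPlan] = []
    for block in (1, 2, 3):
        block_events = [ids[i] for i in rng.permutation(len(ids))]
        for pos, eid in enumerate(block_events):
            plans.append(
                EncodingTrialPlan(
                    event_id=eid,
                    condition=condition,
                    roles_shown=assignment[(eid, block)],
                    block_index=block,
                    within_block_position=pos + 1,
                )
            )
    return plans


def build_retrieval_schedule(
    events: Sequence[EventTriplet], rng_seed: int
) -> list[RetrievalTrialPlan]:
    """Plan the retrieval phase: six 4AFC trials per event.

    Set 1 tests every association once, in a direction randomised per event
    and pair; Set 2 repeats every association in the opposite direction.
    Within each set there are three blocks, each with one trial per event
    and pair types split evenly.
    """
    if not events:
        raise DesignError("events must be non-empty")
    rng = np.random.default_rng(rng_seed)
    ids = [e.event_id for e in events]
    # Direction of each pair in Set 1, per event; Set 2 reverses it.
    set1_direction: dict[tuple[int, tuple[str, str]], tuple[str, str]] = {}
    for eid in ids:
        for pair in PAIR_TYPES:
            set1_direction[(eid, pair)] = pair if rng.random() < 0.5 else pair[::-1]
    plans: list[RetrievalTrialPlan] = []
    for set_index in (1, 2):
        assignment = _balanced_block_assignment(ids, rng)
        for block in (1, 2, 3):
            block_events = [ids[i] for i in rng.permutation(len(ids))]
            for pos, eid in enumerate(block_events):
                pair = assignment[(eid, block)]
                cue, target = set1_direction[(eid, pair)]
                if set_index == 2:
                    cue, target = target, cue
                plans.append(
                    RetrievalTrialPlan(
                        event_id=eid,
                        cue_role=cue,
                        target_role=target,
                        set_index=set_index,
                        block_index=block,
                        within_block_position=pos + 1,
                    )
                )
    return plans
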