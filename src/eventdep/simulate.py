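"""Synthetic trial-level data from a latent-binding mixture model.

No generative model is published for this paradigm, so the package supplies
its own: each event is either *holistically bound* (with probability
``theta``) or not, and the latent state is shared by all six of the event's
retrieval trials. Given the state, trials succeed independently with
probability ``p_bound`` (bound) or ``p_unbound`` (unbound). The mixture
induces positive dependency between trials of the same event whenever
0 < theta < 1 and p_bound > p_unbound, while theta in {0, 1} collapses to a
single Bernoulli component and hence to independence.

The infinite-events dependency of this model has a closed form (see
:func:`expected_dependency`), which serves as the analytic oracle for the
whole pipeline: simulated cohorts must reproduce it as the number of events
grows.

Default cohort parameters emulate the study design this package analyses:
three age groups (57 six-to-seven-year-olds, 51 nine-to-ten-year-olds, 45
adults), 15 events per encoding condition, group accuracies near .48, .63
and .72, dependency near 0.04 after simultaneous encoding and near 0 after
separated encoding, a 4% response-timeout rate for adults and a 0.66%
encoding inattention-flag rate for children.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .design import (
    CONDITIONS,
    DesignSpec,
    SEPARATED,
    SIMULTANEOUS,
    build_encoding_schedule,
    build_events,
    build_retrieval_schedule,
)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class BindingParams:
    """Parameters of the latent-binding mixture.

    theta : probability an event is holistically bound.
    p_bound : per-trial success probability for bound events.
    p_unbound : per-trial success probability for unbound events.
    guess_floor : chance success rate of the forced choice (0.25 for 4AFC);
        a lower bound on ``p_unbound``.
    """

    theta: float
    p_bound: float
    p_unbound: float
    guess_floor: float = 0.25

    def __post_init__(self) -> None:
        for name in ("theta", "p_bound", "p_unbound", "guess_floor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {v}")
        if not self.p_bound >= self.p_unbound >= self.guess_floor:
            raise SimulationError(
                "require p_bound >= p_unbound >= guess_floor, got "
                f"{self.p_bound}, {self.p_unbound}, {self.guess_floor}"
            )

    @property
    def mean_accuracy(self) -> float:
        """Marginal per-trial accuracy theta*p_bound + (1-theta)*p_unbound."""
        return self.theta * self.p_bound + (1.0 - self.theta) * self.p_unbound


def expected_dependency(params: BindingParams) -> float:
    """Infinite-events limit of the dependency score under the mixture.

    With m the marginal accuracy, the contingent proportion in the data is
    theta*(p_b^2 + (1-p_b)^2) + (1-theta)*(p_u^2 + (1-p_u)^2) and the
    independent model converges to m^2 + (1-m)^2, so

        D_inf = 2 * theta * (1-theta) * (p_bound - p_unbound)^2

    which is 0 at theta in {0, 1} (single component implies independence).
    """
    t, pb, pu = params.theta, params.p_bound, params.p_unbound
    m = params.mean_accuracy
    joint = t * (pb**2 + (1 - pb) ** 2) + (1 - t) * (pu**2 + (1 - pu) ** 2)
    return joint - (m**2 + (1 - m) ** 2)


def binding_params_for(
    accuracy: float, dependency: float, theta: float = 0.5, guess_floor: float = 0.25
) -> BindingParams:
    """Solve for (p_bound, p_unbound) hitting a target marginal accuracy and
    infinite-events dependency at a given theta.

    Uses D = 2*theta*(1-theta)*(p_b - p_u)^2; with theta=0.5 the components
    sit symmetrically around the target accuracy.
    """
    if dependency < 0:
        raise SimulationError("target dependency must be >= 0")
    if dependency == 0 or theta in (0.0, 1.0):
        return BindingParams(theta=theta, p_bound=accuracy, p_unbound=accuracy,
                             guess_floor=guess_floor)
    delta = float(np.sqrt(dependency / (2 * theta * (1 - theta))))
    p_b = accuracy + (1 - theta) * delta
    p_u = accuracy - theta * delta
    return BindingParams(theta=theta, p_bound=p_b, p_unbound=p_u, guess_floor=guess_floor)


def simulate_correct_matrix(
    n_participants: int, n_events: int, params: BindingParams, rng: np.random.Generator
) -> np.ndarray:
    """Correctness matrices (n_participants, n_events, 6) from the mixture.

    One latent bound state per (participant, event), shared by the event's
    six retrieval directions.
    """
    bound = rng.random((n_participants, n_events)) < params.theta
    p = np.where(bound, params.p_bound, params.p_unbound)
    return rng.random((n_participants, n_events, 6)) < p[..., None]


def simulate_responses(
    schedule, params: BindingParams, rng_seed: int, timeout_rate: float = 0.0
) -> pd.DataFrame:
    """Complete a retrieval schedule under the mixture model.

    Returns one row per trial of the schedule with a ``correct`` column in
    {0.0, 1.0, NaN}; NaN marks timed-out (missing) responses, injected at
    ``timeout_rate`` after correctness is drawn. Deterministic per seed.
    """
    if not 0.0 <= timeout_rate <= 1.0:
        raise SimulationError("timeout_rate must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    event_ids = sorted({t.event_id for t in schedule})
    bound = {eid: rng.random() < params.theta for eid in event_ids}
    rows = []
    for trial in schedule:
        p = params.p_bound if bound[trial.event_id] else params.p_unbound
        correct: float = float(rng.random() < p)
        if timeout_rate and rng.random() < timeout_rate:
            correct = np.nan
        rows.append(
            {
                "event_id": trial.event_id,
                "cue_role": trial.cue_role,
                "target_role": trial.target_role,
                "set_index": trial.set_index,
                "block_index": trial.block_index,
                "within_block_position": trial.within_block_position,
                "correct": correct,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupSpec:
    """One age group of a simulated cohort."""

    n_participants: int
    params: Mapping[str, BindingParams]  # condition -> params
    attention_flag_rate: float = 0.0  # encoding trials (children)
    timeout_rate: float = 0.0  # retrieval responses (adults)

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise SimulationError("n_participants must be >= 1")
        for rate in (self.attention_flag_rate, self.timeout_rate):
            if not 0.0 <= rate <= 1.0:
                raise SimulationError("rates must be in [0, 1]")
        unknown = set(self.params) - set(CONDITIONS)
        if unknown:
            raise SimulationError(f"unknown conditions {sorted(unknown)}")


@dataclass(frozen=True)
class CohortSpec:
    """Full specification of a simulated multi-group cohort."""

    groups: Mapping[str, GroupSpec]
    design: DesignSpec = field(default_factory=DesignSpec)
    base_seed: int = 0
    #: condition -> stimulus list id; which fixed list serves which
    #: condition is left free by the design.
    list_for_condition: Mapping[str, int] = field(
        default_factory=lambda: {SIMULTANEOUS: 1, SEPARATED: 2}
    )


def default_cohort_spec(
    base_seed: int = 0,
    n_participants: Mapping[str, int] | None = None,
    simultaneous_dependency: float = 0.04,
    separated_dependency: float = 0.0,
) -> CohortSpec:
    """The study-shaped cohort: group sizes 57/51/45, accuracies
    .48/.63/.72, dependency ~0.04 simultaneous and ~0 separated, adult
    timeouts at 4%, child inattention flags at 0.66%."""
    sizes = {"6-7y": 57, "9-10y": 51, "adult": 45}
    if n_participants:
        sizes.update(n_participants)
    accuracies = {"6-7y": 0.48, "9-10y": 0.63, "adult": 0.72}
    timeout_rates = {"6-7y": 0.0, "9-10y": 0.0, "adult": 0.04}
    groups = {}
    for group, n in sizes.items():
        # timeouts are scored incorrect downstream, so the generative
        # accuracy must be higher for the observed accuracy to land on target
        acc = accuracies[group] / (1.0 - timeout_rates[group])
        groups[group] = GroupSpec(
            n_participants=n,
            params={
                SIMULTANEOUS: binding_params_for(acc, simultaneous_dependency),
                SEPARATED: binding_params_for(acc, separated_dependency, theta=0.0),
            },
            attention_flag_rate=0.0066 if group != "adult" else 0.0,
            timeout_rate=timeout_rates[group],
        )
    return CohortSpec(groups=groups, base_seed=base_seed)


def _participant_seed(base_seed: int, group_index: int, within_index: int) -> np.random.SeedSequence:
    # Deterministic, collision-free per participant; stable across runs.
    return np.random.SeedSequence(entropy=base_seed, spawn_key=(group_index, within_index))


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a full cohort to the long trial format.

    Emits encoding rows (with ``attended`` flags, correctness NaN) and
    retrieval rows (with ``correct`` in {0, 1, NaN}) for every participant
    and condition. Participant seeds derive deterministically from
    ``base_seed``, so the output is reproducible row for row.
    """
    design = spec.design
    events = {
        cond: build_events(design, spec.list_for_condition[cond], rng_seed=spec.base_seed + list_id)
        for cond, list_id in spec.list_for_condition.items()
    }
    frames = []
    seen_ids: set[str] = set()
    for g_idx, (group, gspec) in enumerate(sorted(spec.groups.items())):
        for i in range(gspec.n_participants):
            pid = f"{group}_p{i + 1:03d}"
            if pid in seen_ids:
                raise SimulationError(f"duplicate participant id {pid}")
            seen_ids.add(pid)
            seeds = _participant_seed(spec.base_seed, g_idx, i).generate_state(4)
            for c_idx, cond in enumerate(sorted(gspec.params)):
                params = gspec.params[cond]
                enc_seed = int(seeds[2 * c_idx] % (2**31))
                ret_seed = int(seeds[2 * c_idx + 1] % (2**31))
                rng = np.random.default_rng(ret_seed)
                enc = build_encoding_schedule(events[cond], cond, rng_seed=enc_seed)
                enc_rows = pd.DataFrame(
                    {
                        "event_id": [t.event_id for t in enc],
                        "cue_role": [
                            t.roles_shown[0] if len(t.roles_shown) == 2 else None
                            for t in enc
                        ],
                        "target_role": [
                            t.roles_shown[1] if len(t.roles_shown) == 2 else None
                            for t in enc
                        ],
                        "set_index": np.nan,
                        "block_index": [t.block_index for t in enc],
                        "within_block_position": [t.within_block_position for t in enc],
                        "correct": np.nan,
                        "attended": (
                            rng.random(len(enc)) >= gspec.attention_flag_rate
                        ).astype(float),
                    }
                )
                enc_rows.insert(0, "phase", "encoding")
                sched = build_retrieval_schedule(events[cond], rng_seed=enc_seed + 1)
                ret_rows = simulate_responses(
                    sched, params, rng_seed=ret_seed, timeout_rate=gspec.timeout_rate
                )
                ret_rows.insert(0, "phase", "retrieval")
                ret_rows["attended"] = np.nan
                cell = pd.concat([enc_rows, ret_rows], ignore_index=True)
                cell.insert(0, "condition", cond)
                cell.insert(0, "age_group", group)
                cell.insert(0, "participant_id", pid)
                frames.append(cell)
    return pd.concat(frames, ignore_index=True)
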