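"""Exclusion and data-cleaning rules applied before the dependency analysis.

Three rules, in order:

1. *Timeout resolution* — responses missing because of the response
   deadline are treated as incorrect (the default) or, optionally, the
   trial is dropped and its event becomes incomplete.
2. *Ceiling exclusion* — participants averaging 95% or above across their
   retrieval trials are removed entirely: near-perfect marginals make the
   dependency statistic uninformative.
3. *Attention filter* (optional, attended-only analysis) — events whose
   encoding trials carry any inattention flag are dropped from all six
   contingency tables; a participant-condition left with fewer than 10
   events is excluded outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

AS_INCORRECT = "as_incorrect"
DROP_TRIAL = "drop_trial"

# Machine-readable exclusion reason codes.
CEILING = "CEILING"
TOO_FEW_EVENTS = "TOO_FEW_EVENTS"
OPT_OUT = "OPT_OUT"

POOLED = "pooled"
PER_CONDITION = "per_condition"


class ScreeningError(ValueError):
    pass


@dataclass(frozen=True)
class ScreeningConfig:
    ceiling_threshold: float = 0.95
    min_included_events: int = 10
    timeout_policy: str = AS_INCORRECT
    attention_filter_enabled: bool = False
    #: whether the ceiling criterion pools both conditions (the default) or
    #: applies within each condition separately.
    ceiling_scope: str = POOLED

    def __post_init__(self) -> None:
        if not 0.0 < self.ceiling_threshold <= 1.0:
            raise ScreeningError("ceiling_threshold must be in (0, 1]")
        if self.min_included_events < 1:
            raise ScreeningError("min_included_events must be >= 1")
        if self.timeout_policy not in (AS_INCORRECT, DROP_TRIAL):
            raise ScreeningError(f"unknown timeout_policy {self.timeout_policy!r}")
        if self.ceiling_scope not in (POOLED, PER_CONDITION):
            raise ScreeningError(f"unknown ceiling_scope {self.ceiling_scope!r}")


@dataclass(frozen=True)
class Exclusion:
    """One exclusion with a single machine-readable reason code."""

    participant_id: str
    condition: str | None  # None = whole participant
    reason: str
    detail: str = ""


@dataclass
class ScreeningReport:
    exclusions: list[Exclusion] = field(default_factory=list)
    #: (participant_id, condition) -> sorted excluded event ids
    excluded_events: dict[tuple[str, str], list[int]] = field(default_factory=dict)
    n_timeouts_resolved: int = 0

    @property
    def excluded_participants(self) -> list[str]:
        return sorted({e.participant_id for e in self.exclusions if e.condition is None})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "participant_id": e.participant_id,
                    "condition": e.condition if e.condition is not None else "all",
                    "reason": e.reason,
                    "detail": e.detail,
                }
                for e in self.exclusions
            ],
            columns=["participant_id", "condition", "reason", "detail"],
        )


@dataclass
class ScreenedData:
    """Output of :func:`screen`: clean retrieval trials plus bookkeeping."""

    retrieval: pd.DataFrame
    #: (participant_id, condition) -> included event ids (None when the
    #: whole condition is excluded); only present when filtering applied.
    included_events: dict[tuple[str, str], list[int] | None]
    report: ScreeningReport


def resolve_timeouts(
    trials: pd.DataFrame, config: ScreeningConfig | None = None
) -> tuple[pd.DataFrame, int]:
    """Resolve missing retrieval correctness per the timeout policy.

    Returns the resolved trials and the number of conversions (or drops).
    """
    config = config or ScreeningConfig()
    trials = trials.copy()
    missing = trials["correct"].isna()
    n = int(missing.sum())
    if config.timeout_policy == AS_INCORRECT:
        trials.loc[missing, "correct"] = 0.0
    else:
        trials = trials.loc[~missing]
    return trials, n


def flag_ceiling_participants(
    retrieval: pd.DataFrame, config: ScreeningConfig | None = None
) -> list[Exclusion]:
    """Participants whose mean retrieval accuracy reaches the ceiling
    threshold (inclusive: '95% or above'), computed on resolved trials."""
    config = config or ScreeningConfig()
    if retrieval["correct"].isna().any():
        raise ScreeningError("resolve timeouts before the ceiling check")
    exclusions = []
    if config.ceiling_scope == POOLED:
        grouped = retrieval.groupby("participant_id")["correct"]
        for pid, acc in grouped.mean().items():
            if grouped.count()[pid] == 0:
                raise ScreeningError(f"participant {pid} has no retrieval trials")
            if acc >= config.ceiling_threshold:
                exclusions.append(
                    Exclusion(pid, None, CEILING, f"accuracy {acc:.3f}")
                )
    else:
        for (pid, cond), acc in (
            retrieval.groupby(["participant_id", "condition"])["correct"].mean().items()
        ):
            if acc >= config.ceiling_threshold:
                exclusions.append(
                    Exclusion(pid, cond, CEILING, f"accuracy {acc:.3f}")
                )
    return exclusions


def apply_attention_filter(
    encoding: pd.DataFrame,
    event_ids: Iterable[int],
    config: ScreeningConfig | None = None,
) -> tuple[list[int] | None, list[int]]:
    """Included event ids for one participant-condition after dropping any
    event with a flagged encoding trial.

    Returns ``(included, excluded)``; ``included`` is None when fewer than
    ``min_included_events`` events survive, i.e. the whole
    participant-condition is excluded.
    """
    config = config or ScreeningConfig()
    flagged = set(
        encoding.loc[encoding["attended"] == 0.0, "event_id"].astype(int)
    )
    included = sorted(set(event_ids) - flagged)
    excluded = sorted(set(event_ids) & flagged)
    if len(included) < config.min_included_events:
        return None, excluded
    return included, excluded


def screen(dataset: pd.DataFrame, config: ScreeningConfig | None = None) -> ScreenedData:
    """Run the full screening pipeline on a long-format trial table.

    Idempotent: screening an already-screened dataset changes nothing.
    """
    config = config or ScreeningConfig()
    report = ScreeningReport()
    retrieval = dataset.loc[dataset["phase"] == "retrieval"].copy()
    encoding = dataset.loc[dataset["phase"] == "encoding"]
    if retrieval.empty:
        raise ScreeningError("dataset contains no retrieval trials")

    retrieval, report.n_timeouts_resolved = resolve_timeouts(retrieval, config)

    ceiling = flag_ceiling_participants(retrieval, config)
    report.exclusions.extend(ceiling)
    drop_pids = {e.participant_id for e in ceiling if e.condition is None}
    drop_cells = {(e.participant_id, e.condition) for e in ceiling if e.condition}
    retrieval = retrieval.loc[~retrieval["participant_id"].isin(drop_pids)]
    if drop_cells:
        key = list(zip(retrieval["participant_id"], retrieval["condition"]))
        retrieval = retrieval.loc[[k not in drop_cells for k in key]]

    included: dict[tuple[str, str], list[int] | None] = {}
    if config.attention_filter_enabled or config.timeout_policy == DROP_TRIAL:
        for (pid, cond), cell in retrieval.groupby(["participant_id", "condition"]):
            event_ids = sorted(set(cell["event_id"].astype(int)))
            dropped: list[int] = []
            if config.timeout_policy == DROP_TRIAL:
                # events left without all six directions are uninterpretable
                counts = cell.groupby("event_id").size()
                incomplete = sorted(int(e) for e in counts.index[counts < 6])
                dropped.extend(incomplete)
                event_ids = [e for e in event_ids if e not in set(incomplete)]
            if config.attention_filter_enabled:
                enc = encoding.loc[
                    (encoding["participant_id"] == pid)
                    & (encoding["condition"] == cond)
                ]
                keep, flagged = apply_attention_filter(enc, event_ids, config)
                dropped.extend(flagged)
            else:
                keep = event_ids if len(event_ids) >= config.min_included_events else None
            if dropped:
                report.excluded_events[(pid, cond)] = sorted(set(dropped))
            included[(pid, cond)] = keep
            if keep is None:
                report.exclusions.append(
                    Exclusion(
                        pid,
                        cond,
                        TOO_FEW_EVENTS,
                        f"fewer than {config.min_included_events} events remain",
                    )
                )
    return ScreenedData(retrieval=retrieval, included_events=included, report=report)
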