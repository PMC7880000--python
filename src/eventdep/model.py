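"""Model/Results interface over the dependency pipeline.

:class:`RetrievalDependency` is constructed from a long-format trial table
(real or simulated); :meth:`RetrievalDependency.fit` screens the data,
computes per-participant dependency scores, and runs the permutation
contrasts, returning a :class:`RetrievalDependencyResults` whose
``summary()`` prints group descriptives and test results.

Example
-------
>>> from eventdep import RetrievalDependency, default_cohort_spec, simulate_cohort
>>> trials = simulate_cohort(default_cohort_spec(base_seed=7))
>>> res = RetrievalDependency(trials).fit(seed=7)
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import io as _io
from .dependency import score_participants
from .design import SEPARATED, SIMULTANEOUS
from .inference import (
    one_sample_signflip,
    paired_condition_test,
    summarize,
    two_group_test,
)
from .screening import ScreeningConfig, screen


class RetrievalDependency:
    """Retrieval-dependency analysis of a trial-level dataset.

    Parameters
    ----------
    trials : DataFrame
        Long-format encoding + retrieval trials (see :mod:`eventdep.io`).
    screening : ScreeningConfig, optional
        Exclusion rules; the defaults apply the ceiling criterion with the
        attention filter off.
    """

    def __init__(self, trials: pd.DataFrame, screening: ScreeningConfig | None = None):
        self.trials = _io.validate_trials(trials)
        self.screening = screening or ScreeningConfig()

    @classmethod
    def from_csv(cls, path, screening: ScreeningConfig | None = None) -> "RetrievalDependency":
        return cls(_io.read_trials(path), screening=screening)

    def fit(self, n_perm: int = 10_000, seed: int | None = None) -> "RetrievalDependencyResults":
        """Screen, score, and test.

        Contrasts run: dependency vs 0 within each encoding condition
        (pooled over age groups and per group), the paired
        simultaneous-vs-separated contrast, and pairwise between-group
        differences in dependency per condition.
        """
        screened = screen(self.trials, self.screening)
        scores = score_participants(
            screened.retrieval,
            screened.included_events if screened.included_events else None,
        )
        group_summary = summarize(scores)

        tests = []
        rng = np.random.default_rng(seed)

        def next_seed() -> int:
            return int(rng.integers(2**31))

        conditions = sorted(scores["condition"].unique())
        for cond in conditions:
            d = scores.loc[scores["condition"] == cond, "dependency"]
            tests.append(
                one_sample_signflip(
                    d, n_perm=n_perm, seed=next_seed(),
                    contrast=f"dependency vs 0 [{cond}]",
                )
            )
            for group in sorted(scores["age_group"].unique()):
                dg = scores.loc[
                    (scores["condition"] == cond) & (scores["age_group"] == group),
                    "dependency",
                ]
                if len(dg) >= 2:
                    tests.append(
                        one_sample_signflip(
                            dg, n_perm=n_perm, seed=next_seed(),
                            contrast=f"dependency vs 0 [{cond}, {group}]",
                        )
                    )
        if {SIMULTANEOUS, SEPARATED} <= set(conditions):
            wide = scores.pivot_table(
                index="participant_id", columns="condition", values="dependency"
            )
            tests.append(
                paired_condition_test(
                    wide.get(SIMULTANEOUS), wide.get(SEPARATED),
                    n_perm=n_perm, seed=next_seed(),
                    contrast="dependency: simultaneous - separated",
                )
            )
        groups = sorted(scores["age_group"].unique())
        for cond in conditions:
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    a = scores.loc[
                        (scores["condition"] == cond) & (scores["age_group"] == groups[i])
                    ]
                    b = scores.loc[
                        (scores["condition"] == cond) & (scores["age_group"] == groups[j])
                    ]
                    if len(a) >= 2 and len(b) >= 2:
                        tests.append(
                            two_group_test(
                                a["dependency"], b["dependency"],
                                n_perm=n_perm, seed=next_seed(),
                                contrast=f"dependency: {groups[i]} - {groups[j]} [{cond}]",
                                ids_a=a["participant_id"], ids_b=b["participant_id"],
                            )
                        )

        tests_frame = pd.DataFrame(
            [
                {
                    "contrast": t.contrast,
                    "statistic": t.observed,
                    "p_value": t.p_value,
                    "n_permutations": t.n_permutations,
                    "method": t.method,
                    "n": t.n,
                    "seed": t.seed,
                }
                for t in tests
            ]
        )
        return RetrievalDependencyResults(
            model=self,
            participant_scores=scores,
            group_summary=group_summary,
            tests=tests_frame,
            screening_report=screened.report,
            n_perm=n_perm,
            seed=seed,
        )


class RetrievalDependencyResults:
    """Fitted results: scores, descriptives, tests, screening report."""

    def __init__(self, model, participant_scores, group_summary, tests,
                 screening_report, n_perm, seed):
        self.model = model
        self.participant_scores = participant_scores
        self.group_summary = group_summary
        self.tests = tests
        self.screening_report = screening_report
        self.n_perm = n_perm
        self.seed = seed

    @property
    def dependency_by_condition(self) -> pd.Series:
        """Mean dependency per encoding condition (over participants)."""
        return self.participant_scores.groupby("condition")["dependency"].mean()

    def summary(self) -> str:
        lines = ["Retrieval dependency analysis", "=" * 31, ""]
        n_part = self.participant_scores["participant_id"].nunique()
        lines.append(f"Participants analysed: {n_part}")
        excl = self.screening_report.excluded_participants
        lines.append(f"Participants excluded at ceiling: {len(excl)}")
        lines.append(
            f"Timeouts resolved to incorrect: {self.screening_report.n_timeouts_resolved}"
        )
        lines.append("")
        lines.append("Group descriptives")
        lines.append("-" * 18)
        gs = self.group_summary.copy()
        for col in ("accuracy_mean", "accuracy_sd", "dependency_mean", "dependency_sd", "dependency_ci95"):
            gs[col] = gs[col].map(lambda v: f"{v:.3f}")
        lines.append(gs.to_string(index=False))
        lines.append("")
        lines.append(f"Permutation tests ({self.n_perm} permutations, seed={self.seed})")
        lines.append("-" * 18)
        ts = self.tests.copy()
        ts["statistic"] = ts["statistic"].map(lambda v: f"{v:+.4f}")
        ts["p_value"] = ts["p_value"].map(lambda v: f"{v:.4g}")
        lines.append(ts[["contrast", "statistic", "p_value", "method", "n"]].to_string(index=False))
        return "\n".join(lines) + "\n"

    def plot_dependency(self, ax=None):
        """Strip plot of participant dependency by group and condition, with
        condition means — the standard figure for this analysis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        scores = self.participant_scores
        groups = sorted(scores["age_group"].unique())
        conditions = sorted(scores["condition"].unique())
        rng = np.random.default_rng(0)
        for gi, group in enumerate(groups):
            for ci, cond in enumerate(conditions):
                d = scores.loc[
                    (scores["age_group"] == group) & (scores["condition"] == cond),
                    "dependency",
                ]
                x = gi + (ci - 0.5) * 0.3
                ax.scatter(
                    x + rng.normal(0, 0.03, len(d)), d, s=8, alpha=0.4,
                    color=f"C{ci}", label=cond if gi == 0 else None,
                )
                ax.scatter([x], [d.mean()], s=60, color=f"C{ci}", edgecolor="black", zorder=3)
        ax.axhline(0.0, linestyle="--", color="grey", linewidth=1)
        ax.set_xticks(range(len(groups)), groups)
        ax.set_ylabel("Retrieval dependency (data - independent model)")
        ax.legend(title="Encoding")
        return ax
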