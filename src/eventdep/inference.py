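"""Group-level descriptive summaries and permutation inference.

The bespoke quantity in this pipeline is the per-participant dependency
score; group-level questions about it (is dependency above zero? does it
differ between encoding conditions? between age groups?) are answered with
permutation tests rather than mixed-effects regression:

* :func:`one_sample_signflip` — dependency against 0 within a condition,
  null generated by random sign flips of the participant scores;
* :func:`paired_condition_test` — simultaneous vs separated encoding,
  sign flips on within-participant differences;
* :func:`two_group_test` — between age groups, random relabelling.

All tests are two-sided by absolute value of the statistic. Sign-flip
tests switch to exhaustive enumeration of all 2^n flips when n <= 20, in
which case the p-value is the exact proportion of flips at least as
extreme as the identity; Monte-Carlo p-values use the standard
add-one estimator (b + 1) / (m + 1), which can never be exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GroupSummary",
    "PermutationTestResult",
    "summarize",
    "one_sample_signflip",
    "paired_condition_test",
    "two_group_test",
    "holm_bonferroni",
]

#: largest n for which all 2^n sign flips are enumerated exactly
EXHAUSTIVE_LIMIT = 20

_ABS_TOL = 1e-12  # guard against float noise in |perm| >= |obs| comparisons


class InferenceError(ValueError):
    pass


@dataclass(frozen=True)
class GroupSummary:
    age_group: str
    condition: str
    n: int
    accuracy_mean: float
    accuracy_sd: float
    dependency_mean: float
    dependency_sd: float
    dependency_ci95: float  # normal-approximation half-width


@dataclass(frozen=True)
class PermutationTestResult:
    contrast: str
    observed: float
    n_permutations: int
    p_value: float
    seed: int | None
    method: str  # "exhaustive" or "monte_carlo"
    n: int

    def __str__(self) -> str:
        return (
            f"{self.contrast}: stat={self.observed:+.4f}, "
            f"p={self.p_value:.4g} ({self.method}, {self.n_permutations} perms, n={self.n})"
        )


def summarize(scores: pd.DataFrame) -> pd.DataFrame:
    """Per (age_group, condition) means and SDs of accuracy and dependency.

    ``scores`` is the per-participant-condition table from
    :func:`eventdep.dependency.score_participants`. Sample SDs (ddof=1);
    groups of one report SD 0 with a warning. The 95% CI half-width uses
    the normal approximation 1.96 * sd / sqrt(n).
    """
    if scores.empty:
        raise InferenceError("no scores to summarize")
    rows = []
    for (group, cond), cell in scores.groupby(["age_group", "condition"], sort=True):
        n = len(cell)
        if n == 1:
            warnings.warn(
                f"group ({group}, {cond}) has a single participant; SD set to 0",
                stacklevel=2,
            )
        acc_sd = float(cell["accuracy"].std(ddof=1)) if n > 1 else 0.0
        dep_sd = float(cell["dependency"].std(ddof=1)) if n > 1 else 0.0
        rows.append(
            GroupSummary(
                age_group=group,
                condition=cond,
                n=n,
                accuracy_mean=float(cell["accuracy"].mean()),
                accuracy_sd=acc_sd,
                dependency_mean=float(cell["dependency"].mean()),
                dependency_sd=dep_sd,
                dependency_ci95=1.96 * dep_sd / np.sqrt(n),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def _signflip_pvalue(
    values: np.ndarray, n_perm: int, seed: int | None
) -> tuple[float, int, str]:
    """Two-sided sign-flip p-value for the mean of ``values``."""
    n = len(values)
    observed = float(values.mean())
    if np.all(values == 0):
        warnings.warn("all values are zero: degenerate sign-flip distribution", stacklevel=3)
        return 1.0, 0, "degenerate"
    if n <= EXHAUSTIVE_LIMIT:
        # all 2^n sign patterns, the identity included
        masks = np.arange(2**n, dtype=np.uint32)
        bits = ((masks[:, None] >> np.arange(n, dtype=np.uint32)) & 1).astype(np.uint8)
        # sign pattern s has mean (sum(v) - 2 * sum of flipped v) / n
        perm_means = (values.sum() - 2.0 * (bits @ values)) / n
        b = int(np.sum(np.abs(perm_means) >= abs(observed) - _ABS_TOL))
        return b / 2**n, 2**n, "exhaustive"
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    perm_means = signs @ values / n
    b = int(np.sum(np.abs(perm_means) >= abs(observed) - _ABS_TOL))
    return (b + 1) / (n_perm + 1), n_perm, "monte_carlo"


def one_sample_signflip(
    d_values, n_perm: int = 10_000, seed: int | None = None, contrast: str = "mean vs 0"
) -> PermutationTestResult:
    """Sign-flip permutation test of mean(d) against 0.

    Under the null the scores are symmetric around zero, so flipping signs
    at random regenerates the null distribution of the mean.
    """
    d = np.asarray(d_values, dtype=float)
    if len(d) < 2:
        raise InferenceError("need at least 2 values")
    if n_perm < 1:
        raise InferenceError("n_perm must be >= 1")
    p, m, method = _signflip_pvalue(d, n_perm, seed)
    return PermutationTestResult(
        contrast=contrast,
        observed=float(d.mean()),
        n_permutations=m,
        p_value=p,
        seed=seed,
        method=method,
        n=len(d),
    )


def paired_condition_test(
    d_first,
    d_second,
    n_perm: int = 10_000,
    seed: int | None = None,
    contrast: str = "paired condition difference",
) -> PermutationTestResult:
    """Within-participant condition contrast via sign flips on differences.

    Inputs are aligned per participant; pairs with either side missing
    (NaN) are dropped. Swapping the two condition labels within a
    participant is equivalent to flipping the sign of that participant's
    difference, so the null is the one-sample sign-flip null on d1 - d2.
    """
    a = np.asarray(d_first, dtype=float)
    b = np.asarray(d_second, dtype=float)
    if a.shape != b.shape:
        raise InferenceError("paired inputs must have equal length")
    complete = ~(np.isnan(a) | np.isnan(b))
    diffs = a[complete] - b[complete]
    if len(diffs) < 2:
        raise InferenceError("need at least 2 complete pairs")
    p, m, method = _signflip_pvalue(diffs, n_perm, seed)
    return PermutationTestResult(
        contrast=contrast,
        observed=float(diffs.mean()),
        n_permutations=m,
        p_value=p,
        seed=seed,
        method=method,
        n=len(diffs),
    )


def two_group_test(
    group_a,
    group_b,
    n_perm: int = 10_000,
    seed: int | None = None,
    contrast: str = "group mean difference",
    ids_a=None,
    ids_b=None,
) -> PermutationTestResult:
    """Difference in group means, null by random relabelling.

    ``ids_a``/``ids_b`` (optional participant ids) guard against the same
    participant appearing in both groups.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InferenceError("both groups need at least 2 values")
    if ids_a is not None and ids_b is not None:
        overlap = set(ids_a) & set(ids_b)
        if overlap:
            raise InferenceError(f"participants in both groups: {sorted(overlap)}")
    observed = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    na = len(a)
    count = 0
    # permute in batches to bound memory at large n_perm
    batch = max(1, min(n_perm, 2_000_000 // max(len(pooled), 1)))
    done = 0
    while done < n_perm:
        k = min(batch, n_perm - done)
        idx = np.argsort(rng.random((k, len(pooled))), axis=1)
        perm = pooled[idx]
        stat = perm[:, :na].mean(axis=1) - perm[:, na:].mean(axis=1)
        count += int(np.sum(np.abs(stat) >= abs(observed) - _ABS_TOL))
        done += k
    return PermutationTestResult(
        contrast=contrast,
        observed=observed,
        n_permutations=n_perm,
        p_value=(count + 1) / (n_perm + 1),
        seed=seed,
        method="monte_carlo",
        n=len(pooled),
    )


def holm_bonferroni(p_values) -> np.ndarray:
    """Holm-Bonferroni adjusted p-values (step-down, monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        running_max = max(running_max, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running_max)
    return adjusted
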