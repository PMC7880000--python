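"""Monte-Carlo power analysis for detecting dependency.

For each candidate sample size n, many cohorts of n participants are drawn
from the latent-binding mixture, each participant contributing one
dependency score computed from a simulated events x 6 correctness matrix.
The configured one-sample test of dependency against 0 is run per cohort
and power is the fraction of rejections at the chosen alpha.

The generative model stands in for resampling of real data, so the power
estimates characterise the mixture model, not any particular empirical
dataset. The default test is the sign-flip permutation test (with a
reduced permutation count inside the simulation loop); a one-sample t-test
option trades exactness for speed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dependency import dependency_from_matrix
from .simulate import BindingParams, simulate_correct_matrix

SIGNFLIP = "one_sample_signflip"
TTEST = "one_sample_t"


class PowerError(ValueError):
    pass


@dataclass(frozen=True)
class PowerSpec:
    """Configuration of one power run."""

    params: BindingParams
    sample_sizes: tuple[int, ...]
    alpha: float = 0.001
    n_sims: int = 1000
    n_events: int = 15
    test: str = SIGNFLIP
    n_perm: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise PowerError("alpha must be in (0, 1]")
        if self.n_sims < 1:
            raise PowerError("n_sims must be >= 1")
        if not self.sample_sizes or min(self.sample_sizes) < 2:
            raise PowerError("sample sizes must all be >= 2")
        if self.test not in (SIGNFLIP, TTEST):
            raise PowerError(f"unknown test {self.test!r}")


@dataclass(frozen=True)
class PowerResult:
    """Estimated power per sample size, with Monte-Carlo standard errors."""

    table: pd.DataFrame  # columns: n, power, mc_se, n_sims
    spec: PowerSpec
    null_model: bool  # theta in {0, 1}: the run estimates type-I error

    def power_at(self, n: int) -> float:
        row = self.table.loc[self.table["n"] == n]
        if row.empty:
            raise PowerError(f"sample size {n} not in this result")
        return float(row["power"].iloc[0])


def _simulate_dependency_cohorts(
    n_sims: int, n: int, spec: PowerSpec, rng: np.random.Generator
) -> np.ndarray:
    """(n_sims, n) matrix of per-participant dependency scores."""
    correct = simulate_correct_matrix(n_sims * n, spec.n_events, spec.params, rng)
    _, _, d = dependency_from_matrix(correct)
    return d.reshape(n_sims, n)


def _reject_signflip(d: np.ndarray, alpha: float, n_perm: int, rng) -> np.ndarray:
    """Vectorised Monte-Carlo sign-flip rejections, one per cohort row."""
    n_sims, n = d.shape
    observed = np.abs(d.mean(axis=1))
    counts = np.zeros(n_sims, dtype=np.int64)
    # batch over permutations to bound the (n_perm, n_sims, n) working set
    batch = max(1, int(2e7) // max(n_sims * n, 1))
    done = 0
    while done < n_perm:
        k = min(batch, n_perm - done)
        signs = rng.choice([-1.0, 1.0], size=(k, 1, n))
        perm_means = np.abs((signs * d[None, :, :]).mean(axis=2))
        counts += np.sum(perm_means >= observed[None, :] - 1e-12, axis=0)
        done += k
    p = (counts + 1) / (n_perm + 1)
    return p <= alpha


def estimate_power(spec: PowerSpec) -> PowerResult:
    """Estimate rejection rates for every sample size in ``spec``.

    Power is the fraction of simulated cohorts whose test of dependency
    against 0 rejects at ``spec.alpha``; the Monte-Carlo standard error is
    sqrt(p(1-p)/n_sims). Under a null parameterisation (theta 0 or 1) the
    run estimates the type-I error rate and is flagged as such.
    """
    null_model = spec.params.theta in (0.0, 1.0) or (
        spec.params.p_bound == spec.params.p_unbound
    )
    rows = []
    for size_idx, n in enumerate(spec.sample_sizes):
        # independent, reproducible stream per sample size
        seq = np.random.SeedSequence(entropy=spec.seed, spawn_key=(size_idx,))
        rng = np.random.default_rng(seq)
        d = _simulate_dependency_cohorts(spec.n_sims, n, spec, rng)
        if spec.test == SIGNFLIP:
            reject = _reject_signflip(d, spec.alpha, spec.n_perm, rng)
        else:
            t = stats.ttest_1samp(d, 0.0, axis=1)
            reject = t.pvalue <= spec.alpha
        p_hat = float(np.mean(reject))
        se = float(np.sqrt(p_hat * (1 - p_hat) / spec.n_sims))
        rows.append(
            {"n": n, "power": p_hat, "mc_se": se if spec.n_sims > 1 else np.nan,
             "n_sims": spec.n_sims}
        )
    return PowerResult(table=pd.DataFrame(rows), spec=spec, null_model=null_model)


def power_curve(spec: PowerSpec) -> PowerResult:
    """Power across several sample sizes, warning on non-monotone dips
    beyond Monte-Carlo noise (3 combined standard errors)."""
    if len(spec.sample_sizes) < 2:
        raise PowerError("power_curve needs at least 2 sample sizes")
    ordered = PowerSpec(
        params=spec.params,
        sample_sizes=tuple(sorted(spec.sample_sizes)),
        alpha=spec.alpha,
        n_sims=spec.n_sims,
        n_events=spec.n_events,
        test=spec.test,
        n_perm=spec.n_perm,
        seed=spec.seed,
    )
    result = estimate_power(ordered)
    t = result.table
    for i in range(1, len(t)):
        drop = t["power"].iloc[i - 1] - t["power"].iloc[i]
        noise = 3.0 * np.sqrt(
            np.nan_to_num(t["mc_se"].iloc[i - 1]) ** 2
            + np.nan_to_num(t["mc_se"].iloc[i]) ** 2
        )
        if drop > noise:
            warnings.warn(
                f"power decreased from n={t['n'].iloc[i-1]} to n={t['n'].iloc[i]} "
                "beyond Monte-Carlo noise",
                stacklevel=2,
            )
    return result
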