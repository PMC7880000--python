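# eventdep

Retrieval-dependency analysis of three-element event memories.

## The problem

When people remember an *event* made of several elements — say an animal, an
object, and a location — do they retrieve those elements as a coherent whole
(holistic retrieval via pattern completion), or independently of one
another? A standard behavioural answer comes from testing every pairwise
association within each event in both cue→target directions and asking
whether retrieval successes cluster by event: if remembering the object
given the animal predicts remembering the location given the animal, the
event is behaving like a bound unit.

`eventdep` packages this analysis for trial-level four-alternative
forced-choice (4AFC) data: per-participant contingency tables and
dependency scores, the standard exclusion rules, permutation inference,
a latent-binding simulator that makes the whole pipeline testable without
any real data, and Monte-Carlo power analysis. It is aimed at memory
researchers running (or re-analysing) multi-element association designs
with simultaneous vs. separated encoding conditions.

## The statistic

For one participant and condition with *N* events, each event contributes
six retrieval trials (three role pairs × two directions). Six 2×2
contingency tables are formed — one per role as a **common cue** (e.g. cued
by the animal, retrieve the object / the location) and one per role as a
**common target** (retrieve the animal when cued by the object / by the
location). Each table cross-classifies, over events, the correctness of its
two directions; cells sum to *N*.

Per table, the observed proportion of *contingent* outcomes (both correct
or both incorrect) is

> joint_data = (n₁₁ + n₀₀) / N

and the proportion expected if the two retrievals were independent given
the marginal accuracies P_AB = (n₁₁+n₁₀)/N and P_AC = (n₁₁+n₀₁)/N is

> joint_independent = P_AB·P_AC + (1 − P_AB)(1 − P_AC).

The **dependency score** D is the mean of joint_data minus the mean of
joint_independent across the six tables. D > 0 indicates that within-event
associations succeed and fail together beyond what overall accuracy
predicts.

The simulator draws, per event, a latent bound state ~ Bernoulli(θ) shared
by all six trials; trials succeed with probability p_b (bound) or p_u
(unbound). Its infinite-events dependency has the closed form
D∞ = 2·θ(1−θ)(p_b − p_u)², the analytic oracle the pipeline is tested
against.

## Worked example

```python
import eventdep as ed

trials = ed.simulate_cohort(ed.default_cohort_spec(base_seed=7))
res = ed.RetrievalDependency(trials).fit(n_perm=10_000, seed=7)
print(res.summary())
```

prints (abbreviated):

```
Participants analysed: 153
Participants excluded at ceiling: 0
Timeouts resolved to incorrect: 327

Group descriptives
------------------
age_group    condition  n accuracy_mean accuracy_sd dependency_mean dependency_sd dependency_ci95
     6-7y    separated 57         0.483       0.054           0.004         0.053           0.014
     6-7y simultaneous 57         0.497       0.061           0.039         0.061           0.016
    9-10y    separated 51         0.617       0.050           0.003         0.044           0.012
    9-10y simultaneous 51         0.628       0.061           0.035         0.062           0.017
    adult    separated 45         0.722       0.041           0.002         0.034           0.010
    adult simultaneous 45         0.728       0.064           0.029         0.046           0.013

Permutation tests (10000 permutations, seed=7)
------------------
                                contrast statistic   p_value      method   n
             dependency vs 0 [separated]   +0.0030    0.4176 monte_carlo 153
          dependency vs 0 [simultaneous]   +0.0347 9.999e-05 monte_carlo 153
    dependency: simultaneous - separated   +0.0317 9.999e-05 monte_carlo 153
```

The default synthetic cohort has three age groups (57/51/45 participants)
whose generative accuracy rises with age while holistic binding is present
only in the simultaneous encoding condition; the fitted results recover
exactly that pattern — dependency reliably above zero after simultaneous
encoding in every group, indistinguishable from zero after separated
encoding, and no age differences in dependency despite large age
differences in accuracy.

The `fit()` pipeline applies the standard screening first: missing
responses (adult timeouts) are scored incorrect, participants at ≥95%
accuracy are excluded, and — optionally (`ScreeningConfig(attention_filter_enabled=True)`)
— events with encoding trials flagged for inattention are dropped, with any
participant-condition left under 10 events excluded.

A command-line interface wraps the same pipeline:

```sh
eventdep simulate --seed 7 --out trials.csv
eventdep analyze trials.csv --seed 7 --out-dir results/
eventdep power --seed 7 --sizes 20,45 --alpha 0.001
```

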