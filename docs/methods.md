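# Methods

## The dependency statistic

Each participant-condition contributes *N* events (15 by default), each
tested with six 4AFC retrieval trials: the three within-event role pairs
(animal–object, animal–location, object–location), each in both cue→target
directions. Six 2×2 contingency tables cross-classify correctness over
events: three *common-cue* tables (the two directions cued by the same
role) and three *common-target* tables (the two directions retrieving the
same role). Every trial therefore enters exactly two tables — once through
its cue role, once through its target role.

Per table, the observed contingent proportion (n₁₁ + n₀₀)/N is compared
with the independence prediction P_AB·P_AC + (1−P_AB)(1−P_AC) computed
from the table's own marginals (plug-in, no shrinkage or continuity
correction). The dependency score D is the difference of the two six-table
means. Per-table differences are retained for diagnostics, though only the
mean is analysed.

Degenerate inputs: a participant with all trials correct (or all
incorrect) has joint_data = joint_independent = 1, hence D = 0 exactly —
which is why ceiling participants are uninformative and excluded. Tables
with zero included events raise rather than return NaN. Missing
correctness is refused at this layer; resolving it is screening's job, so
no silent imputation can occur.

## Screening rules

1. **Timeouts**: missing retrieval responses are scored incorrect (the
   default, matching how timed-out adult responses are conventionally
   handled in this paradigm); a `drop_trial` alternative removes the trial
   and marks its event incomplete, excluding it from all six tables.
2. **Ceiling**: participants averaging ≥ 0.95 accuracy (inclusive bound)
   across all their retrieval trials are excluded. The criterion pools
   both encoding conditions by default — exclusion of a whole participant
   implies a participant-level criterion — with a per-condition variant
   available via `ceiling_scope`.
3. **Attention filter** (attended-only analysis): any event with a flagged
   encoding trial is removed from all six tables, so all tables of a
   participant-condition share the same event count. In the separated
   condition one flag among the three encoding trials suffices, since the
   point of the filter is to guarantee all three associations were
   attended. If fewer than 10 events remain, the participant-condition is
   excluded (reason code `TOO_FEW_EVENTS`).

Screening is idempotent, and on flag-free data the attended-only pipeline
returns results identical to the full pipeline (both are tested).

## The generative model

No data-generating process is established for this paradigm, so the
simulator defines one deliberately minimal mixture: per event, a latent
bound state ~ Bernoulli(θ), shared by the event's six trials; given the
state, trials succeed independently with probability p_b (bound) or p_u
(unbound), with p_b ≥ p_u ≥ 0.25 (the 4AFC guessing floor). Marginal
accuracy is m = θ·p_b + (1−θ)·p_u and the infinite-events dependency is

    D∞ = θ(p_b² + (1−p_b)²) + (1−θ)(p_u² + (1−p_u)²) − (m² + (1−m)²)
        = 2·θ(1−θ)(p_b − p_u)²

verified against a 2×10⁶-event brute-force simulation (0.21125 at θ = 0.5,
p_b = 0.9, p_u = 0.25) before the statistic was built on it. θ ∈ {0, 1}
collapses the mixture to a single Bernoulli component and D∞ = 0; this is
the null model used for calibration checks.

With finitely many events the plug-in independent model is biased slightly
upward (the two marginals share sampling noise across the same events), so
the measured D at 15 events sits a little below D∞; the bias is O(1/N) and
the 500-event calibration check bounds it empirically. Encoding conditions
differ only through their `BindingParams` — separated encoding with
disrupted integration is simply θ = 0 — because the scientific contrast of
interest *is* a difference in holistic binding.

### Default cohort (what the simulator emulates)

Three age groups with 57, 51 and 45 participants; two lists of 15
animal–object–location events (which list serves which condition is a free
parameter, defaulting to list 1 = simultaneous); observed accuracies
targeted at .48, .63 and .72 for the 6–7-year-olds, 9–10-year-olds and
adults; D∞ = 0.04 in the simultaneous condition (θ = 0.5, p_b − p_u =
√0.08 ≈ 0.28, symmetric about the target accuracy) and 0 in the separated
condition (θ = 0); adult retrieval responses time out at rate .04
(children have no deadline), and children's encoding trials carry
inattention flags at rate .0066 (adults none). Because timeouts are scored
incorrect downstream, the adult generative accuracy is inflated to
.72/(1−.04) = .75 so the *observed* accuracy lands on target. Seeds per
participant derive from the cohort base seed through
`numpy.random.SeedSequence` spawn keys, so cohorts are reproducible row
for row.

What the generator does **not** model: individual differences in ability
(between-participant accuracy variance is purely binomial, so nobody
reaches the 95% ceiling, unlike real adult samples), response times,
serial-position or interference effects, foil confusability, and any
difference between encoding conditions beyond the binding parameters.
Passing tests therefore demonstrate the pipeline's correctness and
calibration under the mixture, not fidelity of the mixture to any real
dataset.

## Schedules

Separated encoding and each retrieval set use the same balanced layout:
three blocks, one trial per event per block, pair types split N/3 per
block, every event covering all three pair types across blocks. The
assignment partitions events into three random groups and routes them
through a uniformly random 3×3 Latin square (row/column/symbol
permutations of the cyclic square reach all twelve), then shuffles within
blocks — a rejection-free construction satisfying the composition
constraints for every seed (property-tested over 100 seeds). Which
direction of a pair appears in retrieval Set 1 is randomised per event;
Set 2 reverses it. N must be divisible by 3; indices in emitted files are
1-based.

## Inference

The per-participant dependency scores feed permutation tests rather than
mixed-effects regressions: the regression machinery is standard and
off-the-shelf, while the permutation analogues stay exact and
assumption-light at these sample sizes.

* Dependency vs 0 within a condition: sign-flip test on the participant
  scores (null: symmetric distribution about 0).
* Simultaneous vs separated: sign flips on within-participant differences,
  equivalent to swapping condition labels per participant; incomplete
  pairs are dropped and counted.
* Between age groups: difference of group means under random relabelling.

All tests are two-sided by absolute value. Sign-flip tests enumerate all
2ⁿ flips exactly when n ≤ 20 (p = b/2ⁿ, the identity included, so p = 2/2ⁿ
for a perfectly consistent sample); Monte-Carlo tests use the add-one
estimator p = (b+1)/(m+1), which is never exactly 0. Default 10,000
permutations; every test records its seed. The event-list random intercept
of regression treatments has no permutation analogue here: with only two
lists it is weakly identified, and list is ignored in inference.
Holm–Bonferroni adjustment is available as a post-hoc utility
(cross-checked against statsmodels).

The sign-flip null assumes symmetry of D around 0; under the θ = 0 mixture
E[D] = 0 exactly (the marginals of a table are independent across its two
directions), and measured type-I error at n = 45, 15 events, α = .05 is
within binomial tolerance of nominal (tested at 1,000 replicate cohorts).

## Power

For each candidate n, `estimate_power` simulates `n_sims` cohorts from the
mixture, computes each participant's D from an events × 6 correctness
matrix (the vectorised path, bit-identical to the table path), runs the
configured test at α (default .001), and reports the rejection fraction
with SE = √(p̂(1−p̂)/n_sims). Inside the power loop the sign-flip test runs
at 999 permutations; a one-sample t-test option trades exactness for
speed. The power module samples from the generative model rather than
resampling any empirical dataset, so its outputs characterise the mixture,
not a particular study population. Under a strong binding effect (θ = 0.5,
p_b = 0.95, p_u = 0.3, 15 events) power at n = 45 and α = .001 exceeds
0.9.

## Numerical and design choices

* Permutation comparisons use |perm| ≥ |obs| − 10⁻¹² to keep ties stable
  under float noise.
* The vectorised dependency path and the contingency-table path are
  verified equal on all 2¹² two-event patterns against an independently
  coded brute-force oracle.
* Problem sizes in the shipped checks: simulator calibration at 500
  participants × 500 events; type-I calibration at 1,000 replicate cohorts
  of 45; power at 300–400 simulations per sample size. These sizes give
  Monte-Carlo standard errors small enough for 3-SE acceptance bands while
  keeping the default suite fast.
* Trial tables are plain pandas DataFrames with a validated schema
  (`eventdep.io.COLUMNS`); every CSV the package writes is re-readable by
  its own readers.

## Known limitations

* The ceiling criterion's pooled-vs-per-condition scope is a genuine
  ambiguity in the paradigm's conventions; pooled is the default and the
  alternative is a config switch.
* The mixture's lack of participant-level heterogeneity makes simulated
  dependency SDs somewhat smaller than real ones at equal means.
* Dependency confidence intervals for single participants are out of
  scope, as is the "dependent model" upper-bound benchmark from the older
  literature.
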