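"""The latent-binding mixture simulator against its analytic expectations."""

import numpy as np
import pandas as pd
import pytest

from eventdep.dependency import dependency_from_matrix
from eventdep.design import DesignSpec, build_events, build_retrieval_schedule
from eventdep.simulate import (
    BindingParams,
    CohortSpec,
    GroupSpec,
    SimulationError,
    binding_params_for,
    default_cohort_spec,
    expected_dependency,
    simulate_cohort,
    simulate_correct_matrix,
    simulate_responses,
)


@pytest.fixture(scope="module")
def schedule():
    events = build_events(DesignSpec(), 1, 3)
    return build_retrieval_schedule(events, 4)


class TestBindingParams:
    def test_invalid_orderings_rejected(self):
        with pytest.raises(SimulationError):
            BindingParams(theta=0.5, p_bound=0.3, p_unbound=0.6)
        with pytest.raises(SimulationError):
            BindingParams(theta=0.5, p_bound=0.9, p_unbound=0.1)  # below guess floor
        with pytest.raises(SimulationError):
            BindingParams(theta=1.5, p_bound=0.9, p_unbound=0.3)

    @pytest.mark.parametrize("theta", [0.0, 1.0])
    def test_single_component_implies_independence(self, theta):
        params = BindingParams(theta=theta, p_bound=0.9, p_unbound=0.9)
        assert expected_dependency(params) == pytest.approx(0.0)

    def test_closed_form_value(self):
        # frozen from a 2e6-event Monte-Carlo run of the mixture
        params = BindingParams(theta=0.5, p_bound=0.9, p_unbound=0.25)
        assert expected_dependency(params) == pytest.approx(0.21125)

    def test_solver_hits_accuracy_and_dependency(self):
        params = binding_params_for(accuracy=0.63, dependency=0.04)
        assert params.mean_accuracy == pytest.approx(0.63)
        assert expected_dependency(params) == pytest.approx(0.04)


class TestSimulateResponses:
    def test_deterministic_upper_bound(self, schedule):
        params = BindingParams(theta=1.0, p_bound=1.0, p_unbound=1.0)
        trials = simulate_responses(schedule, params, rng_seed=0)
        assert (trials["correct"] == 1.0).all()
        assert len(trials) == 90

    def test_guessing_floor(self):
        events = build_events(DesignSpec(n_events_per_condition=900), 1, 1)
        sched = build_retrieval_schedule(events, 2)
        params = BindingParams(theta=0.0, p_bound=0.25, p_unbound=0.25)
        trials = simulate_responses(sched, params, rng_seed=3)
        assert trials["correct"].mean() == pytest.approx(0.25, abs=0.02)

    def test_pair_joint_success_matches_mixture(self, rng):
        # P(both trials of a pair correct) = theta*p_b^2 + (1-theta)*p_u^2
        params = BindingParams(theta=0.5, p_bound=0.9, p_unbound=0.25)
        mat = simulate_correct_matrix(1, 5000, params, rng)[0]
        both = np.mean(mat[:, 0] & mat[:, 1])
        assert both == pytest.approx(0.43625, abs=0.02)

    def test_seed_reproducibility(self, schedule):
        params = BindingParams(theta=0.5, p_bound=0.9, p_unbound=0.3)
        a = simulate_responses(schedule, params, rng_seed=5, timeout_rate=0.1)
        b = simulate_responses(schedule, params, rng_seed=5, timeout_rate=0.1)
        pd.testing.assert_frame_equal(a, b)


class TestMixtureCalibration:
    def test_mean_dependency_matches_closed_form(self, rng):
        params = BindingParams(theta=0.4, p_bound=0.85, p_unbound=0.35)
        mat = simulate_correct_matrix(300, 300, params, rng)
        _, _, d = dependency_from_matrix(mat)
        se = d.std(ddof=1) / np.sqrt(len(d))
        assert abs(d.mean() - expected_dependency(params)) < 3 * se

    def test_dependency_monotone_in_component_gap(self, rng):
        gaps = [0.0, 0.2, 0.4]
        means = []
        for gap in gaps:
            params = BindingParams(theta=0.5, p_bound=0.55 + gap, p_unbound=0.55)
            _, _, d = dependency_from_matrix(simulate_correct_matrix(400, 60, params, rng))
            means.append(float(d.mean()))
        assert means[0] < means[1] < means[2]

    @pytest.mark.parametrize("theta", [0.0, 1.0])
    def test_degenerate_theta_gives_zero_mean(self, theta, rng):
        params = BindingParams(theta=theta, p_bound=0.6, p_unbound=0.6)
        _, _, d = dependency_from_matrix(simulate_correct_matrix(500, 60, params, rng))
        se = d.std(ddof=1) / np.sqrt(len(d))
        assert abs(d.mean()) < 3 * se + 1e-9


class TestSimulateCohort:
    def test_study_shaped_cohort(self):
        spec = default_cohort_spec(base_seed=1)
        trials = simulate_cohort(spec)
        assert trials["participant_id"].nunique() == 57 + 51 + 45
        per_participant = trials.loc[trials["phase"] == "retrieval"].groupby(
            "participant_id"
        ).size()
        assert (per_participant == 180).all()  # 90 per condition, two conditions
        adults = trials.loc[
            (trials["age_group"] == "adult") & (trials["phase"] == "retrieval"), "correct"
        ]
        assert adults.isna().mean() == pytest.approx(0.04, abs=0.01)
        children = trials.loc[
            (trials["age_group"] != "adult") & (trials["phase"] == "retrieval"), "correct"
        ]
        assert children.isna().sum() == 0

    def test_single_participant_single_condition(self):
        params = {"simultaneous": BindingParams(0.5, 0.9, 0.3)}
        spec = CohortSpec(
            groups={"adult": GroupSpec(n_participants=1, params=params)},
            base_seed=9,
        )
        trials = simulate_cohort(spec)
        assert (trials["phase"] == "retrieval").sum() == 90

    def test_zero_timeout_rate_means_no_missing(self):
        spec = default_cohort_spec(base_seed=2)
        no_timeout = CohortSpec(
            groups={
                g: GroupSpec(
                    n_participants=3,
                    params=dict(s.params),
                    attention_flag_rate=s.attention_flag_rate,
                    timeout_rate=0.0,
                )
                for g, s in spec.groups.items()
            },
            base_seed=2,
        )
        trials = simulate_cohort(no_timeout)
        retrieval = trials.loc[trials["phase"] == "retrieval"]
        assert retrieval["correct"].isna().sum() == 0

    def test_cohort_reproducible(self):
        spec = default_cohort_spec(base_seed=42, n_participants={"6-7y": 2, "9-10y": 2, "adult": 2})
        pd.testing.assert_frame_equal(simulate_cohort(spec), simulate_cohort(spec))
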