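"""Structural invariants of the Markov machinery on randomized inputs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trialpath import msm, synth
from trialpath.msm import (
    PanelDataset,
    ParameterVector,
    Subject,
    build_intensity_matrix,
    default_spec,
    log_likelihood,
    transition_probability,
)

rates = st.floats(min_value=0.01, max_value=3.0)
times = st.floats(min_value=0.0, max_value=10.0)


def q_from(rate_list):
    spec = default_spec()
    params = ParameterVector(np.log(np.asarray(rate_list)), np.array([]))
    return build_intensity_matrix(spec, params).q


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(rates, min_size=6, max_size=6), times)
def test_rows_of_p_sum_to_one(rate_list, t):
    p = transition_probability(q_from(rate_list), t)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-8)
    assert p.min() >= 0.0 and p.max() <= 1.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(rates, min_size=6, max_size=6), times, times)
def test_chapman_kolmogorov(rate_list, s, t):
    q = q_from(rate_list)
    left = transition_probability(q, s + t)
    right = transition_probability(q, s) @ transition_probability(q, t)
    np.testing.assert_allclose(left, right, atol=1e-8)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(rates, min_size=6, max_size=6),
       st.floats(min_value=0.1, max_value=5.0))
def test_enlarging_censor_set_never_decreases_likelihood(rate_list, dt):
    """Panel-mode censored terminal: adding states to the censoring set adds
    non-negative probability mass."""
    spec = default_spec(exact_transition_times=False)
    x = np.log(np.asarray(rate_list))
    sets = [frozenset({2}), frozenset({2, 3}), frozenset({2, 3, 4})]
    lls = []
    for cset in sets:
        data = PanelDataset([Subject("d", [0.0, dt], (1, cset))])
        lls.append(log_likelihood(data, spec, x))
    assert lls[0] <= lls[1] + 1e-12 <= lls[2] + 2e-12


def test_censored_contribution_at_least_single_state():
    spec = default_spec(exact_transition_times=False)
    x = np.log([0.3, 0.1, 0.2, 0.15, 0.1, 0.12])
    cset = frozenset({2, 3, 4})
    ll_set = log_likelihood(
        PanelDataset([Subject("d", [0.0, 1.5], (1, cset))]), spec, x
    )
    for s in cset:
        single = log_likelihood(
            PanelDataset([Subject("d", [0.0, 1.5], (1, frozenset({s})))]), spec, x
        )
        assert ll_set >= single - 1e-12


def test_likelihood_invariant_to_subject_order():
    data, _ = synth.simulate_cohort(synth.SimulationConfig(n_drugs=80, seed=13))
    spec = default_spec(["biomarker"])
    x = np.concatenate([np.log([0.3, 0.2, 0.25, 0.3, 0.2, 0.25]), [1.0, 1.0, 1.0]])
    ll = log_likelihood(data, spec, x)
    reordered = PanelDataset(list(reversed(data.subjects)))
    assert log_likelihood(reordered, spec, x) == pytest.approx(ll, rel=1e-12)


def test_lrt_invariant_to_subject_order_and_scale():
    """The LRT statistic does not depend on subject ordering, and the
    log-scale parameterization yields the same maximum as a natural-scale
    fit started elsewhere (the optimum is parameterization-free)."""
    data, _ = synth.simulate_cohort(synth.SimulationConfig(n_drugs=150, seed=21))
    spec0 = default_spec()
    spec1 = default_spec(["biomarker"])
    f0 = msm.fit(data, spec0, compute_covariance=False)
    f1 = msm.fit(data, spec1, compute_covariance=False)
    lrt = msm.likelihood_ratio_test(f0, f1)

    shuffled = PanelDataset(list(reversed(data.subjects)))
    g0 = msm.fit(shuffled, spec0, compute_covariance=False)
    g1 = msm.fit(shuffled, spec1, compute_covariance=False)
    lrt2 = msm.likelihood_ratio_test(g0, g1)
    assert lrt2.statistic == pytest.approx(lrt.statistic, abs=1e-4)
    assert lrt2.p_value == pytest.approx(lrt.p_value, abs=1e-5)

    # different starting point, same optimum
    init = ParameterVector(np.full(6, np.log(0.05)), np.zeros(3))
    f1b = msm.fit(data, spec1, init=init, compute_covariance=False)
    assert f1b.log_likelihood == pytest.approx(f1.log_likelihood, abs=1e-4)


def test_simulated_panels_satisfy_observation_invariants():
    data, _ = synth.simulate_cohort(synth.SimulationConfig(n_drugs=200, seed=17))
    for subj in data.subjects:
        assert np.all(np.diff(subj.times) > 0)
        assert subj.times[0] == 0.0 and subj.states[0] == 1
        for s in subj.states[:-1]:
            assert isinstance(s, (int, np.integer)) and int(s) not in (4, 5)
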