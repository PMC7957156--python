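"""Intensity matrices, transition probabilities, likelihood terms, fitting.

Closed-form expectations here were derived independently from exponential
survival: a single clock gives P11(t) = exp(-q12 t), and one transient
state feeding two absorbing states gives P1s(t) = (q1s/q1.)(1 - e^{-q1. t}).
"""

import numpy as np
import pytest

from trialpath import msm
from trialpath.msm import (
    IntensityMatrix,
    ModelSpec,
    PanelDataset,
    ParameterVector,
    Subject,
    build_intensity_matrix,
    default_spec,
    likelihood_ratio_test,
    log_likelihood,
    transition_probability,
)


def two_state_spec(**kw) -> ModelSpec:
    return ModelSpec(
        n_states=2, transitions=((1, 2),), absorbing=(2,),
        exact_absorbing=frozenset(), exact_transition_times=False, **kw
    )


def competing_spec() -> ModelSpec:
    return ModelSpec(
        n_states=3, transitions=((1, 2), (1, 3)), absorbing=(2, 3),
        exact_absorbing=frozenset(), exact_transition_times=False,
    )


class TestIntensityMatrix:
    def test_baseline_matrix_rows_balance(self):
        spec = default_spec()
        params = ParameterVector(
            np.log([0.3, 0.1, 0.2, 0.15, 0.1, 0.12]), np.array([])
        )
        q = build_intensity_matrix(spec, params).q
        assert q[0, 1] == pytest.approx(0.3)
        assert q[0, 4] == pytest.approx(0.1)
        assert q[0, 0] == pytest.approx(-0.4)
        np.testing.assert_allclose(q.sum(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(q[3:], 0, atol=0)  # absorbing rows

    def test_zero_beta_leaves_baseline(self):
        spec = default_spec(["biomarker"])
        params = ParameterVector(np.full(6, -1.0), np.zeros(3))
        q0 = build_intensity_matrix(spec, params, {"biomarker": 0.0}).q
        q1 = build_intensity_matrix(spec, params, {"biomarker": 1.0}).q
        np.testing.assert_allclose(q0, q1)

    def test_covariate_doubles_one_intensity(self):
        spec = default_spec(["z"], attach_to=((1, 2),))
        params = ParameterVector(np.full(6, -1.0), np.array([np.log(2.0)]))
        q0 = build_intensity_matrix(spec, params, {"z": 0.0}).q
        q1 = build_intensity_matrix(spec, params, {"z": 1.0}).q
        assert q1[0, 1] == pytest.approx(2 * q0[0, 1])
        # all other off-diagonals untouched, diagonals rebalanced
        mask = ~np.eye(5, dtype=bool)
        mask[0, 1] = False
        np.testing.assert_allclose(q1[mask], q0[mask])
        np.testing.assert_allclose(q1.sum(axis=1), 0, atol=1e-12)

    def test_invalid_matrices_rejected(self):
        q = np.array([[-0.5, 0.5], [0.1, -0.1]])
        IntensityMatrix(q)  # valid
        with pytest.raises(ValueError):
            IntensityMatrix(np.array([[-0.5, 0.4], [0.0, 0.0]]))
        with pytest.raises(ValueError):
            IntensityMatrix(np.array([[0.5, -0.5], [0.0, 0.0]]))


class TestTransitionProbability:
    def test_zero_time_is_identity(self):
        q = np.array([[-0.5, 0.5], [0.0, 0.0]])
        np.testing.assert_allclose(transition_probability(q, 0.0), np.eye(2))

    def test_two_state_closed_form(self):
        q = np.array([[-0.5, 0.5], [0.0, 0.0]])
        p = transition_probability(q, 2.0)
        assert p[0, 0] == pytest.approx(np.exp(-1.0), abs=1e-10)
        assert p[0, 1] == pytest.approx(1 - np.exp(-1.0), abs=1e-10)

    def test_competing_risks_closed_form(self):
        q = np.array([[-0.4, 0.3, 0.1], [0, 0, 0], [0, 0, 0]])
        p = transition_probability(q, 1.0)
        assert p[0, 0] == pytest.approx(np.exp(-0.4), abs=1e-10)
        assert p[0, 1] == pytest.approx(0.75 * (1 - np.exp(-0.4)), abs=1e-10)
        assert p[0, 2] == pytest.approx(0.25 * (1 - np.exp(-0.4)), abs=1e-10)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_probability(np.zeros((2, 2)), -0.1)


class TestLogLikelihood:
    def test_empty_dataset_is_zero(self):
        assert log_likelihood(PanelDataset([]), two_state_spec(), np.array([0.0])) == 0.0

    def test_two_state_panel_pair(self):
        spec = two_state_spec()
        data = PanelDataset([Subject("d", [0.0, 2.0], (1, 2))])
        ll = log_likelihood(data, spec, np.array([np.log(0.5)]))
        assert ll == pytest.approx(np.log(1 - np.exp(-1.0)), abs=1e-10)

    def test_exact_death_term(self):
        # exact entry into the absorbing state: survival times hazard
        spec = ModelSpec(
            n_states=2, transitions=((1, 2),), absorbing=(2,),
            exact_absorbing=frozenset({2}), exact_transition_times=True,
        )
        data = PanelDataset([Subject("d", [0.0, 2.0], (1, 2))])
        ll = log_likelihood(data, spec, np.array([np.log(0.5)]))
        assert ll == pytest.approx(-1.0 + np.log(0.5), abs=1e-10)

    def test_censored_terminal_sums_states(self):
        spec = competing_spec()
        x = np.log([0.3, 0.1])
        single = PanelDataset([Subject("d", [0.0, 1.0], (1, frozenset({1, 2})))])
        q = np.array([[-0.4, 0.3, 0.1], [0, 0, 0], [0, 0, 0]])
        expected = np.exp(-0.4) + 0.75 * (1 - np.exp(-0.4))
        assert log_likelihood(single, spec, x) == pytest.approx(
            np.log(expected), abs=1e-10
        )

    def test_impossible_transition_gives_minus_inf(self):
        # observation after an absorbing state is rejected at construction
        with pytest.raises(ValueError, match="absorbing"):
            Subject("d", [0.0, 1.0, 2.0], (1, 5, 5))
        # a zero-probability pair warns and returns -inf (panel 2->1 disallowed)
        spec3 = ModelSpec(
            n_states=3, transitions=((1, 2), (2, 3)), absorbing=(3,),
            exact_absorbing=frozenset(), exact_transition_times=False,
        )
        bad = PanelDataset([Subject("d", [0.0, 1.0], (2, 1))])
        with pytest.warns(RuntimeWarning, match="zero-probability"):
            assert log_likelihood(bad, spec3, np.log([0.3, 0.2])) == -np.inf

    def test_compiled_likelihood_matches_reference(self):
        from trialpath import synth

        rng = np.random.default_rng(3)
        for exact in (True, False):
            spec = default_spec(["biomarker"], exact_transition_times=exact)
            data, _ = synth.simulate_cohort(
                synth.SimulationConfig(n_drugs=60, seed=5)
            )
            compiled = msm._compile(data, spec)
            for _ in range(3):
                x = rng.normal(-1.0, 0.4, spec.n_params)
                a = log_likelihood(data, spec, x)
                b = msm._ll_compiled(compiled, spec, x)
                assert a == pytest.approx(b, rel=1e-10)


class TestFit:
    def test_two_state_mle_matches_events_over_exposure(self):
        """With exact absorbing times the MLE of a single exponential clock
        is the analytic #events / total exposure."""
        rng = np.random.default_rng(42)
        q_true, horizon = 0.5, 2.0
        subjects = []
        events = exposure = 0.0
        for i in range(400):
            t = rng.exponential(1 / q_true)
            if t < horizon:
                subjects.append(Subject(f"d{i}", [0.0, t], (1, 2)))
                events += 1
                exposure += t
            else:
                subjects.append(
                    Subject(f"d{i}", [0.0, horizon], (1, frozenset({1})))
                )
                exposure += horizon
        spec = ModelSpec(
            n_states=2, transitions=((1, 2),), absorbing=(2,),
            exact_absorbing=frozenset({2}), exact_transition_times=True,
        )
        res = msm.fit(PanelDataset(subjects), spec)
        assert res.converged
        assert np.exp(res.params[0]) == pytest.approx(events / exposure, rel=1e-5)

    def test_unreachable_state_warns(self):
        spec = default_spec()
        data = PanelDataset(
            [Subject(f"d{i}", [0.0, 1.0], (1, frozenset({1, 2, 3, 4}))) for i in range(5)]
        )
        with pytest.warns(RuntimeWarning, match="unidentified"):
            res = msm.fit(data, spec, compute_covariance=False)
        # rates of never-observed transitions sit at the crude-rate floor
        assert res.params[2] <= np.log(1e-5)

    def test_hazard_ratio_interval_shape(self):
        from trialpath import synth

        data, _ = synth.simulate_cohort(synth.SimulationConfig(n_drugs=300, seed=2))
        spec = default_spec(["biomarker"])
        res = msm.fit(data, spec)
        for (key, cov), (point, lo, hi) in res.hazard_ratios.items():
            if lo is not None:
                assert 0 < lo < point < hi
        point, lo, hi = msm.hazard_ratio(res, (2, 3), "biomarker")
        assert lo < point < hi
        with pytest.raises(KeyError):
            msm.hazard_ratio(res, (1, 5), "biomarker")


class TestLRT:
    def test_identical_fits_give_zero(self):
        from trialpath import synth

        data, _ = synth.simulate_cohort(synth.SimulationConfig(n_drugs=80, seed=9))
        spec0 = default_spec()
        f0 = msm.fit(data, spec0, compute_covariance=False)
        spec1 = default_spec(["biomarker"])
        f1 = msm.fit(data, spec1, compute_covariance=False)
        same = likelihood_ratio_test(f0, f0, df=1)
        assert same.statistic == 0.0 and same.p_value == 1.0
        lrt = likelihood_ratio_test(f0, f1)
        assert lrt.df == 3  # one beta per progression transition
        assert lrt.statistic >= 0.0

    def test_non_nested_rejected(self):
        from trialpath import synth

        data, _ = synth.simulate_cohort(synth.SimulationConfig(n_drugs=50, seed=9))
        spec_a = default_spec(["biomarker"], attach_to=((1, 2),))
        spec_b = default_spec(["biomarker"], attach_to=((2, 3),))
        fa = msm.fit(data, spec_a, compute_covariance=False)
        fb = msm.fit(data, spec_b, compute_covariance=False)
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(fa, fb)

    def test_shared_nested_in_per_transition(self):
        from trialpath import synth

        data, _ = synth.simulate_cohort(synth.SimulationConfig(n_drugs=200, seed=4))
        shared = msm.fit(data, default_spec(["biomarker"], shared_effects=True),
                         compute_covariance=False)
        per_tr = msm.fit(data, default_spec(["biomarker"]), compute_covariance=False)
        lrt = likelihood_ratio_test(shared, per_tr)
        assert lrt.df == 2
        assert lrt.statistic >= -1e-6
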