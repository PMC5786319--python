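"""Estimator correctness against closed forms, optimization and Monte-Carlo oracles."""
import numpy as np
import pytest
import scipy.optimize

from posekin import msm, synthetic
from posekin.exceptions import UnreachableStateError, ValidationError
from posekin.msm import CountModel, TransitionModel
from posekin.types import DiscreteTrajectory


def _dtraj(states, n=None, dt=1.0, tid="t0"):
    states = np.asarray(states, dtype=int)
    return DiscreteTrajectory(states=states, n_microstates=n or states.max() + 1,
                              dt=dt, trajectory_id=tid)


def _count_model(C, lag=1, dt=1.0):
    C = np.asarray(C, dtype=float)
    return CountModel(lag=lag, counts=C, active_set=np.arange(len(C)), dt=dt)


class TestKmeansDiscretize:
    def test_single_microstate(self):
        rng = np.random.default_rng(0)
        dtrajs, centers = msm.kmeans_discretize([rng.normal(size=(50, 2))], 1, seed=1)
        assert np.all(dtrajs[0].states == 0)
        assert centers.shape == (1, 2)

    def test_separated_clouds_recovered_exactly(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.1, (200, 2))
        b = rng.normal(0, 0.1, (200, 2)) + 20.0
        dtrajs, centers = msm.kmeans_discretize([np.concatenate([a, b])], 2, seed=2)
        labels = dtrajs[0].states
        assert len(set(labels[:200])) == 1 and len(set(labels[200:])) == 1
        assert labels[0] != labels[-1]

    def test_too_few_distinct_points_rejected(self):
        pts = np.tile([[1.0, 2.0]], (10, 1))
        with pytest.raises(ValidationError, match="distinct"):
            msm.kmeans_discretize([pts], 3, seed=0)

    def test_assign_to_centers_matches_fit(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(300, 3))
        dtrajs, centers = msm.kmeans_discretize([x], 10, seed=3)
        re = msm.assign_to_centers([x], centers)
        assert np.array_equal(re[0].states, dtrajs[0].states)


class TestCountMatrix:
    def test_hand_counted_lag1(self):
        cm = msm.count_matrix([_dtraj([0, 0, 1, 1])], lag=1)
        assert np.array_equal(cm.counts, [[1, 1], [0, 1]])

    def test_hand_counted_lag3(self):
        cm = msm.count_matrix([_dtraj([0, 0, 1, 1])], lag=3)
        assert np.array_equal(cm.counts, [[0, 1], [0, 0]])

    def test_matches_explicit_double_loop(self):
        rng = np.random.default_rng(3)
        dtrajs = [_dtraj(rng.integers(0, 5, size=60), n=5, tid=f"t{i}")
                  for i in range(3)]
        for lag in (1, 2, 7):
            cm = msm.count_matrix(dtrajs, lag)
            expect = np.zeros((5, 5))
            for d in dtrajs:
                for t in range(len(d) - lag):
                    expect[d.states[t], d.states[t + lag]] += 1
            assert np.array_equal(cm.counts, expect)

    def test_counting_never_crosses_trajectories(self):
        cm = msm.count_matrix([_dtraj([0, 0], n=2), _dtraj([1, 1], n=2)], lag=1)
        assert np.array_equal(cm.counts, [[1, 0], [0, 1]])

    def test_all_short_trajectories_rejected(self):
        with pytest.raises(ValidationError, match="shorter"):
            msm.count_matrix([_dtraj([0, 1])], lag=5)

    def test_active_set_excludes_disconnected_states(self):
        # states {0,1} exchange; state 2 is an isolated self-looper
        cm = msm.count_matrix([_dtraj([0, 1, 0, 1, 0], n=3), _dtraj([2, 2, 2], n=3)],
                              lag=1)
        assert np.array_equal(cm.active_set, [0, 1])
        assert cm.n_frames_outside == 3


class TestReversibleMLE:
    def test_symmetric_counts_give_symmetric_model(self):
        mdl = msm.estimate_reversible_mle(_count_model([[90, 10], [10, 90]]))
        assert np.allclose(mdl.transition_matrix, [[0.9, 0.1], [0.1, 0.9]], atol=1e-10)
        assert np.allclose(mdl.stationary, [0.5, 0.5], atol=1e-10)

    def test_2x2_matches_direct_likelihood_maximizer(self):
        C = np.array([[80.0, 20.0], [10.0, 90.0]])
        mdl = msm.estimate_reversible_mle(_count_model(C))

        # oracle: maximize the reversible likelihood over symmetric weights
        def negll(theta):
            x = np.array([[np.exp(theta[0]), np.exp(theta[1])],
                          [np.exp(theta[1]), np.exp(theta[2])]])
            P = x / x.sum(axis=1, keepdims=True)
            return -np.sum(C * np.log(P))

        best = scipy.optimize.minimize(negll, np.zeros(3), method="Nelder-Mead",
                                       options={"xatol": 1e-12, "fatol": 1e-14,
                                                "maxiter": 20_000})
        x = np.array([[np.exp(best.x[0]), np.exp(best.x[1])],
                      [np.exp(best.x[1]), np.exp(best.x[2])]])
        P_oracle = x / x.sum(axis=1, keepdims=True)
        assert np.allclose(mdl.transition_matrix, P_oracle, atol=1e-6, rtol=0)
        # for 2 states detailed balance is unrestrictive, so the closed-form
        # optimum is plain row normalization; the estimator must hit it
        assert np.allclose(mdl.transition_matrix,
                           C / C.sum(axis=1, keepdims=True), atol=1e-8, rtol=0)

    def test_3x3_matches_constrained_optimizer(self):
        C = np.array([[50.0, 6.0, 2.0], [9.0, 70.0, 4.0], [1.0, 6.0, 40.0]])
        mdl = msm.estimate_reversible_mle(_count_model(C))

        iu = np.triu_indices(3)

        def negll(theta):
            x = np.zeros((3, 3))
            x[iu] = np.exp(theta)
            x = x + np.triu(x, 1).T
            P = x / x.sum(axis=1, keepdims=True)
            return -np.sum(C * np.log(P))

        best = scipy.optimize.minimize(negll, np.zeros(6), method="Nelder-Mead",
                                       options={"xatol": 1e-12, "fatol": 1e-14,
                                                "maxiter": 100_000, "maxfev": 100_000})
        x = np.zeros((3, 3))
        x[iu] = np.exp(best.x)
        x = x + np.triu(x, 1).T
        P_oracle = x / x.sum(axis=1, keepdims=True)
        assert np.allclose(mdl.transition_matrix, P_oracle, atol=1e-7)

    def test_recovers_generating_chain(self, small_system):
        spec, hidden, _ = small_system
        dtrajs = [_dtraj(h, n=3, dt=spec.dt, tid=f"t{i}")
                  for i, h in enumerate(hidden)]
        mdl = msm.estimate_reversible_mle(msm.count_matrix(dtrajs, 1))
        n_trans = sum(len(h) - 1 for h in hidden)
        assert np.max(np.abs(mdl.transition_matrix - spec.exchange)) < \
            5 * np.sqrt(0.02 / (0.2 * n_trans))

    def test_detailed_balance_and_left_eigenvector(self):
        rng = np.random.default_rng(4)
        C = rng.integers(1, 200, size=(6, 6)).astype(float)
        mdl = msm.estimate_reversible_mle(_count_model(C))
        P, pi = mdl.transition_matrix, mdl.stationary
        assert np.max(np.abs(pi[:, None] * P - (pi[:, None] * P).T)) < 1e-10
        assert np.max(np.abs(P.sum(axis=1) - 1.0)) < 1e-10
        assert np.max(np.abs(pi @ P - pi)) < 1e-8


class TestImpliedTimescales:
    def test_closed_form_two_state(self):
        mdl = TransitionModel(transition_matrix=np.array([[0.9, 0.1], [0.1, 0.9]]),
                              stationary=np.array([0.5, 0.5]), lag=1, dt=1.0)
        assert mdl.timescales[0] == pytest.approx(-1 / np.log(0.8))

    def test_markovian_data_has_flat_its(self, small_system):
        spec, hidden, _ = small_system
        dtrajs = [_dtraj(h, n=3, dt=spec.dt, tid=f"t{i}")
                  for i, h in enumerate(hidden)]
        res = msm.implied_timescales(dtrajs, [1, 2, 5, 10], n_timescales=2,
                                     n_samples=50, seed=0)
        # ML curve of each process stays within every lag's 95% band
        for i in range(2):
            ref = res.timescales[0, i]
            assert np.all(res.lower[:, i] <= ref * 1.2)
            assert np.all(res.upper[:, i] >= ref * 0.8)

    def test_eigenvalue_one_reports_infinity(self):
        P = np.eye(2)
        mdl = TransitionModel(transition_matrix=P, stationary=np.array([0.5, 0.5]),
                              lag=1, dt=1.0)
        assert np.isinf(mdl.timescales[0])

    def test_too_many_timescales_rejected(self):
        dtrajs = [_dtraj([0, 1, 0, 1, 1, 0])]
        with pytest.raises(ValidationError, match="timescales"):
            msm.implied_timescales(dtrajs, [1], n_timescales=5)


class TestBayesianSampling:
    def test_symmetric_counts_center_on_half(self):
        ens = msm.bayesian_sample(_count_model([[450, 50], [50, 450]]),
                                  n=400, seed=1)
        assert ens.n_samples == 400
        assert np.allclose(ens.samples_pi.mean(axis=0), [0.5, 0.5], atol=0.02)

    def test_posterior_concentrates_with_counts(self):
        C = np.array([[80.0, 20.0], [10.0, 90.0]])
        sd1 = msm.bayesian_sample(_count_model(C), n=800, seed=2) \
            .samples_pi.std(axis=0)[0]
        sd10 = msm.bayesian_sample(_count_model(10 * C), n=800, seed=3) \
            .samples_pi.std(axis=0)[0]
        assert sd1 / sd10 == pytest.approx(np.sqrt(10), rel=0.3)

    def test_every_sample_is_reversible_and_stochastic(self):
        ens = msm.bayesian_sample(_count_model([[50, 6, 2], [9, 70, 4], [1, 6, 40]]),
                                  n=50, seed=4)
        for P, pi in ens.sample_models():
            assert np.max(np.abs(P.sum(axis=1) - 1.0)) < 1e-10
            flux = pi[:, None] * P
            assert np.max(np.abs(flux - flux.T)) < 1e-10

    def test_requires_at_least_two_samples(self):
        with pytest.raises(ValidationError):
            msm.bayesian_sample(_count_model([[5, 1], [1, 5]]), n=1)


class TestMFPT:
    P = np.array([[0.9, 0.1], [0.2, 0.8]])

    def test_geometric_waiting_times(self):
        assert msm.mfpt_from_matrix(self.P, [0], [1]) == pytest.approx(10.0)
        assert msm.mfpt_from_matrix(self.P, [1], [0]) == pytest.approx(5.0)

    def test_stationary_from_detailed_balance(self):
        mdl = TransitionModel(transition_matrix=self.P,
                              stationary=np.array([2 / 3, 1 / 3]), lag=1, dt=1.0)
        assert np.allclose(mdl.stationary, [2 / 3, 1 / 3])
        assert 1.0 / msm.mfpt(mdl, [0], [1]) == pytest.approx(0.1)

    def test_rate_is_inverse_mfpt(self):
        mdl = TransitionModel(transition_matrix=self.P,
                              stationary=np.array([2 / 3, 1 / 3]), lag=2, dt=0.5)
        t = msm.mfpt(mdl, [0], [1])
        assert t == pytest.approx(10.0)  # 10 steps of P x (2 frames x 0.5 ns)

    def test_matches_monte_carlo_hitting_times(self):
        rng = np.random.default_rng(5)
        C = rng.integers(5, 100, size=(6, 6)).astype(float)
        mdl = msm.estimate_reversible_mle(_count_model(C))
        P = mdl.transition_matrix
        source, target = [0], [4]
        expect = msm.mfpt_from_matrix(P, source, target, stationary=mdl.stationary)
        n_sim = 100_000
        cum = np.cumsum(P, axis=1)
        state = np.zeros(n_sim, dtype=int)
        steps = np.zeros(n_sim)
        alive = np.ones(n_sim, dtype=bool)
        t = 0
        while alive.any():
            t += 1
            u = rng.random(alive.sum())
            nxt = (cum[state[alive]] < u[:, None]).sum(axis=1)
            state[alive] = nxt
            hit = nxt == target[0]
            idx = np.flatnonzero(alive)
            steps[idx[hit]] = t
            alive[idx[hit]] = False
        se = steps.std() / np.sqrt(n_sim)
        assert abs(steps.mean() - expect) < 2 * se + 1e-9

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValidationError, match="disjoint"):
            msm.mfpt_from_matrix(self.P, [0], [0, 1])

    def test_unreachable_target_raises(self):
        P = np.array([[1.0, 0.0], [0.5, 0.5]])
        with pytest.raises(UnreachableStateError):
            msm.mfpt_from_matrix(P, [0], [1])


class TestCKTest:
    def _markov_dtrajs(self, seed):
        spec = synthetic.default_system_spec(seed=seed, n_traj=8, n_steps=1500)
        hidden = synthetic.simulate_hidden_chain(spec)
        return [_dtraj(h, n=3, tid=f"t{i}") for i, h in enumerate(hidden)]

    def test_k_equal_one_is_identity(self):
        dtrajs = self._markov_dtrajs(0)
        mdl = msm.estimate_reversible_mle(msm.count_matrix(dtrajs, 2))
        ck = msm.ck_test(dtrajs, mdl, np.eye(3), [1], n_bootstrap=20, seed=0)
        assert np.allclose(ck.predicted[:, 0], ck.estimated[:, 0], atol=1e-10)

    def test_markovian_data_passes(self):
        dtrajs = self._markov_dtrajs(1)
        mdl = msm.estimate_reversible_mle(msm.count_matrix(dtrajs, 2))
        ck = msm.ck_test(dtrajs, mdl, np.eye(3), [1, 2, 3, 4, 5],
                         n_bootstrap=200, seed=1)
        assert ck.passed.all()

    def test_lumped_nonmarkovian_data_fails(self):
        spec, lump = synthetic.nonmarkov_lumped_spec(seed=0)
        hidden = synthetic.simulate_hidden_chain(spec)
        dtrajs = [_dtraj(lump[h], n=2, tid=f"t{i}") for i, h in enumerate(hidden)]
        mdl = msm.estimate_reversible_mle(msm.count_matrix(dtrajs, 1))
        ck = msm.ck_test(dtrajs, mdl, np.eye(2), [1, 2, 3, 4, 5],
                         n_bootstrap=200, seed=0)
        assert not ck.passed.all()

    def test_insufficient_data_reported_as_gap(self):
        dtrajs = [_dtraj([0, 1, 0, 1, 0, 1])]
        mdl = msm.estimate_reversible_mle(msm.count_matrix(dtrajs, 1))
        ck = msm.ck_test(dtrajs, mdl, np.eye(2), [1, 2, 10], n_bootstrap=10, seed=0)
        assert 10 in ck.gaps
        assert np.isnan(ck.estimated[:, 2]).all()


class TestVariationalScore:
    def test_single_state_scores_one(self):
        rng = np.random.default_rng(6)
        proj = [rng.normal(size=(400, 2)) for _ in range(4)]
        df = msm.variational_cv_score(proj, lag=2, k_candidates=[1], n_folds=2,
                                      m=3, seed=0)
        assert df["score_mean"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_plateau_at_true_state_count(self, small_system):
        spec, hidden, trajs = small_system
        proj = [t.values[:, :4] for t in trajs]
        df = msm.variational_cv_score(proj, lag=5, k_candidates=[1, 2, 3, 6, 12],
                                      n_folds=2, m=3, seed=0)
        scores = dict(zip(df["k"], df["score_mean"]))
        assert scores[3] > scores[2] + 0.1
        assert abs(scores[12] - scores[3]) < 0.1
        assert abs(scores[6] - scores[3]) < 0.1
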