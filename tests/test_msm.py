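"""Markov-state-model estimation, spectral analysis and coarse graining."""

import numpy as np
import pytest

from confex import msm, synthetic as syn, tpt
from tests.conftest import two_state_model


class TestCountMatrix:
    @pytest.mark.parametrize(
        "states,lag,expected",
        [
            ([0, 0, 0], 1, [[2]]),
            ([0, 1, 0, 1], 1, [[0, 2], [1, 0]]),
            ([0, 1, 0, 1], 2, [[1, 0], [0, 1]]),
        ],
    )
    def test_hand_counts(self, states, lag, expected):
        c = msm.count_matrix(msm.StateTraj(np.array(states), 1.0), lag)
        np.testing.assert_array_equal(c, expected)

    def test_no_counting_across_trajectory_boundaries(self):
        trajs = [msm.StateTraj(np.array([0, 1]), 1.0), msm.StateTraj(np.array([1, 0]), 1.0)]
        c = msm.count_matrix(trajs, 1)
        np.testing.assert_array_equal(c, [[0, 1], [1, 0]])

    def test_lag_exceeding_all_trajectories(self):
        with pytest.raises(ValueError, match="lag"):
            msm.count_matrix(msm.StateTraj(np.array([0, 1, 0]), 1.0), 5)

    def test_strided_counts_subsample(self):
        traj = msm.StateTraj(np.array([0, 1, 0, 1, 0]), 1.0)
        c = msm.count_matrix(traj, 2, mode="strided")
        assert c.sum() == 2  # pairs (t=0,2) and (t=2,4)


class TestTransitionMatrix:
    def test_nonreversible_hand_example(self):
        c = np.array([[8, 2], [1, 9]])
        model = msm.transition_matrix(c, reversible=False, lag_time=1.0)
        np.testing.assert_allclose(model.transition_mat, [[0.8, 0.2], [0.1, 0.9]])
        np.testing.assert_allclose(model.stationary, [1 / 3, 2 / 3], atol=1e-12)

    def test_symmetric_counts_estimators_coincide(self):
        c = np.array([[50, 10], [10, 30]])
        t_rev = msm.transition_matrix(c, reversible=True).transition_mat
        t_non = msm.transition_matrix(c, reversible=False).transition_mat
        np.testing.assert_allclose(t_rev, t_non, atol=1e-14)

    def test_reversible_satisfies_detailed_balance(self):
        rng = np.random.default_rng(0)
        c = rng.integers(1, 50, size=(5, 5))
        model = msm.transition_matrix(c, reversible=True)
        flows = model.stationary[:, None] * model.transition_mat
        np.testing.assert_allclose(flows, flows.T, atol=1e-12)
        assert np.all(np.abs(np.imag(model.eigenvalues)) < 1e-12)
        assert np.all(np.diff(np.real(model.eigenvalues)) <= 1e-12)
        assert np.all(model.stationary > 0)

    def test_disconnected_states_trimmed_and_reported(self):
        c = np.zeros((4, 4), dtype=int)
        c[:2, :2] = [[30, 5], [5, 10]]
        c[3, 3] = 2  # isolated self-transitioning state; state 2 never seen
        model = msm.transition_matrix(c, reversible=True)
        assert model.n_states == 2
        np.testing.assert_array_equal(model.active_states, [0, 1])
        assert set(model.trimmed_states) == {2, 3}


class TestSpectralAnalysis:
    def test_two_state_implied_timescale_closed_form(self):
        model = two_state_model(0.1, 0.3, lag_time=22.5)
        assert model.eigenvalues[1] == pytest.approx(0.6, abs=1e-9)
        assert model.timescales[0] == pytest.approx(-22.5 / np.log(0.6), rel=1e-9)
        assert model.timescales[0] == pytest.approx(44.05, abs=0.01)

    def test_identity_matrix_infinite_timescales(self):
        model = msm.TransitionModel(
            lag_time=1.0, count_mat=np.eye(3, dtype=int), transition_mat=np.eye(3),
            stationary=np.full(3, 1 / 3), eigenvalues=np.ones(3, dtype=complex),
            right_eigenvectors=np.eye(3), left_eigenvectors=np.eye(3),
            active_states=np.arange(3), trimmed_states=np.array([], dtype=int),
            reversible=True,
        )
        assert np.all(np.isinf(model.timescales))

    def test_timescales_invariant_under_trajectory_duplication(self):
        traj = syn.gen_markov_traj(
            syn.GeneratorMatrixSpec(
                n_states=2, dt=1.0, t_gen=np.array([[0.9, 0.1], [0.2, 0.8]])
            ),
            5000, seed=1, start=0,
        )
        m1 = msm.transition_matrix(msm.count_matrix(traj, 1), lag_time=1.0)
        m2 = msm.transition_matrix(msm.count_matrix([traj, traj], 1), lag_time=1.0)
        np.testing.assert_allclose(m1.timescales, m2.timescales, rtol=1e-12)

    def test_implied_timescale_table_flat_for_markov_data(self):
        spec = syn.GeneratorMatrixSpec(
            n_states=2, dt=1.0, t_gen=np.array([[0.98, 0.02], [0.05, 0.95]])
        )
        trajs = [syn.gen_markov_traj(spec, 50_000, seed=i, start=0) for i in range(4)]
        table = msm.implied_timescales(trajs, [1, 2, 5, 10])
        t2 = table["t2"].to_numpy()
        true_t2 = -1.0 / np.log(0.93)
        assert np.all(np.abs(t2 - true_t2) / true_t2 < 0.15)


class TestPropagate:
    def test_zero_steps_returns_initial(self, chain3_model):
        p0 = np.array([1.0, 0.0, 0.0])
        np.testing.assert_allclose(msm.propagate(chain3_model, p0, 0), p0)

    def test_stationary_is_fixed_point(self, chain3_model):
        pi = chain3_model.stationary
        for n in (1, 5, 50):
            np.testing.assert_allclose(msm.propagate(chain3_model, pi, n), pi, atol=1e-12)

    def test_matches_successive_multiplication(self, chain3_model):
        p0 = np.array([0.5, 0.3, 0.2])
        p_direct = p0.copy()
        for _ in range(7):
            p_direct = p_direct @ chain3_model.transition_mat
        np.testing.assert_allclose(msm.propagate(chain3_model, p0, 7), p_direct, atol=1e-12)
        assert msm.propagate(chain3_model, p0, 7).sum() == pytest.approx(1.0, abs=1e-12)


class TestKabschRmsd:
    def test_identical_sets(self):
        x = np.random.default_rng(0).normal(size=(10, 3))
        assert msm.kabsch_rmsd(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_gives_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(12, 3))
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1]]
        )
        y = x @ rot.T + np.array([1.0, -2.0, 3.0])
        assert msm.kabsch_rmsd(x, y) == pytest.approx(0.0, abs=1e-10)

    def test_matches_brute_force_rotation_search(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(8, 3))
        y = x.copy()
        y[0] += np.array([0.5, -0.2, 0.3])
        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)

        def rmsd_of(q):
            w, a, b, c = q / np.linalg.norm(q)
            rot = np.array(
                [
                    [1 - 2 * (b * b + c * c), 2 * (a * b - w * c), 2 * (a * c + w * b)],
                    [2 * (a * b + w * c), 1 - 2 * (a * a + c * c), 2 * (b * c - w * a)],
                    [2 * (a * c - w * b), 2 * (b * c + w * a), 1 - 2 * (a * a + b * b)],
                ]
            )
            return float(np.sqrt(np.mean(np.sum((xc @ rot - yc) ** 2, axis=1))))

        # coarse random search over rotations, then local refinement
        best_q, best = None, np.inf
        for _ in range(20_000):
            q = rng.normal(size=4)
            r = rmsd_of(q)
            if r < best:
                best_q, best = q, r
        for scale in (0.1, 0.03, 0.01, 0.003):
            for _ in range(3_000):
                q = best_q + scale * rng.normal(size=4)
                r = rmsd_of(q)
                if r < best:
                    best_q, best = q, r
        kab = msm.kabsch_rmsd(x, y)
        assert kab <= best + 1e-9
        assert best - kab < 0.005

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            msm.kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))


class TestClustering:
    def test_two_separated_blobs_recovered(self):
        rng = np.random.default_rng(3)
        a = rng.normal(loc=(-5, 0), scale=0.1, size=(200, 2))
        b = rng.normal(loc=(5, 0), scale=0.1, size=(200, 2))
        traj = msm.FeatureTraj(np.vstack([a, b]), 1.0)
        straj, centers = msm.assign_microstates(traj, 2, seed=0)
        assert len(np.unique(straj.states[:200])) == 1
        assert len(np.unique(straj.states[200:])) == 1
        assert straj.states[0] != straj.states[-1]

    def test_seed_reproducible_centers(self):
        rng = np.random.default_rng(4)
        traj = msm.FeatureTraj(rng.normal(size=(300, 2)), 1.0)
        _, c1 = msm.assign_microstates(traj, 5, seed=7)
        _, c2 = msm.assign_microstates(traj, 5, seed=7)
        np.testing.assert_array_equal(c1, c2)

    def test_single_cluster_and_too_many_clusters(self):
        traj = msm.FeatureTraj(np.random.default_rng(5).normal(size=(50, 2)), 1.0)
        straj, _ = msm.assign_microstates(traj, 1, seed=0)
        assert np.all(straj.states == 0)
        with pytest.raises(ValueError, match="n_micro"):
            msm.assign_microstates(traj, 100, seed=0)


class TestLumping:
    def block_model(self, eps=0.01):
        t = np.array(
            [
                [0.6 - eps, 0.4, eps, 0.0],
                [0.4, 0.6 - eps, 0.0, eps],
                [eps, 0.0, 0.7 - eps, 0.3],
                [0.0, eps, 0.3, 0.7 - eps],
            ]
        )
        c = np.rint(t * 1e7).astype(np.int64)
        return msm.transition_matrix(c, reversible=True, lag_time=1.0)

    def test_two_blocks_recovered(self):
        lump = msm.lump_macrostates(self.block_model(), 2)
        assert lump.assignments[0] == lump.assignments[1]
        assert lump.assignments[2] == lump.assignments[3]
        assert lump.assignments[0] != lump.assignments[2]

    def test_full_lumping_is_identity_partition(self):
        model = self.block_model()
        lump = msm.lump_macrostates(model, 4)
        assert len(np.unique(lump.assignments)) == 4

    def test_assignment_is_partition_with_unit_weight(self):
        lump = msm.lump_macrostates(self.block_model(), 2)
        assert lump.assignments.shape == (4,)
        assert lump.macro_weights.sum() == pytest.approx(1.0, abs=1e-12)


class TestChapmanKolmogorov:
    def test_markov_data_self_consistent(self):
        t = np.array([[0.95, 0.05], [0.1, 0.9]])
        spec = syn.GeneratorMatrixSpec(n_states=2, dt=1.0, t_gen=t)
        trajs = [syn.gen_markov_traj(spec, 20_000, seed=i, start=0) for i in range(5)]
        model = msm.transition_matrix(msm.count_matrix(trajs, 1), reversible=False, lag_time=1.0)
        table = msm.ck_test(trajs, model, [1, 2, 5, 10])
        assert np.all(table[table.n == 1]["deviation"] < 1e-12)
        assert np.all(table[table.available]["deviation"] < 0.02)

    def test_hidden_state_data_fails_ck(self):
        # 3 hidden states projected onto 2 observed symbols: non-Markov
        t_hidden = np.array([[0.99, 0.01, 0.0], [0.05, 0.9, 0.05], [0.0, 0.01, 0.99]])
        spec = syn.GeneratorMatrixSpec(n_states=3, dt=1.0, t_gen=t_hidden)
        hidden = [syn.gen_markov_traj(spec, 50_000, seed=i, start=0) for i in range(4)]
        observed = [msm.StateTraj((h.states >= 2).astype(int), 1.0) for h in hidden]
        model = msm.transition_matrix(msm.count_matrix(observed, 1), lag_time=1.0)
        table = msm.ck_test(observed, model, [1, 30])
        dev_30 = table[(table.n == 30) & table.available]["deviation"]
        assert np.max(dev_30) > 0.05


class TestTwoStateReduction:
    def test_exact_two_state_self_consistency(self):
        p01, p10 = 0.02, 0.08
        model = two_state_model(p01, p10, lag_time=2.0)
        red = msm.two_state_reduction(model, None, [0], [1])
        kex_expected = 1.0 / (-2.0 / np.log(1 - p01 - p10))
        assert red.kex == pytest.approx(kex_expected, rel=1e-9)
        assert red.p_e == pytest.approx(model.stationary[0], rel=1e-9)

    def test_restricted_population_ratio(self, chain3_model):
        red = msm.two_state_reduction(chain3_model, None, [0], [2])
        pi = chain3_model.stationary
        assert red.p_e == pytest.approx(pi[0] / (pi[0] + pi[2]), rel=1e-12)

    def test_overlapping_sets_rejected(self, chain3_model):
        with pytest.raises(ValueError, match="disjoint"):
            msm.two_state_reduction(chain3_model, None, [0, 1], [1, 2])


class TestFreeEnergySurface:
    def test_uniform_two_bins_zero_difference(self):
        xy = np.array([[0.25, 0.5]] * 50 + [[0.75, 0.5]] * 50)
        surf = msm.free_energy_surface(
            msm.FeatureTraj(xy, 1.0), np.zeros(100, dtype=int), np.array([1.0]), bins=2
        )
        finite = surf.f_grid[np.isfinite(surf.f_grid)]
        assert np.max(finite) == pytest.approx(0.0, abs=1e-12)

    def test_e_to_one_occupancy_ratio_gives_one_kbt(self):
        n_a, n_b = 100, 100
        xy = np.array([[0.25, 0.5]] * n_a + [[0.75, 0.5]] * n_b)
        assign = np.array([0] * n_a + [1] * n_b)
        e = np.e
        pi = np.array([e / (1 + e), 1 / (1 + e)])
        surf = msm.free_energy_surface(msm.FeatureTraj(xy, 1.0), assign, pi, bins=2)
        pmf = surf.pmf_x
        assert np.max(pmf[np.isfinite(pmf)]) == pytest.approx(1.0, abs=1e-12)

    def test_langevin_double_well_depth_recovered(self):
        # asymmetric wells: free-energy offset between minima ~ potential offset
        pot = syn.PotentialSpec(
            wells=[((-1.0, 0.0), 6.5, 0.35), ((1.0, 0.0), 5.0, 0.35)],
            confine_k=1.0,
        )
        traj = syn.gen_langevin_traj(pot, 1e-3, 1_500_000, seed=6, x0=(-1.0, 0.0), stride=3)
        assign = (traj.x[:, 0] > 0).astype(int)
        c = msm.count_matrix(msm.StateTraj(assign, traj.dt), 10)
        model = msm.transition_matrix(c, reversible=True, lag_time=10 * traj.dt)
        surf = msm.free_energy_surface(
            traj, assign, model.stationary, bins=np.linspace(-2.0, 2.0, 41).tolist()
        )
        centers = 0.5 * (surf.x_edges[:-1] + surf.x_edges[1:])
        pmf = surf.pmf_x
        f_a = np.min(pmf[centers < 0])
        f_b = np.min(pmf[centers > 0])
        du = pot.energy([1.0, 0.0]) - pot.energy([-1.0, 0.0])
        assert f_b - f_a == pytest.approx(du, abs=0.3)

    def test_single_bin_degenerate_warning(self):
        xy = np.zeros((10, 2))
        with pytest.warns(UserWarning, match="degenerate"):
            surf = msm.free_energy_surface(
                msm.FeatureTraj(xy, 1.0), np.zeros(10, dtype=int), np.array([1.0]), bins=3
            )
        assert surf.degenerate
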