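"""Committors, reactive flux, pathway decomposition and path times."""

import numpy as np
import pytest

from confex import msm, synthetic as syn, tpt
from tests.conftest import two_state_model


def chain_model(n, p=0.5):
    """Unbiased nearest-neighbor chain of n states."""
    t = np.zeros((n, n))
    for i in range(n):
        if i > 0:
            t[i, i - 1] = p / 2
        if i < n - 1:
            t[i, i + 1] = p / 2
        t[i, i] = 1.0 - t[i].sum()
    c = np.rint(t * 1e7).astype(np.int64)
    return msm.transition_matrix(c, reversible=True, lag_time=1.0)


def lattice_model(pot, n=21, extent=2.0):
    """Deterministic grid MSM from a 2-D potential via Metropolis rates.

    Gives an exact, sampling-free discretization for flux/pathway tests."""
    xs = np.linspace(-extent, extent, n)
    xy = np.array([(x, y) for x in xs for y in xs])
    u = pot.energy(xy)
    n2 = n * n
    t = np.zeros((n2, n2))
    hop = 0.2
    for i in range(n2):
        ix, iy = divmod(i, n)
        for jx, jy in ((ix - 1, iy), (ix + 1, iy), (ix, iy - 1), (ix, iy + 1)):
            if 0 <= jx < n and 0 <= jy < n:
                j = jx * n + jy
                t[i, j] = hop * min(1.0, np.exp(-(u[j] - u[i]) / pot.kbt))
        t[i, i] = 1.0 - t[i].sum()
    pi = np.exp(-u / pot.kbt)
    pi /= pi.sum()
    c = np.rint(t * pi[:, None] * 1e13).astype(np.int64)
    model = msm.transition_matrix(c, reversible=True, lag_time=1.0)
    centers = xy[model.active_states]
    return model, centers


class TestCommittors:
    def test_symmetric_chain_transition_state(self, chain3_model):
        comm = tpt.committors(chain3_model, [0], [2])
        assert comm.q_plus[1] == pytest.approx(0.5, abs=1e-12)

    def test_gamblers_ruin_closed_form(self):
        n = 7
        model = chain_model(n)
        comm = tpt.committors(model, [0], [n - 1])
        np.testing.assert_allclose(comm.q_plus, np.arange(n) / (n - 1), atol=1e-9)

    def test_boundary_conditions(self, chain3_model):
        comm = tpt.committors(chain3_model, [0], [2])
        assert comm.q_plus[0] == 0.0 and comm.q_plus[2] == 1.0
        assert comm.q_minus[0] == 1.0 and comm.q_minus[2] == 0.0

    def test_reversible_backward_committor_complement(self):
        model = chain_model(6, p=0.8)
        comm = tpt.committors(model, [0], [5])
        np.testing.assert_allclose(comm.q_minus, 1.0 - comm.q_plus, atol=1e-10)

    def test_unreachable_sink_reported(self):
        t = np.array([[0.9, 0.1, 0.0], [0.1, 0.9, 0.0], [0.0, 0.0, 1.0]])
        model = msm.TransitionModel(
            lag_time=1.0, count_mat=np.rint(t * 1e6).astype(int), transition_mat=t,
            stationary=np.array([0.5, 0.5, 0.0]),
            eigenvalues=np.array([1.0, 1.0, 0.8]),
            right_eigenvectors=np.eye(3), left_eigenvectors=np.eye(3),
            active_states=np.arange(3), trimmed_states=np.array([], dtype=int),
            reversible=False,
        )
        with pytest.raises(ValueError, match="unreachable"):
            tpt.committors(model, [0], [2])


class TestReactiveFlux:
    def test_divergence_free_at_intermediates(self):
        model = chain_model(6, p=0.6)
        comm = tpt.committors(model, [0], [5])
        flux = tpt.reactive_flux(model, comm)
        div = flux.net.sum(axis=1) - flux.net.sum(axis=0)
        np.testing.assert_allclose(div[1:-1], 0.0, atol=1e-14)
        assert flux.total == pytest.approx(flux.net[:, 5].sum(), rel=1e-10)

    def test_total_flux_matches_mfpt_cycle_rate(self):
        # the A->B transition frequency equals 1/(mfpt(A->B)+mfpt(B->A));
        # mean first-passage times from an independent linear solve
        model = chain_model(5, p=0.7)
        t = model.transition_mat

        def mfpt(target):
            others = [i for i in range(5) if i != target]
            a = np.eye(4) - t[np.ix_(others, others)]
            tau = np.linalg.solve(a, np.ones(4))
            out = np.zeros(5)
            out[others] = tau
            return out

        m_ab = mfpt(4)[0]
        m_ba = mfpt(0)[4]
        comm = tpt.committors(model, [0], [4])
        flux = tpt.reactive_flux(model, comm)
        assert flux.total == pytest.approx(1.0 / (m_ab + m_ba), rel=1e-9)


class TestPathwayDecomposition:
    def test_single_chain_single_path(self):
        model = chain_model(4)
        comm = tpt.committors(model, [0], [3])
        flux = tpt.reactive_flux(model, comm)
        paths = tpt.decompose_pathways(flux)
        assert len(paths.paths) == 1
        assert paths.paths[0][0] == (0, 1, 2, 3)
        assert paths.fractions[0] == pytest.approx(1.0, rel=1e-9)

    def test_parallel_branches_three_to_one(self):
        # A -> {fast branch 3u, slow branch u} -> B constructed directly
        net = np.zeros((4, 4))
        net[0, 1] = 3.0
        net[1, 3] = 3.0
        net[0, 2] = 1.0
        net[2, 3] = 1.0
        flux = tpt.FluxNetwork(gross=net, net=net, total=4.0,
                               source=np.array([0]), sink=np.array([3]))
        paths = tpt.decompose_pathways(flux)
        assert [p for p, _ in paths.paths] == [(0, 1, 3), (0, 2, 3)]
        np.testing.assert_allclose(paths.fractions, [0.75, 0.25])

    def test_fractions_non_increasing_residual_small(self):
        pot = syn.default_rugged_potential()
        model, centers = lattice_model(pot, n=17)
        a = [int(np.argmin(np.linalg.norm(centers - [-1.2, 0.0], axis=1)))]
        b = [int(np.argmin(np.linalg.norm(centers - [1.2, 0.0], axis=1)))]
        comm = tpt.committors(model, a, b)
        flux = tpt.reactive_flux(model, comm)
        paths = tpt.decompose_pathways(flux, stop_fraction=0.999)
        fr = paths.fractions
        assert np.all(np.diff(fr) <= 1e-12)
        assert paths.residual_flux / paths.total_flux < 1e-3

    def test_rugged_surface_multiple_paths_and_trap_routing(self):
        # the rugged surface supports many distinct pathways, and deepening
        # the intermediate traps (which lowers the saddles around them)
        # routes a growing share of the reactive flux through the traps
        shallow = syn.default_rugged_potential()
        trap_centers = np.array([w[0] for w in shallow.wells[2:]])
        fractions = []
        counts = []
        for extra in (0.0, 1.0, 2.0):
            pot = syn.PotentialSpec(
                wells=[(c, d + extra if i >= 2 else d, w)
                       for i, (c, d, w) in enumerate(shallow.wells)],
                confine_k=shallow.confine_k,
            )
            model, centers = lattice_model(pot, n=17)
            a = [int(np.argmin(np.linalg.norm(centers - [-1.2, 0.0], axis=1)))]
            b = [int(np.argmin(np.linalg.norm(centers - [1.2, 0.0], axis=1)))]
            comm = tpt.committors(model, a, b)
            flux = tpt.reactive_flux(model, comm)
            paths = tpt.decompose_pathways(flux, stop_fraction=0.99)
            counts.append(len(paths.paths))
            via_trap = 0.0
            for p, f in paths.paths:
                d = np.linalg.norm(centers[list(p)][:, None, :] - trap_centers[None, :, :], axis=2)
                if np.any(d < 0.35):
                    via_trap += f / paths.total_flux
            fractions.append(via_trap)
        assert counts[0] > 1
        assert fractions[0] < fractions[1] < fractions[2]


class TestTransitionPaths:
    def test_hand_labeled_sequence(self):
        traj = msm.StateTraj(np.array([0, 0, 2, 2, 2, 1]), 1.0)
        sample = tpt.extract_transition_paths(traj, [0], [1])
        assert len(sample) == 1
        assert sample.durations[0] == 4.0
        assert sample.directions[0] == 1

    def test_no_sink_visit_gives_empty_sample(self):
        traj = msm.StateTraj(np.array([0, 2, 0, 2]), 1.0)
        sample = tpt.extract_transition_paths(traj, [0], [1])
        assert len(sample) == 0

    def test_both_directions_pooled(self):
        traj = msm.StateTraj(np.array([0, 2, 1, 2, 2, 0]), 1.0)
        sample = tpt.extract_transition_paths(traj, [0], [1])
        assert list(sample.directions) == [1, -1]
        assert list(sample.durations) == [2.0, 3.0]

    def test_langevin_path_times_much_shorter_than_waiting(self):
        pot = syn.double_well_potential(depth=6.5, width=0.35)
        traj = syn.gen_langevin_traj(pot, 1e-3, 1_000_000, seed=12, x0=(-1.0, 0.0), stride=5)
        labels = tpt.core_labels(traj.x, (-1.0, 0.0), (1.0, 0.0), 0.5)
        st = msm.StateTraj(labels, traj.dt)
        sample = tpt.extract_transition_paths(st, [0], [1])
        assert len(sample) > 5
        time_in_wells = np.sum(labels != 2) * traj.dt
        mean_wait = time_in_wells / len(sample)
        assert sample.mean / mean_wait < 0.05


class TestOrdering:
    def test_ordered_model_identity_permutation(self):
        model = chain_model(5)
        comm = tpt.committors(model, [0], [4])
        order, _ = tpt.order_states_by_committor(model, comm)
        np.testing.assert_array_equal(order, np.arange(5))

    def test_reversed_labels_fully_reversed(self):
        model = chain_model(5)
        comm = tpt.committors(model, [4], [0])
        order, _ = tpt.order_states_by_committor(model, comm)
        np.testing.assert_array_equal(order, np.arange(5)[::-1])

    def test_permutation_preserves_spectrum(self):
        model = chain_model(6, p=0.8)
        comm = tpt.committors(model, [0], [5])
        _, relabeled = tpt.order_states_by_committor(model, comm)
        lam_old = np.sort(np.linalg.eigvals(model.transition_mat))
        lam_new = np.sort(np.linalg.eigvals(relabeled.transition_mat))
        np.testing.assert_allclose(lam_old, lam_new, atol=1e-10)
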