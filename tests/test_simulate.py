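"""Event-driven simulator: local rules, conservation, exact limits."""

import numpy as np
import pytest

import failrecov as fr
from failrecov.simulate import ACTIVE, EXT_FAILED, INT_FAILED, read_snapshot, write_snapshot


def states_like(net, value=ACTIVE):
    return np.full(net.n, value, dtype=np.int8)


class TestCdn:
    def test_isolated_node_always_critical(self, single_node):
        st = states_like(single_node)
        assert fr.is_cdn(single_node, st, 0, m=0)

    def test_two_active_neighbors_not_critical_at_m1(self, lattice3):
        st = states_like(lattice3, INT_FAILED)
        nbrs = lattice3.adjacency_csr()[1][:4]  # neighbors of node 0
        st[nbrs[0]] = ACTIVE
        st[nbrs[1]] = ACTIVE
        assert not fr.is_cdn(lattice3, st, 0, m=1)

    def test_all_neighbors_failed_is_critical(self, lattice3):
        st = states_like(lattice3, EXT_FAILED)
        st[0] = ACTIVE
        assert fr.is_cdn(lattice3, st, 0, m=1)

    def test_unknown_node_rejected(self, lattice3):
        with pytest.raises(KeyError):
            fr.is_cdn(lattice3, states_like(lattice3), 99, m=1)


class TestNodeRates:
    def test_active_in_cdn_has_two_channels(self, lattice3):
        st = states_like(lattice3, INT_FAILED)
        st[0] = ACTIVE
        params = fr.ModelParams(p=0.1, r=0.95, q=1.0, q_prime=0.1, m=1)
        total, menu = fr.node_rates(lattice3, st, params, 0)
        assert total == pytest.approx(1.05)
        assert {t for t, _ in menu} == {INT_FAILED, EXT_FAILED}

    def test_internally_failed_single_channel(self, lattice3):
        st = states_like(lattice3)
        st[0] = INT_FAILED
        params = fr.ModelParams(p=0.1, r=0.95, q=1.0, q_prime=0.1, m=1)
        total, menu = fr.node_rates(lattice3, st, params, 0)
        assert total == pytest.approx(1.0)
        assert menu == [(ACTIVE, 1.0)]

    def test_active_outside_cdn_only_internal(self, lattice3):
        st = states_like(lattice3)
        params = fr.ModelParams(p=0.1, r=0.95, q=1.0, q_prime=0.1, m=1)
        total, menu = fr.node_rates(lattice3, st, params, 0)
        assert total == pytest.approx(0.1)
        assert menu == [(INT_FAILED, 0.1)]


class TestGillespie:
    def test_absorbing_all_active_without_failure(self, lattice3):
        params = fr.ModelParams(p=0.0, r=0.0, q=1.0, q_prime=1.0, m=1)
        traj = fr.run_gillespie(lattice3, params, t_max=10, sample_dt=1, seed=0)
        assert np.all(traj.z == 1.0)
        assert traj.event_count == 0

    def test_single_node_three_state_stationary(self, single_node):
        # detailed balance of A<->X, A<->Y gives pi_A = 1/(1 + p/q + r/q')
        params = fr.ModelParams(p=1.0, r=1.0, q=1.0, q_prime=1.0, m=0)
        traj = fr.run_gillespie(single_node, params, t_max=30000, sample_dt=0.5, seed=42)
        keep = traj.times >= 100
        assert np.mean(traj.z[keep]) == pytest.approx(1 / 3, abs=0.02)
        assert np.mean(traj.u_int[keep]) == pytest.approx(1 / 3, abs=0.02)

    def test_compartments_sum_to_one_exactly(self, lattice3):
        params = fr.ModelParams(p=0.5, r=1.0, q=1.0, q_prime=0.3, m=1)
        traj = fr.run_gillespie(lattice3, params, t_max=200, sample_dt=0.25, seed=1)
        total = traj.z + traj.u_int + traj.u_ext
        # underlying counts sum to N exactly; fractions only up to rounding
        assert np.max(np.abs(total - 1.0)) < 1e-12
        assert np.all(np.diff(traj.times) > 0)

    def test_same_seed_reproduces_trajectory(self, lattice3):
        params = fr.ModelParams(p=0.3, r=0.9, q=1.0, q_prime=0.2, m=1)
        a = fr.run_gillespie(lattice3, params, t_max=100, sample_dt=1, seed=7)
        b = fr.run_gillespie(lattice3, params, t_max=100, sample_dt=1, seed=7)
        c = fr.run_gillespie(lattice3, params, t_max=100, sample_dt=1, seed=8)
        assert np.array_equal(a.z, b.z)
        assert a.event_count == b.event_count
        assert np.array_equal(a.final_states, b.final_states)
        assert not np.array_equal(a.z, c.z)

    def test_r_zero_independent_node_limit(self, lattice3):
        # without induced failure each node is a two-state unit:
        # stationary failed fraction (p/q)/(1 + p/q)
        params = fr.ModelParams(p=0.5, r=0.0, q=1.0, q_prime=0.7, m=1)
        traj = fr.run_gillespie(lattice3, params, t_max=20000, sample_dt=0.5, seed=3)
        keep = traj.times >= 50
        assert np.mean(traj.a[keep]) == pytest.approx(0.5 / 1.5, abs=0.02)

    def test_m_above_degree_closed_form(self, lattice3):
        # CDN always true: failed fraction s/(1+s), s = p/q + r/q'
        params = fr.ModelParams(p=0.25, r=0.375, q=1.0, q_prime=0.5, m=4)
        s = 0.25 + 0.75
        traj = fr.run_gillespie(lattice3, params, t_max=20000, sample_dt=0.5, seed=4)
        keep = traj.times >= 50
        assert np.mean(traj.a[keep]) == pytest.approx(s / (1 + s), abs=0.02)

    def test_partial_init_assigned_internal_type(self, lattice50):
        params = fr.ModelParams(p=0.0, r=0.0, q=0.0, q_prime=0.0, m=1)
        traj = fr.run_gillespie(lattice50, params, init=0.3, t_max=5, sample_dt=1, seed=0)
        assert traj.u_int[0] == pytest.approx(0.3, abs=1e-9)
        assert traj.u_ext[0] == 0.0

    def test_invalid_inputs_rejected(self, lattice3):
        params = fr.ModelParams(p=0.1, r=0.1, q=1.0, q_prime=1.0, m=1)
        with pytest.raises(ValueError):
            fr.run_gillespie(lattice3, params, t_max=0)
        with pytest.raises(ValueError):
            fr.run_gillespie(lattice3, params, init=np.zeros(5, dtype=np.int8))


class TestSnapshots:
    def test_all_active_snapshot_is_zero_matrix(self, lattice3):
        params = fr.ModelParams(p=0.0, r=0.0, q=1.0, q_prime=1.0, m=1)
        traj = fr.run_gillespie(
            lattice3, params, t_max=5, sample_dt=1, seed=0, snapshot_times=[0.0]
        )
        grid = fr.export_snapshot(traj, 0)
        assert grid.shape == (3, 3)
        assert np.all(grid == 0)

    def test_round_trip(self, tmp_path, lattice3):
        params = fr.ModelParams(p=0.5, r=1.0, q=1.0, q_prime=0.5, m=1)
        traj = fr.run_gillespie(
            lattice3, params, t_max=10, sample_dt=1, seed=2, snapshot_times=[5.0]
        )
        grid = fr.export_snapshot(traj, 0)
        path = tmp_path / "snap.txt"
        write_snapshot(grid, path)
        assert np.array_equal(read_snapshot(path), grid)

    def test_non_lattice_rejected(self, three_cycle):
        params = fr.ModelParams(p=0.1, r=0.1, q=1.0, q_prime=1.0, m=1)
        traj = fr.run_gillespie(
            three_cycle, params, t_max=5, sample_dt=1, seed=0, snapshot_times=[0.0]
        )
        with pytest.raises(ValueError):
            fr.export_snapshot(traj, 0)
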