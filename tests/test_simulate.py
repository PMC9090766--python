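"""Integration scheme, neighbour rules, boxes, protocol and reproducibility."""

import numpy as np
import pytest

from marginalflock import (BoxGeometry, HeterogeneitySpec, ModelParams,
                           NeighbourRule, ParticleState, Protocol,
                           build_adjacency, displacement_sanity, euler_step,
                           init_lattice, minimum_image_displacement,
                           neighbour_counts, polarization, run)
from conftest import random_state


class TestMinimumImage:
    def test_zero_for_identical_points(self):
        box = BoxGeometry.cubic(10.0)
        assert np.allclose(minimum_image_displacement([1, 2, 3], [1, 2, 3], box), 0)

    def test_wrap_around(self):
        box = BoxGeometry.cubic(10.0)
        d = minimum_image_displacement([9.5, 0, 0], [0.5, 0, 0], box)
        assert abs(d[0]) == pytest.approx(1.0)

    def test_components_bounded_by_half_side(self, rng):
        box = BoxGeometry(7.0, 5.0, 11.0)
        for _ in range(200):
            a = rng.uniform(0, box.sides)
            b = rng.uniform(0, box.sides)
            d = minimum_image_displacement(a, b, box)
            assert (np.abs(d) <= box.sides / 2 + 1e-12).all()
        # cubic bound: distance <= sqrt(3)/2 * L
        cub = BoxGeometry.cubic(6.0)
        for _ in range(200):
            a = rng.uniform(0, 6.0, 3)
            b = rng.uniform(0, 6.0, 3)
            d = minimum_image_displacement(a, b, cub)
            assert np.linalg.norm(d) <= np.sqrt(3) / 2 * 6.0 + 1e-12


class TestBuildAdjacency:
    def test_metric_threshold(self):
        box = BoxGeometry.cubic(10.0)
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.3, 0, 0]])
        vel = np.tile([0, 0, 1.0], (3, 1))
        adj = build_adjacency(ParticleState(0, pos, vel),
                              NeighbourRule("metric", r_c=1.2), box)
        assert adj.matrix[0, 1]          # distance 1.0 < 1.2
        assert not adj.matrix[1, 2]      # distance 1.3 >= 1.2
        assert not adj.matrix[0, 2]

    def test_bulk_lattice_agent_has_six_neighbours(self, lattice_state, small_box,
                                                   metric_rule):
        adj = build_adjacency(lattice_state, metric_rule, small_box)
        assert (adj.degrees() == 6).all()  # every agent is bulk under PBC

    def test_topological_symmetrized(self, rng):
        box = BoxGeometry.cubic(12.0)
        state = random_state(rng, n=20, box_side=12.0)
        adj = build_adjacency(state, NeighbourRule("topological", n_c=3), box)
        assert np.array_equal(adj.matrix, adj.matrix.T)
        assert (adj.degrees() >= 3).all()

    def test_large_rc_is_an_error(self, lattice_state, small_box):
        with pytest.raises(ValueError):
            build_adjacency(lattice_state, NeighbourRule("metric", r_c=3.0),
                            small_box)


class TestInitLattice:
    def test_count_polarization_and_spacing(self):
        box = BoxGeometry.cubic(4.0)
        state = init_lattice(box, spacing=1.0, v0=1.0, direction=(0, 0, 1))
        assert state.n_agents == 64  # density 1
        assert polarization(state.velocities) == pytest.approx(1.0)
        d = state.positions[None, :, :] - state.positions[:, None, :]
        d -= box.sides * np.round(d / box.sides)
        r = np.linalg.norm(d, axis=-1)
        np.fill_diagonal(r, np.inf)
        assert r.min() == pytest.approx(1.0)

    def test_non_commensurate_is_an_error(self):
        with pytest.raises(ValueError):
            init_lattice(BoxGeometry.cubic(4.5), spacing=1.0)

    def test_elongated_box_aspect_ratio(self):
        box = BoxGeometry.elongated(3.0)
        assert box.L1 / box.L2 == pytest.approx(6.0)
        assert init_lattice(box).n_agents == box.volume


class TestEulerStep:
    def test_aligned_zero_noise_is_fixed_point_of_velocity_update(
            self, lattice_state, small_box, metric_rule, rng):
        for control, kw in (("linear", dict(g=1.0)), ("quartic", dict(g=1.0)),
                            ("marginal", dict(lam=1.0))):
            p = ModelParams(T=0.0, v0=1.0, dt=0.01, control=control, **kw)
            new = euler_step(lattice_state, p, metric_rule, small_box, rng)
            assert np.allclose(new.velocities, lattice_state.velocities)
            drift = np.mod(lattice_state.positions + p.dt * lattice_state.velocities,
                           small_box.sides)
            assert np.allclose(new.positions, drift)

    def test_noise_variance_matches_convention(self, rng):
        # free particles: each velocity component performs a random walk
        # with per-step increment variance 2 T dt
        T, dt, nsteps = 0.5, 0.01, 6_000
        box = BoxGeometry.cubic(6.0)
        state = init_lattice(box, v0=1.0)
        p = ModelParams(J=0.0, g=0.0, T=T, v0=1.0, dt=dt, control="quartic")
        rule = NeighbourRule("metric", r_c=1.2)
        increments = []
        for _ in range(nsteps // 100):
            prev = state.velocities.copy()
            for _ in range(100):
                state = euler_step(state, p, rule, box, rng)
            # collect per-step variance estimate from 100-step blocks
            increments.append(state.velocities - prev)
        inc = np.concatenate([i.ravel() for i in increments])
        var_per_step = inc.var() / 100
        expect = 2 * T * dt
        se = expect * np.sqrt(2.0 / (inc.size - 1)) * 10  # generous block SE
        assert abs(var_per_step - expect) < max(5 * se, 0.05 * expect)

    def test_blowup_reports_agent(self, small_box, metric_rule, rng):
        state = init_lattice(small_box, v0=5.0)
        p = ModelParams(J=0.0, lam=1e6, T=0.0, v0=1.0, dt=1.0, control="marginal")
        with pytest.raises(FloatingPointError, match="agent"):
            s = state
            for _ in range(50):
                s = euler_step(s, p, metric_rule, small_box, rng)

    def test_heterogeneity_overrides_apply(self, small_box, metric_rule, rng):
        state = init_lattice(small_box, v0=1.0)
        het = HeterogeneitySpec(indices=(0,), v0=2.0)
        p = ModelParams(J=0.0, g=1.0, T=0.0, v0=1.0, dt=0.1, control="linear")
        new = euler_step(state, p, metric_rule, small_box, rng, het=het)
        sp = np.linalg.norm(new.velocities, axis=1)
        assert sp[0] > 1.0  # pulled towards its own larger v0
        assert np.allclose(sp[1:], 1.0)


class TestRun:
    def test_sample_count_and_determinism(self, small_box, metric_rule):
        state = init_lattice(small_box)
        p = ModelParams(J=1.0, lam=1.0, T=0.05, dt=0.01, control="marginal")
        proto = Protocol(10, 100, 10, seed=5)
        t1 = run(state, p, metric_rule, small_box, proto)
        assert len(t1) == 10
        t2 = run(state, p, metric_rule, small_box, proto)
        assert np.array_equal(t1.positions, t2.positions)
        assert np.array_equal(t1.velocities, t2.velocities)
        t3 = run(state, p, metric_rule, small_box, Protocol(10, 100, 10, seed=6))
        assert not np.array_equal(t1.velocities, t3.velocities)

    def test_kernel_step_matches_reference_euler_step_at_zero_noise(
            self, small_box, metric_rule, rng):
        # independent NumPy implementation vs the compiled kernel, one step
        state = random_state(rng, n=30, box_side=6.0)
        state = ParticleState(0.0, np.mod(state.positions, small_box.sides),
                              state.velocities)
        for control, kw in (("linear", dict(g=0.5)), ("marginal", dict(lam=0.5))):
            p = ModelParams(J=1.0, T=0.0, v0=1.0, dt=0.001, control=control, **kw)
            traj = run(state, p, metric_rule, small_box,
                       Protocol(1, 1, 1, seed=0), check_displacement=False)
            ref = euler_step(state, p, metric_rule, small_box, rng)
            ref2 = euler_step(ref, p, metric_rule, small_box, rng)
            assert np.allclose(traj.positions[0], ref2.positions, atol=1e-12)
            assert np.allclose(traj.velocities[0], ref2.velocities, atol=1e-12)

    def test_aligned_zero_noise_fixed_point_over_many_steps(self, small_box,
                                                            metric_rule):
        state = init_lattice(small_box, v0=1.3)
        p = ModelParams(J=1.0, g=1.0, T=0.0, v0=1.3, dt=0.001, control="linear")
        traj = run(state, p, metric_rule, small_box, Protocol(0, 500, 100, seed=1))
        assert np.allclose(traj.velocities, state.velocities[None])

    def test_ordered_phase_marginal_polarization_high(self, metric_rule):
        box = BoxGeometry.cubic(6.0)
        state = init_lattice(box)
        p = ModelParams(J=1.0, lam=1.0, T=0.05, dt=0.01, control="marginal")
        traj = run(state, p, metric_rule, box, Protocol(2000, 10_000, 1000, seed=2))
        phis = [polarization(v) for v in traj.velocities]
        assert np.mean(phis) > 0.9

    def test_neighbour_count_distribution_stays_homogeneous(self, metric_rule):
        # early production: the initial lattice is intact and the count is
        # sharply peaked at 6; over long horizons the lattice melts into a
        # homogeneous fluid whose mode sits near the continuum value
        # rho * 4/3 pi r_c^3 ~ 7, still unimodal (no fragmentation)
        box = BoxGeometry.cubic(6.0)
        state = init_lattice(box)
        p = ModelParams(J=1.0, lam=1.0, T=0.05, dt=0.01, control="marginal")
        early = run(state, p, metric_rule, box, Protocol(500, 1500, 500, seed=3))
        counts = np.concatenate([neighbour_counts(st, box, metric_rule.r_c)
                                 for st in early])
        values, freq = np.unique(counts, return_counts=True)
        assert values[np.argmax(freq)] == 6

        # over long horizons the lattice melts and, as generically happens in
        # ordered active matter without repulsion, density fluctuations grow;
        # the distribution stays unimodal with a bulk mode (no fragmentation
        # into disconnected clusters, no empty-gas majority)
        late = run(state, p, metric_rule, box, Protocol(2000, 10_000, 1000, seed=3))
        counts = np.concatenate([neighbour_counts(st, box, metric_rule.r_c)
                                 for st in late])
        values, freq = np.unique(counts, return_counts=True)
        mode = values[np.argmax(freq)]
        assert 5 <= mode <= 10
        assert (counts == 0).mean() < 0.05

    def test_topological_requires_frozen_network(self, small_box):
        state = init_lattice(small_box)
        p = ModelParams(control="marginal", lam=1.0, T=0.01)
        with pytest.raises(NotImplementedError):
            run(state, p, NeighbourRule("topological", n_c=6), small_box,
                Protocol(1, 10, 10, seed=0))
        traj = run(state, p, NeighbourRule("topological", n_c=6), small_box,
                   Protocol(1, 10, 10, seed=0), freeze_network=True)
        assert len(traj) == 1


class TestDisplacementSanity:
    def test_paper_scale_step_passes(self):
        p = ModelParams(v0=1.0, dt=0.01)
        assert displacement_sanity(p, BoxGeometry.cubic(16.0))

    def test_reckless_step_fails(self):
        p = ModelParams(v0=10.0, dt=1.0)
        assert not displacement_sanity(p, BoxGeometry.cubic(4.0))

    def test_run_warns_on_large_displacement(self, metric_rule):
        box = BoxGeometry.cubic(4.0)
        state = init_lattice(box)
        p = ModelParams(J=0.0, lam=1.0, T=0.0, v0=1.0, dt=0.05, control="marginal")
        with pytest.warns(UserWarning):
            run(state, p, metric_rule, box, Protocol(1, 10, 10, seed=0))
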