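"""DEM engine physics checks against independent oracles.

The oracles are deliberately computed outside the engine: event-resolved
two-body integration (scipy solve_ivp) for restitution, a scalar root-find
on the Hertz law for the static resting overlap, and brute-force all-pairs
distance checks for packing overlap.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

import granumix as gx
from granumix.engine import CapacityError, DEMSimulation, InstabilityError
from granumix.params import damping_ratio_from_restitution, rayleigh_time

from conftest import desk_geometry, desk_params


def free_space_sim(params, positions, velocities, dt, gravity=0.0):
    geo = gx.VesselGeometry(vessel_radius=10.0, blade_height=0.05)
    con = gx.ContactModelParams(timestep_dt=dt, gravity=gravity)
    return DEMSimulation(params, geo, con, positions=np.asarray(positions, float),
                         velocities=np.asarray(velocities, float), walls=False)


# ---------------------------------------------------------------- initialize
class TestInitializeBed:
    def test_four_particles_split_two_per_label(self):
        params = desk_params(n_particles=4, cake_height=0.02)
        snap = gx.initialize_bed(params, desk_geometry(), seed=3)
        counts = np.bincount(snap.labels, minlength=3)
        assert counts[1] == 2 and counts[2] == 2

    def test_label_counts_balanced_and_split_by_x(self):
        params = desk_params(n_particles=251)
        snap = gx.initialize_bed(params, desk_geometry(), seed=5)
        counts = np.bincount(snap.labels, minlength=3)
        assert abs(int(counts[1]) - int(counts[2])) <= 1
        # every label-1 particle lies left of every label-2 particle
        assert snap.positions[snap.labels == 1, 0].max() <= \
            snap.positions[snap.labels == 2, 0].min()

    def test_settled_overlap_below_one_percent(self):
        # stiffer granules: static Hertzian overlaps are well below 1% of R
        params = desk_params(n_particles=200, youngs_modulus=5e7,
                             cohesion_energy_density=0.0)
        snap = gx.initialize_bed(params, desk_geometry(vessel_radius=0.04),
                                 seed=7)
        pos, r = snap.positions, params.particle_radius
        n = len(pos)
        max_overlap = 0.0
        for i in range(n):          # brute-force all-pairs oracle
            d = np.linalg.norm(pos[i + 1:] - pos[i], axis=1)
            if len(d):
                max_overlap = max(max_overlap, float((2 * r - d).max()))
        assert max_overlap <= 0.01 * r

    def test_same_seed_bitwise_identical(self):
        params = desk_params(n_particles=60, cake_height=0.03)
        a = gx.initialize_bed(params, desk_geometry(), seed=42)
        b = gx.initialize_bed(params, desk_geometry(), seed=42)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.labels, b.labels)

    def test_capacity_error_when_bed_cannot_fit(self):
        params = desk_params(n_particles=100000, cake_height=0.02)
        with pytest.raises(CapacityError):
            gx.initialize_bed(params, desk_geometry(), seed=0)


# ----------------------------------------------------------------- stepping
class TestStep:
    def test_free_fall_matches_ballistics(self):
        params = desk_params(n_particles=1)
        sim = free_space_sim(params, [[0, 0, 1.0]], [[0, 0, 0]],
                             dt=1e-5, gravity=9.81)
        sim.step(1000)
        t = sim.time
        assert sim.vel[0, 2] == pytest.approx(-9.81 * t, rel=1e-12)

    @pytest.mark.parametrize("e", [0.4, 0.6, 0.8])
    def test_two_body_restitution_matches_configured_e(self, e):
        params = desk_params(n_particles=2, restitution=e, friction=0.0,
                             cohesion_energy_density=0.0)
        dt = 0.05 * rayleigh_time(3e-3, 1100.0, 5e6)
        v0 = 0.4
        sim = free_space_sim(params, [[0, 0, 0.1], [0.00605, 0, 0.1]],
                             [[v0 / 2, 0, 0], [-v0 / 2, 0, 0]], dt=dt)
        sim.step(int(0.02 / dt))
        ratio = abs(sim.vel[1, 0] - sim.vel[0, 0]) / v0
        assert ratio == pytest.approx(e, rel=0.05)

    def test_two_body_restitution_matches_ode_oracle(self):
        # event-resolved integration of the 1-D Hertz + dashpot contact
        e = 0.6
        R, rho, E, nu = 3e-3, 1100.0, 5e6, 0.3
        m = (4 / 3) * math.pi * R**3 * rho
        mstar, rstar = m / 2, R / 2
        estar = E / (2 * (1 - nu**2))
        beta = damping_ratio_from_restitution(e)
        v0 = 0.4

        def rhs(t, y):
            delta, ddelta = y          # delta = approach overlap
            if delta <= 0:
                return [ddelta, 0.0]
            sq = math.sqrt(rstar * delta)
            f = ((4 / 3) * estar * sq * delta
                 + 2 * math.sqrt(5 / 6) * (-beta)
                 * math.sqrt(2 * estar * sq * mstar) * ddelta)
            return [ddelta, -f / mstar]

        def separated(t, y):
            return y[0] + 1e-15
        separated.terminal = True
        separated.direction = -1
        sol = solve_ivp(rhs, [0, 1.0], [1e-12, v0], events=separated,
                        rtol=1e-10, atol=1e-14)
        oracle_ratio = abs(sol.y[1, -1]) / v0

        params = desk_params(n_particles=2, restitution=e, friction=0.0,
                             cohesion_energy_density=0.0)
        dt = 0.05 * rayleigh_time(R, rho, E)
        sim = free_space_sim(params, [[0, 0, 0.1], [0.00605, 0, 0.1]],
                             [[v0 / 2, 0, 0], [-v0 / 2, 0, 0]], dt=dt)
        sim.step(int(0.02 / dt))
        dem_ratio = abs(sim.vel[1, 0] - sim.vel[0, 0]) / v0
        assert dem_ratio == pytest.approx(oracle_ratio, rel=0.02)

    def test_resting_overlap_matches_root_find_oracle(self):
        # particle resting on the floor: Hertz force balances weight
        # (blade stationary: rpm = 0)
        params = desk_params(n_particles=1, cohesion_energy_density=0.0,
                             rpm=0.0)
        R, nu = params.particle_radius, 0.3
        m, g = params.particle_mass, 9.81
        estar_wall = params.youngs_modulus / (1 - nu**2)  # rigid floor
        delta_star = brentq(
            lambda d: (4 / 3) * estar_wall * math.sqrt(R) * d**1.5 - m * g,
            1e-12, R)
        geo = desk_geometry()
        con = gx.ContactModelParams(timestep_dt=1e-5)
        sim = DEMSimulation(params, geo, con,
                            positions=np.array([[0.02, 0.02, R * 1.001]]))
        sim.step(40000)  # ring-down to static equilibrium
        measured = R - sim.pos[0, 2]
        assert measured == pytest.approx(delta_star, rel=0.01)

    def test_momentum_conserved_in_isolated_collision(self):
        params = desk_params(n_particles=2, cohesion_energy_density=0.0)
        dt = 0.1 * rayleigh_time(3e-3, 1100.0, 5e6)
        sim = free_space_sim(params, [[0, 0, 0.1], [0.0058, 0.001, 0.1]],
                             [[0.3, 0, 0], [-0.3, 0, 0]], dt=dt)
        p_scale = float(np.abs(sim.mass[:, None] * sim.vel).sum())
        n_steps = 500
        sim.step(n_steps)
        drift = float(np.abs((sim.mass[:, None] * sim.vel).sum(axis=0)).max())
        assert drift <= 1e-10 * p_scale * n_steps

    def test_instability_error_names_dt(self):
        # deep initial overlap with a grossly oversized dt: the Hertz kick
        # in a single step ejects the pair at unphysical speed
        params = desk_params(n_particles=2)
        sim = free_space_sim(params, [[0, 0, 0.1], [0.0006, 0, 0.1]],
                             [[0, 0, 0], [0, 0, 0]], dt=5e-3)
        with pytest.raises(InstabilityError) as err:
            for _ in range(200):
                sim.step(10)
                sim._check_stable()
        assert f"{sim.dt:.3g}" in str(err.value)

    def test_cohesion_holds_touching_pair_together(self):
        # strong cohesion beats a small separating impulse: pair stays bound
        params = desk_params(n_particles=2, cohesion_energy_density=5e5,
                             friction=0.0)
        dt = 0.1 * rayleigh_time(3e-3, 1100.0, 5e6)
        sim = free_space_sim(params, [[0, 0, 0.1], [0.005995, 0, 0.1]],
                             [[-0.001, 0, 0], [0.001, 0, 0]], dt=dt)
        sim.step(int(0.05 / dt))
        gap = np.linalg.norm(sim.pos[1] - sim.pos[0]) - 2 * params.particle_radius
        assert gap < 1e-5  # still (near-)touching, not separated


# --------------------------------------------------------------------- runs
class TestRunSimulation:
    def test_snapshot_count_includes_t0(self, small_settled_sim):
        import copy
        sim = small_settled_sim
        params = desk_params(n_particles=40, cake_height=0.03, rpm=60.0)
        snaps = gx.run_simulation(params, desk_geometry(), duration_s=0.1,
                                  snapshot_interval_s=0.02, seed=2)
        assert len(snaps) == 6
        assert snaps[0].time == 0.0
        times = [s.time for s in snaps]
        assert np.allclose(np.diff(times), 0.02)

    def test_labels_conserved_and_particles_inside_vessel(self):
        params = desk_params(n_particles=150, rpm=120.0, cake_height=0.04)
        geo = desk_geometry()
        snaps = gx.run_simulation(params, geo, duration_s=0.3,
                                  snapshot_interval_s=0.1, seed=9)
        c0 = np.bincount(snaps[0].labels, minlength=3)
        for s in snaps:
            assert np.array_equal(np.bincount(s.labels, minlength=3), c0)
            rho = np.hypot(s.positions[:, 0], s.positions[:, 1])
            assert rho.max() < geo.vessel_radius
            assert s.positions[:, 2].min() > 0

    def test_identical_seed_gives_identical_trajectory(self):
        params = desk_params(n_particles=80, cake_height=0.03, rpm=90.0)
        a = gx.run_simulation(params, desk_geometry(), duration_s=0.1,
                              snapshot_interval_s=0.05, seed=4)
        b = gx.run_simulation(params, desk_geometry(), duration_s=0.1,
                              snapshot_interval_s=0.05, seed=4)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.positions, sb.positions)
            assert np.array_equal(sa.velocities, sb.velocities)


# ------------------------------------------------------------------- energy
class TestEnergy:
    def test_kinetic_energy_dissipates_after_kick(self, small_settled_sim):
        import copy
        sim = copy.deepcopy(small_settled_sim)
        rng = np.random.default_rng(0)
        sim.vel[:] = rng.normal(0.0, 0.05, sim.vel.shape)
        ke0 = sim.kinetic_energy()
        last = np.inf
        for _ in range(30):
            sim.step(1000, blade_moving=False)
        assert sim.kinetic_energy() < 1e-6 * ke0

    def test_mechanical_energy_non_increasing_after_settling(self,
                                                             small_settled_sim):
        import copy
        sim = copy.deepcopy(small_settled_sim)
        energies = [sim.mechanical_energy()]
        for _ in range(8):
            sim.step(400, blade_moving=False)
            energies.append(sim.mechanical_energy())
        e = np.array(energies)
        # slack covers the energy reservoirs the audit omits (tangential
        # springs, blade-contact elastic storage)
        assert np.all(np.diff(e) <= 1e-7 * abs(e[0]))

    def test_pairwise_forces_cancel_to_machine_precision(self):
        # gravity off, walls off: total force is a pure pairwise sum
        params = desk_params(n_particles=64, cohesion_energy_density=1e4)
        rng = np.random.default_rng(3)
        pos = rng.uniform(0.0, 0.03, (64, 3))
        sim = free_space_sim(params, pos, np.zeros((64, 3)), dt=1e-5)
        sim._compute_forces()
        total = sim.force.sum(axis=0)
        scale = max(float(np.abs(sim.force).max()), 1e-30)
        assert float(np.abs(total).max()) <= 1e-12 * scale * len(pos)
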