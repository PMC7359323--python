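"""Desk-scale soft-sphere DEM simulator of a bladed cylindrical mixer.

Labeled cohesive spheres in a flat-bottomed cylindrical vessel are agitated
by flat vertical blades rotating about the axis.  The integrator is velocity
Verlet; contacts follow the Hertz-Mindlin law with restitution-calibrated
damping, tangential spring history, and simplified-JKR cohesion (see
``_kernels``).  Intended problem sizes are hundreds to a few thousand
particles and seconds of physical time.
"""

from __future__ import annotations

import logging
import math
import time as _time


import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from ._kernels import MAXC, compute_forces, vv_kick, vv_kick_drift
from .params import (ContactModelParams, MaterialProcessParams, VesselGeometry,
                     damping_ratio_from_restitution)
from .trajectory import TrajectorySnapshot

logger = logging.getLogger(__name__)

__all__ = ["DEMSimulation", "initialize_bed", "run_simulation",
           "CapacityError", "InstabilityError"]


class CapacityError(ValueError):
    """Requested particle count cannot fit below the cake height."""


class InstabilityError(RuntimeError):
    """Integration blew up (NaN or runaway kinetic energy)."""

    def __init__(self, message: str, dt: float,
                 partial: list[TrajectorySnapshot] | None = None):
        super().__init__(message)
        self.dt = dt
        self.partial = partial or []


class DEMSimulation:
    """Mutable DEM state plus the material/geometry/numerics it evolves under."""

    def __init__(self, params: MaterialProcessParams, geometry: VesselGeometry,
                 contact: ContactModelParams | None = None, *,
                 positions: np.ndarray, velocities: np.ndarray | None = None,
                 labels: np.ndarray | None = None, walls: bool = True):
        self.params = params
        self.geometry = geometry
        self.contact = contact or ContactModelParams()
        n = len(positions)
        self.pos = np.ascontiguousarray(positions, float)
        self.vel = (np.zeros((n, 3)) if velocities is None
                    else np.ascontiguousarray(velocities, float))
        self.omg = np.zeros((n, 3))
        self.labels = (np.ones(n, np.int64) if labels is None
                       else np.asarray(labels, np.int64))
        self.rad = np.full(n, params.particle_radius)
        self.mass = np.full(n, params.particle_mass)
        self.inertia = 0.4 * self.mass * self.rad**2
        self.walls = walls
        self.time = 0.0
        self.blade_angle = geometry.blade_angle0
        self.blade_omega = 2.0 * math.pi * params.rpm / 60.0
        self.dt = self.contact.resolve_dt(params)
        self.step_count = 0

        self._estar = self.contact.effective_youngs(params)
        self._gstar = self.contact.effective_shear(params)
        self._beta = damping_ratio_from_restitution(params.restitution)

        nwall = 2 + geometry.blade_count
        self._ct_p = np.full((n, MAXC), -1, np.int64)
        self._ct_x = np.zeros((n, MAXC, 3))
        self._ct_n = np.zeros(n, np.int64)
        self._ct_p2 = np.full((n, MAXC), -1, np.int64)
        self._ct_x2 = np.zeros((n, MAXC, 3))
        self._ct_n2 = np.zeros(n, np.int64)
        self._wall_xi = np.zeros((n, nwall, 3))
        self.force = np.zeros((n, 3))
        self.torque = np.zeros((n, 3))
        self._forces_current = False

    # ------------------------------------------------------------------ core
    @property
    def n_particles(self) -> int:
        return len(self.pos)

    def _compute_forces(self) -> None:
        compute_forces(self.pos, self.vel, self.omg, self.rad, self.mass,
                       self._ct_p, self._ct_x, self._ct_n,
                       self._ct_p2, self._ct_x2, self._ct_n2,
                       self._wall_xi, self.force, self.torque,
                       self._estar, self._gstar, self._beta,
                       self.params.friction,
                       self.params.cohesion_energy_density,
                       self.contact.gravity,
                       self.geometry.vessel_radius,
                       self.geometry.blade_height,
                       self.geometry.blade_count if self.walls else 0,
                       self.blade_angle, self.blade_omega,
                       self.walls, self.dt)
        # swap history buffers
        self._ct_p, self._ct_p2 = self._ct_p2, self._ct_p
        self._ct_x, self._ct_x2 = self._ct_x2, self._ct_x
        self._ct_n, self._ct_n2 = self._ct_n2, self._ct_n
        self._forces_current = True

    def step(self, n_steps: int = 1, *, blade_moving: bool = True) -> None:
        """Advance ``n_steps`` velocity-Verlet steps of size ``dt``."""
        saved = self.blade_omega
        if not blade_moving:
            self.blade_omega = 0.0
        try:
            if not self._forces_current:
                self._compute_forces()
            for _ in range(n_steps):
                vv_kick_drift(self.pos, self.vel, self.omg, self.force,
                              self.torque, self.mass, self.inertia, self.dt)
                self.blade_angle += self.blade_omega * self.dt
                self._compute_forces()
                vv_kick(self.vel, self.omg, self.force, self.torque,
                        self.mass, self.inertia, self.dt)
                self.time += self.dt
                self.step_count += 1
        finally:
            self.blade_omega = saved
            if not blade_moving:
                self._forces_current = False

    def _check_stable(self, partial=None) -> None:
        ke = self.kinetic_energy()
        if not np.isfinite(ke) or not np.all(np.isfinite(self.pos)):
            raise InstabilityError(
                f"non-finite state at t={self.time:.6g}s; dt={self.dt:.3g}s "
                "violates the contact stability limit", self.dt, partial)
        scale = (self.n_particles * self.params.particle_mass
                 * max(self.contact.gravity, 1.0)
                 * self.params.particle_radius)
        if ke > 1e8 * scale:
            raise InstabilityError(
                f"runaway kinetic energy {ke:.3g} J at t={self.time:.6g}s; "
                f"dt={self.dt:.3g}s is too large", self.dt, partial)

    # ----------------------------------------------------------- observables
    def kinetic_energy(self) -> float:
        return float(0.5 * np.sum(self.mass * np.sum(self.vel**2, axis=1))
                     + 0.5 * np.sum(self.inertia * np.sum(self.omg**2, axis=1)))

    def potential_energy(self) -> float:
        return float(np.sum(self.mass * self.contact.gravity * self.pos[:, 2]))

    def elastic_energy(self) -> float:
        """Stored Hertzian normal energy, (8/15) E* sqrt(R*) delta^(5/2)."""
        e_el = 0.0
        tree = cKDTree(self.pos)
        for i, j in tree.query_pairs(2.0 * float(self.rad.max())):
            d = float(np.linalg.norm(self.pos[i] - self.pos[j]))
            delta = self.rad[i] + self.rad[j] - d
            if delta > 0:
                rstar = self.rad[i] * self.rad[j] / (self.rad[i] + self.rad[j])
                e_el += (8.0 / 15.0) * self._estar * math.sqrt(rstar) * delta**2.5
        if self.walls:
            estar_w = 2.0 * self._estar
            for i in range(self.n_particles):
                delta = self.rad[i] - self.pos[i, 2]
                if delta > 0:
                    e_el += (8.0 / 15.0) * estar_w * math.sqrt(self.rad[i]) * delta**2.5
                rho = math.hypot(self.pos[i, 0], self.pos[i, 1])
                delta = self.rad[i] - (self.geometry.vessel_radius - rho)
                if delta > 0:
                    e_el += (8.0 / 15.0) * estar_w * math.sqrt(self.rad[i]) * delta**2.5
        return e_el

    def mechanical_energy(self) -> float:
        return self.kinetic_energy() + self.potential_energy() + self.elastic_energy()

    def snapshot(self) -> TrajectorySnapshot:
        return TrajectorySnapshot(
            time=self.time,
            revolutions=self.params.rpm * self.time / 60.0,
            ids=np.arange(self.n_particles, dtype=np.int64),
            labels=self.labels.copy(),
            positions=self.pos.copy(), velocities=self.vel.copy(),
            radii=self.rad.copy(), masses=self.mass.copy())

    # ------------------------------------------------------------------ runs
    def settle(self, max_time: float = 1.5, ke_tol_factor: float = 1e-5,
               check_every: float = 0.05) -> None:
        """Relax the bed under gravity with the blade stationary.

        Stops when total kinetic energy falls below ``ke_tol_factor`` times
        the natural scale N m g R, then zeroes residual velocities so the
        returned bed is quiescent at t = 0.
        """
        scale = (self.n_particles * self.params.particle_mass
                 * max(self.contact.gravity, 1e-12) * self.params.particle_radius)
        steps = max(1, int(round(check_every / self.dt)))
        elapsed = 0.0
        while elapsed < max_time:
            self.step(steps, blade_moving=False)
            elapsed += steps * self.dt
            self._check_stable()
            if self.kinetic_energy() < ke_tol_factor * scale:
                break
        self.vel[:] = 0.0
        self.omg[:] = 0.0
        self.time = 0.0
        self.step_count = 0
        self._forces_current = False

    def run(self, duration_s: float, snapshot_interval_s: float,
            ) -> list[TrajectorySnapshot]:
        """Advance with the blade rotating, emitting evenly spaced snapshots.

        The timestep is shrunk so an integer number of steps lands exactly on
        each snapshot time.  Returns ``round(duration/interval) + 1``
        snapshots including t = 0.  On instability, the snapshots collected
        so far ride on the raised :class:`InstabilityError`.
        """
        if duration_s <= 0:
            raise ValueError("duration_s must be positive")
        per = max(1, int(math.ceil(snapshot_interval_s / self.dt)))
        self.dt = snapshot_interval_s / per
        self._forces_current = False
        n_snap = int(round(duration_s / snapshot_interval_s))
        snapshots = [self.snapshot()]
        t0 = _time.perf_counter()
        for _ in range(n_snap):
            self.step(per)
            self._check_stable(partial=snapshots)
            snapshots.append(self.snapshot())
        wall = _time.perf_counter() - t0
        logger.info("DEM run: %d particles, %d steps, %.2f s physical, "
                    "%.1f s wall-clock", self.n_particles, self.step_count,
                    self.time, wall)
        return snapshots


def _lattice_positions(params: MaterialProcessParams, geometry: VesselGeometry,
                       rng: np.random.Generator) -> np.ndarray:
    """Loose staggered pour column that settles into a disordered packing.

    Sites sit on a laterally staggered lattice at 1.3 diameters spacing with
    strong jitter, so the rain-down under gravity breaks the crystal and the
    bed relaxes to a random close-ish packing with lateral contacts.  The
    pour column may stand taller than the cake height; what must fit below
    ``cake_height`` is the settled bed (checked at random-close-packing
    fraction 0.6).
    """
    r = params.particle_radius
    # settled-bed capacity at packing fraction ~0.6
    bed_area = math.pi * max(geometry.vessel_radius - r, r) ** 2
    settled_height = (params.n_particles * (4.0 / 3.0) * math.pi * r**3
                      / 0.6 / bed_area)
    if settled_height > params.cake_height:
        raise CapacityError(
            f"n_particles={params.n_particles} of radius {r} m settle to a "
            f"bed of ~{settled_height:.3g} m, above cake height "
            f"{params.cake_height} m (vessel radius "
            f"{geometry.vessel_radius} m)")
    spacing = 2.0 * r * 1.3
    jitter = 0.14 * r
    r_fit = geometry.vessel_radius - r - spacing / 2.0
    coords = np.arange(-r_fit, r_fit + 1e-12, spacing)

    def clear_of_blades(x: float, y: float) -> bool:
        # keep sites out of the (stationary, angle0) blade planes
        for b in range(geometry.blade_count):
            theta = geometry.blade_angle0 + 2.0 * math.pi * b / geometry.blade_count
            s = -x * math.sin(theta) + y * math.cos(theta)
            proj = x * math.cos(theta) + y * math.sin(theta)
            if proj >= -r and abs(s) < r * 1.1 + jitter:
                return False
        return True

    xy = [(x, y) for x in coords for y in coords
          if math.hypot(x, y) <= r_fit and clear_of_blades(x, y)]
    if not xy:
        raise CapacityError(
            f"vessel radius {geometry.vessel_radius} m cannot hold "
            f"particles of radius {r} m")
    z0 = r * 1.02
    dz = spacing * 0.82  # staggered layers sit lower than simple cubic
    sites = []
    layer = 0
    while len(sites) < params.n_particles:
        z = z0 + layer * dz
        # alternate layers shifted by half a spacing so grains rain into
        # the hollows of the layer below
        off = 0.5 * spacing if layer % 2 else 0.0
        order = rng.permutation(len(xy))
        for k in order:
            x, y = xy[k][0] + off, xy[k][1] + off
            if math.hypot(x, y) <= r_fit and clear_of_blades(x, y):
                sites.append((x, y, z))
                if len(sites) == params.n_particles:
                    break
        layer += 1
    pos = np.array(sites, float)
    pos += rng.uniform(-jitter, jitter, size=pos.shape)
    pos[:, 2] = np.maximum(pos[:, 2], r * 1.001)
    return pos


def initialize_bed(params: MaterialProcessParams, geometry: VesselGeometry,
                   contact: ContactModelParams | None = None, seed: int = 0, *,
                   settle_max_time: float = 1.5,
                   return_sim: bool = False):
    """Build a settled two-layer bed: label 1 on the low-x side, label 2 high.

    Particles are placed on a jittered lattice below the cake height,
    relaxed under gravity with the blade stationary, and split into two
    vertical half-cylinder layers by the median-x plane so the label counts
    differ by at most one.  Returns the t = 0 snapshot (or the simulator if
    ``return_sim``).
    """
    rng = np.random.default_rng(seed)
    pos = _lattice_positions(params, geometry, rng)
    sim = DEMSimulation(params, geometry, contact, positions=pos)
    sim.settle(max_time=settle_max_time)
    order = np.argsort(sim.pos[:, 0], kind="stable")
    labels = np.empty(sim.n_particles, np.int64)
    labels[order[: sim.n_particles // 2]] = 1
    labels[order[sim.n_particles // 2:]] = 2
    sim.labels = labels
    if return_sim:
        return sim
    return sim.snapshot()


def run_simulation(params: MaterialProcessParams, geometry: VesselGeometry,
                   contact: ContactModelParams | None = None, *,
                   duration_s: float, snapshot_interval_s: float,
                   seed: int = 0) -> list[TrajectorySnapshot]:
    """Initialize, settle, then agitate; returns the snapshot list."""
    sim = initialize_bed(params, geometry, contact, seed, return_sim=True)
    return sim.run(duration_s, snapshot_interval_s)
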