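"""Shared fixtures: small settled beds and one desk-scale mixing run.

Everything is generated programmatically at test time; the expensive
agitated DEM run is session-scoped so the segregation-index forecasting
checks reuse a single trajectory.
"""

from __future__ import annotations

import numpy as np
import pytest

import granumix as gx
from granumix.mixing import series_from_trajectory

# desk-scale study conditions: mildly cohesive 3 mm pharmaceutical-like
# granules, soft (5e6 Pa) modulus, bladed 8 cm vessel
DESK_MATERIAL = dict(particle_radius=3e-3, density=1100.0, restitution=0.6,
                     friction=0.1, cohesion_energy_density=2e4,
                     youngs_modulus=5e6)
DESK_GEOMETRY = dict(vessel_radius=0.08, blade_count=2, blade_height=0.012)


def desk_params(**over) -> gx.MaterialProcessParams:
    kw = {**DESK_MATERIAL, "n_particles": 500, "rpm": 30.0,
          "cake_height": 0.045}
    kw.update(over)
    return gx.MaterialProcessParams(**kw)


def desk_geometry(**over) -> gx.VesselGeometry:
    kw = dict(DESK_GEOMETRY)
    kw.update(over)
    return gx.VesselGeometry(**kw)


@pytest.fixture(scope="session")
def small_settled_sim():
    """A settled 300-particle pile in a narrow vessel, reused read-only."""
    params = desk_params(n_particles=300, rpm=0.0)
    # tall blades: the settled pile must not bury the blade top edges
    return gx.initialize_bed(params,
                             desk_geometry(vessel_radius=0.04,
                                           blade_height=0.06),
                             seed=11, return_sim=True)


@pytest.fixture(scope="session")
def small_settled_snapshot(small_settled_sim):
    return small_settled_sim.snapshot()


@pytest.fixture(scope="session")
def dem_mixing_run():
    """Desk-scale agitated run: N_p = 2000, 60 RPM, full-height blades,
    2.5 s (2.5 revolutions).

    This is the forecast-validation rig: the bed rotates with the blades
    and the interface erodes gently, so the observed window is a small
    fraction of the full mixing transient — the regime in which a
    half-split forecast is meaningful.  Returns (params, geometry,
    snapshots, series).
    """
    params = desk_params(n_particles=2000, rpm=60.0)
    geometry = desk_geometry(blade_height=0.06)
    snaps = gx.run_simulation(params, geometry, duration_s=2.5,
                              snapshot_interval_s=0.02, seed=1)
    series = series_from_trajectory(snaps, geometry)
    return params, geometry, snaps, series


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
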