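"""Synthetic mixing curves and descriptor design tables.

The curve generator emulates the dominant feature of bladed-mixer
segregation-index traces: an exponential relaxation toward the
random-mixing asymptote driven by the impeller *revolution count*,

    psi(t) = 1 + (psi0 - 1) exp(-k * rpm t / 60) + noise,

so doubling the RPM halves every crossing time in seconds.  The design
generator samples the nine material/process descriptors over realistic
manufacturing-scale ranges and plants a documented response surface for
the mixing time, which lets the forecasting and surrogate stages be tested
without running DEM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixing import SegregationSeries
from .params import DESCRIPTOR_NAMES, MaterialProcessParams

__all__ = ["SyntheticCurveSpec", "generate_mixing_curve",
           "SyntheticDesignSpec", "generate_design_table",
           "mixing_kinetics_from_params", "DEFAULT_RANGES"]


@dataclass(frozen=True)
class SyntheticCurveSpec:
    """Parametric segregation-index curve (decay per impeller revolution)."""

    psi0: float = 1.9          # initial psi, in (1, 2]
    rate_k: float = 0.15       # decay constant per revolution
    rpm: float = 30.0
    noise_sd: float = 0.0
    n_points: int = 200
    duration_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1.0 < self.psi0 <= 2.0):
            raise ValueError("psi0 must lie in (1, 2]")
        if self.rate_k <= 0:
            raise ValueError("rate_k must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")

    def analytic_crossing(self, cutoff: float = 1.1) -> float:
        """Exact crossing time (s) of the noiseless curve at the cutoff."""
        if not (1.0 < cutoff < self.psi0):
            raise ValueError("cutoff must lie in (1, psi0)")
        revs = math.log((self.psi0 - 1.0) / (cutoff - 1.0)) / self.rate_k
        return 60.0 * revs / self.rpm


def generate_mixing_curve(spec: SyntheticCurveSpec) -> SegregationSeries:
    """Noisy exponential psi(t), clipped to [0, 2], with analytic metadata."""
    rng = np.random.default_rng(spec.seed)
    t = np.linspace(0.0, spec.duration_s, spec.n_points)
    revs = spec.rpm * t / 60.0
    psi = 1.0 + (spec.psi0 - 1.0) * np.exp(-spec.rate_k * revs)
    if spec.noise_sd > 0:
        psi = psi + rng.normal(0.0, spec.noise_sd, size=psi.shape)
    psi = np.clip(psi, 0.0, 2.0)
    return SegregationSeries(
        times=t, revolutions=revs, psi_bulk=psi,
        meta={"generator": "exponential-in-revolutions",
              "psi0": spec.psi0, "rate_k": spec.rate_k, "rpm": spec.rpm,
              "noise_sd": spec.noise_sd, "seed": spec.seed,
              "analytic_crossing_1.1": spec.analytic_crossing(1.1)})


#: Descriptor sampling ranges mirroring the study design space (SI units).
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "particle_radius": (1.5e-3, 4.5e-3),
    "density": (800.0, 2000.0),
    "restitution": (0.3, 0.9),
    "cohesion_energy_density": (0.0, 1e5),
    "friction": (0.05, 0.7),
    "youngs_modulus": (5e6, 5e7),
    "n_particles": (1.35e5, 1.0e6),
    "rpm": (2.0, 60.0),
    "cake_height": (0.007, 0.21),
}


def _standardize(col: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Map a uniform [lo, hi] sample to zero mean, unit variance."""
    mid = 0.5 * (lo + hi)
    sd = (hi - lo) / math.sqrt(12.0)
    return (col - mid) / sd


def _response(kind: str, df: pd.DataFrame, ranges: dict, noise_sd: float,
              rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    z = {k: _standardize(df[k].to_numpy(), *ranges[k]) for k in DESCRIPTOR_NAMES}
    n = len(df)
    eps = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    if kind == "paper_like":
        # multiplicative surface dominated by fill level, then impeller
        # speed, then particle radius; the other six descriptors are inert
        h = df["cake_height"].to_numpy()
        rpm = df["rpm"].to_numpy()
        r = df["particle_radius"].to_numpy()
        y = (600.0 * (h / 0.1) ** 1.4 * (20.0 / rpm)
             * (r / 3e-3) ** 0.3 * np.exp(eps))
        info = {"form": "600*(h/0.1)^1.4*(20/rpm)*(R/3mm)^0.3*exp(eps)",
                "active": ["cake_height", "rpm", "particle_radius"]}
    elif kind == "planted_ranking":
        # well-separated effect sizes (2.5x apart) so the planted order
        # h > rpm > R is identifiable at feature-table sample sizes
        y = (4.0 * z["cake_height"] + 2.0 * z["rpm"]
             + 1.0 * z["particle_radius"] + eps)
        info = {"form": "4*z_h + 2*z_rpm + 1*z_R + eps",
                "active": ["cake_height", "rpm", "particle_radius"],
                "effects": {"cake_height": 4.0, "rpm": 2.0,
                            "particle_radius": 1.0}}
    elif kind == "interaction":
        # corner interaction: a deep cake agitated slowly takes
        # disproportionately long — additive models cannot represent the
        # h-AND-rpm corner, trees can
        corner = (z["cake_height"] > 0.0) & (z["rpm"] < 0.0)
        y = (0.4 * z["cake_height"] - 0.3 * z["rpm"]
             + 4.0 * corner.astype(float) + eps)
        info = {"form": "0.4*z_h - 0.3*z_rpm + 4*[z_h>0 and z_rpm<0] + eps",
                "active": ["cake_height", "rpm"]}
    elif kind == "linear":
        y = 2.0 * df["cake_height"].to_numpy() + 3.0 / df["rpm"].to_numpy() + eps
        info = {"form": "2*h + 3/rpm + eps",
                "active": ["cake_height", "rpm"]}
    elif kind == "null":
        y = rng.normal(0.0, 1.0, n)
        info = {"form": "pure noise", "active": []}
    else:
        raise ValueError(f"unknown response kind {kind!r}")
    return np.asarray(y, float), info


@dataclass(frozen=True)
class SyntheticDesignSpec:
    """Design-space sample with a planted mixing-time response."""

    n_rows: int = 40
    seed: int = 0
    response: str = "paper_like"
    noise_sd: float = 0.0
    ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))

    def __post_init__(self) -> None:
        if self.n_rows < 1:
            raise ValueError("n_rows must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for k, (lo, hi) in self.ranges.items():
            if k not in DESCRIPTOR_NAMES:
                raise ValueError(f"unknown descriptor {k!r}")
            if not (hi > lo >= 0):
                raise ValueError(f"invalid range for {k!r}")


def generate_design_table(spec: SyntheticDesignSpec):
    """Sample descriptors uniformly and attach the planted t_end response.

    Returns a :class:`granumix.surrogate.FeatureTable` whose metadata
    documents the planted effects.
    """
    from .surrogate import FeatureTable  # local import: avoid cycle
    rng = np.random.default_rng(spec.seed)
    data = {}
    for name in DESCRIPTOR_NAMES:
        lo, hi = spec.ranges.get(name, DEFAULT_RANGES[name])
        col = rng.uniform(lo, hi, spec.n_rows)
        if name == "n_particles":
            col = np.round(col)
        data[name] = col
    df = pd.DataFrame(data)
    y, info = _response(spec.response, df, spec.ranges, spec.noise_sd, rng)
    df["t_end_s"] = y
    df["provenance"] = "synthetic"
    meta = {"response": spec.response, "noise_sd": spec.noise_sd,
            "seed": spec.seed, "planted": info}
    return FeatureTable.from_frame(df, metadata=meta)


def mixing_kinetics_from_params(params: MaterialProcessParams,
                                ) -> tuple[float, float]:
    """(psi0, per-revolution decay rate) emulated for a descriptor set.

    Deeper cakes mix slower per revolution and larger particles mix a bit
    faster (fewer particles per blade pass to rearrange); time-domain rates
    then scale with RPM through the revolution count.  This is the
    pipeline's stand-in kinetics when the DEM stage is switched off.
    """
    psi0 = 1.9
    k = (0.35 * (0.05 / params.cake_height) ** 0.4
         * (params.particle_radius / 3e-3) ** 0.15)
    return psi0, k
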