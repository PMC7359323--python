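"""Contact census and segregation index.

The segregation index

    psi = C11 / (C11 + C12) + C22 / (C22 + C21)

summarises mixing of two particle populations from the contact census C_ij
(contacts between labels i and j): psi = 2 for a completely unmixed bed,
1 for uniform random mixing, 0 for a perfectly alternating arrangement.
Contacts are geometric: a pair is in contact when the centre distance is at
most (r_i + r_j) (1 + tolerance), decoupled from the force-model overlap so
the census is robust to snapshot rounding.  Each unordered pair is credited
to both of its orderings (a 1-1 pair counts twice in C11; a 1-2 pair counts
once in C12 and once in C21, so C12 = C21 identically) — the normalisation
under which random mixing gives psi = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .params import VesselGeometry
from .trajectory import TrajectorySnapshot

__all__ = ["ContactCensus", "SegregationSeries", "EmptyDomainError",
           "UndefinedSegregationError", "contact_pairs", "contact_census",
           "census_from_labels", "segregation_index", "radial_partition",
           "series_from_trajectory"]


class EmptyDomainError(ValueError):
    """No particles in the domain being censused."""


class UndefinedSegregationError(ValueError):
    """A label has zero total contacts, so psi is undefined (not 0)."""


@dataclass(frozen=True)
class ContactCensus:
    """Counts of contacts between particle labels within one domain."""

    c11: int
    c12: int
    c21: int
    c22: int
    region_id: int | None = None

    def __post_init__(self) -> None:
        if min(self.c11, self.c12, self.c21, self.c22) < 0:
            raise ValueError("contact counts must be non-negative")

    def __add__(self, other: "ContactCensus") -> "ContactCensus":
        return ContactCensus(self.c11 + other.c11, self.c12 + other.c12,
                             self.c21 + other.c21, self.c22 + other.c22)

    @property
    def total_pairs(self) -> int:
        """Number of unordered contacting pairs behind this census."""
        return (self.c11 + self.c22) // 2 + self.c12


def contact_pairs(snapshot: TrajectorySnapshot, tolerance: float = 1e-3,
                  ) -> np.ndarray:
    """Indices (k, 2) of unordered particle pairs in geometric contact."""
    if snapshot.n_particles == 0:
        raise EmptyDomainError("snapshot contains no particles")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    rad = snapshot.radii
    cutoff = 2.0 * float(rad.max()) * (1.0 + tolerance)
    tree = cKDTree(snapshot.positions)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return pairs.reshape(0, 2)
    d = np.linalg.norm(snapshot.positions[pairs[:, 0]]
                       - snapshot.positions[pairs[:, 1]], axis=1)
    keep = d <= (rad[pairs[:, 0]] + rad[pairs[:, 1]]) * (1.0 + tolerance)
    return pairs[keep]


def census_from_labels(pairs: np.ndarray, labels: np.ndarray,
                       region_id: int | None = None) -> ContactCensus:
    """Census a fixed contact graph under a labeling (labels in {1, 2}).

    Contacts are counted as ordered: each unordered pair credits both of
    its orderings, so a same-label pair adds 2 to C11 (or C22) and a cross
    pair adds 1 to each of C12 and C21.  This is the normalisation under
    which psi equals 1 in expectation for uniform random mixing.
    """
    if len(pairs) == 0:
        return ContactCensus(0, 0, 0, 0, region_id)
    la = labels[pairs[:, 0]]
    lb = labels[pairs[:, 1]]
    c11 = 2 * int(np.sum((la == 1) & (lb == 1)))
    c22 = 2 * int(np.sum((la == 2) & (lb == 2)))
    c12 = int(np.sum(la != lb))
    return ContactCensus(c11, c12, c12, c22, region_id)


def contact_census(snapshot: TrajectorySnapshot, tolerance: float = 1e-3,
                   ) -> ContactCensus:
    """Bulk contact census of one snapshot."""
    return census_from_labels(contact_pairs(snapshot, tolerance),
                              snapshot.labels)


def segregation_index(census: ContactCensus) -> float:
    """psi = C11/(C11+C12) + C22/(C22+C21), in [0, 2]."""
    den1 = census.c11 + census.c12
    den2 = census.c22 + census.c21
    if den1 == 0 or den2 == 0:
        raise UndefinedSegregationError(
            f"a label has zero total contacts (C11+C12={den1}, "
            f"C22+C21={den2}); psi is undefined")
    return census.c11 / den1 + census.c22 / den2


def radial_partition(snapshot: TrajectorySnapshot, n_regions: int,
                     geometry: VesselGeometry, tolerance: float = 1e-3,
                     ) -> list[ContactCensus]:
    """Per-region censuses over equal-width annuli from the axis to the wall.

    A contact is assigned to the annulus containing the midpoint of the two
    particle centres.  Region 0 is innermost (closest to the impeller axis).
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    pairs = contact_pairs(snapshot, tolerance)
    edges = np.linspace(0.0, geometry.vessel_radius, n_regions + 1)
    if len(pairs) == 0:
        return [ContactCensus(0, 0, 0, 0, r) for r in range(n_regions)]
    mid = 0.5 * (snapshot.positions[pairs[:, 0]]
                 + snapshot.positions[pairs[:, 1]])
    rho = np.hypot(mid[:, 0], mid[:, 1])
    region = np.clip(np.searchsorted(edges, rho, side="right") - 1,
                     0, n_regions - 1)
    return [census_from_labels(pairs[region == r], snapshot.labels, r)
            for r in range(n_regions)]


@dataclass
class SegregationSeries:
    """Bulk and per-region psi(t) with the impeller revolution count."""

    times: np.ndarray
    revolutions: np.ndarray
    psi_bulk: np.ndarray
    psi_by_region: np.ndarray | None = None  # (n_t, n_regions), NaN = undefined
    region_edges: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.revolutions = np.asarray(self.revolutions, float)
        self.psi_bulk = np.asarray(self.psi_bulk, float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        finite = self.psi_bulk[np.isfinite(self.psi_bulk)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("psi must lie in [0, 2]")

    def to_frame(self) -> pd.DataFrame:
        data = {"t": self.times, "psi_bulk": self.psi_bulk}
        if self.psi_by_region is not None:
            for r in range(self.psi_by_region.shape[1]):
                data[f"psi_R{r + 1}"] = self.psi_by_region[:, r]
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, rpm: float = 0.0) -> "SegregationSeries":
        df = pd.read_csv(path)
        if "t" not in df.columns or "psi_bulk" not in df.columns:
            # accept a bare two-column file
            df.columns = ["t", "psi_bulk"] + list(df.columns[2:])
        region_cols = [c for c in df.columns if c.startswith("psi_R")]
        return cls(times=df["t"].to_numpy(float),
                   revolutions=rpm * df["t"].to_numpy(float) / 60.0,
                   psi_bulk=df["psi_bulk"].to_numpy(float),
                   psi_by_region=(df[region_cols].to_numpy(float)
                                  if region_cols else None))


def series_from_trajectory(snapshots: Sequence[TrajectorySnapshot],
                           geometry: VesselGeometry | None = None,
                           n_regions: int = 3, tolerance: float = 1e-3,
                           ) -> SegregationSeries:
    """psi(t) from a trajectory: bulk always, per-region when geometry given.

    An undefined bulk psi raises :class:`UndefinedSegregationError` carrying
    the timestamp; an undefined per-region psi (a label absent from that
    annulus) is reported as NaN, never interpolated.
    """
    if len(snapshots) < 2:
        raise ValueError("need at least 2 snapshots for a series")
    times, revs, bulk = [], [], []
    by_region = [] if geometry is not None else None
    for snap in snapshots:
        pairs = contact_pairs(snap, tolerance)
        census = census_from_labels(pairs, snap.labels)
        try:
            bulk.append(segregation_index(census))
        except UndefinedSegregationError as err:
            raise UndefinedSegregationError(
                f"bulk psi undefined at t={snap.time:.6g} s: {err}") from err
        times.append(snap.time)
        revs.append(snap.revolutions)
        if by_region is not None:
            row = []
            for cen in radial_partition(snap, n_regions, geometry, tolerance):
                try:
                    row.append(segregation_index(cen))
                except UndefinedSegregationError:
                    row.append(np.nan)
            by_region.append(row)
    edges = (np.linspace(0.0, geometry.vessel_radius, n_regions + 1)
             if geometry is not None else None)
    return SegregationSeries(
        times=np.array(times), revolutions=np.array(revs),
        psi_bulk=np.array(bulk),
        psi_by_region=np.array(by_region) if by_region is not None else None,
        region_edges=edges)
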