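"""Distance time series, contact occupancy, and the ligands x contacts matrix.

Occupancy is the percentage of trajectory frames in which a contact's
governing distance is at or below its type-specific cutoff.  The matrix of
occupancies over ligands and contacts is the predictor block fed to the
PLS stage; a contact never enumerated for a ligand means the pair never
came within the candidate cutoff, so its occupancy is filled as 0%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .contacts import ContactDefinition
from .structure import Topology, Trajectory

__all__ = [
    "DistanceTimeSeries",
    "OccupancyMatrix",
    "distance_timeseries",
    "occupancy_percent",
    "build_matrix",
    "smooth_series",
]


@dataclass
class DistanceTimeSeries:
    contact_id: str
    replicate_id: str
    distances: np.ndarray  # per-frame angstrom
    cutoff: float

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.ndim != 1:
            raise ValueError("distances must be one-dimensional")

    @property
    def n_frames(self) -> int:
        return self.distances.size


def distance_timeseries(
    traj: Trajectory, topo: Topology, contact: ContactDefinition
) -> DistanceTimeSeries:
    """Per-frame governing distance of one contact.

    Atom and group-representative selectors give atom-atom distances;
    ring selectors (index tuples) give centroid-centroid distances.
    """
    coords = traj.coordinates

    def point(selector):
        if isinstance(selector, tuple):
            idx = list(selector)
            if max(idx) >= topo.n_atoms or min(idx) < 0:
                raise ValueError(f"ring selector {selector} out of range")
            return coords[:, idx].mean(axis=1)
        if not 0 <= selector < topo.n_atoms:
            raise ValueError(f"atom selector {selector} out of range")
        return coords[:, selector]

    d = np.linalg.norm(point(contact.ligand_selector) - point(contact.residue_selector), axis=1)
    return DistanceTimeSeries(
        contact_id=contact.contact_id,
        replicate_id=traj.replicate_id,
        distances=d,
        cutoff=contact.cutoff,
    )


def occupancy_percent(ts: DistanceTimeSeries) -> float:
    """100 x (#frames with distance <= cutoff) / n_frames.

    A distance exactly at the cutoff counts as in-contact.
    """
    if ts.n_frames < 1:
        raise ValueError("empty distance series")
    return float(100.0 * np.count_nonzero(ts.distances <= ts.cutoff) / ts.n_frames)


@dataclass
class OccupancyMatrix:
    """Ligands x contacts table of occupancy percentages (the PLS X block)."""

    ligand_ids: list[str]
    contact_ids: list[str]
    values: np.ndarray  # rows x contacts, percent in [0, 100]
    replicate_policy: str = "mean"
    #: with policy "concat", the replicate label of each row (parallel to rows)
    replicate_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ligand_ids), len(self.contact_ids)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.ligand_ids)} rows x {len(self.contact_ids)} contacts"
            )
        if self.values.size and (self.values.min() < 0 or self.values.max() > 100):
            raise ValueError("occupancy values must lie in [0, 100]")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.contact_ids)
        df.insert(0, "ligand_id", self.ligand_ids)
        if self.replicate_ids is not None:
            df.insert(1, "replicate_id", self.replicate_ids)
        return df


def build_matrix(
    occupancies: Sequence[tuple[str, str, Mapping[str, float]]],
    contact_ids: Sequence[str],
    policy: str = "mean",
) -> OccupancyMatrix:
    """Assemble the ligands x contacts occupancy matrix.

    ``occupancies`` holds one entry per (ligand_id, replicate_id):
    a mapping contact_id -> occupancy percent.  Contacts absent from an
    entry fill as 0%.  Policy ``"mean"`` averages replicates per ligand;
    ``"concat"`` keeps each replicate as its own row (ligand label
    repeated).  Duplicate (ligand, replicate) entries are an error.
    """
    if policy not in ("mean", "concat"):
        raise ValueError(f"unknown replicate policy {policy!r}")
    if not occupancies:
        raise ValueError("no occupancy entries given")
    seen = set()
    ligand_order: list[str] = []
    for lig, rep, _ in occupancies:
        if (lig, rep) in seen:
            raise ValueError(f"duplicate (ligand, replicate) entry: ({lig!r}, {rep!r})")
        seen.add((lig, rep))
        if lig not in ligand_order:
            ligand_order.append(lig)
    cols = list(contact_ids)
    rows = np.array(
        [[float(occ.get(c, 0.0)) for c in cols] for _, _, occ in occupancies]
    )
    if policy == "concat":
        return OccupancyMatrix(
            ligand_ids=[lig for lig, _, _ in occupancies],
            contact_ids=cols,
            values=rows,
            replicate_policy="concat",
            replicate_ids=[rep for _, rep, _ in occupancies],
        )
    means = np.array(
        [
            rows[[i for i, (lig, _, _) in enumerate(occupancies) if lig == want]].mean(axis=0)
            for want in ligand_order
        ]
    )
    return OccupancyMatrix(
        ligand_ids=ligand_order, contact_ids=cols, values=means, replicate_policy="mean"
    )


def smooth_series(
    ts: DistanceTimeSeries, window: int
) -> tuple[np.ndarray, np.ndarray]:
    """Centred rolling trend and fluctuation band of a distance series.

    Returns ``(trend, band)``: the rolling mean and rolling population
    standard deviation over a centred window (edges use truncated
    windows).  ``window=1`` returns the raw series with a zero band.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if window > ts.n_frames:
        raise ValueError(f"window {window} exceeds series length {ts.n_frames}")
    s = pd.Series(ts.distances)
    roll = s.rolling(window, center=True, min_periods=1)
    trend = roll.mean().to_numpy()
    band = roll.std(ddof=0).to_numpy()
    return trend, band
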