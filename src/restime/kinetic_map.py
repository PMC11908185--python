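"""Kinetic mapping: label trajectory frames by mixture component.

Every observed residence time t_n corresponds to a trajectory segment
[s_n, s_n + t_n/frame_interval].  The posterior membership
probabilities p_{n,k'} therefore attach to whole frame ranges, which
lets any per-frame analysis be split (hard assignment to the most
probable cluster) or weighted (probability-weighted averages) by
binding timescale.  The one weighted analysis built in is the 3D
spatial density of ligand particles per cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import ContactEvent
from .postprocess import MembershipMatrix

__all__ = [
    "FrameAssignment",
    "WeightedDensity",
    "assign_frames",
    "top_frames",
    "weighted_density",
    "export_dx",
    "assignments_to_table",
]

UNASSIGNED = -1


@dataclass(frozen=True)
class FrameAssignment:
    """One event's frame range with its hard cluster label and full p-row."""

    event_index: int
    start_frame: int
    end_frame: int
    cluster: int  # -1 = unassigned
    probabilities: np.ndarray

    @property
    def frames(self) -> np.ndarray:
        return np.arange(self.start_frame, self.end_frame)


@dataclass(frozen=True)
class WeightedDensity:
    """Probability-weighted 3D histogram of ligand particle positions.

    ``counts`` holds the weighted occupancy per voxel; ``density`` is
    counts / (sum of frame weights * voxel volume).  All ligand copies
    are treated as indistinguishable (same chemical identity).
    """

    counts: np.ndarray
    origin: np.ndarray   # A, grid corner (edge of first voxel)
    spacing: float       # A
    cluster: int
    normalization: float  # sum of frame weights * voxel volume

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if np.any(self.counts < 0):
            raise ValueError("density values must be non-negative")

    @property
    def density(self) -> np.ndarray:
        return self.counts / self.normalization


def assign_frames(events: list, memberships: MembershipMatrix,
                  frame_interval: float = 1.0) -> list:
    """Hard-assign each event's frame range to its most probable cluster.

    Ties go to the slower cluster (clusters are indexed fastest = 0, so
    the larger index wins) -- conservative when hunting long-lived
    poses.  An all-zero membership row yields the label -1
    ("unassigned").
    """
    P = memberships.probabilities
    if len(events) != P.shape[0]:
        raise ValueError("membership rows must align with events")
    out = []
    for n, ev in enumerate(events):
        row = P[n]
        if row.max() <= 0:
            cl = UNASSIGNED
        else:
            # argmax with ties broken toward the larger (slower) index
            cl = int(row.size - 1 - np.argmax(row[::-1]))
        n_frames = int(round(ev.duration / frame_interval))
        out.append(FrameAssignment(
            event_index=n, start_frame=ev.start_frame,
            end_frame=ev.start_frame + n_frames,
            cluster=cl, probabilities=row.copy(),
        ))
    return out


def top_frames(assignments: list, cluster: int, n: int) -> np.ndarray:
    """The n frames with the greatest probability of belonging to a cluster.

    Frames inherit the membership probability of their event; ties are
    broken by ascending frame index for determinism.
    """
    frames = []
    probs = []
    for a in assignments:
        f = a.frames
        frames.append(f)
        probs.append(np.full(f.size, a.probabilities[cluster]))
    frames = np.concatenate(frames)
    probs = np.concatenate(probs)
    order = np.lexsort((frames, -probs))
    return frames[order[:n]]


def _grid_geometry(coords: np.ndarray, spacing: float, padding: float):
    """Origin snapped to the spacing lattice; shape covering the padded box."""
    lo = np.floor((coords.min(axis=0) - padding) / spacing) * spacing
    hi = coords.max(axis=0) + padding
    shape = np.floor((hi - lo) / spacing).astype(int) + 1
    return lo, tuple(shape)


def weighted_density(coords_per_frame, frame_event_map, memberships,
                     cluster: int, spacing: float = 1.0, padding: float = 2.0,
                     origin=None, shape=None) -> WeightedDensity:
    """Accumulate a probability-weighted position histogram for one cluster.

    Parameters
    ----------
    coords_per_frame : sequence of (m_f, 3) arrays
        Ligand particle coordinates (A) for each bound frame.
    frame_event_map : array of int
        For each frame, the index n of the event it belongs to.
    memberships : MembershipMatrix
        Source of the frame weights p_{n,k'}.
    cluster : int
        Cluster index k'; ``cluster=-1`` accumulates the unassigned
        mass (the membership deficit), ``cluster=None`` the unweighted
        histogram.
    spacing, padding : float
        Voxel edge length and bounding-box padding (A).
    origin, shape : optional
        Explicit grid geometry; needed when densities from several
        clusters are to be compared voxel by voxel.  By default the
        grid covers the padded bounding box of the contributing
        coordinates, origin snapped to the spacing lattice.

    Voxels are half-open boxes [edge, edge + spacing).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    frame_event_map = np.asarray(frame_event_map, int)
    if len(coords_per_frame) != frame_event_map.size:
        raise ValueError("one event index is required per frame")
    if cluster is None:
        w_frame = np.ones(frame_event_map.size)
    elif cluster == UNASSIGNED:
        w_frame = memberships.unassigned[frame_event_map]
    else:
        w_frame = memberships.probabilities[frame_event_map, cluster]

    pos = np.flatnonzero(w_frame > 0)
    if pos.size == 0:
        raise ValueError("no frames carry positive weight for this cluster")
    coords = np.concatenate([np.atleast_2d(coords_per_frame[f]) for f in pos])
    if not np.isfinite(coords).all():
        raise ValueError("coordinates must be finite")
    weights = np.concatenate([
        np.full(np.atleast_2d(coords_per_frame[f]).shape[0], w_frame[f])
        for f in pos
    ])

    if origin is None:
        origin, shape = _grid_geometry(coords, spacing, padding)
    origin = np.asarray(origin, float)
    idx = np.floor((coords - origin) / spacing).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(shape)):
        raise ValueError("coordinates fall outside the supplied grid")
    counts = np.zeros(shape)
    np.add.at(counts, tuple(idx.T), weights)
    return WeightedDensity(
        counts=counts, origin=origin, spacing=float(spacing),
        cluster=UNASSIGNED if cluster is None else int(cluster),
        normalization=float(w_frame[pos].sum() * spacing ** 3),
    )


def export_dx(dens: WeightedDensity, path, kind: str = "density") -> None:
    """Write a density to OpenDX format (the standard volumetric
    exchange format for MD densities)."""
    from gridData import Grid

    arr = dens.density if kind == "density" else dens.counts
    g = Grid(arr, origin=dens.origin + dens.spacing / 2.0,
             delta=np.full(3, dens.spacing))
    g.export(str(path), file_format="dx")


def assignments_to_table(assignments: list) -> pd.DataFrame:
    """Frame-assignment table: event, frame range, hard label, p-row."""
    if not assignments:
        return pd.DataFrame()
    kp = assignments[0].probabilities.size
    rows = []
    for a in assignments:
        row = {"event": a.event_index, "start_frame": a.start_frame,
               "end_frame": a.end_frame, "cluster": a.cluster}
        for k in range(kp):
            row[f"p_{k}"] = a.probabilities[k]
        rows.append(row)
    return pd.DataFrame(rows)
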