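"""Contact-event extraction and empirical residence-time summaries.

A binding event is a maximal run of trajectory frames during which the
minimum residue--ligand distance stays within a cutoff.  The durations of
these events (the residence times) are the data vector handed to the
Bayesian mixture inference; the empirical survival function is the
standard visual summary of that vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DistanceSeries",
    "ContactEvent",
    "ResidenceSeries",
    "extract_events",
    "pool_series",
    "survival_function",
    "events_to_table",
    "table_to_events",
    "read_events",
    "write_events",
    "read_distances",
    "write_survival",
]

#: Default contact cutoff in Angstrom, appropriate for coarse-grained beads.
DEFAULT_CUTOFF = 7.0

#: Sentinel residue id used for series pooled over all residues.
POOLED = "all"


@dataclass(frozen=True)
class DistanceSeries:
    """Per-frame minimum distance between one residue and one ligand.

    Parameters
    ----------
    residue_id, ligand_id : int
        Integer labels identifying the pair.
    distances : ndarray
        Minimum distance (A) for every trajectory frame, length >= 1.
    frame_interval : float
        Time between frames in ns; the only place time units enter.
    """

    residue_id: int
    ligand_id: int
    distances: np.ndarray
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        object.__setattr__(self, "distances", d)
        if d.ndim != 1 or d.size < 1:
            raise ValueError("distances must be a non-empty 1-d sequence")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        bad = np.flatnonzero(~np.isfinite(d))
        if bad.size:
            raise ValueError(f"non-finite distance at frame {bad[0]}")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.distances.size


@dataclass(frozen=True)
class ContactEvent:
    """One binding event: a maximal in-cutoff run of frames.

    ``censored`` marks events still in contact at the final frame; their
    observed duration is a lower bound on the true one.
    """

    residue_id: int
    ligand_id: int
    start_frame: int
    duration: float  # ns
    censored: bool = False

    def __post_init__(self) -> None:
        if self.start_frame < 0:
            raise ValueError("start_frame must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class ResidenceSeries:
    """The residence times observed for one residue (pooled over ligands).

    ``durations`` is the data vector of the mixture model; ``omega`` its
    length (the number of observed binding events).
    """

    residue_id: object
    events: list = field(default_factory=list)

    @property
    def durations(self) -> np.ndarray:
        return np.array([e.duration for e in self.events], dtype=float)

    @property
    def omega(self) -> int:
        return len(self.events)

    @classmethod
    def from_durations(cls, residue_id, durations) -> "ResidenceSeries":
        """Build a series from bare durations (start frames set to 0)."""
        events = [
            ContactEvent(residue_id=residue_id if isinstance(residue_id, int) else -1,
                         ligand_id=-1, start_frame=0, duration=float(t))
            for t in np.asarray(durations, dtype=float)
        ]
        return cls(residue_id=residue_id, events=events)


def extract_events(series: DistanceSeries, cutoff: float = DEFAULT_CUTOFF) -> list:
    """Threshold a distance series into contact events.

    Each maximal contiguous run of frames with distance <= ``cutoff``
    becomes exactly one event of duration ``run length * frame_interval``.
    A run touching the final frame is emitted with its observed duration
    and flagged censored.  A ligand that leaves and re-enters the cutoff
    produces separate events (single-cutoff scheme, no hysteresis).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    inside = series.distances <= cutoff
    if not inside.any():
        return []
    # run boundaries: transitions of the padded in/out mask
    padded = np.concatenate(([False], inside, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)  # exclusive
    n = series.n_frames
    events = []
    for s, e in zip(starts, ends):
        events.append(
            ContactEvent(
                residue_id=series.residue_id,
                ligand_id=series.ligand_id,
                start_frame=int(s),
                duration=float((e - s) * series.frame_interval),
                censored=bool(e == n),
            )
        )
    return events


def pool_series(series_list: list) -> ResidenceSeries:
    """Concatenate events from several residues into one pooled series.

    The pooled series carries the sentinel residue id ``"all"``; it feeds
    the whole-protein survival function.
    """
    if not series_list:
        raise ValueError("need at least one series to pool")
    events = [e for s in series_list for e in s.events]
    return ResidenceSeries(residue_id=POOLED, events=events)


def survival_function(t) -> tuple:
    """Empirical survival function of a duration vector.

    Returns ``(times, S)`` with S evaluated at the sorted unique
    durations: ``S(t) = fraction of events with duration >= t``.  By
    construction S starts at exactly 1 and is non-increasing.
    """
    t = np.asarray(t, dtype=float)
    if t.size == 0:
        raise ValueError("empty duration vector")
    if np.any(t <= 0):
        raise ValueError("durations must be positive")
    srt = np.sort(t)
    times = np.unique(srt)
    # number of events with duration >= times[i]
    n_ge = t.size - np.searchsorted(srt, times, side="left")
    return times, n_ge / t.size


# ---------------------------------------------------------------------------
# Delimited-text interfaces

EVENT_COLUMNS = ["residue_id", "ligand_id", "start_frame", "duration_ns", "censored"]


def events_to_table(events) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "residue_id": [e.residue_id for e in events],
            "ligand_id": [e.ligand_id for e in events],
            "start_frame": [e.start_frame for e in events],
            "duration_ns": [e.duration for e in events],
            "censored": [bool(e.censored) for e in events],
        }
    )


def table_to_events(df: pd.DataFrame) -> list:
    missing = [c for c in EVENT_COLUMNS if c not in df.columns and c != "censored"]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    censored = df["censored"] if "censored" in df.columns else [False] * len(df)
    return [
        ContactEvent(
            residue_id=int(r), ligand_id=int(l), start_frame=int(s),
            duration=float(d), censored=bool(c),
        )
        for r, l, s, d, c in zip(
            df["residue_id"], df["ligand_id"], df["start_frame"],
            df["duration_ns"], censored,
        )
    ]


def write_events(events, path, sep: str = ",") -> None:
    events_to_table(events).to_csv(path, sep=sep, index=False)


def read_events(path, sep: str = ",") -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed event table {path}: {err}") from err
    missing = [c for c in ("residue_id", "ligand_id", "start_frame", "duration_ns")
               if c not in df.columns]
    if missing:
        raise ValueError(f"event table {path} missing columns: {missing}")
    return df


def read_distances(path, frame_interval: float = 1.0, sep: str = ",") -> list:
    """Read a tidy per-frame distance table into DistanceSeries objects.

    Expected columns: ``residue_id, ligand_id, frame, min_distance``.
    Rows for each (residue, ligand) pair must cover consecutive frames.
    """
    df = pd.read_csv(path, sep=sep)
    needed = ["residue_id", "ligand_id", "frame", "min_distance"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"distance table {path} missing columns: {missing}")
    out = []
    for (res, lig), grp in df.groupby(["residue_id", "ligand_id"], sort=True):
        grp = grp.sort_values("frame")
        out.append(
            DistanceSeries(
                residue_id=int(res), ligand_id=int(lig),
                distances=grp["min_distance"].to_numpy(float),
                frame_interval=frame_interval,
            )
        )
    return out


def write_survival(t, path, sep: str = ",") -> None:
    times, S = survival_function(t)
    pd.DataFrame({"time_ns": times, "survival": S}).to_csv(path, sep=sep, index=False)
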