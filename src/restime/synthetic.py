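"""Ground-truth synthetic data: hyperexponential samples and toy distance series.

The default scenario is the validation condition used throughout the
package's tests: three exponential components with weights
(0.9, 0.09, 0.01) and rates (5, 0.5, 0.05) 1/ns -- a dominant fast
"flicker" process, an intermediate one, and a rare slow one, each
separated by roughly an order of magnitude -- sampled 5 x 10^4 times.
Generated component labels are returned for validation only; inference
operations accept bare durations and never see them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contacts import ContactEvent, DistanceSeries, ResidenceSeries

__all__ = ["GroundTruth", "SCENARIOS", "sample_hyperexponential",
           "make_toy_distance_series", "durations_to_events"]


@dataclass(frozen=True)
class GroundTruth:
    """Known mixture parameters for a synthetic waiting-time dataset."""

    weights: np.ndarray
    rates: np.ndarray  # 1/ns
    n: int
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        lam = np.asarray(self.rates, float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "rates", lam)
        if w.shape != lam.shape or w.ndim != 1:
            raise ValueError("weights and rates must be 1-d and the same length")
        if abs(w.sum() - 1.0) > 1e-12 or np.any(w < 0):
            raise ValueError("weights must form a simplex")
        if np.any(lam <= 0):
            raise ValueError("rates must be positive")

    @classmethod
    def default(cls, n: int = 50_000, seed: int = 0) -> "GroundTruth":
        """The three-component validation scenario."""
        return cls(weights=np.array([0.9, 0.09, 0.01]),
                   rates=np.array([5.0, 0.5, 0.05]), n=n, seed=seed)


def _scenario(weights, rates):
    def make(n: int, seed: int = 0) -> GroundTruth:
        return GroundTruth(weights=np.array(weights, float),
                           rates=np.array(rates, float), n=n, seed=seed)
    return make

#: Named generating conditions for power exploration.
SCENARIOS = {
    "three_component": _scenario([0.9, 0.09, 0.01], [5.0, 0.5, 0.05]),
    "two_component": _scenario([0.95, 0.05], [5.0, 0.1]),
    "four_component": _scenario([0.85, 0.1, 0.04, 0.01], [10.0, 1.0, 0.1, 0.01]),
    "close_rates": _scenario([0.7, 0.3], [1.0, 0.3]),
}


def sample_hyperexponential(truth: GroundTruth, rng=None):
    """Two-stage draw: a component per event, then an exponential duration.

    Returns ``(durations, labels)``; labels exist only so tests can
    check recovery against the ground truth.
    """
    rng = np.random.default_rng(truth.seed) if rng is None else rng
    labels = rng.choice(truth.weights.size, size=truth.n, p=truth.weights)
    durations = rng.exponential(scale=1.0 / truth.rates[labels])
    return durations, labels


def make_toy_distance_series(pattern, cutoff: float = 7.0, jitter: float = 0.0,
                             margin: float = 1.0, frame_interval: float = 1.0,
                             residue_id: int = 0, ligand_id: int = 0,
                             seed: int = 0) -> DistanceSeries:
    """Build a distance series realizing an explicit in/out contact pattern.

    ``pattern`` is a list of ("in"|"out", run_length) segments.  In-
    segments sit at cutoff - margin, out-segments at cutoff + margin,
    with uniform jitter of amplitude < margin so no sample ever crosses
    the cutoff; event extraction on the result recovers the pattern
    exactly by construction.
    """
    if jitter >= margin:
        raise ValueError("jitter must be smaller than the margin to the cutoff")
    if margin <= 0 or margin >= cutoff:
        raise ValueError("margin must lie in (0, cutoff)")
    rng = np.random.default_rng(seed)
    chunks = []
    for state, length in pattern:
        if length < 1:
            raise ValueError("run lengths must be >= 1")
        base = cutoff - margin if state == "in" else cutoff + margin
        if state not in ("in", "out"):
            raise ValueError(f"unknown pattern state {state!r}")
        chunks.append(base + jitter * rng.uniform(-1, 1, size=length))
    return DistanceSeries(residue_id=residue_id, ligand_id=ligand_id,
                          distances=np.concatenate(chunks),
                          frame_interval=frame_interval)


def durations_to_events(durations, residue_id: int = 0, ligand_id: int = 0,
                        frame_interval: float = 1.0) -> ResidenceSeries:
    """Pack synthetic durations into a ResidenceSeries with synthetic,
    non-overlapping start frames (events laid end to end with a gap)."""
    events = []
    frame = 0
    for t in np.asarray(durations, float):
        n_frames = max(1, int(np.ceil(t / frame_interval)))
        events.append(ContactEvent(residue_id=residue_id, ligand_id=ligand_id,
                                   start_frame=frame, duration=float(t)))
        frame += n_frames + 1
    return ResidenceSeries(residue_id=residue_id, events=events)
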