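"""Spatial exploration and social-contact metrics.

Coverage discretizes the circular arena into a square grid (1 x 1 mm by
default) and reports the fraction of accessible cells whose cell the
centroid ever occupied.  Encounters are proximity events between a focal
individual and any nestmate, with contacts separated by less than 1 s
pooled into a single event.  Inner-region occupancy measures the
fraction of time spent within a concentric inner disc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Arena, Trajectory

__all__ = [
    "CoverageResult",
    "EncounterEvents",
    "coverage",
    "total_distance",
    "detect_encounters",
    "inner_occupancy",
]


@dataclass(frozen=True)
class CoverageResult:
    id: str
    cell_mm: float
    cells_visited: int
    cells_accessible: int

    @property
    def coverage_rate(self) -> float:
        return self.cells_visited / self.cells_accessible


@dataclass(frozen=True)
class EncounterEvents:
    """Pooled social-contact events of one focal individual.

    Events are non-overlapping (start, end) second intervals, time
    ordered, with at least the merge gap between consecutive events.
    """

    focal_id: str
    events: tuple[tuple[float, float], ...]

    @property
    def count(self) -> int:
        return len(self.events)


def _cells(xy: np.ndarray, cell_mm: float, origin: np.ndarray) -> np.ndarray:
    """Half-open cell membership [i, i+1) x [j, j+1) anchored at `origin`."""
    return np.floor((xy - origin) / cell_mm).astype(np.int64)


def accessible_cells(arena: Arena, cell_mm: float = 1.0) -> int:
    """Number of grid cells whose centers lie within the arena disc."""
    origin = np.asarray(arena.center) - arena.radius
    n = int(np.ceil(2 * arena.radius / cell_mm))
    idx = np.arange(n)
    centers = origin[0] + (idx + 0.5) * cell_mm
    cx, cy = np.meshgrid(
        centers, origin[1] + (idx + 0.5) * cell_mm, indexing="ij"
    )
    inside = (cx - arena.center[0]) ** 2 + (cy - arena.center[1]) ** 2 <= arena.radius**2
    return int(inside.sum())


def coverage(traj: Trajectory, arena: Arena | None = None, cell_mm: float = 1.0) -> CoverageResult:
    """Unique grid cells the centroid occupied, against accessible cells."""
    if arena is None:
        arena = traj.arena
    if arena is None:
        raise ValueError("coverage needs an arena")
    if traj.gap_mask.any():
        raise ValueError("trajectory has unfilled gaps; preprocess first")
    origin = np.asarray(arena.center) - arena.radius
    visited = np.unique(_cells(traj.xy, cell_mm, origin), axis=0).shape[0]
    return CoverageResult(
        id=traj.id,
        cell_mm=cell_mm,
        cells_visited=visited,
        cells_accessible=accessible_cells(arena, cell_mm),
    )


def total_distance(traj: Trajectory) -> float:
    """Cumulative Euclidean distance travelled by the centroid, in mm."""
    if traj.gap_mask.any():
        raise ValueError("trajectory has unfilled gaps; preprocess first")
    return float(np.hypot(*np.diff(traj.xy, axis=0).T).sum())


def detect_encounters(
    focal_traj: Trajectory,
    other_trajs,
    contact_radius: float = 2.0,
    merge_gap_s: float = 1.0,
) -> EncounterEvents:
    """Proximity encounters between a focal individual and any nestmate.

    A frame is in contact when the focal centroid lies within
    ``contact_radius`` of any other individual's centroid (the default,
    2 mm, is twice the simulated agent radius — a centroid proxy for
    antennal contact).  Maximal contact runs separated by less than
    ``merge_gap_s`` seconds are pooled into single events.
    """
    if isinstance(other_trajs, Trajectory):
        other_trajs = [other_trajs]
    others = list(other_trajs)
    times = focal_traj.times
    contact = np.zeros(len(focal_traj), dtype=bool)
    for o in others:
        if len(o) != len(focal_traj) or not np.allclose(o.times, times):
            raise ValueError("trajectories must share a common time base")
        dist = np.hypot(*(focal_traj.xy - o.xy).T)
        contact |= dist <= contact_radius
    if not contact.any():
        return EncounterEvents(focal_id=focal_traj.id, events=())
    # maximal contact runs
    edges = np.diff(contact.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1))
    if contact[0]:
        starts.insert(0, 0)
    if contact[-1]:
        ends.append(len(contact) - 1)
    runs = [(times[s], times[e]) for s, e in zip(starts, ends)]
    merged = [runs[0]]
    for s, e in runs[1:]:
        if s - merged[-1][1] < merge_gap_s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return EncounterEvents(
        focal_id=focal_traj.id, events=tuple((float(s), float(e)) for s, e in merged)
    )


def inner_occupancy(
    traj: Trajectory, arena: Arena | None = None, inner_fraction: float = 0.5
) -> float:
    """Fraction of samples within the inner disc of radius ``inner_fraction * R``."""
    if arena is None:
        arena = traj.arena
    if arena is None:
        raise ValueError("inner_occupancy needs an arena")
    if not (0 < inner_fraction <= 1):
        raise ValueError("inner_fraction must lie in (0, 1]")
    if traj.gap_mask.any():
        raise ValueError("trajectory has unfilled gaps; preprocess first")
    r = np.hypot(
        traj.xy[:, 0] - arena.center[0], traj.xy[:, 1] - arena.center[1]
    )
    return float((r <= inner_fraction * arena.radius).mean())
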