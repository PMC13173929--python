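"""Trajectory containers, CSV input/output, and preprocessing.

Trajectories are time-stamped 2D centroid positions of one individual
moving inside a circular arena.  Units are millimetres and seconds
throughout; the nominal recording rate is stored alongside the samples.
Missing positions (tracking dropouts, wall-climbing intervals) are held
as NaN rows until :func:`interpolate_gaps` fills them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Arena",
    "Trajectory",
    "read_trajectory",
    "write_trajectory",
    "interpolate_gaps",
    "clamp_to_arena",
    "preprocess",
    "downsample",
]

CASTES = ("queen", "worker", "soldier", "king", "agent")

#: a gap longer than this many seconds triggers a warning on interpolation
LONG_GAP_WARN_S = 10.0


@dataclass(frozen=True)
class Arena:
    """Circular arena, default a 90-mm Petri dish (radius 45 mm)."""

    center: tuple[float, float] = (0.0, 0.0)
    radius: float = 45.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"arena radius must be positive, got {self.radius}")

    def contains(self, xy: np.ndarray, tol: float = 0.0) -> np.ndarray:
        """Boolean mask of points within ``radius + tol`` of the center."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        r = np.hypot(xy[:, 0] - self.center[0], xy[:, 1] - self.center[1])
        return r <= self.radius + tol


@dataclass(frozen=True)
class Trajectory:
    """One individual's time-stamped 2D path.

    ``times`` are strictly increasing seconds; ``xy`` is an (n, 2) float
    array in mm where a NaN coordinate pair marks a tracking gap.
    """

    times: np.ndarray
    xy: np.ndarray
    rate_hz: float
    id: str = "traj"
    caste: str = "agent"
    arena: Arena | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        xy = np.asarray(self.xy, dtype=float)
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise ValueError("xy must be an (n, 2) array")
        if times.shape[0] != xy.shape[0]:
            raise ValueError("times and xy must have equal length")
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise ValueError("non-monotonic time")
        if self.caste not in CASTES:
            raise ValueError(f"unknown caste {self.caste!r}; expected one of {CASTES}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "xy", xy)

    def __len__(self) -> int:
        return self.times.shape[0]

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def gap_mask(self) -> np.ndarray:
        """True where either coordinate is missing."""
        return np.isnan(self.xy).any(axis=1)

    @property
    def n_gaps(self) -> int:
        return int(self.gap_mask.sum())


def read_trajectory(
    path: str | Path,
    rate_hz: float,
    arena: Arena | None = None,
    id: str | None = None,
    caste: str = "agent",
) -> Trajectory:
    """Read a ``time,x,y`` CSV into a :class:`Trajectory`.

    Missing positions (empty fields or NaN) are kept as NaN rows and can
    be filled later with :func:`interpolate_gaps`.  Raises on
    non-monotonic time stamps or fewer than two valid rows.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"time", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    times = df["time"].to_numpy(dtype=float)
    if np.isnan(times).any():
        raise ValueError(f"{path}: time column contains missing values")
    xy = df[["x", "y"]].to_numpy(dtype=float)
    # a single missing coordinate invalidates the whole position
    xy[np.isnan(xy).any(axis=1)] = np.nan
    n_valid = int((~np.isnan(xy).any(axis=1)).sum())
    if n_valid < 2:
        raise ValueError(f"{path}: fewer than 2 valid rows")
    if times.size >= 2 and not np.all(np.diff(times) > 0):
        raise ValueError(f"{path}: non-monotonic time")
    return Trajectory(
        times=times,
        xy=xy,
        rate_hz=rate_hz,
        id=id if id is not None else path.stem,
        caste=caste,
        arena=arena,
    )


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a ``time,x,y`` CSV (gaps become empty fields)."""
    df = pd.DataFrame(
        {"time": traj.times, "x": traj.xy[:, 0], "y": traj.xy[:, 1]}
    )
    df.to_csv(path, index=False, float_format="%.9g")


def interpolate_gaps(traj: Trajectory) -> Trajectory:
    """Fill interior tracking gaps by linear interpolation against time.

    Leading or trailing gaps have no bracketing positions, so they are
    trimmed (with a warning) rather than extrapolated.  Valid samples are
    never altered; the operation is idempotent.  Gaps longer than
    ``LONG_GAP_WARN_S`` seconds trigger a warning because linear fill over
    long intervals fabricates motion.
    """
    gaps = traj.gap_mask
    if not gaps.any():
        return traj
    valid = ~gaps
    idx_valid = np.flatnonzero(valid)
    first, last = idx_valid[0], idx_valid[-1]
    times, xy = traj.times, traj.xy
    if first > 0 or last < len(traj) - 1:
        warnings.warn(
            f"{traj.id}: trimmed {first + (len(traj) - 1 - last)} "
            "leading/trailing gap samples (cannot interpolate without a bracket)"
        )
        times = times[first : last + 1]
        xy = xy[first : last + 1]
        gaps = np.isnan(xy).any(axis=1)
        valid = ~gaps

    # warn about long interior gaps before filling them
    t_valid = times[valid]
    long_gaps = np.diff(t_valid) > LONG_GAP_WARN_S
    if long_gaps.any():
        warnings.warn(
            f"{traj.id}: {int(long_gaps.sum())} gap(s) longer than "
            f"{LONG_GAP_WARN_S:g} s linearly interpolated"
        )

    filled = xy.copy()
    for c in range(2):
        filled[gaps, c] = np.interp(times[gaps], t_valid, xy[valid, c])
    return replace(traj, times=times, xy=filled)


def clamp_to_arena(traj: Trajectory, tol: float = 1.0) -> Trajectory:
    """Clamp positions marginally outside the arena back to its boundary.

    Tracking noise can place a centroid slightly beyond the wall; such
    points are projected radially onto the boundary circle with a warning.
    Points further out than ``tol`` mm raise, since that indicates a unit
    or geometry mismatch rather than noise.
    """
    if traj.arena is None:
        return traj
    cx, cy = traj.arena.center
    r = np.hypot(traj.xy[:, 0] - cx, traj.xy[:, 1] - cy)
    with np.errstate(invalid="ignore"):
        outside = r > traj.arena.radius
        far = r > traj.arena.radius + tol
    if far.any():
        raise ValueError(
            f"{traj.id}: {int(far.sum())} positions more than {tol:g} mm "
            "outside the arena; check units and arena geometry"
        )
    if not outside.any():
        return traj
    warnings.warn(
        f"{traj.id}: clamped {int(outside.sum())} positions to the arena boundary"
    )
    xy = traj.xy.copy()
    scale = traj.arena.radius / r[outside]
    xy[outside, 0] = cx + (xy[outside, 0] - cx) * scale
    xy[outside, 1] = cy + (xy[outside, 1] - cy) * scale
    return replace(traj, xy=xy)


def preprocess(traj: Trajectory) -> Trajectory:
    """Standard repair pipeline: interpolate gaps, then clamp to the arena."""
    return clamp_to_arena(interpolate_gaps(traj))


def downsample(traj: Trajectory, target_hz: float) -> Trajectory:
    """Keep every k-th sample, k = round(rate_hz / target_hz).

    The ratio must be (approximately) integral; upsampling is refused.
    """
    if target_hz > traj.rate_hz:
        raise ValueError(
            f"target_hz {target_hz:g} exceeds source rate {traj.rate_hz:g}"
        )
    ratio = traj.rate_hz / target_hz
    k = round(ratio)
    if abs(ratio - k) > 1e-6 * k:
        raise ValueError(
            f"rate ratio {ratio:g} is not integral; cannot downsample evenly"
        )
    if k == 1:
        return traj
    return replace(
        traj, times=traj.times[::k], xy=traj.xy[::k], rate_hz=target_hz
    )
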