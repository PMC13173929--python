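"""Path tortuosity, turning statistics, and velocity autocovariance.

Straightness S = D/L compares net displacement to path length over a
sliding window (default 5 s window, 1 s stride at the native frame
rate): S near 1 is ballistic, near 0 tortuous.  The velocity
autocovariance function C_v(tau) = <v(t)·v(t+tau)> / <|v(t)|^2>
quantifies directional persistence; rapid decay to zero means
reorientations randomize direction quickly.  Turning frequency (turns
per second above an angle threshold) links reorientation behaviour to
the step-length scaling exponent via ordinary least squares.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
from scipy import stats

from .io import Trajectory

__all__ = [
    "straightness_index",
    "turning_angles",
    "turning_frequency",
    "vacf",
    "regress_mu_on_turning",
]

#: default threshold (rad) above which a reorientation counts as a turn
TURN_THRESHOLD = np.pi / 4


def _require_filled(traj: Trajectory) -> np.ndarray:
    if traj.gap_mask.any():
        raise ValueError(f"{traj.id}: trajectory has unfilled gaps; preprocess first")
    return traj.xy


def straightness_index(
    traj: Trajectory, window_s: float = 5.0, stride_s: float = 1.0
) -> tuple[float, np.ndarray]:
    """Sliding-window straightness S = net displacement / path length.

    The window spans ``window_s`` seconds (25 frames at 5 Hz) and slides
    in ``stride_s`` increments.  Windows whose path length is zero (fully
    stationary) have undefined S (0/0) and are excluded from the mean.
    Returns the mean over windows and the per-window series.
    """
    xy = _require_filled(traj)
    win = int(round(window_s * traj.rate_hz))
    stride = max(1, int(round(stride_s * traj.rate_hz)))
    if win < 2:
        raise ValueError("window too short for the sampling rate")
    if len(traj) < win:
        raise ValueError("trajectory shorter than one window")
    seg = np.hypot(*np.diff(xy, axis=0).T)  # inter-frame distances
    cum = np.concatenate(([0.0], np.cumsum(seg)))
    out = []
    # a window of `win` frames covers win-1 inter-frame segments
    for start in range(0, len(traj) - win + 1, stride):
        end = start + win - 1
        path = cum[end] - cum[start]
        if path == 0.0:
            out.append(np.nan)
            continue
        net = float(np.hypot(*(xy[end] - xy[start])))
        out.append(net / path)
    series = np.asarray(out)
    valid = series[~np.isnan(series)]
    if valid.size == 0:
        raise ValueError("all windows stationary; straightness undefined")
    return float(valid.mean()), series


def turning_angles(traj: Trajectory) -> np.ndarray:
    """Signed angles between consecutive displacement vectors, in (-pi, pi].

    Zero-displacement frames have no direction; those segments are
    dropped before computing angles (rather than imputing a 0 turn, which
    would inflate forward persistence).
    """
    xy = _require_filled(traj)
    if len(traj) < 3:
        raise ValueError("need at least 3 samples for turning angles")
    d = np.diff(xy, axis=0)
    d = d[(d != 0).any(axis=1)]
    if d.shape[0] < 2:
        return np.empty(0)
    ang = np.arctan2(d[:, 1], d[:, 0])
    turns = np.diff(ang)
    # wrap to (-pi, pi]
    turns = -((-turns + np.pi) % (2 * np.pi) - np.pi)
    return turns


def turning_frequency(traj: Trajectory, angle_threshold: float = TURN_THRESHOLD) -> float:
    """Turns per second: reorientations with |angle| > threshold over duration."""
    angles = turning_angles(traj)
    if traj.duration_s <= 0:
        raise ValueError("zero-duration trajectory")
    return float((np.abs(angles) > angle_threshold).sum() / traj.duration_s)


def vacf(
    trajs: Trajectory | Iterable[Trajectory], max_lag_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble velocity autocovariance C_v(tau) at integer-frame lags.

    Velocities come from consecutive-sample displacements at the native
    frame rate.  The numerator averages v(t)·v(t+tau) over all
    trajectories and valid t; the denominator is the ensemble mean
    squared speed, so C_v(0) = 1 exactly.  Returns (lags_s, C_v).
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    trajs = list(trajs)
    if not trajs:
        raise ValueError("no trajectories")
    rate = trajs[0].rate_hz
    if any(t.rate_hz != rate for t in trajs):
        raise ValueError("trajectories must share a common sampling rate")
    max_lag = int(round(max_lag_s * rate))
    vels = []
    for t in trajs:
        xy = _require_filled(t)
        vels.append(np.diff(xy, axis=0) * rate)
    denom = sum(float((v**2).sum()) for v in vels)
    n_tot = sum(v.shape[0] for v in vels)
    if denom == 0:
        raise ValueError("all trajectories stationary; VACF undefined")
    msq = denom / n_tot
    lags = np.arange(max_lag + 1)
    cv = np.empty(lags.size)
    for i, lag in enumerate(lags):
        num, cnt = 0.0, 0
        for v in vels:
            if v.shape[0] <= lag:
                continue
            num += float((v[: v.shape[0] - lag] * v[lag:]).sum())
            cnt += v.shape[0] - lag
        if cnt == 0:
            raise ValueError(f"max_lag_s too long for the shortest trajectory")
        cv[i] = num / cnt / msq
    return lags / rate, cv


def regress_mu_on_turning(
    points: Sequence[tuple[float, float]]
) -> tuple[float, float, float]:
    """OLS of the scaling exponent on turning frequency: (slope, intercept, R^2)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (turning_frequency, mu) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("constant predictor; regression undefined")
    if np.ptp(y) == 0:  # flat response: R^2 is 0 by convention, not 0/0
        return 0.0, float(y.mean()), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
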