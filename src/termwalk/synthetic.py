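"""Synthetic trajectory and step-length generation.

Emulates the kind of data the analysis expects: per-individual recordings
of roughly 51 minutes at 5 Hz inside a 90-mm circular arena, with
heavy-tailed (truncated power-law), truncated-exponential, or
bi-exponential step statistics, sub-0.5-mm positional jitter, and
occasional missing-coordinate gaps.  Every draw is reproducible from a
single integer seed; cohorts fan the seed out into independent
per-individual substreams.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Arena, Trajectory, write_trajectory

__all__ = ["WalkSpec", "CohortGroup", "sample_steps", "generate_walk", "make_cohort"]

MODELS = ("TPL", "TE", "BiExp")


@dataclass(frozen=True)
class WalkSpec:
    """Parameters of a synthetic random walker.

    ``model`` selects the step-length law: truncated power law (TPL,
    exponent ``mu``), truncated exponential (TE, rate ``lam``), or a
    two-rate exponential mixture (BiExp, weight ``w`` on the faster rate
    ``lam1``).  ``l_max=inf`` leaves the law untruncated above.
    Headings are redrawn uniformly per step by default; a wrapped-normal
    turn model with concentration ``heading_kappa`` adds directional
    persistence for autocovariance experiments.
    """

    model: str = "TPL"
    mu: float = 1.35
    lam: float = 1.0
    w: float = 0.5
    lam1: float = 5.0
    lam2: float = 0.5
    l_min: float = 0.5
    l_max: float = np.inf
    speed: float = 2.0            # mm/s
    heading_model: str = "uniform"
    heading_kappa: float = 4.0
    jitter_sd: float = 0.1        # mm, below the 0.5-mm step filter
    pause_s: float = 0.0          # stationary reorientation pause after each step
    gap_prob: float = 0.0
    duration_s: float = 51 * 60.0
    rate_hz: float = 5.0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if not (0 < self.l_min < self.l_max):
            raise ValueError("require 0 < l_min < l_max")
        if self.model == "TPL":
            if self.mu < 1:
                raise ValueError("TPL exponent mu must be >= 1")
            if self.mu <= 1 and not np.isfinite(self.l_max):
                raise ValueError("mu <= 1 requires a finite l_max")
        if self.model == "TE" and self.lam <= 0:
            raise ValueError("TE rate lam must be positive")
        if self.model == "BiExp":
            if not (0 <= self.w <= 1):
                raise ValueError("mixture weight w must lie in [0, 1]")
            if self.lam1 <= 0 or self.lam2 <= 0:
                raise ValueError("BiExp rates must be positive")
        if self.heading_model not in ("uniform", "wrapped_normal"):
            raise ValueError("heading_model must be 'uniform' or 'wrapped_normal'")
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if not (0 <= self.gap_prob < 1):
            raise ValueError("gap_prob must lie in [0, 1)")
        if self.pause_s < 0:
            raise ValueError("pause_s must be >= 0")


def _tpl_inverse_cdf(u: np.ndarray, mu: float, l_min: float, l_max: float) -> np.ndarray:
    """Inverse CDF of the truncated power law; mu == 1 is the log-uniform limit."""
    if abs(mu - 1.0) < 1e-9:
        return l_min * (l_max / l_min) ** u
    a = l_min ** (1.0 - mu)
    b = l_max ** (1.0 - mu) if np.isfinite(l_max) else 0.0
    return (a - u * (a - b)) ** (1.0 / (1.0 - mu))


def _te_inverse_cdf(u: np.ndarray, lam: float, l_min: float, l_max: float) -> np.ndarray:
    """Inverse CDF of the exponential truncated to [l_min, l_max]."""
    if np.isfinite(l_max):
        mass = -np.expm1(-lam * (l_max - l_min))  # 1 - exp(-lam*(b-a))
        return l_min - np.log1p(-u * mass) / lam
    return l_min - np.log1p(-u) / lam


def sample_steps(spec: WalkSpec, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. step lengths from the spec's truncated density.

    TPL and TE use inverse-CDF sampling.  BiExp samples the mixture
    component first — with weights adjusted for each component's mass on
    [l_min, l_max] — then inverts that component's truncated CDF, which
    yields exact draws from the domain-renormalized mixture.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    u = rng.random(n)
    if spec.model == "TPL":
        return _tpl_inverse_cdf(u, spec.mu, spec.l_min, spec.l_max)
    if spec.model == "TE":
        return _te_inverse_cdf(u, spec.lam, spec.l_min, spec.l_max)
    # BiExp: component mass on [l_min, l_max] for rate lam is
    # exp(-lam*l_min) - exp(-lam*l_max)
    def mass(lam: float) -> float:
        hi = np.exp(-lam * spec.l_max) if np.isfinite(spec.l_max) else 0.0
        return np.exp(-lam * spec.l_min) - hi

    m1 = spec.w * mass(spec.lam1)
    m2 = (1.0 - spec.w) * mass(spec.lam2)
    p1 = m1 / (m1 + m2)
    pick1 = rng.random(n) < p1
    out = np.empty(n)
    out[pick1] = _te_inverse_cdf(u[pick1], spec.lam1, spec.l_min, spec.l_max)
    out[~pick1] = _te_inverse_cdf(u[~pick1], spec.lam2, spec.l_min, spec.l_max)
    return out


def _draw_heading(rng: np.random.Generator, spec: WalkSpec, prev: float | None) -> float:
    if spec.heading_model == "uniform" or prev is None:
        return float(rng.uniform(-np.pi, np.pi))
    # wrapped-normal turn with concentration kappa -> sd 1/sqrt(kappa)
    return float(prev + rng.normal(0.0, 1.0 / np.sqrt(spec.heading_kappa)))


def generate_walk(
    spec: WalkSpec,
    arena: Arena | None = None,
    seed: int | np.random.Generator = 0,
    id: str = "synthetic",
    caste: str = "agent",
) -> Trajectory:
    """Simulate one walker and sample its position at ``spec.rate_hz``.

    The walker draws a step length from the spec's law and a heading,
    then traverses the step at constant ``spec.speed``, emitting samples
    at the frame rate.  After each step it stays put for ``pause_s``
    seconds (a reorientation pause; 0 disables it).  Steps that would
    exit the arena are cut at the wall (stop-at-boundary), after which a
    fresh step begins.  Gaussian jitter of sd ``jitter_sd`` is added to
    every emitted position, and interior samples are blanked to NaN with
    probability ``gap_prob``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_frames = int(round(spec.duration_s * spec.rate_hz)) + 1
    dt = 1.0 / spec.rate_hz
    times = np.arange(n_frames) * dt
    xy = np.empty((n_frames, 2))

    if arena is not None:
        cx, cy = arena.center
        pos = np.array([cx, cy], dtype=float)
    else:
        pos = np.zeros(2)
    xy[0] = pos

    heading: float | None = None
    remaining = 0.0   # mm left of the current step
    pause_left = 0.0  # s left of the current reorientation pause
    direction = np.zeros(2)
    for i in range(1, n_frames):
        budget = dt  # seconds of walk time this frame
        while budget > 1e-12:
            if pause_left > 1e-12:
                c = min(pause_left, budget)
                pause_left -= c
                budget -= c
                continue
            if remaining <= 1e-12:
                heading = _draw_heading(rng, spec, heading)
                remaining = float(sample_steps(spec, 1, rng)[0])
                direction = np.array([np.cos(heading), np.sin(heading)])
                if arena is not None:
                    remaining = min(
                        remaining, _wall_distance(pos, direction, arena)
                    )
                    if remaining <= 1e-12:
                        # pinned against the wall on this heading: pause,
                        # then redraw
                        remaining = 0.0
                        pause_left = spec.pause_s
                        if pause_left <= 0:
                            continue
                continue
            move_t = min(budget, remaining / spec.speed)
            pos = pos + move_t * spec.speed * direction
            budget -= move_t
            remaining -= move_t * spec.speed
            if remaining <= 1e-12:
                pause_left = spec.pause_s
        xy[i] = pos

    if spec.jitter_sd > 0:
        xy = xy + rng.normal(0.0, spec.jitter_sd, size=xy.shape)
        if arena is not None:
            # jitter must not push samples outside the arena disc
            r = np.hypot(xy[:, 0] - arena.center[0], xy[:, 1] - arena.center[1])
            over = r > arena.radius
            if over.any():
                scale = arena.radius / r[over]
                xy[over, 0] = arena.center[0] + (xy[over, 0] - arena.center[0]) * scale
                xy[over, 1] = arena.center[1] + (xy[over, 1] - arena.center[1]) * scale
    if spec.gap_prob > 0 and n_frames > 2:
        gaps = rng.random(n_frames) < spec.gap_prob
        gaps[0] = gaps[-1] = False  # keep gaps interior so interpolation brackets them
        xy[gaps] = np.nan
    return Trajectory(
        times=times, xy=xy, rate_hz=spec.rate_hz, id=id, caste=caste, arena=arena
    )


def _wall_distance(pos: np.ndarray, direction: np.ndarray, arena: Arena) -> float:
    """Distance along ``direction`` from ``pos`` to the arena wall."""
    rel = pos - np.asarray(arena.center, dtype=float)
    b = float(rel @ direction)
    c = float(rel @ rel) - arena.radius**2
    disc = b * b - c
    if disc <= 0:
        return 0.0
    return max(0.0, -b + np.sqrt(disc))


@dataclass(frozen=True)
class CohortGroup:
    """One experimental condition: ``replicates`` focal walkers of a caste
    recorded at group size ``group_size`` under a common walk spec."""

    caste: str
    group_size: int
    replicates: int
    spec: WalkSpec = field(default_factory=WalkSpec)


def make_cohort(
    groups: list[CohortGroup],
    out_dir: str | Path,
    seed: int = 0,
    arena: Arena | None = None,
) -> pd.DataFrame:
    """Write one trajectory CSV per focal individual plus a manifest.

    Deterministic: the global seed spawns one independent substream per
    individual, so the same seed reproduces every file byte-for-byte.
    Returns the manifest (also written as ``manifest.csv``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if arena is None:
        arena = Arena()
    if not groups:
        warnings.warn("empty cohort specification; writing manifest only")
    rows = []
    ss = np.random.SeedSequence(seed)
    total = sum(g.replicates for g in groups)
    children = ss.spawn(total) if total else []
    k = 0
    for g in groups:
        for rep in range(g.replicates):
            ind_id = f"{g.caste}_N{g.group_size}_r{rep}"
            sub_seed = int(children[k].generate_state(1)[0] % (2**31))
            k += 1
            traj = generate_walk(
                g.spec, arena=arena, seed=sub_seed, id=ind_id, caste=g.caste
            )
            fname = f"{ind_id}.csv"
            write_trajectory(traj, out_dir / fname)
            rows.append(
                {
                    "id": ind_id,
                    "caste": g.caste,
                    "N": g.group_size,
                    "model": g.spec.model,
                    "params": json.dumps(_model_params(g.spec)),
                    "seed": sub_seed,
                    "file": fname,
                }
            )
    manifest = pd.DataFrame(
        rows, columns=["id", "caste", "N", "model", "params", "seed", "file"]
    )
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def _model_params(spec: WalkSpec) -> dict:
    if spec.model == "TPL":
        return {"mu": spec.mu}
    if spec.model == "TE":
        return {"lam": spec.lam}
    return {"w": spec.w, "lam1": spec.lam1, "lam2": spec.lam2}
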