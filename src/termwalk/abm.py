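"""Agent-based simulator of Lévy walkers under crowding and confinement.

Agents are persistent random walkers carrying an intrinsic, unbounded
power-law step template (exponent ``mu_int``, default 1.35) inside a
circular arena (radius 45 mm, agent radius 1 mm).  Headings evolve by
wrapped-normal turns (sd ``heading_sigma``, default 0.25 rad); the
persistence matters, because a walker leaving the wall tangentially
executes short chords, whereas a memoryless walker piles realized mass
onto long arena-crossing chords and biases the fitted exponent well
below the intrinsic one.  Two truncation mechanisms act on every
intended step:

* boundary truncation — a step that would exit the effective disc of
  radius ``R - R_agent`` is cut at the wall (stop-at-boundary);
* social blocking — a Poisson-like failure whose success probability is
  ``exp(-k(N) * l)`` with interruption rate ``k(N) = c * sqrt(N)``; a
  blocked step is wholly replaced by a short stagnation displacement.

Crowding is mediated entirely by the stochastic blocking rule; agents do
not interact geometrically, so tracked agents are statistically
independent and a subsample represents any group size exactly.  Fitting
the truncated power law to the realized steps yields the effective
exponent ``mu_eff``, which rises with density as long steps are chopped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Arena, Trajectory
from .models import fit_model

__all__ = [
    "ABMConfig",
    "SimResult",
    "draw_intended_step",
    "apply_boundary",
    "apply_social_blocking",
    "run_simulation",
    "effective_exponent",
    "mu_sweep",
]

OUTCOMES = ("completed", "wall_truncated", "socially_blocked")


@dataclass(frozen=True)
class ABMConfig:
    """Simulation parameters.

    ``N`` is the nominal group size entering the interruption rate
    ``k(N) = blocking_c * sqrt(N)``; blocking is disabled for a solitary
    agent (no nestmates to collide with).  ``tracked_agents`` limits how
    many independent walkers are actually simulated per trial (None =
    min(N, 100)); since blocking is stochastic rather than geometric this
    is an exact subsample, not an approximation.
    """

    N: int = 1
    arena: Arena = field(default_factory=Arena)
    agent_radius: float = 1.0
    mu_int: float = 1.35
    l_min: float = 1.0
    blocking_c: float = 0.002         # mm^-1 prefactor of k(N)
    steps_per_agent: int = 1500
    trials: int = 5
    stagnation_length: float | None = None  # defaults to l_min
    heading_model: str = "persistent"
    heading_sigma: float = 0.25       # rad, sd of the wrapped-normal turn
    tracked_agents: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not self.mu_int > 1:
            raise ValueError("mu_int must exceed 1")
        if self.blocking_c < 0:
            raise ValueError("blocking_c must be >= 0")
        if self.steps_per_agent < 1 or self.trials < 1:
            raise ValueError("steps_per_agent and trials must be >= 1")
        if not self.agent_radius < self.arena.radius:
            raise ValueError("agent radius must be smaller than the arena")
        if self.heading_model not in ("persistent", "uniform"):
            raise ValueError("heading_model must be 'persistent' or 'uniform'")
        if self.heading_model == "persistent" and not self.heading_sigma > 0:
            raise ValueError("heading_sigma must be positive")

    @property
    def k(self) -> float:
        """Density-dependent interruption rate; zero for a solitary agent."""
        return 0.0 if self.N <= 1 else self.blocking_c * np.sqrt(self.N)

    @property
    def effective_radius(self) -> float:
        return self.arena.radius - self.agent_radius

    @property
    def stagnation(self) -> float:
        return self.l_min if self.stagnation_length is None else self.stagnation_length

    @property
    def n_tracked(self) -> int:
        if self.tracked_agents is not None:
            return self.tracked_agents
        return min(self.N, 100)


@dataclass(frozen=True)
class SimResult:
    config: ABMConfig
    trajectories: list[list[Trajectory]]   # [trial][agent]
    realized_steps: list[np.ndarray]       # pooled per trial
    outcome_counts: pd.DataFrame           # per trial: completed/wall/blocked

    @property
    def total_steps(self) -> int:
        return int(self.outcome_counts[list(OUTCOMES)].to_numpy().sum())


def draw_intended_step(
    mu_int: float, l_min: float, rng: np.random.Generator, size: int | None = None
):
    """Pareto draw on [l_min, inf) with tail exponent mu_int, by inverse CDF."""
    if not mu_int > 1:
        raise ValueError("mu_int must exceed 1")
    u = rng.random(size)
    return l_min * (1.0 - u) ** (-1.0 / (mu_int - 1.0))


def apply_boundary(
    position: np.ndarray,
    heading: float | np.ndarray,
    length: float | np.ndarray,
    arena: Arena,
    agent_radius: float,
) -> np.ndarray:
    """Executed step length after stop-at-boundary wall truncation.

    If the intended segment exits the effective disc of radius
    ``R - R_agent``, it is cut at the chord intersection (root of the
    ray-circle quadratic); otherwise it executes fully.  Vectorized over
    agents; start positions must lie inside the effective disc.
    """
    pos = np.atleast_2d(np.asarray(position, dtype=float))
    heading = np.atleast_1d(np.asarray(heading, dtype=float))
    length = np.atleast_1d(np.asarray(length, dtype=float))
    r_eff = arena.radius - agent_radius
    rel = pos - np.asarray(arena.center, dtype=float)
    r2 = (rel**2).sum(axis=1)
    if np.any(r2 > r_eff**2 * (1 + 1e-12)):
        raise ValueError("start position outside the effective disc")
    d = np.stack([np.cos(heading), np.sin(heading)], axis=1)
    b = (rel * d).sum(axis=1)
    disc = b * b - (r2 - r_eff**2)
    t_wall = -b + np.sqrt(np.maximum(disc, 0.0))
    return np.minimum(length, t_wall)


def apply_social_blocking(
    length: float | np.ndarray,
    k: float,
    rng: np.random.Generator,
    stagnation_length: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson-like interruption of intended steps by nestmate crowding.

    Each step survives intact with probability exp(-k*l); a blocked step
    is wholly replaced by ``stagnation_length`` in the same heading (loss
    of momentum, not partial progress).  Returns (executed, blocked mask).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    length = np.atleast_1d(np.asarray(length, dtype=float))
    if k == 0:
        return length.copy(), np.zeros(length.shape, dtype=bool)
    blocked = rng.random(length.shape) >= np.exp(-k * length)
    executed = np.where(blocked, stagnation_length, length)
    return executed, blocked


def run_simulation(config: ABMConfig) -> SimResult:
    """Run ``config.trials`` independent trials of the crowding model.

    Per trial, tracked agents start uniformly in the effective disc and
    execute ``steps_per_agent`` cycles of draw-heading, draw-length,
    social blocking, boundary truncation.  All randomness derives from
    ``config.seed``; realized step lengths are pooled per trial.
    """
    ss = np.random.SeedSequence(config.seed)
    trial_seeds = ss.spawn(config.trials)
    r_eff = config.effective_radius
    center = np.asarray(config.arena.center, dtype=float)
    k = config.k
    m = config.n_tracked

    all_traj: list[list[Trajectory]] = []
    all_steps: list[np.ndarray] = []
    counts = []
    for t_seed in trial_seeds:
        rng = np.random.default_rng(t_seed)
        # uniform start positions in the effective disc
        phi = rng.uniform(0, 2 * np.pi, m)
        rad = r_eff * np.sqrt(rng.random(m))
        pos = center + np.stack([rad * np.cos(phi), rad * np.sin(phi)], axis=1)
        path = np.empty((config.steps_per_agent + 1, m, 2))
        path[0] = pos
        realized = np.empty((config.steps_per_agent, m))
        n_blocked = 0
        n_wall = 0
        heading = rng.uniform(-np.pi, np.pi, m)
        for s in range(config.steps_per_agent):
            if config.heading_model == "persistent":
                heading = heading + rng.normal(0.0, config.heading_sigma, m)
            else:
                heading = rng.uniform(-np.pi, np.pi, m)
            intended = draw_intended_step(config.mu_int, config.l_min, rng, m)
            executed, blocked = apply_social_blocking(
                intended, k, rng, config.stagnation
            )
            cut = apply_boundary(
                pos, heading, executed, config.arena, config.agent_radius
            )
            wall = (cut < executed - 1e-12) & ~blocked
            n_wall += int(wall.sum())
            n_blocked += int(blocked.sum())
            pos = pos + cut[:, None] * np.stack(
                [np.cos(heading), np.sin(heading)], axis=1
            )
            # guard against float drift just outside the effective disc
            rel = pos - center
            r = np.hypot(rel[:, 0], rel[:, 1])
            over = r > r_eff
            if over.any():
                pos[over] = center + rel[over] * (r_eff / r[over])[:, None]
            path[s + 1] = pos
            realized[s] = cut
        steps_flat = realized.T.ravel()
        all_steps.append(steps_flat)
        counts.append(
            {
                "completed": config.steps_per_agent * m - n_wall - n_blocked,
                "wall_truncated": n_wall,
                "socially_blocked": n_blocked,
            }
        )
        trial_trajs = [
            Trajectory(
                times=np.arange(config.steps_per_agent + 1, dtype=float),
                xy=path[:, a, :],
                rate_hz=1.0,
                id=f"agent_{a}",
                caste="agent",
                arena=config.arena,
            )
            for a in range(m)
        ]
        all_traj.append(trial_trajs)
    outcome = pd.DataFrame(counts)
    outcome.insert(0, "trial", np.arange(config.trials))
    return SimResult(
        config=config,
        trajectories=all_traj,
        realized_steps=all_steps,
        outcome_counts=outcome,
    )


def effective_exponent(
    sim: SimResult, l_min: float | None = None
) -> tuple[np.ndarray, float, float]:
    """Per-trial TPL fit of the realized steps: (mu per trial, mean, SEM).

    Realized steps shorter than ``l_min`` (stubs from truncation right at
    the wall) fall below the fitting domain and are dropped, mirroring
    the minimum-step filter of the empirical pipeline.  ``l_max`` is each
    trial's largest realized step.
    """
    if l_min is None:
        l_min = sim.config.l_min
    mus = []
    for steps in sim.realized_steps:
        kept = steps[steps >= l_min]
        if kept.size < 10:
            raise ValueError("too few realized steps above l_min to fit")
        fit = fit_model("TPL", kept, l_min=l_min)
        mus.append(fit.params["mu"])
    mus = np.asarray(mus)
    sem = float(mus.std(ddof=1) / np.sqrt(mus.size)) if mus.size > 1 else 0.0
    return mus, float(mus.mean()), sem


def _cell_sequence(path: np.ndarray, cell_mm: float, origin: np.ndarray) -> np.ndarray:
    """Grid cells entered along a polyline, consecutive duplicates removed."""
    pts = []
    for a, b in zip(path[:-1], path[1:]):
        seg = b - a
        n = max(1, int(np.ceil(np.hypot(*seg) / (0.25 * cell_mm))))
        t = np.linspace(0.0, 1.0, n + 1)
        pts.append(a + t[:, None] * seg)
    dense = np.concatenate(pts)
    cells = np.floor((dense - origin) / cell_mm).astype(np.int64)
    keep = np.ones(cells.shape[0], dtype=bool)
    keep[1:] = (cells[1:] != cells[:-1]).any(axis=1)
    return cells[keep]


def mu_sweep(
    mu_values,
    arena: Arena | None = None,
    path_length_mm: float = 6000.0,
    cell_mm: float = 1.0,
    n_seeds: int = 20,
    seed: int = 0,
    l_min: float = 1.0,
    agent_radius: float = 1.0,
) -> pd.DataFrame:
    """Spatial-exploration consequences of the scaling exponent.

    For each exponent, single boundary-truncated walkers with memoryless
    (uniform) headings and no social blocking travel a fixed path-length
    budget ``path_length_mm``; the path is rasterized on the ``cell_mm``
    grid.  Reports, averaged over ``n_seeds`` walkers, the unique cells
    visited (global search) and the revisit count (entries into
    already-visited cells, a proxy for localized residence and
    interaction intensity).

    Comparing equal travel budgets — equal observation time at constant
    speed — is what makes the trade-off visible: at a fixed budget, low
    exponents spread the path over many cells (wide exploration, few
    revisits) while high exponents fold it into a small neighbourhood
    (many revisits).  Memoryless headings isolate the effect of the
    step-length law from directional persistence.
    """
    if arena is None:
        arena = Arena()
    mu_values = np.asarray(mu_values, dtype=float)
    if np.any(mu_values <= 1):
        raise ValueError("exponents must exceed 1")
    if path_length_mm <= 0:
        raise ValueError("path_length_mm must be positive")
    r_eff = arena.radius - agent_radius
    center = np.asarray(arena.center, dtype=float)
    origin = center - arena.radius
    ss = np.random.SeedSequence(seed)
    rows = []
    for mu, mu_ss in zip(mu_values, ss.spawn(mu_values.size)):
        uniq, revis = [], []
        for walker_ss in mu_ss.spawn(n_seeds):
            rng = np.random.default_rng(walker_ss)
            phi = rng.uniform(0, 2 * np.pi)
            rad = r_eff * np.sqrt(rng.random())
            pos = center + [rad * np.cos(phi), rad * np.sin(phi)]
            verts = [pos]
            travelled = 0.0
            while travelled < path_length_mm:
                heading = rng.uniform(-np.pi, np.pi)
                length = float(draw_intended_step(float(mu), l_min, rng))
                cut = float(
                    apply_boundary(pos, heading, length, arena, agent_radius)[0]
                )
                cut = min(cut, path_length_mm - travelled)
                pos = pos + cut * np.array([np.cos(heading), np.sin(heading)])
                rel = pos - center
                r = float(np.hypot(*rel))
                if r > r_eff:  # float drift from the chord intersection
                    pos = center + rel * (r_eff / r)
                travelled += cut
                verts.append(pos)
            cells = _cell_sequence(np.asarray(verts), cell_mm, origin)
            n_unique = np.unique(cells, axis=0).shape[0]
            uniq.append(n_unique)
            revis.append(cells.shape[0] - n_unique)
        rows.append(
            {
                "mu": float(mu),
                "unique_cells": float(np.mean(uniq)),
                "revisit_frequency": float(np.mean(revis)),
            }
        )
    return pd.DataFrame(rows)
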