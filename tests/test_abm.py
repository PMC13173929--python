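import numpy as np
import pytest

from termwalk import (
    ABMConfig,
    Arena,
    apply_boundary,
    apply_social_blocking,
    draw_intended_step,
    effective_exponent,
    mu_sweep,
    run_simulation,
)


class TestIntendedSteps:
    def test_support(self, rng):
        s = draw_intended_step(1.35, 1.0, rng, 10_000)
        assert s.min() >= 1.0

    def test_pareto_median_closed_form(self, rng):
        # median of Pareto(mu=2, l_min=1) is 2^(1/(mu-1)) = 2
        s = draw_intended_step(2.0, 1.0, rng, 200_000)
        assert np.median(s) == pytest.approx(2.0, rel=0.02)

    def test_hill_estimator_recovers_exponent(self, rng):
        # Hill estimator oracle: mu = 1 + n / sum(log(l / l_min))
        s = draw_intended_step(1.35, 1.0, rng, 100_000)
        hill = 1.0 + s.size / np.log(s).sum()
        assert hill == pytest.approx(1.35, abs=0.01)

    def test_invalid_exponent(self, rng):
        with pytest.raises(ValueError):
            draw_intended_step(1.0, 1.0, rng)


class TestBoundary:
    def test_radial_from_center(self, arena):
        out = apply_boundary([0.0, 0.0], 0.0, 100.0, arena, 1.0)
        assert out[0] == pytest.approx(44.0)

    def test_short_step_untouched(self, arena):
        assert apply_boundary([0.0, 0.0], 1.0, 1.0, arena, 1.0)[0] == pytest.approx(1.0)

    def test_near_wall_chord(self, arena):
        out = apply_boundary([43.0, 0.0], 0.0, 10.0, arena, 1.0)
        assert out[0] == pytest.approx(1.0)

    def test_start_outside_rejected(self, arena):
        with pytest.raises(ValueError, match="outside"):
            apply_boundary([44.5, 0.0], 0.0, 1.0, arena, 1.0)


class TestSocialBlocking:
    def test_zero_rate_never_blocks(self, rng):
        lengths = rng.uniform(1, 50, 1000)
        executed, blocked = apply_social_blocking(lengths, 0.0, rng, 1.0)
        np.testing.assert_array_equal(executed, lengths)
        assert not blocked.any()

    def test_half_life_length(self, rng):
        # k*l = ln 2 gives success probability exactly 1/2
        l = np.full(40_000, np.log(2.0))
        _, blocked = apply_social_blocking(l, 1.0, rng, 1.0)
        assert blocked.mean() == pytest.approx(0.5, abs=0.01)

    def test_harsh_blocking_limit(self, rng):
        l = np.full(10_000, 100.0)
        executed, blocked = apply_social_blocking(l, 1.0, rng, 1.0)
        assert blocked.mean() > 0.999
        assert np.all(executed[blocked] == 1.0)


class TestSimulation:
    def test_outcome_conservation(self):
        cfg = ABMConfig(N=100, trials=2, steps_per_agent=200, tracked_agents=10, seed=1)
        sim = run_simulation(cfg)
        counts = sim.outcome_counts
        total = cfg.trials * cfg.steps_per_agent * 10
        assert counts[["completed", "wall_truncated", "socially_blocked"]].to_numpy().sum() == total
        assert (counts["socially_blocked"] > 0).all()

    def test_agents_stay_inside_effective_disc(self):
        cfg = ABMConfig(N=1, trials=2, steps_per_agent=500, seed=2)
        sim = run_simulation(cfg)
        for trial in sim.trajectories:
            for traj in trial:
                r = np.hypot(*traj.xy.T)
                assert r.max() <= cfg.effective_radius + 1e-9

    def test_deterministic_given_seed(self):
        cfg = ABMConfig(N=100, trials=2, steps_per_agent=100, tracked_agents=5, seed=3)
        a, b = run_simulation(cfg), run_simulation(cfg)
        for sa, sb in zip(a.realized_steps, b.realized_steps):
            np.testing.assert_array_equal(sa, sb)

    def test_blocking_disabled_for_solitary(self):
        cfg = ABMConfig(N=1, blocking_c=0.5, trials=1, steps_per_agent=300, seed=4)
        assert cfg.k == 0.0
        sim = run_simulation(cfg)
        assert (sim.outcome_counts["socially_blocked"] == 0).all()


class TestEffectiveExponent:
    def test_consistency_without_truncation(self):
        # an effectively unbounded arena and no blocking recover mu_int
        cfg = ABMConfig(
            N=1, arena=Arena(radius=1e6), trials=3, seed=3, heading_model="uniform"
        )
        _, mean, _ = effective_exponent(run_simulation(cfg))
        assert mean == pytest.approx(1.35, abs=0.05)

    def test_monotone_in_blocking_constant(self):
        mus = []
        for c in (0.0, 0.002, 0.01):
            cfg = ABMConfig(N=100, blocking_c=c, trials=3, seed=5)
            _, mean, _ = effective_exponent(run_simulation(cfg))
            mus.append(mean)
        assert mus[0] < mus[1] < mus[2]

    def test_per_trial_output_shape(self):
        cfg = ABMConfig(N=1, trials=4, steps_per_agent=400, seed=6)
        mus, mean, sem = effective_exponent(run_simulation(cfg))
        assert mus.shape == (4,)
        assert mean == pytest.approx(mus.mean())
        assert sem >= 0.0


class TestMuSweep:
    def test_columns_and_bounds(self):
        df = mu_sweep([1.5, 2.5], path_length_mm=200.0, n_seeds=2, seed=0)
        assert list(df.columns) == ["mu", "unique_cells", "revisit_frequency"]
        assert (df["unique_cells"] >= 1).all()
        assert (df["revisit_frequency"] >= 0).all()

    def test_invalid_exponent_rejected(self):
        with pytest.raises(ValueError):
            mu_sweep([0.9], path_length_mm=100.0, n_seeds=1)
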