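# termwalk

Movement analysis and crowding simulation for confined-arena trajectories.

Social insects move through crowds. A termite worker alone in a dish
performs long, nearly ballistic runs whose step lengths are heavy-tailed;
packed among a thousand nestmates, the same animal produces short, tortuous,
localized paths. `termwalk` is a library for quantifying that transition
from time-stamped 2D centroid recordings (mm, seconds) and for testing
whether simple physical blocking is sufficient to explain it. It is aimed
at movement ecologists and behavioural physicists working with tracked
arena experiments — or with no data at all, since every stage can be fed
from the built-in synthetic generators.

## What it computes

**Step-length model selection.** Trajectories are downsampled to 1 Hz and
segmented by the one-dimensional projection method: each coordinate axis is
treated independently, and a step is the distance travelled between
consecutive reversal points (sign changes of the increment, with pauses as
boundaries), subject to a minimum step length l_min = 0.5 mm. Step samples
are fitted by maximum likelihood (L-BFGS-B) with three truncated densities
on [l_min, l_max]:

- truncated power law (Lévy walk in a bounded arena):
  p(l) = C_TPL · l^(−µ), C_TPL = (µ−1) / (l_min^(1−µ) − l_max^(1−µ))
- truncated exponential (boundary-limited Brownian motion):
  p(l) = C_TE · e^(−λl), C_TE = λ / (e^(−λ·l_min) − e^(−λ·l_max))
- bi-exponential mixture (composite Brownian, two motility modes):
  p(l) ∝ w·λ₁e^(−λ₁l) + (1−w)·λ₂e^(−λ₂l), renormalized to [l_min, l_max]

Models are ranked by AIC = 2k − 2 ln L and Akaike weights; a weight above
0.9 declares a decisive winner, otherwise the lowest AIC does.

**Kinematics.** Sliding-window straightness S = D/L (5-s window, 1-s
stride), signed turning angles and turning frequency, the velocity
autocovariance function C_v(τ) = ⟨v(t)·v(t+τ)⟩ / ⟨|v(t)|²⟩, and the OLS
regression of the fitted exponent on turning frequency.

**Crowding simulator.** Persistent random walkers with an intrinsic Pareto
step template (exponent µ_int = 1.35, l_min = 1 mm) inside a 45-mm circular
arena. Steps are truncated at the wall (stop-at-boundary) and interrupted
stochastically by nestmates: a step of length l survives with probability
exp(−k(N)·l), where k(N) = c·√N, and a blocked step collapses to a 1-mm
stagnation move. Refitting the truncated power law to the realized steps
yields the effective exponent µ_eff, which rises with crowd size.

**Spatial & social metrics.** 1-mm grid coverage of the arena, cumulative
travel distance, proximity encounters (contacts < 1 s apart pooled into
single events), inner-region occupancy, and an exploration sweep showing
the trade-off between unique cells visited and revisit frequency as the
exponent varies.

**Synthetic data.** Inverse-CDF samplers for all three step laws, a
constant-speed walk generator with arena truncation, positional jitter,
reorientation pauses and tracking gaps, and a cohort writer that emits
one `time,x,y` CSV per individual plus a manifest, reproducibly from one
seed.

## Worked example

```
$ python examples/04_crowding_simulation.py
 N      k(N)    mu_eff   (SEM over 5 trials)
    1  0.0000   1.325   (+/- 0.042, 0% of steps blocked)
  100  0.0200   2.182   (+/- 0.003, 34% of steps blocked)
  200  0.0283   2.335   (+/- 0.002, 38% of steps blocked)
 1000  0.0632   2.890   (+/- 0.001, 49% of steps blocked)
```

The solitary agent's µ_eff ≈ 1.33 (± stochastic trial spread) shows that
confinement alone barely steepens the intrinsic 1.35 template, while
increasing density drives the exponent up monotonically — long
displacements are selectively destroyed by steric blocking, not by any
change in the walkers' internal rules. The other scripts in `examples/`
demonstrate cohort generation, step-model selection, kinematics, the
exploration trade-off, and the spatial/social metrics, each printing a
short interpretation of its numbers.

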