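# Methods

This note records the models implemented in `termwalk`, the numerical
choices behind them, and what the synthetic-data based tests do and do
not demonstrate.

## Data model and preprocessing

A trajectory is a strictly increasing time base (s) with 2D centroid
positions (mm) at a nominal frame rate (5 Hz for the emulated
recordings), inside a circular arena (default radius 45 mm, a 90-mm
Petri dish). Missing positions — tracking dropouts, wall-climbing
intervals — are NaN rows. Interior gaps are filled by linear
interpolation of each coordinate against time; leading and trailing gaps
are trimmed rather than extrapolated, because extrapolation fabricates
motion. Gaps longer than 10 s trigger a warning: linear fill over such
spans is a straight-line fiction and the warning leaves the decision to
the analyst. Positions marginally outside the arena (tracking noise) are
clamped radially to the boundary; positions more than 1 mm outside raise,
since that indicates a unit or geometry error rather than noise.
Downsampling keeps every k-th sample (k = round(rate/target)), so the
5 Hz → 1 Hz step-analysis path is exact decimation, not resampling.

## Step segmentation (1D projection)

Each coordinate axis is segmented independently: a step is a maximal run
of same-signed per-sample increments, ended by a reversal (sign change)
or a pause (zero increment), and its length is the absolute coordinate
difference across the run. Both axis projections are pooled into one
series per individual (one distribution is fitted per individual; the
axis labels are kept for diagnostics). Candidate steps below
l_min = 0.5 mm are discarded as jitter-scale micromovement; l_max is the
largest observed step of that individual. Unfiltered per-axis step sums
equal the coordinate's total variation exactly — a conservation identity
the tests assert.

Two semantics deserve justification:

- *Pauses delimit steps.* On recorded data the alternative conventions
  coincide: increments across a genuine pause are dominated by positional
  jitter, and their random signs terminate the run under either rule.
  Exact zero increments occur only in noise-free synthetic data, where
  treating them as boundaries is the jitter → 0 limit of the recorded
  behaviour. The choice also matters quantitatively: if pauses are
  ignored, successive same-direction moves merge into runs of geometric
  mean length 2, and the refitted power-law exponent of a synthetic
  walker is depressed by 0.13–0.30 (measured at µ = 1.2–2.0). With
  pause-delimited steps the pipeline closes (see below).
- *Projection bias.* A step of length l at heading θ projects to
  l·|cos θ|. Within the scale-free region of a power law this factor
  provably preserves the exponent (the projected density is
  x^(−µ)·∫f(u)u^(µ−1)du); near the generating l_min and l_max it flattens
  and smears the density. Pipeline-closure tests therefore generate with
  l_min below the 0.5-mm filter and l_max well above the fitted range
  (0.1 and 2000 mm), so the extraction window sits inside the preserved
  region. Measured recovery: 1.232 / 1.502 / 1.990 for generating
  exponents 1.2 / 1.5 / 2.0 (n ≥ 3000 steps each); the residual +0.03 at
  µ = 1.2 is the soft-upper-cutoff remnant.

## Likelihoods, fitting, and selection

All three models are compared on the same support [l_min, l_max]; the
bi-exponential mixture, printed as an untruncated density, is
renormalized by its mass on that interval, otherwise its AIC would be
computed against a different sample space than the truncated models'.
Negative log-likelihoods are minimized with L-BFGS-B:

- TPL: µ ∈ (1.001, 5]; µ = 1 is excluded because the normalization is
  singular there (the sampler supports µ = 1 via the log-uniform limit,
  the fitter does not need it — observed exponents live in 1.0–3).
  Three deterministic starts (1.2, 1.6, 2.5).
- TE: λ ∈ (1e−8, 1e4], seeded by the untruncated moment estimate
  1/(mean − l_min) and two scale perturbations.
- Bi-Exp: (w, λ₁, λ₂) with five deterministic quantile-based starts (the
  sample is split at a quantile and each half's reciprocal mean excess
  seeds one rate), guarding against local optima; label switching is
  resolved by reporting w as the weight of the faster rate (λ₁ > λ₂).

AIC = 2k + 2·NLL with k = 1, 1, 3. Akaike weights are softmax(−ΔAIC/2);
a weight above 0.9 marks a decisive winner, otherwise the lowest AIC
decides, with exact ties broken by parsimony (fewest parameters) and
then the fixed order TPL < TE < Bi-Exp for reproducibility. Fits require
at least 10 steps; smaller samples are refused rather than fitted.

Identifiability caveat: with l_min = 0.5 mm a fast mixture component with
λ₁ = 5 mm⁻¹ retains only e^(−2.5) ≈ 8% of its mass above the threshold,
so its MLE standard error at n = 10⁴ is ≈ 0.3; recovery assertions at
that configuration use tolerances of that order, and the unit test of the
fitter itself uses l_min = 0.1 where the component is well identified.

## Crowding simulator

Agents are persistent random walkers: headings evolve by wrapped-normal
turns with sd 0.25 rad per step, and step lengths are Pareto draws on
[1 mm, ∞) with intrinsic exponent µ_int = 1.35. Two mechanisms truncate
intended steps inside the 45-mm arena (agent radius 1 mm, so the
effective disc has radius 44 mm):

1. *Boundary truncation*: a step exiting the effective disc is cut at
   the ray–circle intersection; the agent stops at the wall.
2. *Social blocking*: a step of length l survives with probability
   exp(−k(N)·l), k(N) = c·√N with c = 0.002 mm⁻¹ by default; a blocked
   step is wholly replaced by a 1-mm stagnation move in the same
   heading. Blocking is disabled at N = 1 (no nestmates).

Heading persistence is not cosmetic. A memoryless walker that stops at
the wall departs in a uniformly random direction, piling realized step
mass onto long arena-crossing chords; the TPL refit of such steps gives
µ_eff ≈ 1.19, well below the intrinsic 1.35. A persistent walker leaves
the wall near-tangentially, executing short chords, and the solitary
baseline lands at µ_eff ≈ 1.33–1.39 across seeds — confinement barely
perturbs the template, which is the behaviour the baseline is meant to
show. The persistence sd is the one calibrated constant (set once against
that solitary baseline); `heading_model="uniform"` remains available for
sensitivity runs.

Because blocking is a per-step stochastic rule and agents never interact
geometrically, tracked walkers are i.i.d.; large-N conditions are
simulated with 100 tracked focal agents, which is an exact subsample,
not an approximation. The effective exponent is the per-trial TPL MLE of
realized steps ≥ l_min (sub-l_min wall stubs fall below the fitting
domain, mirroring the empirical minimum-step filter), reported as mean ±
SEM over 5 trials of 1500 steps per agent. The blocking prefactor c is
not identified by any printed quantity; 0.002 mm⁻¹ keeps the whole
density ladder N ∈ {1, 100, 200, 1000} strictly increasing and inside
the fitting domain (≈ 1.33 → 2.19 → 2.34 → 2.89), which is the qualitative
claim the simulator supports. Point values at N ≥ 100 are
calibration-dependent and are not asserted.

## Exploration sweep

The sweep quantifies the functional consequence of the exponent alone:
single boundary-truncated walkers with memoryless headings and no
blocking each travel a fixed path-length budget (default 6000 mm), and
the path is rasterized on the 1-mm grid (cells sampled at quarter-cell
spacing along each segment, consecutive duplicates dropped). Unique
cells measure global search; entries into already-visited cells measure
localized residence. Equal travel budgets — equal observation time at
constant speed — are essential: at a fixed step count the total path
length varies tenfold across exponents and both metrics then simply
track path length. Memoryless headings isolate the step-length law from
persistence effects (a persistent near-ballistic walker rides the wall,
which reverses the coverage trend). Averaged over 20 walkers the sweep
gives monotone trends: unique cells fall and revisits rise with µ.

## Spatial and social metrics

Grid cells are half-open 1-mm squares anchored at the arena's
bounding-box corner (boundary points belong to the higher-index cell);
accessible cells are those whose centers lie inside the disc, and
coverage is per-centroid-sample, matching the recording definition.
Encounters are proximity events: a contact frame has the focal centroid
within the contact radius (default 2 mm = two agent radii, a centroid
proxy for antennal contact) of any nestmate, and contact runs separated
by less than 1 s merge into one event. Inner-region occupancy uses a
half-radius disc by default (25% of the arena area), exposed as a
parameter since no canonical value exists.

## Synthetic data: what it emulates, and what it does not

The generators emulate the recording protocol: ~51-minute trajectories
at 5 Hz in the 90-mm arena (~15,300 samples), heavy-tailed or
multi-phasic step statistics, 0.1-mm positional jitter (below the 0.5-mm
step filter), occasional missing-coordinate gaps, and optional
reorientation pauses. Cohorts fan one global seed into per-individual
substreams, so files reproduce byte-for-byte. They do not emulate
wall-following behaviour, caste-specific speed profiles, inter-individual
interaction (the simulator owns that), or the autocorrelated jitter of
real video tracking; passing tests therefore demonstrate the estimators'
correctness on data satisfying the models' assumptions, not robustness
to every artefact of real footage.

## Problem sizes and tolerances

Test and acceptance runs use the study-scale configurations: 5 trials ×
1500 steps for the simulator, n = 10⁴ for parameter recovery, 200
replicates of n = 1000 for model discrimination, ≥ 3000 extracted steps
per closure fit, 20 walkers per sweep point. The TPL grid-search oracle
(10⁴-point grid) agrees with the optimizer to 10⁻³. Stochastic
assertions use fixed seeds; closed-form assertions (CCDF values,
single-point likelihoods, OLS on three points) are exact to printed
precision.
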