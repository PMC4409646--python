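# Methods

## Model

### Units

Each of the ten populations is a leaky rate unit
`τ_j u̇_j = −u_j + b_j + Σ w_ji a_i` with activation `a = [tanh u]⁺`, so
activations live in `[0, 1)` and a unit is a mean-field abstraction of a
whole nucleus on the minutes timescale of tonic activity changes. A
negative intrinsic drive `b_j` acts as an activation threshold; this is how
CeA (b = −0.44) stays silent at rest and responds only to a sufficiently
strong prelimbic + stressor drive, and how the mesocortical VTA unit
(b = −0.05) sits just below its raphe input. Unit time constants are 4–5
min; they set the speed of loop ignition, not the slow phase structure.

### Neuromodulator pools

Extracellular NE/DA/5-HT levels follow
`τ l̇ = −th·tanh(l) + (1 − d)·w·a_source`. Below the reuptake capacity
`th` the level equilibrates at `artanh(w·a/th)`; above it the level grows
without bound with slope `(w·a − th)/τ` — both closed forms are asserted in
the test suite against the integrator. All pools in the reference fit
operate sub-threshold, so every condition reaches a well-defined plateau.
The depletion coefficient `d` relaxes exponentially (τ_d = 20 min) toward
its experimental target (0.9 for the depletion conditions) and scales
release only, never reuptake.

### Neuromodulation

Pool levels act on units multiplicatively,
`(b + Σ w a + stressor) · (1 + Σ μ_e l)/(1 + Σ μ_d l)`, and additively,
`+ Σ α_e l − Σ α_d l`. With all levels at zero this reduces exactly to the
plain leaky drive (a tested identity). The reference modulation table is:
NE multiplicatively excites PL (μ_e ≈ 13 — PL's stressor gain is small, so
almost all of its phase-1 activity is NE-amplified), NE multiplicatively
inhibits IL (μ_d ≈ 0.7), and cortical DA both multiplicatively (μ_e ≈ 5.6)
and additively (α_e ≈ 0.3) excites IL.

### Plasticity

One Hebbian rule lives on the inhibitory IL→PL connection. The printed
form of the rule is a per-tick increment with no step size; to keep the
integrator convergent under step halving the in-loop update is applied as
a per-minute rate, `ẇ = sign · η · [a_PL − th_PL]⁺ · [a_IL − th_IL]⁺`, with
the weight stored signed and the magnitude growing in the connection's
native (inhibitory) direction. `hebbian_step()` keeps the discrete form
(`dt = 1`) so the textbook arithmetic holds verbatim. The post-synaptic
threshold is high (0.3): learning runs only while PL is strongly active,
i.e. during an ignited active-coping phase. The pre-synaptic threshold is
low (0.03) so IL's standing, DA-fed activity is enough to gate it open.

### Why the phases and the critical value emerge

At stress onset the PL→CeA→LC→NE→PL loop self-ignites (NE availability is
the loop gain; this is why NE depletion prevents ignition), CeA shuts the
mesolimbic GABA gate and accumbal DA surges. The Hebbian weight then grows
at a roughly constant rate; PL's effective drive is
`(ext_PL + w·a_IL) · NE-factor`, so PL collapses once `|w|` approaches
`ext_PL / a_IL`. With the fitted stressor gain (≈ 0.16) and NE-suppressed
phase-1 IL activity (≈ 0.1), the collapse weight is below −1; with resting
IL activity (≈ 0.15, no NE surge) the *ignition* threshold for the initial
weight is near −1. That cancellation point is the model's critical value:
presets above it ignite and transition on the naive schedule, presets below
it never ignite, so the passive phase arrives as fast as the mesocortical
DA pool can lift IL (~40 min). After collapse, PL releases the raphe,
mesocortical DA rises to its sustained plateau, IL (DA-boosted) drives the
GABA gate above rest, and accumbal DA falls below baseline.

## Protocols and measurement

A session is 60 min of recorded baseline followed by 240 min of a constant
stressor drive (magnitude 1.0, an arbitrary unit the fitted weights
absorb) delivered to OFC/ACC, PL, IL, CeA and DR through fitted gains
(IL's gain is the smallest, so PL dominates the first appraisal). Before
recording, the circuit is settled for 240 unrecorded minutes so that
units, pools and any pre-established depletion start from steady state;
depletion schedules with onset 0 are active throughout the settling period,
matching a depletion performed surgically before the session. Shorter
pre-stress windows are accepted as long as they hold at least three
sampling intervals, which the %-of-baseline normalisation needs.

Microdialysis is emulated by reading each pool level at the end of every
20-min bin (end-of-bin sampling, not bin averaging: at these time
constants the difference is far below the 5-point baseline band) and
normalising to the mean of the three bins immediately before stress onset.
Phase metrics use a ±5 percentage-point baseline band; the below-baseline
onset is the first post-peak bin at or below 95%, and the
return-to-baseline time is the first post-peak bin back inside the band,
reported relative to the peak sample. All onset times are therefore
quantised to the 20-min sampling grid, exactly like the in vivo fractions.

## Numerical choices

Explicit Euler with dt = 0.1 min and a stability guard dt ≤ min(τ)/10.
A step-halving test on the full reference circuit bounds the
discretisation error below 0.5% (with a small absolute floor where
activations cross their rectification zero). Pool levels are clamped at
zero. Any potential exceeding |u| = 50 aborts the run with the offending
unit named — tanh saturates near 1, so such values indicate pathological
parameters, not biology. Integration is fully deterministic; the packed
inner loop is JIT-compiled with numba and falls back to the identical pure
NumPy path when numba is unavailable.

## Fitting

The in vivo curves behind the reference tuning are not machine-readable,
so the fit targets are canonical piecewise-linear curves that encode every
printed timing statement (NE peak 20–40 min post-onset and back to
baseline within 120 min of the peak; cortical DA modest early rise and a
larger sustained rise from 60–80 min; accumbal DA peak at 20–40 min and
below baseline from 80–100 min; the depletion conditions' qualitative
effects). Curve amplitudes are package defaults, not measurements, and the
qualitative constraint suite (`copingsim.fitting.default_constraints`) is
the authoritative acceptance surface; bins carrying a constraint get
double fitting weight.

The genetic algorithm uses tournament selection (size 3), uniform
crossover (rate 0.7), Gaussian mutation (rate 0.1, scale 10% of each
bound's width) and elitism (2), seeded and exactly reproducible. Candidates
that destabilise the integrator receive a penalty error instead of
crashing the run. Free parameters are magnitudes inside sign-constrained
boxes — anatomy fixes every sign, the fit only scales. The committed
reference fit (`data/reference_fit.json`, produced by
`scripts/fit_reference.py` with population 48 and 40 generations, seed
1234, starting from the hand-designed template and penalising constraint
violations at 2·10⁴ per failure) satisfies all twelve shape constraints,
including the long-experience and IL–VTA-lesion predictions, and roughly
halves the quadratic error of the template.

## Repeated stress

Daily sessions are chained by relaxing the learned IL→PL weight toward its
naive value by a recovery fraction ρ between sessions. The default is
ρ = 0.05: a naive session ends near −1.27, and with 5% nightly recovery the
weight stays in the long-experience regime (< −1) through a five-day
series, the condition under which the anticipated passive phase is
predicted. Larger ρ values model faster spontaneous forgetting and let the
circuit re-ignite after a few stress-free days.

## What the synthetic conditions do and do not show

The generator of target curves and the simulated conditions reproduce the
*timing structure* of the published group means — peak windows,
return-to-baseline and below-baseline onsets on a 20-min grid — not animal-
to-animal variability, absolute concentrations (the model works in percent
of baseline), probe recovery, or assay noise. Passing the suite shows the
circuit mechanism can generate these dynamics under the stated
perturbations; it does not validate amplitudes.

## Known limitations

* Percent-of-baseline readouts are only weakly sensitive to depletion at
  equilibrium (scaling release rescales the baseline too), so the
  depleted conditions' NE/DA *percent* traces still show residual rises;
  the functional effects of depletion act through the absolute levels that
  drive the modulation, which is where the model's predictions live.
* Under the IL–VTA disconnection the model reproduces the baseline
  second-phase accumbal DA but not a first-phase rise *larger* than sham:
  the lesion also removes IL's resting excitation of the GABA gate, which
  raises the lesioned baseline and compresses the percent peak.
* Below-baseline cortical NE (seen in vivo after repeated stress) is
  outside the architecture: nothing inhibits LC below its resting drive.
* The medium-experience preset (−1.0) sits marginally below the fitted
  critical value, so it anticipates the transition rather than exactly
  preserving naive timing; the discontinuity is located between −0.5 and
  −1.0.
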