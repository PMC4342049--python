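# Methods

`dbsmotor` turns per-second home-cage position recordings of a mouse under
deep brain stimulation (DBS) into inference about arousal: did stimulation
move the animal, how does the response scale with amperage and pulse
frequency, and how does it relate to the circadian (light/dark) structure of
movement.  The central modelling commitment throughout is **piecewise
stationarity**: each motor process is treated as strictly stationary within
a time segment (10-min stimulation intervals, 3-hr analysis segments), with
parameters free to change across segments.  This note records the models,
the defaults and why, the numerical choices, and the limitations we have
measured.

## Motor processes

From gridded positions r(t) = (x(t), y(t)), t = 1..N seconds:

* velocity V(t) = r(t+1) − r(t), speed M(t) = |V(t)|, direction angle
  θ(t) ∈ [−π, π) (π identified with −π; undefined at rest).  The path is
  exactly recoverable from (M, θ) and the starting point — verified to
  machine precision in the tests.
* Angles split into **P** (multiples of π/2 on the circle, within an
  angular tolerance of 1e-9 rad by default — exact for wall-parallel moves
  on an axis-aligned cage, configurable because real sensors jitter) and
  **NP** (everything else).  Rest seconds belong to neither class, and the
  windowed angle statistics are *fractions of moving seconds*.
* Each forward 30-s window of positions is classified 0-, 1- or
  2-dimensional.  ID=0: all points coincide (bounding-box diagonal ≤
  tol, default 1e-6 cm).  ID=1: every point within tol of the
  total-least-squares line; D1 is the *extent* of the projections onto
  that line (not the path length).  ID=2: otherwise; D2 is the convex hull
  area (Qhull; a degenerate zero-area hull re-classifies as 1-D — ties
  break toward the lower dimension).  Speed splits accordingly:
  M = M1D + M2D wherever ID ∈ {1, 2}.

The seven analysis processes, in order: M1D, D1, θ_P, θ_NP, M, M2D, D2.
The first three are one-dimensional statistics; the last four carry
two-dimensional information.  Two windowed statistics apply to each: a
forward mean over w1 = 600 s and a right-minus-left difference of
w2 = 120 s means (a high-pass filter for rapid onset).  Mean activity obeys
Ā = Ā1D + Ā2D identically.

Implementation note: window classification uses vectorized fast paths for
the two cases that dominate a cage recording (all-points-coincide and
exactly axis-aligned movement) and falls back to the exact per-window
classifier elsewhere; the two paths are cross-checked against each other
and against brute-force hull/length oracles in the tests.

## Stationarity diagnostics

Sample autocovariances are the biased (1/n) estimates.  The decorrelation
diagnostic finds the smallest lag at which the autocorrelation enters the
±1.96/√n band and stays for 5 consecutive lags — the band is pointwise, so
a literal "never leaves again" reading would fail even white noise.
Spectra are Thomson multitaper estimates (NW = 4, K = 7 by default; the
source gives no values) on demeaned segments.

The spectral equality (Diggle–Fisher) test compares variance-normalized
cumulative periodograms of several same-phase segments: the statistic is
the maximum over frequency of the largest pairwise difference, and the
null comes from shuffling the raw spectral ordinates across segments
independently at each frequency (add-one p-value).  Two implementation
facts matter:

* **Bandwidth decimation.** Multitaper ordinates are correlated within the
  taper bandwidth (±NW Fourier bins), and on the full grid the shuffle
  destroys that within-series smoothness, making the observed curve wavier
  than every shuffle — the test then rejects everything, including four
  segments of one AR(1) process.  The test therefore runs on every
  (2·NW+1)-th ordinate, where ordinates are effectively independent.
  Measured on AR(1) data: type-I error 3–5% at nominal 5%; power 100%
  separating φ = 0 from φ = 0.9 at n = 10,800.
* **Limitation on bursty data.** The shuffle null also needs ordinates
  independent across frequencies *within* a segment.  For a doubly
  stochastic, high-kurtosis burst process the fourth-order-cumulant term
  correlates ordinates across the whole grid at 1–3-hr segment lengths;
  measured on the simulator's speed process, the test rejects a truly
  stationary phase 25–40% of the time at nominal 5% (an iid shuffle of the
  same heavy-tailed marginal alone gives ~10%).  The diagnostic is
  therefore trustworthy for near-linear series and *anticonservative* for
  strongly bursty ones; the per-phase report should be read with that in
  mind.  We did not replace the test with a block-permutation variant,
  which would be a different procedure.

## Hypothesis I: the rotation (translation-restricted permutation) test

Each stimulation onset S_k is surrounded by a ±80-min window; windows of
distinct onsets are separated by ≥20 min, beyond the measured decorrelation
horizon, so their tests are treated as independent.  Under stationarity the
only permutations that respect the dependence structure are translations —
rotations when the window is wrapped into a circle.  The window statistic
(forward mean or RL difference of one of the seven processes; fractions use
circular numerator and denominator sums) is recomputed at all 9600
integer-second rotations; p = #{rotations with value ≥ observed}/9600, the
observed rotation included, so p ≥ 1/9600 and a constant window gives
p = 1.  The test is one-sided: the alternative is stimulation-*increased*
activity.  Calibration, measured: p-values over 1000 independent stationary
AR(1) windows are uniform (KS distance ~0.02–0.03).

Evidence aggregates by step-up FDR with threshold (j/m)(q/cv): cv = 1
(Benjamini–Hochberg) under independence, cv = Σ 1/i (Benjamini–Yekutieli)
for correlated statistics.  75-µA intervals are a baseline/placebo arm and
form their own family; the headline family combines the 100- and 125-µA
intervals.

## Hypothesis II: dose-response with long-run-variance standard errors

The mean of a motor process over one 10-min stimulation interval gets its
standard error from that interval alone (its steady state differs from the
surroundings): Var(mean) = lrv/n with the Bartlett-tapered long-run
variance lrv = γ̂(0) + 2 Σ_{h<m} (1−h/m) γ̂(h) and m = ⌊√n⌋ = 24 lags.  The
Bartlett weights make the estimate nonnegative by construction (it is the
value at frequency zero of a nonnegative spectral estimate); a defensive
floor at zero remains for degenerate inputs.  Measured convergence on
AR(1), φ = 0.5 (closed form 4σ²): mean relative error ~8% at n = 10³, ~3%
at 10⁴, <1% at 10⁵.

Confidence intervals use a *t* quantile at the effective block degrees of
freedom n/m − 1 (= 24 for a 600-s interval): the Bartlett SE is noisy and
slightly downward-biased in finite samples, and the normal quantile covers
~93.5% instead of 95%; the t correction restores ~94–95% (measured 94.1%
at φ = 0.5, 94.8% at φ = 0.2).  Coverage degrades with persistence at
fixed m — at stronger dependence than the burst scale the m = √n rule is
built for, intervals under-cover.

Interval estimates pool across animals and repeats by inverse-variance
weighting by default; an exactly quiescent interval has zero estimated
variance and (per the stated convention) dominates the pool as an exact
value, with a warning.  Because the simulator produces such intervals with
non-trivial probability at the inactive 75-µA baseline, the pipeline-level
analyses in this package's own acceptance runs use the unweighted pooling
flag (mean of means, variance Σvᵢ/k²), which stays well defined in that
regime.

Condition comparisons use the Dunnett C construction, valid under unequal
variances and sample sizes: pair (i, j) differs when |mᵢ − mⱼ| exceeds
q*·√((vᵢ+vⱼ)/2), with q* the studentized-range quantile (at the group
count and each group's effective df) averaged with weights vᵢ, vⱼ.  With
equal variances and df this reduces to the classical studentized-range
decision at the per-group df.  The amperage × frequency synergy screen is
a reconstruction (no canonical test is prescribed anywhere): each cell's
mean is contrasted against its additive prediction (row + column − grand
mean of the cell means), the contrast variance propagates the independent
cell variances through the contrast coefficients, and cells with |z| above
the two-sided normal α-quantile are flagged.  Its variance input inherits
any underestimation from the interval-level long-run variances (burst-count
noise at scales beyond m lags), so isolated spurious flags occur; the
screen is read as a flag for follow-up, not a calibrated test.

## Hypothesis III: light/dark contrasts

Each 12-h phase contributes three 3-hr segments (minutes 30–210, 270–450,
510–690), separated by 1 h, so ±30 min around every transition is excluded
by construction; stimulation intervals plus 20 min after each are masked.
A canonical 3-day recording yields 18 segments.  Per segment, the mean of
M1D or M2D gets a long-run variance (computed on the longest unmasked run
when a mask splits a segment — rare by design); segment means average
within phase, Y = dark − light, and z = Y/√Var(Y) is referred to a
Gaussian null (CLT for stationary mixing means), two-sided by default.
The 2-D movement fraction per (light/dark × stim/non-stim) condition is
the share of *moving* seconds (ID ≠ 0) with ID = 2; an all-seconds
denominator is available by flag.  Whether such fractions should be
time-based or activity-weighted is genuinely open; time-based is the
default because it matches the per-second labelling.

## The synthetic cage model

No animal data are available, so the simulator generates trajectories with
the statistical structure the analysis assumes, plus ground-truth labels.
It is a two-state semi-Markov process on the 1-s grid: quiescence ends
with a burst onset (per-second geometric hazard); bursts are wall runs
(1-D: axis-aligned, gamma step sizes, reflecting walls) or interior
excursions (2-D: correlated random walk, heading diffusion 0.5 rad/s,
gamma steps scaled 1.5× the 1-D scale); durations are lognormal (medians
8 s / 12 s, σ = 0.6; exponential selectable); positions are reported only
on change, as the monitor does.  Three structural choices came out of
validating the analysis chain against the generator:

* **Refractory dead time (35 s > the 30-s classification window).**  Bouts
  are separated by at least one window length, so no window ever contains
  two bursts and the window dimension labels are exact.  Without it, a
  phase-dependent share of wall-running windows mixes with interior bursts
  and re-classifies as 2-D, structurally breaking the light/dark 1-D null.
* **Burst-end deceleration (final steps scaled 0.6/0.3/0.05).**  The last
  second of any bout has a two-point forward window — collinear, hence
  1-D by the tie rule — so without deceleration every 2-D bout leaks one
  full-speed second into M1D, and dark (with ~4× more 2-D bouts) acquires
  a spurious positive 1-D contrast (null z biased ≈ +2).  Bouts that slow
  to a stop remove the leak physically.
* **Phase-symmetric wall-running.**  The defaults are derived so the
  realized (dead-time-adjusted) 1-D bout frequency is 0.0075/s in both
  phases, while 2-D bouts arrive 4× as often in dark (0.006/s vs
  0.0015/s) — the circadian asymmetry lives entirely in interior
  movement, which is the condition the light/dark tests are meant to
  detect.  The renewal-cycle expectation for each occupancy is exposed as
  `SimulationConfig.expected_occupancy` and verified against simulation.

Stimulation multiplies the 2-D burst-onset rate by 1 + {0, 5, 8} for
{75, 100, 125} µA (frequency-independent; 75 µA is an inactive baseline)
and the 2-D step size by 1 + amp + freq + synergy on active cells
(amp ∈ {0.3, 0.6}, freq 0 at 50 Hz and 0.25 above, synergy 2.0 at the
125 µA × 125 Hz cell).  The speed grid is *additive* because mean activity
responds linearly to step size, which makes the injected synergy exactly
the quantity the additive-prediction screen estimates; onset-rate effects
saturate (burst occupancy is concave in the rate), so carrying the dose grading
through rate multipliers alone makes the response concave and synergy
unrecoverable on the additive scale.  The synergy injection is sized to
several contrast SEs at a four-animal cohort: the suite verifies
*recoverability* of an unambiguous injection, not detection power at the
margin.  An `effect_scale` knob scales all injected effects jointly
(0 reproduces the null configuration).

What the generator does not emulate: sub-second event timing (events are
grid-aligned, so zero-order-hold regridding is exact), sensor position
jitter (wall-parallel angles are exact multiples of π/2), drift or
habituation across days, within-bout speed rhythms, and micro-movements
during quiescence.  Consequently the angle-class fractions are cleaner
than in real data, zero-activity 10-min windows occur with nonzero
probability (real monitors see occasional small movements), and passing
the suites here demonstrates correctness of the statistical machinery
under the stated assumptions — not robustness to sensor artefacts.

Two measured consequences worth knowing: the NP-angle fraction statistic
has a granular p-value floor under purely bursty movement (entire windows
can be all-2-D, tying at fraction 1 under the conservative ≥ rule), so its
FDR rejection count varies widely across seeds even at strong effects; and
the RL (high-pass) statistics rarely reject because a rate-mediated
response ramps over minutes rather than jumping within the 2-min side
windows.

## Problem sizes used in the shipped suites

Tests and the acceptance script regenerate everything: cohorts of 4
stimulated + 2 control animals at the canonical 3-day design; 1000-window
rotation-test calibration at the full 9600-s window; Diggle–Fisher
calibration with 500 type-I replicates (1-hr segments, 200 shuffles) and
40 power replicates (3-hr segments, 999 shuffles); 4000 coverage
replicates; 1000 random windows against the brute-force geometry oracles.
These sizes put Monte-Carlo noise well inside the asserted tolerances
while keeping a full run in the low minutes on one CPU.
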