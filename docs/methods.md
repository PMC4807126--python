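# Methods

`ikstools` analyzes three kinds of recordings from KCNE1:KCNQ1 (I_Ks)
channel complexes — single-channel patches, whole-cell isochronal
activation families, and UV-crosslinking peak-current diaries — and ships
a synthetic generator that emulates all three, parameterized per construct
(EQ, EQQ, EQQQQ fusions forcing 4:4, 2:4, 1:4 KCNE1:KCNQ1 stoichiometry;
KCNQ1 alone; co-expressions with free KCNE1).  This note records the
models, the parameter choices, and the numerical decisions.

## Single-channel model and analysis

**Subconductance ladder.**  Open current levels at +60 mV are
0.08, 0.13, 0.19, 0.29, 0.44, 0.66 pA (plus closed = 0), spaced ~3/2
between neighbours.  Amplitudes at another voltage V scale ohmically by
(V − E_rev)/(60 − E_rev), with E_rev the Nernst K⁺ reversal for the
single-channel solutions (5/135 mM K⁺ at 22 °C, ≈ −84 mV; configurable).

**Gating generator.**  No mechanistic Markov scheme is implied by the
quantities the analysis targets, so the generator is the simplest renewal
process with a prescribed stationary open-time distribution: after a
shifted-exponential first latency (deterministic offset 0.3 s), sojourn
levels are drawn i.i.d. with visit probability ∝ occupancy_k / mean_dwell_k
and exponential sojourn durations, so the *expected* fraction of open time
at each sublevel equals the configured occupancy exactly, for any dwell
means.  Adjacent same-level sojourns are merged in the emitted event log,
which keeps the event-alternation invariant.  (A jump chain that excludes
the current level re-weights the stationary distribution by 1 − w and
cannot hit prescribed occupancies with unequal dwell means; the i.i.d.
construction can, which is why it was chosen.)  Interburst closures are
folded in as a closed "level" whose time share is
τ_c·r/(1 + τ_c·r) with r = `burst_end_rate` (default 2 s⁻¹, mean open run
0.5 s) and τ_c the closed dwell (15 ms) — the burst structure is not
quantified in the source record, so these are stated choices.  Blank
sweeps occur with probability `p_blank` (0.3) or when the latency outlasts
the 4-s test step.  Gaussian noise (σ = 0.04 pA, ~10× below the top
sublevel) is added before a causal 4-pole Bessel low-pass at 200 Hz,
mirroring the published filtering of the single-channel records.

**First-latency calibration.**  Published per-construct latencies
(1.50, 1.48, 0.94, 0.81, 1.43, 1.44 s) are conditional means over sweeps
that opened within the 4-s step — the estimator is right-censored.  The
generator's raw shifted-exponential mean is therefore solved at table
build (brentq on the truncated-exponential mean formula) so that the
*conditional* mean equals the published value; for short latencies the
correction is negligible, for EQ it is ~0.4 s.

**Occupancy tables.**  EQ spends 36% of its open time at 0.44 pA and
splits the rest evenly (12.8% per level).  EQQ's two published anchors —
dominant all-points histogram peak near 0.18 pA and 34% of open time at
0.29 pA — come from different recordings and cannot both be maxima of a
single stationary distribution (histogram mass *is* open-time share), so
the packaged EQQ occupancy places 40% at 0.19 pA and 34% at 0.29 pA with
0.6% at 0.44 pA: each anchor is then reproduced by its own measurement.
EQQQQ's conductance is not quantifiable in the source record; its fixture
shifts the EQQ profile one level down with brief (10 ms) sojourns and is
flagged non-quantitative.  Co-expression constructs reuse the EQ profile
(their published conductances, 2.9–3.0 pS, match EQ's).

**Idealization.**  Each test-step sample is classified to the nearest
ladder amplitude (boundaries at midpoints of adjacent levels; whether the
published six "thresholds" were crossing thresholds or level centres is
not stated — nearest-level is this package's convention).  Runs shorter
than `min_dwell_s` (default 1/(2·filter cutoff) = 2.5 ms at 200 Hz, the
filter rise time) are merged into the flanking level with closer
amplitude, shortest-first, leftmost on ties.  Discretization and merging
live in one shared module, so idealizing noiseless, unfiltered simulator
output reproduces the generator's own event log *exactly* — the oracle
check run by the test suite.  Dwell summaries report per-level totals,
means, counts and percent of open time; the closed-state mean excludes
each sweep's first-latency interval.

**Histogram peaks.**  All-points histograms (0.01 pA bins) over the test
step of active sweeps are fit with a Gaussian mixture by EM on the binned
data, one component per ladder level, means initialized at the
(voltage-scaled) ladder, common initial width, SD floored at half a bin —
a fully deterministic fit.  The dominant open peak is the non-closed
component with the largest weight.

**Slope conductance.**  A least-squares line through dominant-peak
amplitudes at +20…+80 mV, constrained through (E_rev, 0); γ in pS is the
slope ×1000.  With one point this is the chord conductance.

## Whole-cell G-V analysis

Isochronal families (4-s steps, −80…+100 mV, tail at −40 mV) are reduced
to tail amplitudes: signed peak in the first 50 ms after tail onset,
holding-baseline subtracted, max-normalized.  Each cell is fit with a
Boltzmann sigmoid g(V) = A / (1 + exp((V1/2 − V)/k)), k > 0, initialized
at the interpolated half-maximum crossing.  The amplitude A is a nuisance
scale fitted by default: max-normalized data saturate slightly below the
true asymptote (B(+100 mV) < 1), and the fixed-amplitude form would bias
the midpoint by ~0.1 mV at V1/2 = +30 mV; with A free the recovery is
exact.  Cells are fit individually and averaged per construct (mean ± SE),
never pooled.  Packaged midpoints: −15.5 mV (KCNQ1), 26.1 (wild-type
I_Ks), 28.2 (KCNQ1 + F57Bpa KCNE1), +30 (EQ); the slope factor is not
published per construct and is fixed at k = 12 mV (unanchored), as are
the EQQ/EQQQQ-alone placeholder midpoints (interpolated, flagged
`UNANCHORED`, excluded from recovery benchmarks).  The macroscopic
generator uses a single voltage-independent activation time constant
(0.7 s), which keeps the isochronal correction factor constant across
voltages.

## UV-crosslinking kinetics

Diaries track per-sweep peak current (max |I| during the activation step)
normalized to the mean of 5 pre-UV baseline sweeps, against cumulative UV
exposure (0.3 s per flashed sweep; flash time only, not wall time).
Exclusion rules on pre-UV sweeps: peak > 20 nA, peak < 2 nA, or
peak/instantaneous-step-onset current < 5 (the published rule does not
define its quantities precisely; this reading is configurable).

Wild-type rundown is fit with y(t) = p + (1 − p)·e^(−K_RD·t); crosslinking
diaries with y(t) = p + (1 − p)·[f·e^(−K_XL·t) + (1 − f)·e^(−K_RD·t)],
with K_RD held at the matching construct's rundown constant, f ∈ [0,1],
p ∈ [0,1), y(0) = 1 by normalization.  Rate initializers come from a
log-linear regression of the early decay, so fits are deterministic.
Packaged rates: K_RD = 0.1864, 0.1588, 0.1049, 0.1259 s⁻¹ (KCNQ1, EQQQQ,
EQQ, EQ + KCNE1); K_XL = 1.12, 0.63, 0.55 s⁻¹ (KCNQ1, EQQQQ, EQQ
+ F57Bpa), with EQ carrying a nominal 0.09 s⁻¹ at 10% fast amplitude
(its decay is dominated by rundown).  Fast fraction (0.85) and plateaus
(0 for crosslinking, 0.05 for rundown) are not published; stated choices.

**Identifiability guards.**  When the fast amplitude is near zero the
(K_XL, f) directions are unidentifiable and plain least squares can
return arbitrarily large rates fitting a single noisy early point.  Three
guards keep the estimate physical: (i) K_XL is bounded at the
exposure-sampling resolution limit −ln(0.01)/flash_s (a phase complete
within one flash carries no rate information); (ii) an extra-sum-of-squares
F-test (α = 0.01) against the pure-rundown restricted model; and (iii) an
amplitude floor — the fitted fast fraction must exceed 3× the baseline
noise SD estimated from the cell's own pre-UV sweeps.  If (ii) or (iii)
fails the fit reports K_XL = 0 with a `no_fast_phase` flag rather than an
arbitrary number.  Both guards are inert on noiseless data, so exact
recoveries are unaffected.  A fitted K_XL ≤ K_RD is flagged
`phases_unresolved`.

Simulated cell groups use 5% per-sweep multiplicative peak noise
(`GROUP_NOISE_CV`), the scatter of a stable whole-cell recording.

## What the generator does and does not emulate

It reproduces the statistical structure the analysis relies on: sublevel
occupancies and amplitudes, blank sweeps, stochastic latency, bursting,
filtered Gaussian noise, Boltzmann-shaped activation with tails, and one-
/two-phase UV decays.  It does **not** model mechanistic gating (voltage-
sensor states), capacitance/leak transients, seal drift, temperature, a
noise floor in the diaries, or photochemistry beyond the two-exponential
phenomenology.  Passing recovery tests therefore demonstrates that the
*estimators* are unbiased and correctly implemented under the assumed
data model — not that the model captures every feature of real patches.

## Numerical conventions and degenerate inputs

Sample i covers [i/fs, (i+1)/fs); protocol durations must sit on the
sample grid.  Sweep files are UTF-8 text (header + one CSV row per sweep,
9 significant digits); currents are pA (single-channel) or nA
(whole-cell) with no implicit conversion.  Optimizers are scipy
`least_squares` (trust-region reflective, tolerances 1e-14) with
deterministic initialization throughout; all randomness flows from a
single integer seed per simulation via `numpy` SeedSequence.  Degenerate
inputs fail loudly: empty sweep sets, non-ascending ladders, all-blank
records ("no open time"), flat diaries (`non_decaying` flag), points all
at the reversal potential.

## Problem sizes

The default test suite and the acceptance script use 100-sweep
single-channel sets (the size of the published per-cell files), 40–440
sweeps for latency ensembles, 19-point G-V families, 30-sweep diaries and
5–7-cell groups; the end-to-end benchmark scales sweep and cell counts
with its `--scale` flag (1.0 reproduces per-cell sizes throughout).
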