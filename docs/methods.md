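# Methods

## The estimation problem

Single ion channels of the CFTR type gate between a long-lived closed
("interburst") state and an open-channel "burst" that is interrupted by
brief "flickery" closures.  In a hydrolysis-deficient background the
gating reduces to a closed–open equilibrium, so the opening rate
k<sub>CO</sub> = 1/τ<sub>ib</sub>, the closing rate
k<sub>OC</sub> = 1/τ<sub>b</sub> and the equilibrium constant
K<sub>eq</sub> = k<sub>CO</sub>/k<sub>OC</sub> can all be read off the mean
interburst and burst durations of a single-channel record.  For a series of
point substitutions at one position, the slope Φ of the Brønsted plot —
ln k<sub>CO</sub> against ln K<sub>eq</sub> — measures how far that position
has progressed along the opening reaction coordinate in the transition
state (Φ = 1: moves early, perturbations affect only opening; Φ = 0: moves
late, perturbations affect only closing).  `phigate` implements the whole
chain from raw (or simulated) current traces to Φ with uncertainty, with a
synthetic-data generator whose ground truth makes every stage verifiable by
parameter recovery.

## Gating model

A three-state continuous-time Markov chain

```
C  <--k_CO/k_OC-->  O  <--k_OF/k_FO-->  C_f
```

with C the interburst closed state, O the open state, and C_f a single
within-burst flicker class — the minimal scheme producing burst/flicker
phenomenology on top of a two-state equilibrium.  Closed forms used as
oracles throughout:

- τ<sub>ib</sub> = 1/k<sub>CO</sub>
- τ<sub>b</sub> = (1 + k<sub>OF</sub>/k<sub>FO</sub>)/k<sub>OC</sub>
  (mean sojourn in {O, C_f})
- P<sub>o</sub> = 1/(1 + k<sub>OC</sub>/k<sub>CO</sub> + k<sub>OF</sub>/k<sub>FO</sub>)
  (stationary occupancy of O)

ATP dependence is a single-site hyperbola applied to k<sub>CO</sub> only,
`k_CO(c) = k_CO_max * c/(c + K_m)` — the simplest saturable form, since the
analysis only needs to *verify* saturation, not model binding.

A perturbation series with designed ground truth Φ shifts each construct's
rates on the log scale, ln k<sub>CO</sub> += Φδ and
ln k<sub>OC</sub> −= (1−Φ)δ, so ln K<sub>eq</sub> shifts by exactly δ and
the Brønsted slope over exact rates is exactly Φ (recovered to ≥10
significant digits by the regression on noise-free readouts).

## Synthetic recordings

Trajectories are simulated event-by-event (exponential dwells, successors
by rate ratios, stationary initial state, final dwell truncated).  Default
rates k<sub>CO</sub> = 1, k<sub>OC</sub> = 2, k<sub>OF</sub> = 10,
k<sub>FO</sub> = 100 s⁻¹ give ~1 s interbursts, 0.55 s bursts and ~10 ms
flickers — the recording regime the analysis is built for; they are
simulator defaults, not measurements.  Rendering integrates channel
occupancy over each sample bin (sub-sample dwells contribute
time-weighted), multiplies by a unitary amplitude of −0.8 pA (inward
current at negative potential; placeholder magnitude), adds Gaussian white
noise, and applies the analysis filter (below).  Noise is specified as the
*post-filter* SD (default 0.15 pA, the experimenter-visible number); the
injected white SD is inflated by the filter's closed-form variance
reduction, `mean|H(f)|² = sqrt(pi/ln2)·(fc/fs)·erf(sqrt(ln2)·fs/2fc)`.
Defaults fs = 1 kHz, fc = 50 Hz.

A generated series writes, per construct, a main single-channel segment at
saturating ATP, optionally a paired 3 mM ATP segment and a stimulated
multi-channel "counting" segment, plus a YAML manifest holding the full
ground truth.  Per-construct seeds are spawned deterministically from one
master seed.

Not emulated: open-channel excess noise, baseline drift (an optional flag
is reserved), capacitive/solution-exchange transients, modal gating.
Passing recovery tests therefore shows correctness of the estimator chain
under ideal stationarity, not robustness to instrumental artifacts.

## Filtering and idealization

The low-pass filter has Gaussian magnitude response
|H(f)| = exp(−(ln2/2)(f/fc)²), i.e. fc is the −3 dB point, DC gain 1,
applied zero-phase in the frequency domain on reflection-padded data (phase
shifts would bias threshold-crossing times).  Its 10–90% step rise time is
2·Φ⁻¹(0.9)·√(ln2)/(2π fc) = 0.3397/fc, verified numerically.

Levels are estimated from the all-points amplitude histogram by EM on a
constrained mixture: equally spaced Gaussian peaks (free weights, common
SD) plus a uniform background that absorbs filter-transition samples.
Candidate starts come from smoothed-histogram peaks; the best likelihood
with the expected amplitude sign wins.  For high-P<sub>o</sub> counting
segments the closed level is essentially unvisited, so the baseline can be
pinned to a calibration estimate from the low-P<sub>o</sub> main segment of
the same patch (`fixed_baseline`).

Idealization assigns each sample its nearest conductance class (equivalent
to half-amplitude thresholds midway between classes) and places event
boundaries at the linear interpolation of the crossing between bracketing
samples, so durations sum exactly to the record length.  A dead time is
then imposed retrospectively: events shorter than T_d are deleted shortest
first; same-class flanking events are concatenated (different-class flanks,
possible only with >2 classes, split the deleted time equally); the
procedure is idempotent and conserves total time.

**Dead time choice.**  The filter-resolution bound 0.179/fc (3.58 ms at
50 Hz) is the floor, but at the default SNR it is not sufficient: Gaussian
noise of SD σ crosses the half-amplitude threshold (z = |A|/2σ ≈ 2.7) at
the Rice rate ν = fc/√(2 ln2) · exp(−z²/2) ≈ 1.2 s⁻¹, and a measurable
fraction of those excursions outlast 3.58 ms (~0.4 surviving false events
per second, enough to shred 1-s interbursts).  The default dead time is
therefore noise-aware: raised above the floor until the predicted surviving
false-event rate (Rice rate × a Rayleigh model of excursion durations)
drops below 0.02 Hz — about 7–8 ms at default SNR, with a measured surviving
rate of ~0.007 s⁻¹.  Any fixed dead time can be passed explicitly.  Note
the crossing-time jitter σ_t = σ·t_rise/|A| (~1.3 ms at defaults) bounds
achievable duration accuracy for any threshold idealizer.

Multi-channel stretches are handled by restricting analysis to maximal
runs with ≤1 channel open; run edges abutting superimposed openings are
duration-censored and flagged, and censored edge events are excluded from
dwell samples and burst delimitation.

## Burst reconstruction

Closed dwell durations (censored edges excluded) are fitted with a
left-truncated two-exponential mixture by EM (truncation at the dead time
is handled exactly by shifting — the truncated exponential MLE is
`mean − t_min`); a deterministic quantile multi-start grid makes the fit
reproducible, and a likelihood-ratio test (χ², 2 df, α = 0.05) can admit a
third component with a warning that the two-step description is then
questionable.  The critical time solves equal component densities,

t_c = τ_f τ_s/(τ_s − τ_f) · ln(a_f τ_s / (a_s τ_f)),

which minimizes the expected number of misclassified closures
N(t) = a_f e^(−t/τ_f) + a_s (1 − e^(−t/τ_s)).  t_c is fitted per construct
by default (each mutant's flicker/interburst separation differs); a global
override exists.  Closures ≥ t_c delimit bursts; shorter closures are
flickers whose time counts inside the burst (burst = first opening to end
of last opening, consistent with k<sub>OC</sub> = 1/τ<sub>b</sub> for the
burst-exit step).  Bursts/interbursts abutting segment edges are censored
and discarded.  Summaries report mean ± SEM (SD/√n), k<sub>CO</sub>,
k<sub>OC</sub>, K<sub>eq</sub>, and P<sub>o</sub> both time-based (open
time/total time) and burst-based (Στ_b/(Στ_b+Στ_ib)), since the two
definitions differ by the intra-burst flicker load.

**Known bias.**  The interburst sample is by construction left-truncated at
t_crit, so its uncorrected mean overestimates the slow time constant by
≈ t_crit (+5% at τ_ib = 1 s, +30% at τ_ib = 0.135 s), and misclassified
short interbursts merge bursts, inflating τ_b.  No correction is applied —
rates are deliberately defined as inverses of the raw means, matching
standard practice — which compresses recovered Brønsted slopes by
0.02–0.07 across a ±2 ln-unit series at the default flicker load.  The
recovery tests bound this (Φ̂ within ±0.10 of truth); the ±2·se interval of
the OLS slope does *not* reliably cover the truth under these conditions,
because the bias exceeds the nominal slope SE.  This is a property of the
uncorrected critical-time method itself (it persists when the burst stage
is run on perfect, noise-free event lists) and is the main caveat when
comparing small Φ differences between positions.

**Channel counting.**  The count is the maximum simultaneous level, taken
on a heavily refiltered segment (default 10 Hz): near the top level the
thresholds sit only ~2 noise SD above the (slightly attenuated) plateau at
analysis bandwidth, and sustained noise excursions otherwise fake an extra
level.  The analytic risk of undercounting is reported as exp(−rate·T)
with rate = π_{N−1}·k_CO from binomial occupancy.

**ATP saturation.**  The 3 mM/10 mM mean-current ratio (baseline
subtracted; the closed-peak mode with parabolic refinement is the default
baseline) is flagged saturating at ≥0.9.  A near-zero 10 mM current
(<0.05 pA, about the precision of the histogram-mode baseline at default
noise) is an error rather than a ratio.

## Brønsted regression

x = ln K<sub>eq</sub>, y = ln k<sub>CO</sub>, with delta-method standard
errors (se<sub>ln k</sub> = SEM(τ)/τ; x combines both dwell SEMs in
quadrature).  Φ is the unweighted OLS slope with
se = √(SSR/(n−2)/Σ(x−x̄)²) — the convention a generic linear-regression
tool reports; weighted least squares (1/se_y²) is available behind a flag
for sensitivity analysis, as is a per-construct bootstrap.  The background
construct enters the fit as an ordinary point.  Caveat: x and y share the
k<sub>CO</sub> estimate, so their errors are correlated; plain regression
is used deliberately, and the propagated point SEs are reported alongside
rather than folded into the fit.

## Pipeline

Stages `simulate → idealize → burst → refer` run one-shot or stage-wise
over on-disk artifacts (all text: trace files in a two-column text dialect
or float32-binary with key-value sidecar, event lists and summaries as
TSV with `#` metadata headers, manifest/config as YAML).  All randomness
flows from one master seed; reruns with the same configuration are
byte-identical.  CLI exit codes: 0 ok, 2 configuration error, 3 data
error.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use 20-minute single-channel
segments per construct for Φ recovery (≈1,000–2,000 gating events each,
comparable to the long recordings the method is designed for), a 30-minute
segment (~1,100 bursts) for rate recovery, and 50-channel, 240-s
quasi-macroscopic pairs for the saturation check; these sizes keep every
recovered quantity's sampling error well inside its asserted tolerance.

## Limitations

- No missed-event (dead-time) correction of τ estimates, and no
  truncation correction of interburst means (see bias note above).
- One flicker class only; unequal sub-conductance levels are out of scope.
- Gating must be stationary: modal shifts and baseline drift are neither
  simulated by default nor corrected.
- Φ interpretation as relative timing presumes an equilibrium two-state
  opening step; the package does not check hydrolysis-independence itself
  (the saturation check covers the ATP axis only).
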