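# Methods

## Paradigm and measures

Each trial presents 2 s of amplitude-modulated white noise (8 Hz, 100%
depth), then — after a silent delay — a 50 ms (experiment 1) or 25 ms
(experiment 2) multitone target whose onset falls at phase
x ∈ {0, 0.5π, π, 1.5π, 2π} of the AM cycle *had the envelope continued*.
The listener later reproduces the target's fundamental on a 220–880 Hz
logarithmic response pad.  A block holds 15 trials (3 per phase condition,
randomly ordered); experiment 1 runs 10 blocks and experiment 2 runs 14,
with block 1 discarded as practice, leaving 27 and 39 analyzed trials per
phase condition per subject.  Target fundamentals are drawn uniformly with
replacement from 211 log-spaced values in 270–715 Hz (no balancing across
phase conditions; the design leaves this open and uniform assignment is
the simplest choice).

All pitch arithmetic is done in semitones relative to 440 Hz, the
geometric center of the response range: u = 12·log₂(f/440).  The matching
regression is fit in this log space rather than in Hz because the accuracy
measure is defined in semitones and the response pad itself moves in
logarithmic increments; a Hz-space regression would make the residual SD
heteroscedastic across the range for a listener with constant relative
error.

Per subject × phase cell (≥ 3 trials required, error otherwise):

- OLS of matched position v on target position u.
- Accuracy error: mean of |prediction − identity| at u = ±12 st
  (the 220/880 Hz extremes).  Evaluating at the extremes rather than
  averaging over trials makes the statistic a pure function of the fitted
  line: a slope-s line through the 440 Hz pivot scores 12·|1 − s|.
- Precision: residual SD with denominator n − 2 (regression residual
  degrees of freedom; pinned by test).  It is an inverse-precision
  quantity — the conventional name is kept.

Group profiles carry within-subject standard errors: each subject's
cross-phase mean is removed (grand mean restored) before the per-phase SEM
across subjects, so purely additive between-subject differences contribute
nothing.  No small-sample (Morey-type) correction is applied; with 5
conditions it would inflate the SEMs by √(5/4) uniformly and a flag can be
added if wanted.

## Constrained cosine fit

The five condition means are fit with y = a·cos(x + c) + b under a ≤ 0.
Phases 0 and 2π enter as distinct x values; the cosine treats them
identically by periodicity, which is the intended physics.  With Gaussian
homoscedastic errors, maximum likelihood is least squares, and at fixed c
the problem is linear: the unconstrained amplitude is the simple-regression
coefficient of y on cos(x + c), and a positive estimate is clamped to the
boundary a = 0 with b = mean(y) (giving R² = 0).  R² = 1 − SSE/SST, defined
as 0 for a constant profile.

The free-phase variant solves the fixed-c problem on a uniform c grid
(default step 0.005 rad over [0, 2π), ties to the smallest c) and then
polishes c once by parabolic interpolation through the argmin's periodic
neighbors, re-solving the inner problem at the interpolated c.  This keeps
the procedure fully deterministic — no iterative optimizer, no
initialization sensitivity — while recovering exact profiles to machine
precision rather than to the grid step.  Because a ≤ 0 with free c spans
all cosine phases, the free fit always attains the unconstrained cosine
fit's R².  Both fits are verified in the test suite against brute-force
grid searches that evaluate the SSE directly over (a, b) and (a, b, c).

## Permutation null

Phase labels are shuffled across all non-practice trials within each
subject — preserving each subject's label multiset, so no subject × phase
cell can be emptied — and the entire chain (per-cell regressions, group
means, constrained fit) is recomputed; 500 iterations by default.  The
p value counts null R² values strictly exceeding the observed one; the
(k+1)/(n+1) variant is reported alongside because the strict count can be
exactly 0.  Whether the original study shuffled within subject or within
block is not documented; within-subject is implemented as the default and
a within-block option (`scope="block"`) is available.  The engine
vectorizes all cell regressions per shuffle with bincount sums, so a
500-iteration test on a 26-subject dataset takes well under a second.

## Circular statistics

Individual free-phase offsets are unit vectors on the circle.  Mean
resultant length R̄ and direction come from the complex sum; the Rayleigh
statistic is Z = n·R̄² with the classical small-sample approximation
p = exp(√(1 + 4n + 4(n² − R²)) − (1 + 2n)), R = n·R̄ — the form used by the
standard circular-statistics toolboxes (Zar; Berens), cross-checked in the
tests against pingouin.  The 95% CI for the mean direction uses the
dispersion-based half-width d = arccos(t/R) with the two resultant-length
branches (t² = 2n(2R² − nχ²)/(4n − χ²) for R̄ < 0.9, t² = n² − (n² − R²)·
exp(χ²/n) for R̄ ≥ 0.9, χ² the 0.95 quantile at 1 df).  Samples too diffuse
for either branch get an explicit "CI undefined" flag rather than a
guessed interval.  A bootstrap CI would be the natural alternative; the
dispersion formula was chosen because it is deterministic and its coverage
is verified by simulation (0.93–0.97 at von Mises κ = 20, n = 26).

## Synthetic listeners

The generative model modulates *slope compression*: with u the target
position and pivot p (default 0 ≡ 440 Hz),

    v = p + s(x)·(u − p) + β + ε
    s(x) = 1 − γ₀ + γ₁·cos(x + c_subj)
    ε ~ N(0, σ(x)²),   σ(x) = σ₀·(1 − ρ·cos(x + c_subj))

with 0 ≤ γ₁ ≤ γ₀ so the effective compression is nonnegative at every
phase.  This mechanism was picked over bias- or noise-driven alternatives
because the induced accuracy statistic is *exactly* the fitted cosine
form — expectation 12(γ₀ − γ₁·cos(x + c_subj)) semitones, i.e. a = −12γ₁,
b = 12γ₀, c = c_subj — so recovery tests have a closed-form ground truth.
ρ > 0 adds a cyclic precision effect if wanted (default 0, mirroring the
absence of a reliable precision effect).

Responses are clamped (censored) at the pad's 220/880 Hz limits, as the
physical pad cannot exceed its range; under the default population
parameters fewer than 1% of trials hit the clamp (asserted in tests), so
recovery is effectively unbiased.

Population defaults (the simulator's standard study conditions): γ₀ =
0.30 ± 0.05, γ₁ = 0.15 ± 0.05 (truncated to [0, γ₀]), σ₀ = 1.0 ± 0.2 st,
β = 0 ± 0.3 st, c_subj ~ von Mises(0, κ = 20) (circular SD ≈ 0.22 rad),
26 subjects.  γ₀ and γ₁ give a 1.8–5.4 st accuracy range across phases —
the order of magnitude a moderately difficult pitch-matching task
produces — and σ₀ = 1 st is a typical trial-to-trial matching jitter.
The von Mises concentration makes individual optimal phases cluster near
the AM peak while leaving realistic between-listener scatter.

What the simulator does *not* emulate: adjustment trajectories within the
matching window (only the locked-in match is modeled), perceptual fusion
or forward-masking effects of the entraining noise, learning across
blocks, lapses, and any retention-interval dependence (retention duration
is carried as metadata only).  Passing recovery tests therefore show the
*analysis chain* is correct and calibrated, not that real listeners follow
the generative model.

## Stimuli

Multitone targets sum sinusoids at f₀ × {1, 2, 4, 6, 8, 10} — the even
harmonics plus the fundamental, the reading adopted for the complex's
component labels — each successive component 3 dB below the previous
(amplitude ratio 10^(−3/20)), with 5 ms raised-cosine ramps, peak-normalized
to 0.9 digital full scale.  Absolute level calibration (dB HL) is out of
scope; the −8 dB noise-re-target offset is implemented as a peak-amplitude
ratio (the design describes it relative to maximum intensity), with the
enveloped noise peak-normalized before scaling so the ratio is exact.

The AM envelope convention is the one genuinely open choice: the cosine
envelope is taken to start and end at its minimum, e(t) = 1 − d·(1 +
cos(2πft))/2, giving 16 whole cycles in 2 s, no offset transient, and a
well-defined continued-envelope peak 62.5 ms after noise offset.  The
inverse-sawtooth envelope (e(t) = 1 − d·frac(ft)) peaks at each cycle
start, so the first continued peak strictly after offset is one full
period (125 ms) later.  Under either convention the five phase conditions
map to onsets spaced 31.25 ms apart spanning exactly one 125 ms period;
alternative envelope phase conventions would shift all onsets rigidly and
are configurable through the waveform field.

WAV output is 16-bit PCM mono (universal readability); a JSON sidecar
records AM offset time, target onset time, phase and f₀.

## Seeds and reproducibility

Every stochastic stage takes a seed or Generator.  `simulate_experiment`
spawns independent child streams per subject (parameters, schedule,
responses) from one root seed; `run_analysis` derives per-measure
permutation seeds from the run seed.  Identical seeds yield byte-identical
trial tables and reports.

## Problem sizes

The verification suites use the study-scale conditions throughout: 26
subjects per dataset, 500-iteration permutation tests for inference, 20
replicates for recovery, 200 null datasets × 200 iterations for type-I
calibration, and 2000 replicates for CI coverage.  The vectorized
permutation engine makes these sizes cheap (the whole calibration study
runs in ~20 s on one core).

## Known limitations

- The free-phase fit's c is reported on [0, 2π) with grid+parabolic
  accuracy; profiles with near-zero amplitude have an essentially
  unidentified c (it is still returned; the Rayleigh test across subjects
  is the guard against over-reading such values).
- The permutation p is computed from 500 iterations; its own Monte-Carlo
  SE at p ≈ 0.05 is ≈ 0.01.
- The Rayleigh p approximation is slightly conservative below n ≈ 10.
- The CI formula assumes a unimodal, roughly von Mises sample; for
  multimodal offset distributions the "undefined" branch usually, but not
  always, triggers.
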