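# echofit

Analysis pipeline for **entrainment echoes in auditory working memory**:
does the phase of a preceding rhythmic stimulus cyclically modulate how
well a listener remembers and reproduces the pitch of a brief target tone?

In the paradigm this package models, 2 s of amplitude-modulated (AM) white
noise at 8 Hz entrains the listener; after the noise ends, a brief
multitone target occurs at one of five phases of the *continued* AM cycle
— x ∈ {0, 0.5π, π, 1.5π, 2π} radians relative to the next would-be
envelope peak.  After a silent retention interval the listener adjusts a
response pad (220–880 Hz, logarithmic steps) to match the target's
fundamental.  If an entrainment "echo" persists, matching fidelity should
oscillate with x, best at in-phase targets (0, 2π).

The package is organized as an analysis project: the library under
`src/echofit/` holds every computational step, and the numbered scripts
under `analysis/` drive the full study over simulated data.

## The statistics at the core

For each subject and phase condition, an OLS line predicts matched pitch
from target pitch (both in semitones re 440 Hz).  From each line:

- **accuracy error** = ½ (|ŷ(u₋) − u₋| + |ŷ(u₊) − u₊|), the mean
  absolute deviation from the identity line at the response-range extremes
  u∓ = ∓12 st (220 / 880 Hz).  A slope-s line through the pivot scores
  exactly 12·|1 − s| semitones.
- **precision** = SD of residuals around the line (an inverse-precision
  quantity; denominator n − 2).

The five-point group profile y(x) is then fit with the constrained cosine

    y = a·cos(x + c) + b,   a ≤ 0,   c = 0,

so that a < 0 encodes "least error at in-phase targets".  Significance is
assessed non-parametrically: phase labels are shuffled across trials
*within each subject*, the entire chain (regressions included) is
recomputed, and the observed R² is compared with 500 such null R² values
(p = fraction of null values strictly exceeding the observed one).
Individual subjects are refit with c free; the resulting phase offsets are
tested for non-uniformity (Rayleigh Z = n·R̄²) and their circular mean gets
a 95% dispersion-based confidence interval.

A synthetic-listener simulator closes the loop: matched position
v = s(x)·u + ε with s(x) = 1 − γ₀ + γ₁·cos(x + c_subj), chosen because the
induced accuracy profile is then *exactly* of the fitted cosine form
(a = −12γ₁, b = 12γ₀, c = c_subj), making parameter recovery interpretable.
A stimulus module synthesizes the actual audio (AM noise, harmonic
complexes, phase-aligned trial assemblies) for fixtures and documentation.

## Worked example

```sh
python analysis/02_simulate_experiments.py   # 26 listeners per experiment
python analysis/03_fit_entrainment.py        # full fits + permutation + circular stats
```

prints, for the first simulated experiment (10 blocks, 27 analyzed trials
per phase condition per subject):

```
experiment 1 (3900 trials):
  accuracy fit:  a = -1.670 st (generative -12*mean(gamma1) = -1.619), b = 3.428, R2 = 0.989
  permutation:   p_strict = 0.000, p_add_one = 0.002 (500 shuffles)
  precision fit: a = -0.023, p_strict = 0.092
  phase offsets: Rayleigh Z = 23.58, p = 1.5e-15; mean = 6.12 rad, CI [5.99, 6.25], contains 0: False
```

Reading this: the group accuracy profile oscillates with entrainment phase
with amplitude 1.67 semitones — close to the generative −12·γ̄₁ = −1.62 —
and no label shuffle out of 500 produced a better cosine fit (p < 0.002).
Individual optimal phases cluster tightly (Rayleigh Z = 23.6) near 0, i.e.
near the would-be AM peak; in this particular draw the (very narrow) CI
just misses 0 because the sampled listeners' true offsets happened to
average −0.09 rad.  Precision shows no reliable modulation, matching its
much smaller generative effect (ρ = 0 by default).

`analysis/01_synthesize_stimuli.py` writes example WAVs and the
onset-geometry table (onsets spaced 31.25 ms, spanning one 125 ms AM
period); `analysis/04_calibration.py` verifies the permutation test's
type-I error (0.055 at α = 0.05) and the circular CI's coverage (0.944
nominal 0.95).

There is also a CLI for the same three steps:

```sh
echofit simulate --experiment 1 --n-subjects 26 --seed 7 --out sim/
echofit analyze --input sim/trials.csv --n-perm 500 --seed 11 --out out/
echofit stimgen --experiment 2 --phase 3.14159 --f0 300 --seed 5 --out wavs/
```

Real trial tables in the same CSV schema (`subject_id, block, trial,
phase_rad, target_f0_hz, matched_f0_hz, is_practice`) can be analyzed with
`echofit analyze` directly.

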