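"""Circular statistics for individual optimal-phase offsets.

Each subject's free-phase cosine fit yields a phase offset c in [0, 2*pi).
Across subjects these are unit vectors on the circle; the questions are
(i) are they non-uniformly distributed (Rayleigh test), and (ii) is their
mean direction consistent with 0, i.e. with best performance at in-phase
target onsets (95% confidence interval for the mean direction)?

Formulas follow the classical circular-statistics literature (Zar;
Berens's CircStat toolbox):

  mean resultant  R_bar = |sum exp(i*theta)| / n
  Rayleigh        Z = n * R_bar^2
                  p = exp( sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n) ),  R = n*R_bar
  mean-direction CI half-width d = arccos(t / R) with
                  t = sqrt( 2n(2R^2 - n*chi2) / (4n - chi2) )   if R_bar < 0.9
                  t = sqrt( n^2 - (n^2 - R^2) * exp(chi2 / n) ) if R_bar >= 0.9
  where chi2 is the (1 - alpha) quantile of chi-square with 1 df.  The CI
  is undefined when R_bar is too small for either branch (reported, not
  guessed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "CircularSummary",
    "mean_resultant",
    "rayleigh_test",
    "mean_direction_ci",
    "zero_in_ci",
    "summarize_angles",
    "circdist",
]

TWO_PI = 2.0 * math.pi


def circdist(a, b):
    """Signed circular distance a - b wrapped to (-pi, pi]."""
    d = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float), TWO_PI)
    d = np.where(d > math.pi, d - TWO_PI, d)
    return float(d) if d.ndim == 0 else d


def mean_resultant(angles) -> tuple[float, float]:
    """Mean resultant length in [0, 1] and mean direction in [0, 2*pi)."""
    theta = np.asarray(angles, dtype=float)
    if theta.size == 0:
        raise ValueError("need at least one angle")
    z = np.exp(1j * theta).sum()
    length = float(abs(z)) / theta.size
    direction = float(np.mod(np.angle(z), TWO_PI))
    return length, direction


def rayleigh_test(angles) -> tuple[float, float]:
    """Rayleigh test of circular uniformity: Z = n*R_bar^2 and its p value.

    Uses the standard small-sample approximation for p (accurate for
    n >= ~10, conservative below); p is clipped to [0, 1].
    """
    theta = np.asarray(angles, dtype=float)
    n = theta.size
    if n < 2:
        raise ValueError("Rayleigh test needs at least 2 angles")
    rbar, _ = mean_resultant(theta)
    z = n * rbar * rbar
    big_r = n * rbar
    p = math.exp(math.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - big_r * big_r))
                 - (1.0 + 2.0 * n))
    return z, min(max(p, 0.0), 1.0)


def mean_direction_ci(angles, alpha: float = 0.05) -> tuple[float, float]:
    """Mean direction +/- the dispersion-based CI half-width.

    Returns (low, high) on the unwrapped line around the mean (so
    low <= mean <= high always); wrap with ``np.mod(., 2*pi)`` for display.
    Raises when the resultant length is too small for the formula's
    validity branches.
    """
    theta = np.asarray(angles, dtype=float)
    n = theta.size
    if n < 2:
        raise ValueError("CI needs at least 2 angles")
    rbar, mean_dir = mean_resultant(theta)
    big_r = n * rbar
    chi2 = float(sps.chi2.ppf(1.0 - alpha, df=1))

    if rbar >= 0.9:
        t2 = n * n - (n * n - big_r * big_r) * math.exp(chi2 / n)
    elif rbar > math.sqrt(chi2 / (2.0 * n)):
        t2 = 2.0 * n * (2.0 * big_r * big_r - n * chi2) / (4.0 * n - chi2)
    else:
        raise ValueError(
            f"mean-direction CI undefined: resultant length {rbar:.3f} too "
            f"small for n={n} at alpha={alpha}")
    if t2 < 0:
        raise ValueError("mean-direction CI undefined: negative discriminant")
    d = math.acos(min(1.0, math.sqrt(t2) / big_r))
    return mean_dir - d, mean_dir + d


def zero_in_ci(ci: tuple[float, float], target: float = 0.0) -> bool:
    """Whether the wrapped interval contains the target angle (default 0)."""
    low, high = ci
    mean = 0.5 * (low + high)
    half_width = 0.5 * (high - low)
    return abs(circdist(target, mean)) <= half_width + 1e-12


@dataclass(frozen=True)
class CircularSummary:
    """Rayleigh test + mean direction + CI over per-subject phase offsets."""

    angles: np.ndarray
    n: int
    mean_resultant_length: float
    mean_direction: float
    rayleigh_z: float
    rayleigh_p: float
    ci_low: float                 # unwrapped, ci_low <= mean <= ci_high
    ci_high: float
    ci_defined: bool
    alpha: float = 0.05

    @property
    def contains_zero(self) -> bool:
        if not self.ci_defined:
            raise ValueError("CI undefined; containment is not decidable")
        return zero_in_ci((self.ci_low, self.ci_high))

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "rbar": self.mean_resultant_length,
            "mean_rad": self.mean_direction,
            "z": self.rayleigh_z,
            "p": self.rayleigh_p,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_low_wrapped": float(np.mod(self.ci_low, TWO_PI)),
            "ci_high_wrapped": float(np.mod(self.ci_high, TWO_PI)),
            "ci_defined": self.ci_defined,
            "zero_in_ci": self.contains_zero if self.ci_defined else None,
            "alpha": self.alpha,
        }


def summarize_angles(angles, alpha: float = 0.05) -> CircularSummary:
    """Full circular summary; the CI may be flagged undefined for diffuse
    samples rather than guessed."""
    theta = np.asarray(angles, dtype=float)
    rbar, mean_dir = mean_resultant(theta)
    z, p = rayleigh_test(theta)
    try:
        lo, hi = mean_direction_ci(theta, alpha=alpha)
        defined = True
    except ValueError:
        lo = hi = math.nan
        defined = False
    return CircularSummary(
        angles=theta, n=theta.size, mean_resultant_length=rbar,
        mean_direction=mean_dir, rayleigh_z=z, rayleigh_p=p,
        ci_low=lo, ci_high=hi, ci_defined=defined, alpha=alpha,
    )
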