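"""Constrained cosine ("entrainment echo") fits and the permutation null.

The 5-point phase profile (accuracy or precision at phase conditions
x = {0, 0.5*pi, pi, 1.5*pi, 2*pi}) is fit with

    y = a * cos(x + c) + b,      a <= 0

With c fixed at 0 the amplitude constraint encodes the hypothesis that
performance error is lowest at in-phase target onsets.  Under Gaussian
homoscedastic errors, maximum likelihood is least squares, and the
fixed-c problem is linear: the unconstrained amplitude comes from simple
regression of y on cos(x + c); if it is positive, the boundary solution
a = 0, b = mean(y) applies.  The free-phase variant solves the fixed-c
problem on a dense c grid and keeps the best — deterministic, and exact
to the grid step.  (With c free, a <= 0 spans all cosine phases, so the
free fit always attains the unconstrained cosine fit's R^2.)

Significance of the group-level fit is assessed with a within-subject
label permutation: phase-condition labels are shuffled across all
non-practice trials within each subject (preserving each subject's label
multiset), the ENTIRE measures chain — per-cell regressions, group means,
constrained fit — is recomputed, and the observed R^2 is compared with
500 such null R^2 values.  p is the fraction of null values strictly
exceeding the observed one; the (k+1)/(n+1) variant is reported alongside
because the strict count can be exactly zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .measures import cell_regression_stats, _phase_index
from .simulate import PHASE_CONDITIONS, hz_to_semitone

__all__ = [
    "CosineFitResult",
    "PermutationResult",
    "fit_cosine_fixed_phase",
    "fit_cosine_free_phase",
    "permutation_test",
]


@dataclass(frozen=True)
class CosineFitResult:
    a: float            # amplitude, <= 0
    b: float            # bias
    c: float            # phase offset, radians in [0, 2*pi)
    c_fixed: bool
    r_squared: float
    sse: float

    def __post_init__(self) -> None:
        if self.a > 1e-12:
            raise ValueError("amplitude constraint a <= 0 violated")

    def predict(self, x):
        return self.a * np.cos(np.asarray(x, dtype=float) + self.c) + self.b


@dataclass(frozen=True)
class PermutationResult:
    observed_r2: float
    null_r2: np.ndarray
    n_perm: int
    p_value: float        # strict: #(null > observed) / n_perm
    p_add_one: float      # (#(null >= observed) + 1) / (n_perm + 1)
    seed: int
    measure: str
    fit: CosineFitResult


def _constrained_fit_given_c(x: np.ndarray, y: np.ndarray, c: float
                             ) -> tuple[float, float, float]:
    """(a, b, sse) of the a<=0 least-squares fit at fixed phase offset c."""
    w = np.cos(x + c)
    wc = w - w.mean()
    denom = float(wc @ wc)
    a = float(wc @ (y - y.mean())) / denom if denom > 0 else 0.0
    if a > 0.0:
        a = 0.0
    b = float(y.mean() - a * w.mean())
    resid = y - (a * w + b)
    return a, b, float(resid @ resid)


def _r_squared(y: np.ndarray, sse: float) -> float:
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        return 0.0
    return max(0.0, min(1.0, 1.0 - sse / sst))


def fit_cosine_fixed_phase(x, y) -> CosineFitResult:
    """Least-squares y = a*cos(x) + b with a <= 0 (c fixed at 0).

    Closed form: if the unconstrained amplitude is positive, the boundary
    solution a = 0, b = mean(y) applies (R^2 = 0 by construction there).
    R^2 is defined as 0 when the profile is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    a, b, sse = _constrained_fit_given_c(x, y, 0.0)
    return CosineFitResult(a=a, b=b, c=0.0, c_fixed=True,
                           r_squared=_r_squared(y, sse), sse=sse)


def fit_cosine_free_phase(x, y, grid_step: float = 0.005,
                          refine: bool = True) -> CosineFitResult:
    """Least-squares y = a*cos(x + c) + b with a <= 0 and c free.

    Solves the linear fixed-c problem on a uniform c grid over [0, 2*pi)
    and keeps the grid point minimizing SSE (ties broken by smallest c).
    With ``refine`` a single parabolic interpolation through the argmin's
    periodic neighbors polishes c below the grid step; the inner (a, b)
    solve stays closed-form, so the procedure remains deterministic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    if grid_step <= 0 or grid_step > 0.01:
        raise ValueError("grid_step must be in (0, 0.01]")

    c_grid = np.arange(0.0, 2.0 * math.pi, grid_step)
    w = np.cos(x[None, :] + c_grid[:, None])            # (G, 5)
    wm = w.mean(axis=1, keepdims=True)
    wc = w - wm
    yc = y - y.mean()
    denom = (wc * wc).sum(axis=1)
    a = (wc @ yc) / denom
    np.minimum(a, 0.0, out=a)
    b = y.mean() - a * wm[:, 0]
    resid = y[None, :] - (a[:, None] * w + b[:, None])
    sse = (resid * resid).sum(axis=1)
    k = int(np.argmin(sse))                             # first min = smallest c
    best_a, best_b, best_c, best_sse = float(a[k]), float(b[k]), float(c_grid[k]), float(sse[k])

    if refine:
        g = c_grid.size
        s_m, s_0, s_p = sse[(k - 1) % g], sse[k], sse[(k + 1) % g]
        denom = s_m - 2.0 * s_0 + s_p
        if denom > 0:
            c_star = float(np.mod(c_grid[k] + 0.5 * grid_step * (s_m - s_p) / denom,
                                  2.0 * math.pi))
            a_r, b_r, sse_r = _constrained_fit_given_c(x, y, c_star)
            if sse_r < best_sse:
                best_a, best_b, best_c, best_sse = a_r, b_r, c_star, sse_r

    return CosineFitResult(a=best_a, b=best_b, c=best_c,
                           c_fixed=False, r_squared=_r_squared(y, best_sse),
                           sse=best_sse)


# ---------------------------------------------------------------------------
# Permutation engine
# ---------------------------------------------------------------------------

def _group_means_from_labels(u, v, sub_idx, ph_idx, n_subjects, n_ph, column):
    """Group-mean phase profile of one measure given trial-level labels."""
    cell = sub_idx * n_ph + ph_idx
    stats = cell_regression_stats(u, v, cell, n_subjects * n_ph)
    vals = stats[column].reshape(n_subjects, n_ph)
    return vals.mean(axis=0)


def _profile_r2(y: np.ndarray, x: np.ndarray) -> float:
    _, _, sse = _constrained_fit_given_c(x, y, 0.0)
    return _r_squared(y, sse)


def permutation_test(
    table: pd.DataFrame,
    n_perm: int = 500,
    seed: int = 0,
    measure: str = "accuracy",
    conditions: tuple[float, ...] = PHASE_CONDITIONS,
    scope: str = "subject",
) -> PermutationResult:
    """Within-subject label-shuffle null for the fixed-phase fit's R^2.

    Each iteration independently permutes the phase labels across all
    non-practice trials within each subject (``scope='block'`` restricts
    shuffling to within blocks), preserving each subject's label multiset,
    then recomputes the full chain: per-cell regressions -> group means ->
    constrained cosine fit -> R^2.  Every subject x phase cell keeps its
    trial count, so no cell can be emptied by a shuffle.
    """
    if measure not in ("accuracy", "precision"):
        raise ValueError("measure must be 'accuracy' or 'precision'")
    if scope not in ("subject", "block"):
        raise ValueError("scope must be 'subject' or 'block'")
    column = "accuracy" if measure == "accuracy" else "residual_sd"

    data = table[table["is_practice"].astype(int) == 0]
    subjects = sorted(data["subject_id"].unique())
    sub_idx = pd.Categorical(data["subject_id"], categories=subjects).codes.astype(np.int64)
    ph_idx = _phase_index(data["phase_rad"].to_numpy(), conditions)
    u = np.asarray(hz_to_semitone(data["target_f0_hz"].to_numpy()))
    v = np.asarray(hz_to_semitone(data["matched_f0_hz"].to_numpy()))
    n_sub, n_ph = len(subjects), len(conditions)
    x = np.asarray(conditions)

    y_obs = _group_means_from_labels(u, v, sub_idx, ph_idx, n_sub, n_ph, column)
    a, b, sse = _constrained_fit_given_c(x, y_obs, 0.0)
    observed_fit = CosineFitResult(a=a, b=b, c=0.0, c_fixed=True,
                                   r_squared=_r_squared(y_obs, sse), sse=sse)
    observed = observed_fit.r_squared

    # Shuffle units: contiguous segments per subject (or subject-block).
    if scope == "subject":
        seg_ids = sub_idx
    else:
        blocks = data["block"].to_numpy()
        _, seg_ids = np.unique(
            sub_idx * (blocks.max() + 1) + blocks, return_inverse=True)
    order = np.argsort(seg_ids, kind="stable")
    inv_order = np.empty_like(order)
    inv_order[order] = np.arange(order.size)
    seg_sorted = seg_ids[order]
    boundaries = np.flatnonzero(np.diff(seg_sorted)) + 1
    segments = np.split(np.arange(order.size), boundaries)

    rng = np.random.default_rng(seed)
    null_r2 = np.empty(n_perm)
    ph_sorted = ph_idx[order]
    for i in range(n_perm):
        perm_sorted = ph_sorted.copy()
        for seg in segments:
            perm_sorted[seg] = perm_sorted[seg[rng.permutation(seg.size)]]
        perm = perm_sorted[inv_order]
        y_null = _group_means_from_labels(u, v, sub_idx, perm, n_sub, n_ph, column)
        null_r2[i] = _profile_r2(y_null, x)

    p_strict = float(np.sum(null_r2 > observed)) / n_perm
    p_add_one = (float(np.sum(null_r2 >= observed)) + 1.0) / (n_perm + 1.0)
    return PermutationResult(
        observed_r2=observed, null_r2=null_r2, n_perm=n_perm,
        p_value=p_strict, p_add_one=p_add_one, seed=seed,
        measure=measure, fit=observed_fit,
    )
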