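"""Per-subject, per-phase matching accuracy and precision statistics.

For each subject x phase-condition cell, an ordinary least-squares line
predicts the matched pitch from the target pitch, both expressed in
semitones relative to 440 Hz (the geometric center of the 220-880 Hz
response pad).  Two statistics are derived from each line:

accuracy error — the predicted-vs-target absolute deviation in semitones,
evaluated at the two extremes of the adjustable range (220 and 880 Hz)
and averaged.  A veridical matcher (slope 1, intercept 0) scores 0; a
slope-s line through the pivot scores exactly 12*|1 - s|.

precision SD — the standard deviation of residuals around the line
(denominator n - 2, the regression residual degrees of freedom).  This is
an inverse-precision quantity: larger means less precise.

Phases 0 and 2*pi are analyzed as separate conditions (5 profile points),
and the group profile carries within-subject standard errors computed by
subject-centering (each subject's mean across phases removed, grand mean
restored, SEM across subjects per phase).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import PHASE_CONDITIONS, hz_to_semitone

__all__ = [
    "RegressionLine",
    "fit_matching_regression",
    "accuracy_error",
    "precision_sd",
    "compute_phase_measures",
    "group_profile",
    "cell_regression_stats",
    "hz_to_semitone",
]


@dataclass(frozen=True)
class RegressionLine:
    """OLS matching line in semitone space for one subject x phase cell."""

    slope: float
    intercept: float
    n: int
    residual_sd: float

    def predict(self, u):
        return self.slope * np.asarray(u, dtype=float) + self.intercept


def fit_matching_regression(target_hz, matched_hz) -> RegressionLine:
    """OLS of matched position on target position, both in semitones re 440.

    Requires at least 3 trials and nonzero target variance.  The residual
    SD uses denominator n - 2.
    """
    u = np.asarray(hz_to_semitone(np.asarray(target_hz, dtype=float)))
    v = np.asarray(hz_to_semitone(np.asarray(matched_hz, dtype=float)))
    n = u.size
    if n < 3:
        raise ValueError(f"need at least 3 trials to fit a matching line (got {n})")
    su = u - u.mean()
    denom = float(su @ su)
    if denom == 0.0:
        raise ValueError("degenerate input: zero variance in target f0")
    slope = float(su @ (v - v.mean())) / denom
    intercept = float(v.mean() - slope * u.mean())
    resid = v - (slope * u + intercept)
    residual_sd = math.sqrt(float(resid @ resid) / (n - 2))
    return RegressionLine(slope=slope, intercept=intercept, n=n, residual_sd=residual_sd)


def accuracy_error(line: RegressionLine, range_low: float = 220.0,
                   range_high: float = 880.0) -> float:
    """Mean absolute semitone deviation of the line from identity at the
    response-range extremes."""
    u_lo = hz_to_semitone(range_low)
    u_hi = hz_to_semitone(range_high)
    return 0.5 * (abs(line.predict(u_lo) - u_lo) + abs(line.predict(u_hi) - u_hi))


def precision_sd(line: RegressionLine) -> float:
    """Residual SD around the matching line (inverse precision), semitones."""
    return line.residual_sd


# ---------------------------------------------------------------------------
# Vectorized cell statistics (shared by the table API and the permutation
# engine, which recomputes all regressions per shuffle).
# ---------------------------------------------------------------------------

def cell_regression_stats(u: np.ndarray, v: np.ndarray, cell: np.ndarray,
                          n_cells: int) -> dict[str, np.ndarray]:
    """Per-cell OLS slope/intercept/residual SD/accuracy via bincount sums.

    ``cell`` assigns each trial an integer cell id in [0, n_cells).  Returns
    arrays of length n_cells; cells with fewer than 3 trials or zero target
    variance come back as NaN.
    """
    cnt = np.bincount(cell, minlength=n_cells).astype(float)
    su = np.bincount(cell, weights=u, minlength=n_cells)
    sv = np.bincount(cell, weights=v, minlength=n_cells)
    suu = np.bincount(cell, weights=u * u, minlength=n_cells)
    suv = np.bincount(cell, weights=u * v, minlength=n_cells)
    svv = np.bincount(cell, weights=v * v, minlength=n_cells)

    with np.errstate(divide="ignore", invalid="ignore"):
        sxx = suu - su * su / cnt
        sxy = suv - su * sv / cnt
        syy = svv - sv * sv / cnt
        slope = sxy / sxx
        intercept = (sv - slope * su) / cnt
        sse = np.maximum(syy - slope * sxy, 0.0)
        residual_sd = np.sqrt(sse / (cnt - 2.0))

    bad = (cnt < 3) | ~np.isfinite(slope)
    slope[bad] = np.nan
    intercept[bad] = np.nan
    residual_sd[bad] = np.nan

    u_lo = hz_to_semitone(220.0)
    u_hi = hz_to_semitone(880.0)
    acc = 0.5 * (np.abs(slope * u_lo + intercept - u_lo)
                 + np.abs(slope * u_hi + intercept - u_hi))
    return {
        "n": cnt,
        "slope": slope,
        "intercept": intercept,
        "residual_sd": residual_sd,
        "accuracy": acc,
    }


def _phase_index(phase_rad: np.ndarray,
                 conditions: tuple[float, ...] = PHASE_CONDITIONS) -> np.ndarray:
    cond = np.asarray(conditions)
    idx = np.argmin(np.abs(phase_rad[:, None] - cond[None, :]), axis=1)
    if not np.allclose(phase_rad, cond[idx], atol=1e-9):
        bad = np.where(~np.isclose(phase_rad, cond[idx], atol=1e-9))[0]
        raise ValueError(
            f"phase values not in the design set at rows {bad[:10].tolist()}"
        )
    return idx


def compute_phase_measures(table: pd.DataFrame,
                           conditions: tuple[float, ...] = PHASE_CONDITIONS,
                           ) -> pd.DataFrame:
    """Accuracy and precision per subject x phase condition.

    Practice trials are excluded.  Returns one row per subject x phase with
    columns subject_id, phase_rad, accuracy_st, precision_st, slope,
    intercept, n.  A missing subject x phase cell (or one with < 3 trials)
    is an error naming the cell.
    """
    data = table[table["is_practice"].astype(int) == 0]
    subjects = sorted(data["subject_id"].unique())
    sub_idx = pd.Categorical(data["subject_id"], categories=subjects).codes
    ph_idx = _phase_index(data["phase_rad"].to_numpy(), conditions)
    n_ph = len(conditions)
    cell = sub_idx * n_ph + ph_idx

    u = np.asarray(hz_to_semitone(data["target_f0_hz"].to_numpy()))
    v = np.asarray(hz_to_semitone(data["matched_f0_hz"].to_numpy()))
    stats = cell_regression_stats(u, v, cell, len(subjects) * n_ph)

    bad = np.where(~np.isfinite(stats["slope"]))[0]
    if bad.size:
        cells = [(subjects[b // n_ph], conditions[b % n_ph]) for b in bad[:10]]
        raise ValueError(f"insufficient data in subject x phase cells: {cells}")

    rows = pd.DataFrame({
        "subject_id": np.repeat(subjects, n_ph),
        "phase_rad": np.tile(conditions, len(subjects)),
        "accuracy_st": stats["accuracy"],
        "precision_st": stats["residual_sd"],
        "slope": stats["slope"],
        "intercept": stats["intercept"],
        "n": stats["n"].astype(int),
    })
    return rows


def group_profile(measures: pd.DataFrame,
                  conditions: tuple[float, ...] = PHASE_CONDITIONS) -> dict:
    """Group means and within-subject SEMs per phase, for both measures.

    The within-subject SEM removes between-subject offsets by centering
    each subject on their own cross-phase mean before taking the SEM across
    subjects at each phase; additive subject differences therefore
    contribute nothing.
    """
    n_ph = len(conditions)
    piv_acc = measures.pivot(index="subject_id", columns="phase_rad", values="accuracy_st")
    piv_prec = measures.pivot(index="subject_id", columns="phase_rad", values="precision_st")
    for piv in (piv_acc, piv_prec):
        if piv.isna().any().any() or piv.shape[1] != n_ph:
            raise ValueError("incomplete subject x phase grid")

    def summarize(piv: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        vals = piv.reindex(columns=sorted(piv.columns)).to_numpy()
        means = vals.mean(axis=0)
        centered = vals - vals.mean(axis=1, keepdims=True) + vals.mean()
        sem = centered.std(axis=0, ddof=1) / math.sqrt(vals.shape[0])
        return means, sem

    acc_mean, acc_sem = summarize(piv_acc)
    prec_mean, prec_sem = summarize(piv_prec)
    return {
        "phase_conditions": list(conditions),
        "n_subjects": int(piv_acc.shape[0]),
        "mean_accuracy": acc_mean.tolist(),
        "accuracy_within_subject_sem": acc_sem.tolist(),
        "mean_precision": prec_mean.tolist(),
        "precision_within_subject_sem": prec_sem.tolist(),
    }
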