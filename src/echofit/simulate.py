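"""Trial schedules and synthetic listeners for the matching paradigm.

The experimental design: each block presents 15 matching trials, 3 at each
of the 5 phase conditions {0, 0.5*pi, pi, 1.5*pi, 2*pi} in seeded random
order.  Experiment 1 runs 10 blocks, experiment 2 runs 14; block 1 is a
flagged practice block that the analysis discards, leaving 27 (or 39)
analyzed trials per phase condition per subject.  Target fundamentals are
drawn uniformly (with replacement) from the 211-point log grid between 270
and 715 Hz; matched responses are confined to the response pad's 220-880 Hz
range.

The generative listener works in semitone space (reference 440 Hz, the
geometric center of the response range).  With u the target position and
phi the trial's phase condition, the matched position is

    v = pivot + s_eff(phi) * (u - pivot) + beta + eps
    s_eff(phi) = 1 - gamma0 + gamma1 * cos(phi + c_subject)
    eps ~ Normal(0, sigma(phi)^2),  sigma(phi) = sigma0 * (1 - rho*cos(phi + c_subject))

i.e. a slope compression whose depth is cyclically modulated by the
entrainment phase.  This mechanism is chosen because the paradigm's
regression-derived accuracy statistic then has expectation exactly of the
cosine form the analysis fits: unclamped, with beta = 0 and pivot = 0, the
expected accuracy error at phase phi is 12*(gamma0 - gamma1*cos(phi +
c_subject)) semitones — amplitude a = -12*gamma1, bias b = 12*gamma0,
phase offset c = c_subject.  Responses are clamped (censored) at the pad's
range; under the default population parameters clamping affects well under
1% of trials.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .stimulus import make_f0_grid

__all__ = [
    "PHASE_CONDITIONS",
    "DesignConfig",
    "SubjectParams",
    "PopulationParams",
    "SimulationConfig",
    "build_schedule",
    "draw_subject_params",
    "simulate_listener",
    "simulate_experiment",
    "TRIAL_COLUMNS",
]

PHASE_CONDITIONS: tuple[float, ...] = (
    0.0,
    0.5 * math.pi,
    math.pi,
    1.5 * math.pi,
    2.0 * math.pi,
)

#: Canonical trial-table schema (one row per matching trial).
TRIAL_COLUMNS = [
    "subject_id",
    "block",
    "trial",
    "phase_rad",
    "target_f0_hz",
    "matched_f0_hz",
    "is_practice",
]

SEMITONE_REF_HZ = 440.0


def hz_to_semitone(f, ref: float = SEMITONE_REF_HZ):
    """Position of frequency f in semitones relative to ref: 12*log2(f/ref)."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0) or ref <= 0:
        raise ValueError("frequencies must be positive")
    out = 12.0 * np.log2(f / ref)
    return float(out) if out.ndim == 0 else out


def semitone_to_hz(u, ref: float = SEMITONE_REF_HZ):
    u = np.asarray(u, dtype=float)
    out = ref * 2.0 ** (u / 12.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DesignConfig:
    """Block/phase structure of one experiment."""

    n_blocks: int = 10                      # 10 in experiment 1, 14 in experiment 2
    trials_per_phase_per_block: int = 3
    phase_conditions: tuple[float, ...] = PHASE_CONDITIONS
    practice_blocks: int = 1
    f0_low: float = 270.0
    f0_high: float = 715.0
    f0_grid_n: int = 211
    response_low: float = 220.0             # Hz, pad lower bound
    response_high: float = 880.0
    retention_s: float = 4.0                # metadata only

    def __post_init__(self) -> None:
        if self.practice_blocks >= self.n_blocks:
            raise ValueError("practice_blocks must be fewer than n_blocks")
        if self.trials_per_phase_per_block < 1:
            raise ValueError("need at least one trial per phase per block")

    @property
    def block_size(self) -> int:
        return len(self.phase_conditions) * self.trials_per_phase_per_block

    @property
    def analyzed_trials_per_phase(self) -> int:
        return (self.n_blocks - self.practice_blocks) * self.trials_per_phase_per_block

    @property
    def f0_grid(self) -> np.ndarray:
        return make_f0_grid(self.f0_low, self.f0_high, self.f0_grid_n)

    @classmethod
    def for_experiment(cls, experiment: int) -> "DesignConfig":
        if experiment == 1:
            return cls(n_blocks=10, retention_s=4.0)
        if experiment == 2:
            return cls(n_blocks=14, retention_s=2.0)
        raise ValueError("experiment must be 1 or 2")


@dataclass(frozen=True)
class SubjectParams:
    """One synthetic listener.

    gamma0 — baseline slope compression (0 = veridical matching).
    gamma1 — cyclic modulation amplitude of the compression, <= gamma0 so the
    effective error is nonnegative at every phase.
    c_subject — individual phase offset (radians) of the cyclic modulation.
    sigma0 — residual SD in semitones; rho modulates it cyclically.
    pivot — semitone position the compression pivots around (0 = 440 Hz).
    beta — constant additive bias in semitones.
    """

    gamma0: float = 0.3
    gamma1: float = 0.15
    c_subject: float = 0.0
    sigma0: float = 1.0
    rho: float = 0.0
    pivot: float = 0.0
    beta: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma0 < 0:
            raise ValueError("gamma0 must be nonnegative")
        if not 0.0 <= self.gamma1 <= self.gamma0:
            raise ValueError("gamma1 must lie in [0, gamma0]")
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")


@dataclass(frozen=True)
class PopulationParams:
    """Population means/SDs the per-subject parameters are drawn from.

    Defaults define the simulator's standard study conditions: a moderate
    baseline compression (gamma0 = 0.3) with a cyclic modulation of half
    that depth (gamma1 = 0.15), trial-to-trial matching noise of 1 semitone,
    and individual phase offsets concentrated near 0 (von Mises kappa = 20,
    circular SD about 0.22 rad).  Between-subject SDs are small relative to
    the means so every listener shows the same qualitative effect.
    """

    gamma0_mean: float = 0.3
    gamma0_sd: float = 0.05
    gamma1_mean: float = 0.15
    gamma1_sd: float = 0.05
    sigma0_mean: float = 1.0
    sigma0_sd: float = 0.2
    rho_mean: float = 0.0
    rho_sd: float = 0.0
    beta_mean: float = 0.0
    beta_sd: float = 0.3
    pivot: float = 0.0
    kappa_phase: float = 20.0   # von Mises concentration of c_subject about 0

    def __post_init__(self) -> None:
        if self.kappa_phase < 0:
            raise ValueError("kappa_phase must be nonnegative")


@dataclass(frozen=True)
class SimulationConfig:
    n_subjects: int = 26
    design: DesignConfig = field(default_factory=DesignConfig)
    population: PopulationParams = field(default_factory=PopulationParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")


def build_schedule(design: DesignConfig, seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Trial skeletons for one subject: phases balanced within each block.

    Within every block each phase condition appears exactly
    ``trials_per_phase_per_block`` times in seeded random order; target f0
    is sampled uniformly from the log grid per trial; the leading
    ``practice_blocks`` blocks are flagged.  ``matched_f0_hz`` is NaN until
    a listener model fills it in.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = design.f0_grid
    base_labels = np.repeat(design.phase_conditions, design.trials_per_phase_per_block)

    rows = []
    for block in range(1, design.n_blocks + 1):
        phases = rng.permutation(base_labels)
        targets = grid[rng.integers(0, grid.size, size=phases.size)]
        for trial, (phase, f0) in enumerate(zip(phases, targets), start=1):
            rows.append((block, trial, phase, f0, block <= design.practice_blocks))
    df = pd.DataFrame(rows, columns=["block", "trial", "phase_rad", "target_f0_hz", "is_practice"])
    df["matched_f0_hz"] = np.nan
    return df


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, high: float) -> float:
    """Draw by rejection; falls back to clipping for degenerate bands."""
    if sd == 0:
        return float(min(max(mean, low), high))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return float(x)
    return float(min(max(mean, low), high))


def draw_subject_params(pop: PopulationParams, rng: np.random.Generator) -> SubjectParams:
    """Sample one listener from the population distributions.

    c_subject ~ von Mises(0, kappa_phase) (uniform on the circle when
    kappa = 0); scalar parameters are normal draws truncated to their
    validity ranges (gamma1 additionally to [0, gamma0]).
    """
    if pop.kappa_phase == 0:
        c = float(rng.uniform(0.0, 2.0 * math.pi))
    else:
        c = float(np.mod(rng.vonmises(0.0, pop.kappa_phase), 2.0 * math.pi))
    gamma0 = _truncated_normal(rng, pop.gamma0_mean, pop.gamma0_sd, 0.0, np.inf)
    gamma1 = _truncated_normal(rng, pop.gamma1_mean, pop.gamma1_sd, 0.0, gamma0)
    sigma0 = _truncated_normal(rng, pop.sigma0_mean, pop.sigma0_sd, 1e-6, np.inf)
    rho = _truncated_normal(rng, pop.rho_mean, pop.rho_sd, 0.0, 1.0 - 1e-9)
    beta = float(rng.normal(pop.beta_mean, pop.beta_sd)) if pop.beta_sd > 0 else pop.beta_mean
    return SubjectParams(gamma0=gamma0, gamma1=gamma1, c_subject=c,
                         sigma0=sigma0, rho=rho, pivot=pop.pivot, beta=beta)


def simulate_listener(
    skeletons: pd.DataFrame,
    params: SubjectParams,
    rng: np.random.Generator,
    design: DesignConfig | None = None,
) -> pd.DataFrame:
    """Fill matched_f0_hz for one subject under the cyclic-compression model.

    Matched semitone positions are clamped to the response pad's range
    before conversion back to Hz.
    """
    design = design or DesignConfig()
    df = skeletons.copy()
    u = hz_to_semitone(df["target_f0_hz"].to_numpy())
    phi = df["phase_rad"].to_numpy()

    s_eff = 1.0 - params.gamma0 + params.gamma1 * np.cos(phi + params.c_subject)
    sigma = params.sigma0 * (1.0 - params.rho * np.cos(phi + params.c_subject))
    v = params.pivot + s_eff * (u - params.pivot) + params.beta
    v = v + rng.normal(0.0, 1.0, size=v.size) * sigma

    lo = hz_to_semitone(design.response_low)
    hi = hz_to_semitone(design.response_high)
    v = np.clip(v, lo, hi)
    df["matched_f0_hz"] = semitone_to_hz(v)
    return df


def simulate_experiment(cfg: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Full multi-subject dataset plus the ground-truth parameter record.

    Fully reproducible from ``cfg.seed``: the seed expands into independent
    child streams per subject (parameters, schedule, responses).
    """
    root = np.random.SeedSequence(cfg.seed)
    table_parts = []
    truth = {
        "seed": cfg.seed,
        "n_subjects": cfg.n_subjects,
        "design": asdict(cfg.design),
        "population": asdict(cfg.population),
        "subjects": {},
    }
    for s, child in enumerate(root.spawn(cfg.n_subjects), start=1):
        param_ss, sched_ss, resp_ss = child.spawn(3)
        params = draw_subject_params(cfg.population, np.random.default_rng(param_ss))
        sched = build_schedule(cfg.design, np.random.default_rng(sched_ss))
        done = simulate_listener(sched, params, np.random.default_rng(resp_ss), cfg.design)
        sid = f"S{s:02d}"
        done.insert(0, "subject_id", sid)
        table_parts.append(done)
        truth["subjects"][sid] = asdict(params)

    table = pd.concat(table_parts, ignore_index=True)
    table["is_practice"] = table["is_practice"].astype(int)
    return table[TRIAL_COLUMNS], truth


def write_trial_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def write_ground_truth(truth: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth, indent=2))
    return path
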