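"""Synthetic generators for every input the analysis pipeline consumes.

Reference signals: a deterministic binomial multiplicative cascade (a
measure with a closed-form multifractal spectrum, used to validate the
direct spectrum estimator -- for weight p the singularity exponents
span [-log2(max(p,1-p)), -log2(min(p,1-p))]) and stationary AR(1)
Gaussian noise (a linear null signal for calibrating the surrogate
nonlinearity statistic).

Behavioral data mirror the study design the analysis assumes: per
participant, 176 trials (16 repetitions of an 11-step continuum) in 8
blocks of 22, precursors balanced 88/88, responses drawn from a
logistic forward model whose linear predictor includes the multifractal
covariate block, response times log-normal around a 650 ms mean, and
cursor trajectories sampled at 58 Hz (about 30-40 samples per trial)
with a known number of injected horizontal reversals that peaks for the
ambiguous middle continuum steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import orthogonal_step_codes
from .mouse_metrics import Trajectory

__all__ = [
    "CascadeSpec",
    "BehaviorSimSpec",
    "TrajectoryParams",
    "binomial_cascade",
    "linear_gaussian_control",
    "generate_trial_schedule",
    "simulate_responses",
    "simulate_trajectory",
]

N_STEPS = 11
TRIALS_PER_PARTICIPANT = 176
N_BLOCKS = 8
TRIALS_PER_BLOCK = 22
CONTEXTS = ("real_speech", "tone", "simulated_speech")


# ---------------------------------------------------------------- signals

@dataclass
class CascadeSpec:
    """Binomial cascade: weight p, 2**levels cells, seeded branch order."""

    p: float = 0.7
    levels: int = 14
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError("cascade weight p must lie strictly in (0, 1)")
        if not 4 <= self.levels <= 20:
            raise ValueError("levels must lie in 4..20")


def binomial_cascade(spec: CascadeSpec) -> np.ndarray:
    """Multiplicative cascade of total mass 1 and length 2**levels.

    At each level every cell splits its mass into fractions p and 1-p,
    with the left/right assignment randomized per cell by the seed (the
    multiset of cell masses at every dyadic scale is seed-invariant).
    """
    rng = np.random.default_rng(spec.seed)
    mass = np.array([1.0])
    for _ in range(spec.levels):
        flip = rng.integers(0, 2, size=mass.size).astype(bool)
        left = np.where(flip, spec.p, 1.0 - spec.p)
        children = np.empty(mass.size * 2)
        children[0::2] = mass * left
        children[1::2] = mass * (1.0 - left)
        mass = children
    return mass


def linear_gaussian_control(n: int, phi: float = 0.0, seed: int = 0) -> np.ndarray:
    """Stationary AR(1) Gaussian series x_t = phi*x_{t-1} + e_t."""
    if not abs(phi) < 1.0:
        raise ValueError("AR coefficient must satisfy |phi| < 1 (stationarity)")
    rng = np.random.default_rng(seed)
    innovations = rng.standard_normal(n)
    x = np.empty(n)
    # stationary start: marginal variance 1 / (1 - phi^2)
    x[0] = innovations[0] / np.sqrt(1.0 - phi**2)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + innovations[t]
    return x


# ------------------------------------------------------------- schedules

@dataclass
class BehaviorSimSpec:
    """Design and forward-model settings for simulated behavior."""

    n_participants: int = 42
    context: str = "mixed"  # one context name, or "mixed" (round-robin)
    coefficients: dict = field(default_factory=lambda: {
        "intercept": 0.0,
        "step_linear": -4.0,
        "precursor": -0.5,
        "b_w": -0.34,
        "b_t": 0.06,
        "b_wt": -0.39,
        "participant_sd": 0.3,
    })
    rt_mean_ms: float = 650.0
    rt_sigma: float = 0.31  # log-scale SD: 5th-95th percentiles span ~400-1100 ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.context != "mixed" and self.context not in CONTEXTS:
            raise ValueError(f"unknown context: {self.context!r}")

    def context_for(self, participant: int) -> str:
        if self.context == "mixed":
            return CONTEXTS[participant % len(CONTEXTS)]
        return self.context


def generate_trial_schedule(spec: BehaviorSimSpec) -> pd.DataFrame:
    """Design columns for every trial of every participant.

    Per participant: 176 trials, each of the 11 steps appearing 16
    times, precursors balanced 88/88 (8 of each per step), randomized
    order, 8 blocks of 22, counterbalancing alternating by participant.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for pid in range(1, spec.n_participants + 1):
        steps = np.repeat(np.arange(N_STEPS), 16)
        precursor = np.tile(np.repeat([1, 2], 8), N_STEPS)
        order = rng.permutation(TRIALS_PER_PARTICIPANT)
        steps, precursor = steps[order], precursor[order]
        context = spec.context_for(pid - 1)
        if context == "simulated_speech":
            variant = rng.integers(1, 9, size=TRIALS_PER_PARTICIPANT)
        else:
            variant = np.zeros(TRIALS_PER_PARTICIPANT, dtype=np.int64)
        trial_overall = np.arange(1, TRIALS_PER_PARTICIPANT + 1)
        rows.append(pd.DataFrame({
            "participant": pid,
            "block": (trial_overall - 1) // TRIALS_PER_BLOCK + 1,
            "trial_in_block": (trial_overall - 1) % TRIALS_PER_BLOCK + 1,
            "trial_overall": trial_overall,
            "step": steps,
            "precursor": precursor,
            "context": context,
            "variant": variant,
            "cb": (pid - 1) % 2,
        }))
    return pd.concat(rows, ignore_index=True)


def simulate_responses(
    schedule: pd.DataFrame,
    spec: BehaviorSimSpec,
    stimulus_covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Draw "GA" responses and RTs from the logistic forward model.

    ``stimulus_covariates`` must provide (context, precursor, variant,
    w_mf, t_mf) for every context token appearing in the schedule.  The
    linear predictor is intercept + step_linear*linear(step) +
    precursor_coef*precursor + B_W*w + B_t*t + B_Wt*w*t + participant
    intercept; cumulative counts derive from the same Bernoulli draws.
    """
    rng = np.random.default_rng(spec.seed + 1)
    trials = schedule.merge(
        stimulus_covariates[["context", "precursor", "variant", "w_mf", "t_mf"]],
        on=["context", "precursor", "variant"],
        how="left",
        validate="many_to_one",
    )
    if trials["w_mf"].isna().any():
        missing = trials.loc[trials["w_mf"].isna(),
                             ["context", "precursor", "variant"]].drop_duplicates()
        raise ValueError(f"missing covariates for context tokens:\n{missing}")

    c = spec.coefficients
    lin, _ = orthogonal_step_codes(trials["step"].to_numpy())
    intercepts = rng.normal(0.0, c.get("participant_sd", 0.0),
                            size=trials["participant"].nunique())
    pid_index = trials["participant"].rank(method="dense").astype(int) - 1
    eta = (
        c.get("intercept", 0.0)
        + c.get("step_linear", 0.0) * lin
        + c.get("precursor", 0.0) * trials["precursor"].to_numpy()
        + c.get("b_w", 0.0) * trials["w_mf"].to_numpy()
        + c.get("b_t", 0.0) * trials["t_mf"].to_numpy()
        + c.get("b_wt", 0.0) * trials["w_mf"].to_numpy() * trials["t_mf"].to_numpy()
        + intercepts[pid_index]
    )
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    prob = 1.0 / (1.0 + np.exp(-eta))
    trials["ga_response"] = rng.random(len(trials)) < prob
    trials["ga_response"] = trials["ga_response"].astype(int)

    mu = np.log(spec.rt_mean_ms) - spec.rt_sigma**2 / 2.0
    trials["rt"] = np.exp(rng.normal(mu, spec.rt_sigma, size=len(trials)))
    trials["cum_ga"] = trials.groupby("participant")["ga_response"].cumsum()
    return trials


# ----------------------------------------------------------- trajectories

@dataclass
class TrajectoryParams:
    """Screen geometry, noise, and reversal settings for cursor simulation."""

    start: tuple = (640.0, 720.0)
    goal_left: tuple = (160.0, 80.0)
    goal_right: tuple = (1120.0, 80.0)
    rate_hz: float = 58.0
    jitter_px: float = 3.0
    k_max: int = 4
    overshoot_px: float = 60.0


def _min_jerk(tau: np.ndarray) -> np.ndarray:
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def simulate_trajectory(
    trial, params: TrajectoryParams | None = None, seed: int = 0
):
    """One cursor trajectory for a trial; returns (Trajectory, k_injected).

    A minimum-jerk path runs from the start box to the clicked icon,
    sampled at 58 Hz for round(rt*58/1000) samples.  k horizontal
    reversals are injected by routing x through alternating-direction
    waypoints; k follows a quadratic ambiguity profile over continuum
    steps (maximal at step 5), clamped so every reversal is expressible
    at the available sample count.  With zero jitter the measured
    x-flip count equals k exactly.
    """
    params = params or TrajectoryParams()
    rng = np.random.default_rng(seed)
    rt = float(trial["rt"])
    m = round(rt * params.rate_hz / 1000.0)
    if m < 2:
        raise ValueError(f"rt of {rt} ms too short for 2 samples at 58 Hz")

    ga_left = trial.get("cb", 0) == 0
    clicked_ga = bool(trial.get("ga_response", 1))
    goal = params.goal_left if (clicked_ga == ga_left) else params.goal_right

    step = int(trial.get("step", 5))
    ambiguity = max(0.0, 1.0 - ((step - 5) / 5.0) ** 2)
    k = int(round(params.k_max * ambiguity))
    k = min(k, m - 2)

    x0, y0 = params.start
    x1, y1 = goal
    tau = np.arange(m) / max(m - 1, 1)
    y = y0 + (y1 - y0) * _min_jerk(tau)
    if k <= 0:
        k = 0
        x = x0 + (x1 - x0) * _min_jerk(tau)
    else:
        d = np.sign(x1 - x0) or 1.0
        base = np.linspace(x0, x1, k + 2)
        amp = max(params.overshoot_px, 1.5 * abs(base[1] - base[0]))
        bumps = np.zeros(k + 2)
        bumps[1:-1] = [(-1) ** (j + 1) * amp * d for j in range(1, k + 1)]
        waypoints = base + bumps
        idx = np.round(np.arange(k + 2) * (m - 1) / (k + 1)).astype(int)
        x = np.interp(np.arange(m), idx, waypoints)

    if params.jitter_px > 0:
        x = x + rng.normal(0.0, params.jitter_px, size=m)
        y = y + rng.normal(0.0, params.jitter_px, size=m)

    traj = Trajectory(
        t=np.arange(m) / params.rate_hz, x=x, y=y,
        start=params.start, goal=goal, cb=int(trial.get("cb", 0)),
    )
    return traj, k
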