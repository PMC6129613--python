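"""Response models: Poisson (log link) and logistic regression on trials.

Continuum Step enters through orthogonal polynomial codes (degree 1 and
2 over the 11 levels) so the linear and quadratic effects are
uncorrelated.  Model specifications list interaction *families*: a term
like ``"w_mf x t_mf x linear_step"`` expands to the full set of its
lower-order interactions and main effects.  Participant intercepts are
implemented as per-participant fixed-effect dummies, an exchangeable-
intercept device with the same coefficient contract as a random-
intercept fit.

The fitted multifractal block (B_W, B_t, B_Wt) of the cumulative-"GA"
Poisson model implies, for a context with spectrum width w and
nonlinearity statistic t, a marginal probability of one more "GA"
response of 100*exp(B_W*w + B_t*t + B_Wt*w*t) percent -- the closed
form behind the model-predicted probability table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "orthogonal_step_codes",
    "cumulative_counts",
    "expand_interaction_families",
    "build_design_matrix",
    "fit_model",
    "predicted_event_probability",
]

N_STEPS = 11

_FAMILIES = {
    "poisson_log": lambda: sm.families.Poisson(),
    "binomial_logit": lambda: sm.families.Binomial(),
    "gaussian": lambda: sm.families.Gaussian(),
}


def _level_codes() -> tuple:
    """Degree-1 and degree-2 orthogonal polynomial codes over the 11 levels."""
    levels = np.arange(N_STEPS, dtype=np.float64)
    vander = np.vander(levels, 3, increasing=True)
    q, _ = np.linalg.qr(vander)
    linear, quadratic = q[:, 1], q[:, 2]
    if linear[-1] < linear[0]:
        linear = -linear
    if quadratic[0] < 0:  # convention: positive at the continuum endpoints
        quadratic = -quadratic
    return linear, quadratic


def orthogonal_step_codes(steps) -> tuple:
    """Map step indices 0..10 to (linear, quadratic) orthogonal scores."""
    steps = np.asarray(steps, dtype=np.int64)
    if np.any((steps < 0) | (steps >= N_STEPS)):
        raise ValueError("steps must lie in 0..10")
    linear, quadratic = _level_codes()
    return linear[steps], quadratic[steps]


def cumulative_counts(trials: pd.DataFrame) -> pd.Series:
    """Running per-participant total of "GA" responses across trials.

    Trials must already be ordered by ``trial_overall`` within
    participant; the final value per participant is their total count.
    """
    ordered = trials.groupby("participant")["trial_overall"].is_monotonic_increasing
    if not ordered.all():
        raise ValueError("trials must be ordered by trial_overall within participant")
    return trials.groupby("participant")["ga_response"].cumsum()


def _split_family(expr: str) -> tuple:
    # separators: ×, *, or a standalone x (word-bounded, so 'context' survives)
    parts = [p.strip() for p in re.split(r"×|\*|\bx\b", expr) if p.strip()]
    if not parts:
        raise ValueError(f"empty term expression: {expr!r}")
    return tuple(parts)


def expand_interaction_families(terms) -> list:
    """Expand interaction families into all component terms, deduplicated.

    Every higher-order interaction contributes its full set of
    lower-order interactions and main effects exactly once; ordering is
    by interaction order, then first appearance.
    """
    seen = {}
    for expr in terms:
        factors = _split_family(expr)
        for k in range(1, len(factors) + 1):
            for combo in combinations(factors, k):
                seen.setdefault(combo, None)
    return sorted(seen, key=lambda c: (len(c), list(seen).index(c)))


def _factor_columns(name: str, trials: pd.DataFrame) -> list:
    """Resolve one factor name to (label, values) column(s)."""
    if name == "linear_step":
        lin, _ = orthogonal_step_codes(trials["step"].to_numpy())
        return [("linear_step", lin)]
    if name == "quadratic_step":
        _, quad = orthogonal_step_codes(trials["step"].to_numpy())
        return [("quadratic_step", quad)]
    if name == "context":
        ctx = trials["context"].astype(str)
        # real_speech is the reference level
        return [
            ("context(tone)", (ctx == "tone").to_numpy(np.float64)),
            ("context(ss)", (ctx == "simulated_speech").to_numpy(np.float64)),
        ]
    if name not in trials.columns:
        raise KeyError(f"unknown model factor: {name!r}")
    return [(name, trials[name].to_numpy(np.float64))]


@dataclass
class ModelSpec:
    """Family, response column, interaction families, and intercept policy."""

    family: str
    response: str
    terms: list = field(default_factory=list)
    participant_intercepts: bool = False

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family: {self.family!r}")


def build_design_matrix(spec: ModelSpec, trials: pd.DataFrame) -> pd.DataFrame:
    """Expanded design matrix with intercept (and participant dummies)."""
    cols: dict = {"intercept": np.ones(len(trials))}
    for combo in expand_interaction_families(spec.terms):
        # cross-product over the columns of each factor (dummies multiply out)
        parts = [_factor_columns(name, trials) for name in combo]
        stack = [("", np.ones(len(trials)))]
        for factor_cols in parts:
            stack = [
                (f"{lbl} × {flbl}" if lbl else flbl, vals * fvals)
                for lbl, vals in stack
                for flbl, fvals in factor_cols
            ]
        for lbl, vals in stack:
            cols.setdefault(lbl, vals)
    if spec.participant_intercepts:
        participants = pd.unique(trials["participant"])
        for pid in participants[1:]:  # first participant absorbed by intercept
            cols[f"participant[{pid}]"] = (
                (trials["participant"] == pid).to_numpy(np.float64)
            )
    return pd.DataFrame(cols, index=trials.index)


def fit_model(spec: ModelSpec, trials: pd.DataFrame) -> pd.DataFrame:
    """Maximum-likelihood GLM fit; returns the coefficient table.

    Columns: term, B, SE, p, ci_low, ci_high.  Raises on rank-deficient
    designs (reporting the aliased terms) and on non-convergence.
    """
    X = build_design_matrix(spec, trials)
    y = trials[spec.response].to_numpy(np.float64)

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X.to_numpy())
        diag = np.abs(np.diag(r))
        aliased = [X.columns[i] for i in np.flatnonzero(diag < 1e-8 * diag.max())]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")

    model = sm.GLM(y, X, family=_FAMILIES[spec.family]())
    result = model.fit()
    if not result.converged:
        raise RuntimeError(f"{spec.family} fit did not converge")
    ci = result.conf_int()
    return pd.DataFrame(
        {
            "term": X.columns,
            "B": result.params.to_numpy(),
            "SE": result.bse.to_numpy(),
            "p": result.pvalues.to_numpy(),
            "ci_low": ci.iloc[:, 0].to_numpy(),
            "ci_high": ci.iloc[:, 1].to_numpy(),
        }
    )


def predicted_event_probability(coeffs, w: float, t: float) -> float:
    """Percent probability of one more event implied by the multifractal block.

    ``coeffs`` is (B_W, B_t, B_Wt); the value is
    100*exp(B_W*w + B_t*t + B_Wt*w*t), the multiplicative contribution
    of the multifractal covariates on the log-link scale.
    """
    b_w, b_t, b_wt = coeffs
    return 100.0 * float(np.exp(b_w * w + b_t * t + b_wt * w * t))
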