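"""Direct (Chhabra-Jensen) multifractal spectrum estimation.

Given a non-negative series u(k), the method partitions the series into
nonoverlapping bins of size L, forms bin mass proportions

    P_i(L) = sum_{k in bin i} u(k) / sum_k u(k),

warps them into a one-parameter family of normalized measures

    mu_i(q, L) = P_i(L)^q / sum_j P_j(L)^q,

and reads the singularity strength alpha(q) and its fractal dimension
f(q) off the scaling (versus ln L) of sum_i mu_i ln P_i and the Shannon
entropy sum_i mu_i ln mu_i, respectively.  Each q enters the spectrum
only when both scaling regressions are close to linear (|r| > r_min).
The spectrum width w_MF = alpha_max - alpha_min over retained q is the
summary statistic of heterogeneity.

Numerical notes: mu is computed in log space (log-sum-exp) so that
|q| up to 300 cannot overflow; zero-mass bins are excluded at every
scale with renormalization over the retained bins, which keeps negative
q well-posed without an epsilon floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .audio import MagnitudeSeries

__all__ = [
    "CJConfig",
    "MultifractalSpectrum",
    "default_q_grid",
    "default_scales",
    "bin_proportions",
    "mass_distribution",
    "cj_spectrum",
    "spectrum_width",
]


def default_q_grid(step: int = 5) -> np.ndarray:
    """Moment orders -300..300 in integer steps, always containing 0 and 1."""
    grid = np.arange(-300.0, 300.0 + step, step)
    return np.union1d(grid, np.array([0.0, 1.0]))


def default_scales(n: int) -> np.ndarray:
    """Powers of two from 4 up to n // 4 (nonoverlapping-bin construction)."""
    max_scale = n // 4
    if max_scale < 4:
        raise ValueError(f"series of length {n} too short for scaling analysis")
    exps = np.arange(2, int(np.floor(np.log2(max_scale))) + 1)
    return (2 ** exps).astype(np.int64)


@dataclass
class CJConfig:
    """Estimator settings: moment orders, bin sizes, and the linearity filter."""

    q_grid: np.ndarray = field(default_factory=default_q_grid)
    scales: np.ndarray | None = None  # derived from series length when None
    r_min: float = 0.995
    zero_bin_policy: str = "exclude_renormalize"

    def __post_init__(self) -> None:
        self.q_grid = np.sort(np.asarray(self.q_grid, dtype=np.float64))
        if not (np.any(self.q_grid == 0.0) and np.any(self.q_grid == 1.0)):
            raise ValueError("q_grid must contain 0 and 1")
        if self.scales is not None:
            self.scales = np.asarray(self.scales, dtype=np.int64)
            if np.any(np.diff(self.scales) <= 0):
                raise ValueError("scales must be strictly increasing")
        if not (0.0 < self.r_min <= 1.0):
            raise ValueError("r_min must lie in (0, 1]")
        if self.zero_bin_policy != "exclude_renormalize":
            raise ValueError(f"unknown zero_bin_policy: {self.zero_bin_policy}")

    def resolve_scales(self, n: int) -> np.ndarray:
        scales = default_scales(n) if self.scales is None else self.scales
        if scales[-1] > n // 4:
            scales = scales[scales <= n // 4]
        if scales.size < 3:
            raise ValueError("need at least 3 scales not exceeding length/4")
        return scales


@dataclass
class MultifractalSpectrum:
    """The (alpha(q), f(q)) curve with per-q fit diagnostics."""

    q: np.ndarray
    alpha: np.ndarray
    f: np.ndarray
    r_alpha: np.ndarray
    r_f: np.ndarray
    retained: np.ndarray
    width: float
    diagnostic: str = ""

    @property
    def n_retained(self) -> int:
        return int(np.sum(self.retained))


def _as_values(u) -> np.ndarray:
    if isinstance(u, MagnitudeSeries):
        return u.values
    return np.asarray(u, dtype=np.float64)


def bin_proportions(u, L: int) -> np.ndarray:
    """Mass fractions of nonoverlapping L-sized bins (zero bins excluded).

    Trailing samples beyond the last full bin are discarded.  The returned
    fractions are renormalized over the retained (nonzero-mass) bins and
    sum to one.
    """
    values = _as_values(u)
    if L < 1 or L > values.size:
        raise ValueError(f"bin size {L} out of range for length {values.size}")
    n_bins = values.size // L
    sums = values[: n_bins * L].reshape(n_bins, L).sum(axis=1)
    total = sums.sum()
    if total <= 0:
        raise ValueError("series carries no mass (all zeros)")
    kept = sums[sums > 0]
    return kept / kept.sum()


def mass_distribution(P: np.ndarray, q: float) -> np.ndarray:
    """q-warped normalized measure mu_i = P_i^q / sum P^q, via log-sum-exp."""
    P = np.asarray(P, dtype=np.float64)
    if np.any(P <= 0):
        raise ValueError("proportions must be strictly positive after zero-bin handling")
    log_p = np.log(P)
    scaled = q * log_p
    return np.exp(scaled - logsumexp(scaled))


def _ols_rows(x: np.ndarray, Y: np.ndarray) -> tuple:
    """Row-wise OLS slope and Pearson r of Y against x (vectorized)."""
    xc = x - x.mean()
    yc = Y - Y.mean(axis=1, keepdims=True)
    sxx = float(np.dot(xc, xc))
    sxy = yc @ xc
    syy = np.sum(yc * yc, axis=1)
    slope = sxy / sxx
    with np.errstate(invalid="ignore", divide="ignore"):
        r = sxy / np.sqrt(sxx * syy)
    return slope, r


def cj_spectrum(u, cfg: CJConfig | None = None) -> MultifractalSpectrum:
    """Estimate the multifractal spectrum of a non-negative series.

    For each q, sum_i mu_i ln mu_i and sum_i mu_i ln P_i are regressed
    (OLS) against ln L across ``cfg.scales``; the slopes are f(q) and
    alpha(q).  A q is retained only when |r| > cfg.r_min on both
    regressions jointly.  Width is max - min of retained alpha; when no
    q survives the filter, width is NaN and ``diagnostic`` explains why.
    """
    cfg = cfg or CJConfig()
    values = _as_values(u)
    scales = cfg.resolve_scales(values.size)
    if values.size < 4 * scales[0]:
        raise ValueError("series shorter than 4x the minimum scale")

    q = cfg.q_grid
    n_q = q.size
    ent = np.empty((n_q, scales.size))  # sum mu ln mu
    sing = np.empty((n_q, scales.size))  # sum mu ln P
    for j, L in enumerate(scales):
        log_p = np.log(bin_proportions(values, int(L)))
        scaled = q[:, None] * log_p[None, :]
        log_mu = scaled - logsumexp(scaled, axis=1)[:, None]
        mu = np.exp(log_mu)
        # mu underflows to 0 at extreme q; the entropy summand is 0 there
        ent[:, j] = np.sum(np.where(mu > 0, mu * log_mu, 0.0), axis=1)
        sing[:, j] = mu @ log_p

    ln_l = np.log(scales.astype(np.float64))
    alpha, r_alpha = _ols_rows(ln_l, sing)
    f, r_f = _ols_rows(ln_l, ent)

    with np.errstate(invalid="ignore"):
        retained = (np.abs(r_alpha) > cfg.r_min) & (np.abs(r_f) > cfg.r_min)
    retained &= np.isfinite(alpha) & np.isfinite(f)

    if retained.any():
        width = float(alpha[retained].max() - alpha[retained].min())
        diagnostic = ""
    else:
        width = float("nan")
        diagnostic = (
            f"no q passed the joint |r| > {cfg.r_min} linearity filter; "
            "width undefined"
        )
    return MultifractalSpectrum(
        q=q, alpha=alpha, f=f, r_alpha=r_alpha, r_f=r_f,
        retained=retained, width=width, diagnostic=diagnostic,
    )


def spectrum_width(s: MultifractalSpectrum) -> float:
    """w_MF = alpha_max - alpha_min over retained q."""
    if not s.retained.any():
        raise ValueError("no retained q: spectrum width undefined")
    kept = s.alpha[s.retained]
    return float(kept.max() - kept.min())
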