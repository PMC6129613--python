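"""Mouse-cursor trajectory measures.

Three classic geometric measures quantify deviation from the straightest
path between the observed endpoints of a trajectory: x-position flips
(horizontal direction reversals), maximum displacement (MD, the longest
perpendicular from the trajectory to the start-to-end chord) and area
under the curve (AUC, the unsigned area between trajectory and chord).

Two information-theoretic covariates decompose trajectory entropy by
movement speed: psi is the Shannon entropy (natural log) of the
histogram of chord-orthogonal deviations over all samples, and xi the
same entropy over the fast subset (samples whose speed exceeds the
trajectory's mean speed).  This estimator is a documented stand-in: it
preserves the slow/fast decomposition role of the published covariates
without claiming to reproduce their exact values.  Trajectories here
are a few dozen samples long, too short for temporal-correlation
corrections, so none are applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Trajectory",
    "TrajectoryMetrics",
    "x_position_flips",
    "max_displacement",
    "area_under_curve",
    "entropy_decompose",
    "compute_metrics",
]


@dataclass
class Trajectory:
    """Timestamped cursor samples for one trial."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    start: tuple = (0.0, 0.0)
    goal: tuple = (0.0, 0.0)
    cb: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if not (self.t.size == self.x.size == self.y.size):
            raise ValueError("t, x, y must have equal lengths")
        if self.t.size < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size


@dataclass
class TrajectoryMetrics:
    x_flips: int
    md: float
    auc: float
    psi: float
    xi: float


def x_position_flips(traj: Trajectory) -> int:
    """Count of horizontal direction reversals (zero differences dropped)."""
    dx = np.diff(traj.x)
    dx = dx[dx != 0]
    if dx.size < 2:
        return 0
    return int(np.sum(np.sign(dx[1:]) != np.sign(dx[:-1])))


def _chord_coordinates(traj: Trajectory) -> tuple:
    """(along-chord, orthogonal) coordinates relative to the first-to-last chord."""
    p0 = np.array([traj.x[0], traj.y[0]])
    p1 = np.array([traj.x[-1], traj.y[-1]])
    chord = p1 - p0
    norm = np.linalg.norm(chord)
    if norm == 0:
        raise ValueError("degenerate chord: trajectory starts and ends at the same point")
    u = chord / norm
    rel_x = traj.x - p0[0]
    rel_y = traj.y - p0[1]
    along = rel_x * u[0] + rel_y * u[1]
    ortho = rel_x * u[1] - rel_y * u[0]  # signed perpendicular distance
    return along, ortho


def max_displacement(traj: Trajectory) -> float:
    """Largest perpendicular distance from any sample to the chord."""
    _, ortho = _chord_coordinates(traj)
    return float(np.max(np.abs(ortho)))


def area_under_curve(traj: Trajectory) -> float:
    """Unsigned area between the polyline and the chord (lobes summed).

    Trapezoidal integration in chord-aligned coordinates; opposite-side
    lobes add rather than cancel.
    """
    if len(traj) < 3:
        raise ValueError("AUC needs at least 3 samples")
    along, ortho = _chord_coordinates(traj)
    widths = np.diff(along)
    heights = 0.5 * (ortho[:-1] + ortho[1:])
    return float(np.sum(np.abs(widths * heights)))


def _histogram_entropy(values: np.ndarray, n_bins: int) -> float:
    counts, _ = np.histogram(values, bins=n_bins)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-np.sum(p * np.log(p)))


def entropy_decompose(traj: Trajectory, n_bins: int = 16) -> tuple:
    """(psi, xi): whole-trajectory and fast-movement deviation entropies.

    Speeds come from finite differences (``np.gradient``); the fast
    subset is samples with speed strictly above the mean speed.  On a
    constant-speed path no sample is strictly above the mean, and xi is
    computed over all samples (so xi equals psi).
    """
    if len(traj) < 4:
        raise ValueError("entropy decomposition needs at least 4 samples")
    _, ortho = _chord_coordinates(traj)
    dx = np.gradient(traj.x, traj.t)
    dy = np.gradient(traj.y, traj.t)
    speed = np.hypot(dx, dy)
    psi = _histogram_entropy(ortho, n_bins)
    fast = speed > speed.mean()
    if not fast.any():
        fast = np.ones_like(fast, dtype=bool)
    xi = _histogram_entropy(ortho[fast], n_bins)
    return psi, xi


def compute_metrics(traj: Trajectory, n_bins: int = 16) -> TrajectoryMetrics:
    """All five measures for one trajectory."""
    psi, xi = entropy_decompose(traj, n_bins=n_bins)
    return TrajectoryMetrics(
        x_flips=x_position_flips(traj),
        md=max_displacement(traj),
        auc=area_under_curve(traj),
        psi=psi,
        xi=xi,
    )
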