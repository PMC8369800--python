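"""Imaging-derived statistics: Ripley's K/L clustering and MSD mobility.

Ripley's K uses the plain density-normalized estimator

    K(r) = (S / (N - 1)) * (1/N) * sum_i sum_{j != i} [r_ij <= r]

with no edge correction, so it carries a negative bias near the window
border; CSR comparisons should stay at radii well inside the window (see
docs/methods.md).  L(r) = sqrt(K(r)/pi).  MSD uses overlapping time origins
and the 2D->3D conversion msd_3d = 1.5 * msd_2d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .simulate import PointPattern, TrajectorySet

__all__ = ["MSDCurve", "ripley_k", "ripley_l", "msd", "fit_diffusion"]


def ripley_k(pattern: PointPattern, radii: np.ndarray) -> np.ndarray:
    """Ripley's K at the given radii (positive, increasing).

    Vectorized over sorted pairwise distances; equals the O(N^2) double loop
    exactly.  Pairs with r_ij <= r count (ordered pairs, both directions).
    """
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0) or np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be positive and strictly increasing")
    n = pattern.n
    if n < 2:
        raise ValueError("need >= 2 points")
    d = np.sort(pdist(pattern.points))
    # ordered pair count within r = 2 * (# unordered distances <= r)
    counts = 2.0 * np.searchsorted(d, radii, side="right")
    return (pattern.area_S / (n - 1)) * (counts / n)


def ripley_l(k_values: np.ndarray) -> np.ndarray:
    """L(r) = sqrt(K(r) / pi), elementwise."""
    k_values = np.asarray(k_values, dtype=float)
    if np.any(k_values < 0):
        raise ValueError("K must be non-negative")
    return np.sqrt(k_values / np.pi)


@dataclass
class MSDCurve:
    """Mean squared displacement versus lag time."""

    lags: np.ndarray  # multiples of dt, starting at dt
    msd_2d: np.ndarray

    @property
    def msd_3d(self) -> np.ndarray:
        return 1.5 * self.msd_2d


def msd(trajectories: TrajectorySet, max_lag: int) -> MSDCurve:
    """MSD over particles and overlapping start frames.

    msd_2d(tau) = mean over particles and valid t of |r(t+tau) - r(t)|^2,
    for tau = dt .. max_lag*dt.
    """
    pos = trajectories.positions
    if pos.shape[0] == 0:
        raise ValueError("empty trajectory set")
    n_frames = trajectories.n_frames
    if max_lag >= n_frames:
        raise ValueError("max_lag must be < shortest trajectory length")
    vals = np.empty(max_lag)
    for lag in range(1, max_lag + 1):
        disp = pos[:, lag:, :] - pos[:, :-lag, :]
        vals[lag - 1] = np.mean(np.sum(disp**2, axis=-1))
    lags = trajectories.dt * np.arange(1, max_lag + 1)
    return MSDCurve(lags, vals)


def fit_diffusion(curve: MSDCurve, n_lags: int = 4) -> float:
    """Diffusion coefficient: least-squares slope of msd_2d over the first
    ``n_lags`` lags (with intercept, absorbing localization noise), / 4."""
    if curve.lags.size < n_lags:
        raise ValueError("curve has fewer points than n_lags")
    x = curve.lags[:n_lags]
    y = curve.msd_2d[:n_lags]
    slope = np.polyfit(x, y, 1)[0]
    return float(slope / 4.0)
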