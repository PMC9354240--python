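"""Mean-square-displacement analysis of particle trajectories.

The quantitative core: time-averaged MSD per trajectory (all overlapping
pairs), ensemble averaging with SEM across particles, power-law fitting
MSD = K * dt^alpha for the anomalous exponent, origin-constrained linear
fitting MSD = 4 D_T * dt on short lags for the translational diffusion
coefficient, diffusion-regime classification, and two-sample comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .params import Trajectory

__all__ = [
    "MsdCurve",
    "MotilityFit",
    "tamsd",
    "ensemble_msd",
    "fit_power_law",
    "fit_linear",
    "classify_regime",
    "msd_at",
    "compare_groups",
    "fit_trajectories",
]


@dataclass
class MsdCurve:
    """MSD (um^2) vs lag time (s) with per-lag SEM and observation counts."""

    lags: np.ndarray
    msd: np.ndarray
    sem: np.ndarray
    n_obs: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        self.n_obs = np.asarray(self.n_obs, dtype=int)
        if not (len(self.lags) == len(self.msd) == len(self.sem) == len(self.n_obs)):
            raise ValueError("all MsdCurve fields must share a length")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd < 0) or np.any(self.sem < 0):
            raise ValueError("msd and sem must be non-negative")


@dataclass
class MotilityFit:
    """Power-law (K, alpha) and short-lag linear (D_T) fit results."""

    K: float
    alpha: float
    D_T: float
    alpha_window: tuple[float, float]
    linear_window: tuple[float, float]
    r_squared_alpha: float = float("nan")
    r_squared_linear: float = float("nan")


def tamsd(traj: Trajectory, max_lag: float | None = None) -> MsdCurve:
    """Time-averaged MSD of one trajectory over all overlapping pairs.

    For lag k*dt the estimate is mean_t |r(t + k dt) - r(t)|^2 over every
    start frame t; the per-lag SEM treats the overlapping squared
    displacements as independent (an upper-ish count; downstream ensemble
    SEM across particles is the quantity reported).
    """
    n = len(traj)
    if n < 2:
        raise ValueError("trajectory must have at least 2 frames")
    dt = traj.frame_interval
    max_k = n - 1
    if max_lag is not None:
        if max_lag >= traj.times[-1] - traj.times[0] + dt:
            raise ValueError("max_lag must be below the trajectory duration")
        max_k = min(max_k, int(round(max_lag / dt)))
    lags = np.arange(1, max_k + 1) * dt
    msd = np.empty(max_k)
    sem = np.empty(max_k)
    n_obs = np.empty(max_k, dtype=int)
    xy = traj.xy
    for i, k in enumerate(range(1, max_k + 1)):
        sq = np.sum((xy[k:] - xy[:-k]) ** 2, axis=1)
        msd[i] = sq.mean()
        n_obs[i] = len(sq)
        sem[i] = sq.std(ddof=1) / np.sqrt(len(sq)) if len(sq) > 1 else 0.0
    return MsdCurve(lags=lags, msd=msd, sem=sem, n_obs=n_obs)


def ensemble_msd(curves: list[MsdCurve]) -> MsdCurve:
    """Unweighted per-lag mean across particles; SEM = SD / sqrt(n).

    Curves are intersected on their common lag grid (the shortest curve
    wins); this matches reporting MSD as mean +/- SEM over particles.
    """
    if not curves:
        raise ValueError("ensemble_msd requires at least one curve")
    n_lags = min(len(c.lags) for c in curves)
    ref = curves[0].lags[:n_lags]
    for c in curves[1:]:
        if not np.allclose(c.lags[:n_lags], ref, rtol=1e-6):
            raise ValueError("curves must share a lag grid")
    stack = np.stack([c.msd[:n_lags] for c in curves])
    mean = stack.mean(axis=0)
    if len(curves) > 1:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(len(curves))
    else:
        sem = np.zeros(n_lags)
    return MsdCurve(lags=ref.copy(), msd=mean, sem=sem,
                    n_obs=np.full(n_lags, len(curves)))


def _window_mask(lags: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (lags >= lo - 1e-9) & (lags <= hi + 1e-9)


def fit_power_law(curve: MsdCurve, window: tuple[float, float] = (0.2, 10.0)
                  ) -> tuple[float, float]:
    """Fit MSD = K * dt^alpha by OLS of log(msd) on log(lag) in ``window``.

    Returns (K, alpha): alpha is the slope, K = exp(intercept). Log-log
    OLS weights residuals scale-free across the lag decades.
    """
    mask = _window_mask(curve.lags, window)
    if mask.sum() < 4:
        raise ValueError("power-law fit needs at least 4 lags in the window")
    if np.any(curve.msd[mask] <= 0):
        raise ValueError("power-law fit requires strictly positive MSD in the window")
    x = np.log(curve.lags[mask])
    y = np.log(curve.msd[mask])
    res = stats.linregress(x, y)
    return float(np.exp(res.intercept)), float(res.slope)


def fit_linear(curve: MsdCurve, window: tuple[float, float] = (0.2, 3.0)) -> float:
    """Fit MSD = 4 D_T * dt through the origin on short lags; return D_T.

    Applied to the first ~3 s of the curve, where confinement has not yet
    bent the MSD and the motion is effectively free.
    """
    mask = _window_mask(curve.lags, window)
    if mask.sum() < 3:
        raise ValueError("linear fit needs at least 3 lags in the window")
    x = curve.lags[mask]
    y = curve.msd[mask]
    slope = float(np.dot(x, y) / np.dot(x, x))
    return slope / 4.0


def classify_regime(alpha: float, tol: float = 0.05) -> str:
    """Label the diffusion regime from the anomalous exponent.

    |alpha - 1| <= tol is normal (Brownian) diffusion; below is
    sub-diffusive (constrained), above superdiffusive.
    """
    if not np.isfinite(alpha):
        raise ValueError("alpha must be finite")
    if abs(alpha - 1.0) <= tol:
        return "normal"
    return "subdiffusive" if alpha < 1.0 else "superdiffusive"


def msd_at(curve: MsdCurve, lag: float) -> tuple[float, float]:
    """MSD and SEM at one lag time (nearest grid point; exact on grid)."""
    if lag > curve.lags[-1] + 1e-9:
        raise ValueError("requested lag exceeds the curve's maximum")
    idx = int(np.argmin(np.abs(curve.lags - lag)))
    return float(curve.msd[idx]), float(curve.sem[idx])


def compare_groups(values_a, values_b, equal_var: bool = False
                   ) -> tuple[float, float]:
    """Two-sample two-tailed t-test (Welch by default) on motility metrics.

    Returns (t_statistic, p_value). Degenerate identical zero-variance
    groups give (0, 1) with a warning rather than NaN.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        warnings.warn("identical zero-variance groups; returning p = 1")
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def significance_tier(p: float) -> str:
    """Asterisk annotation: * p<0.05, ** p<0.01, *** p<0.001, ns otherwise."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def fit_trajectories(trajs: list[Trajectory],
                     alpha_window: tuple[float, float] = (0.2, 10.0),
                     linear_window: tuple[float, float] = (0.2, 3.0),
                     ) -> tuple[MsdCurve, MotilityFit]:
    """Convenience pipeline: per-particle TAMSD -> ensemble mean -> fits.

    Returns the ensemble MSD curve and a :class:`MotilityFit` holding
    (K, alpha) from the power law and D_T from the origin-constrained
    linear law, each with its R^2 in its own fit space.
    """
    curves = [tamsd(t) for t in trajs]
    ens = ensemble_msd(curves)
    K, alpha = fit_power_law(ens, alpha_window)
    d_t = fit_linear(ens, linear_window)

    mask = _window_mask(ens.lags, alpha_window)
    logy = np.log(ens.msd[mask])
    pred = np.log(K) + alpha * np.log(ens.lags[mask])
    ss_res = np.sum((logy - pred) ** 2)
    ss_tot = np.sum((logy - logy.mean()) ** 2)
    r2a = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    mask_l = _window_mask(ens.lags, linear_window)
    y = ens.msd[mask_l]
    pred_l = 4.0 * d_t * ens.lags[mask_l]
    ss_res = np.sum((y - pred_l) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2l = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    fit = MotilityFit(K=K, alpha=alpha, D_T=d_t, alpha_window=alpha_window,
                      linear_window=linear_window, r_squared_alpha=float(r2a),
                      r_squared_linear=float(r2l))
    return ens, fit
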