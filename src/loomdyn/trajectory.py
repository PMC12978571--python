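"""Time normalization of event-locked pupil traces.

Trial durations vary with each judged time-to-collision, so traces are
mapped onto a unified [0, 1] scale by a two-piece linear warp: the fixed
stimulus epoch (300-1,300 ms) goes to [0, 0.5] and the variable
imagination epoch (1,300 ms to key press) to [0.5, 1].  Warped samples
are then smoothed with penalized cubic B-splines (P-splines) on a common
grid, with the roughness penalty chosen by generalized cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

STIM_ONSET_MS = 300.0
STIM_OFFSET_MS = 1300.0


@dataclass
class NormalizedTrajectory:
    trial_id: str
    grid: np.ndarray
    values: np.ndarray
    spline_coeffs: np.ndarray
    knots: np.ndarray
    gcv_lambda: float
    warp_breakpoint: float = 0.5


def warp_time(t_ms, keypress_ms: float,
              stim: tuple[float, float] = (STIM_ONSET_MS, STIM_OFFSET_MS)):
    """Piecewise-linear map from trial time (ms) to normalized [0, 1].

    ``stim[0]`` maps to 0, ``stim[1]`` to 0.5 and ``keypress_ms`` to 1;
    the map is continuous and strictly increasing.
    """
    t_ms = np.asarray(t_ms, dtype=float)
    t0, t1 = stim
    if keypress_ms <= t1:
        raise ValueError("key press must fall after stimulus offset")
    if np.any(t_ms < t0) or np.any(t_ms > keypress_ms):
        raise ValueError("times outside [stimulus onset, key press]")
    u = np.where(t_ms <= t1,
                 0.5 * (t_ms - t0) / (t1 - t0),
                 0.5 + 0.5 * (t_ms - t1) / (keypress_ms - t1))
    return u if u.ndim else float(u)


def unwarp_time(u, keypress_ms: float,
                stim: tuple[float, float] = (STIM_ONSET_MS, STIM_OFFSET_MS)):
    """Inverse of :func:`warp_time` on [0, 1]."""
    u = np.asarray(u, dtype=float)
    t0, t1 = stim
    t = np.where(u <= 0.5,
                 t0 + u / 0.5 * (t1 - t0),
                 t1 + (u - 0.5) / 0.5 * (keypress_ms - t1))
    return t if t.ndim else float(t)


def _bspline_design(u: np.ndarray, n_basis: int, degree: int = 3
                    ) -> tuple[np.ndarray, np.ndarray]:
    n_interior = n_basis - degree - 1
    if n_interior < 0:
        raise ValueError("n_basis too small for cubic splines")
    interior = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
    knots = np.concatenate([np.zeros(degree + 1), interior,
                            np.ones(degree + 1)])
    B = BSpline.design_matrix(np.clip(u, 0.0, 1.0), knots, degree,
                              extrapolate=False).toarray()
    return B, knots


def smooth_bspline(u: np.ndarray, y: np.ndarray, trial_id: str = "",
                   n_basis: int = 20, grid_size: int = 101,
                   lambdas: np.ndarray | None = None) -> NormalizedTrajectory:
    """Penalized cubic B-spline fit of warped samples, evaluated on the
    common grid.

    Minimizes ||y - Bc||^2 + lam * ||D2 c||^2 over coefficients c, where
    D2 is the second-difference operator; lam is selected from a log grid
    by GCV with the standard trace(H) degrees-of-freedom correction.
    """
    u = np.asarray(u, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    u, y = u[ok], y[ok]
    if len(u) < n_basis:
        raise ValueError("too few valid samples for the spline basis")
    B, knots = _bspline_design(u, n_basis)
    D2 = np.diff(np.eye(n_basis), n=2, axis=0)
    BtB = B.T @ B
    Bty = B.T @ y
    P = D2.T @ D2
    if lambdas is None:
        lambdas = np.logspace(-6, 2, 17)
    best = None
    n = len(y)
    for lam in lambdas:
        A = BtB + lam * P
        try:
            c = np.linalg.solve(A, Bty)
        except np.linalg.LinAlgError:
            continue
        fitted = B @ c
        rss = float(np.sum((y - fitted) ** 2))
        # effective dof = trace of the hat matrix
        edf = float(np.trace(np.linalg.solve(A, BtB)))
        denom = max(n - edf, 1e-8)
        gcv = n * rss / denom ** 2
        if best is None or gcv < best[0]:
            best = (gcv, lam, c)
    if best is None:
        raise RuntimeError("spline smoothing failed for all penalties")
    _, lam, c = best
    grid = np.linspace(0.0, 1.0, grid_size)
    values = BSpline(knots, c, 3)(grid)
    return NormalizedTrajectory(trial_id=trial_id, grid=grid, values=values,
                                spline_coeffs=c, knots=knots, gcv_lambda=lam)


def normalize_trace(t_ms: np.ndarray, d: np.ndarray, keypress_ms: float,
                    valid: np.ndarray | None = None, trial_id: str = "",
                    n_basis: int = 20, grid_size: int = 101
                    ) -> NormalizedTrajectory:
    """Warp one corrected trace (samples at/after stimulus onset) onto
    [0, 1] and smooth it.  Samples before 300 ms are baseline-only and
    are dropped here."""
    t_ms = np.asarray(t_ms, dtype=float)
    d = np.asarray(d, dtype=float)
    keep = (t_ms >= STIM_ONSET_MS) & (t_ms <= keypress_ms)
    if valid is not None:
        keep &= np.asarray(valid, dtype=bool)
    u = warp_time(t_ms[keep], keypress_ms)
    return smooth_bspline(u, d[keep], trial_id=trial_id,
                          n_basis=n_basis, grid_size=grid_size)


def trajectory_matrix(trajectories: list[NormalizedTrajectory]
                      ) -> tuple[np.ndarray, list[str]]:
    """Stack trajectories into a trials x grid matrix plus id list."""
    X = np.stack([tr.values for tr in trajectories])
    ids = [tr.trial_id for tr in trajectories]
    return X, ids
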