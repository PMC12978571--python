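"""Functional principal component analysis of normalized pupil
trajectories.

The trial ensemble on a common grid is decomposed into a mean function
plus orthonormal eigenfunctions of the sample covariance operator,
discretized with trapezoid quadrature.  Per-trial scores are quadrature
inner products of the centered trajectories with the eigenfunctions, so
each trajectory is approximately mean(t) + sum_j score_j * phi_j(t).
Components are retained while cumulative explained variance stays below
85%, then any retained component explaining <= 5% individually is
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f_oneway, pearsonr

from .stats import bh_fdr

__all__ = ["FPCAModel", "fit_fpca", "retain_components", "reconstruct",
           "score_condition_tests"]


@dataclass
class FPCAModel:
    grid: np.ndarray
    mean_fn: np.ndarray
    eigenfunctions: np.ndarray  # J x G
    eigenvalues: np.ndarray
    explained_share: np.ndarray
    scores: np.ndarray          # trials x J
    quadrature: np.ndarray
    retained: list[int] = field(default_factory=list)


def _trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    w = np.empty(len(grid))
    dg = np.diff(grid)
    w[0] = dg[0] / 2
    w[-1] = dg[-1] / 2
    w[1:-1] = (dg[:-1] + dg[1:]) / 2
    return w


def fit_fpca(X: np.ndarray, grid: np.ndarray, n_components: int | None = None
             ) -> FPCAModel:
    """Eigendecomposition of the sample covariance surface of the
    trials-x-grid matrix ``X`` under trapezoid quadrature.

    Sign convention: each eigenfunction is flipped so that its integral
    over the stimulus half [0, 0.5] is non-negative.
    """
    X = np.asarray(X, dtype=float)
    grid = np.asarray(grid, dtype=float)
    n, G = X.shape
    if n < 2:
        raise ValueError("need at least 2 trajectories")
    w = _trapezoid_weights(grid)
    mean_fn = X.mean(axis=0)
    Xc = X - mean_fn
    total_var = float(np.sum(w * Xc.var(axis=0, ddof=1)))
    if total_var <= 1e-14:
        raise ValueError("degenerate ensemble: zero total variance")
    C = (Xc.T @ Xc) / (n - 1)
    sw = np.sqrt(w)
    M = sw[:, None] * C * sw[None, :]
    M = (M + M.T) / 2
    evals, evecs = np.linalg.eigh(M)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    J = n_components if n_components is not None else min(n - 1, G)
    evals = evals[:J]
    phi = (evecs[:, :J] / sw[:, None]).T  # J x G, orthonormal under w
    # sign convention
    half = grid <= 0.5
    for j in range(phi.shape[0]):
        if np.sum(w[half] * phi[j, half]) < 0:
            phi[j] = -phi[j]
    shares = evals / evals.sum() if evals.sum() > 0 else evals
    scores = Xc @ (w[None, :] * phi).T
    model = FPCAModel(grid=grid, mean_fn=mean_fn, eigenfunctions=phi,
                      eigenvalues=evals, explained_share=shares,
                      scores=scores, quadrature=w)
    model.retained = retain_components(model)
    return model


def retain_components(model: FPCAModel, cum_share: float = 0.85,
                      min_share: float = 0.05) -> list[int]:
    """Smallest prefix of components whose cumulative explained share
    exceeds ``cum_share``; members with individual share <= ``min_share``
    are then dropped.  Zero-based indices."""
    shares = model.explained_share
    cum = np.cumsum(shares)
    if not np.any(cum > cum_share):
        import warnings
        warnings.warn("cumulative share never exceeds the threshold; "
                      "retaining all components")
        prefix = list(range(len(shares)))
    else:
        j_star = int(np.argmax(cum > cum_share))
        prefix = list(range(j_star + 1))
    return [j for j in prefix if shares[j] > min_share]


def reconstruct(model: FPCAModel, scores, components: list[int] | None = None
                ) -> np.ndarray:
    """Mean function plus score-weighted eigenfunctions on the grid."""
    comps = model.retained if components is None else components
    s = np.atleast_2d(np.asarray(scores, dtype=float))
    out = np.tile(model.mean_fn, (s.shape[0], 1))
    for pos, j in enumerate(comps):
        out += s[:, pos:pos + 1] * model.eigenfunctions[j][None, :]
    return out if out.shape[0] > 1 else out[0]


def score_condition_tests(scores: np.ndarray, factors: pd.DataFrame,
                          q: float = 0.05) -> pd.DataFrame:
    """Associations of per-trial component scores with design factors.

    Categorical factors get a one-way ANOVA across levels, numeric
    factors a Pearson correlation; p-values are BH-FDR corrected within
    each component's family of tests.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] != len(factors):
        raise ValueError("scores and factors are misaligned")
    rows = []
    for j in range(scores.shape[1]):
        fam = []
        for col in factors.columns:
            vals = factors[col]
            entry = {"component": j + 1, "factor": col}
            if pd.api.types.is_numeric_dtype(vals) and vals.nunique() > 6:
                r, p = pearsonr(scores[:, j], vals.to_numpy(float))
                entry.update(stat=r, stat_name="pearson_r", p=p)
            else:
                groups = [scores[:, j][(vals == lv).to_numpy()]
                          for lv in vals.unique()]
                groups = [g for g in groups if len(g) >= 2]
                if len(groups) < 2:
                    continue
                F, p = f_oneway(*groups)
                entry.update(stat=F, stat_name="anova_F", p=p)
            fam.append(entry)
        if fam:
            padj, rej = bh_fdr([e["p"] for e in fam], q=q)
            for e, pa, rj in zip(fam, padj, rej):
                e["p_adj"] = pa
                e["significant"] = bool(rj)
            rows.extend(fam)
    return pd.DataFrame(rows)
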