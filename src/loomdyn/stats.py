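"""Shared statistical machinery.

* Benjamini-Hochberg false-discovery-rate control.
* Mixed-design repeated-measures ANOVA via the univariate contrast
  approach: within-subject effects are projected onto orthonormal
  contrast columns, each column is regressed on the between-subject
  factorial, and sums of squares are pooled across columns.  The
  Greenhouse-Geisser epsilon for every within effect comes from the
  covariance of its contrast scores.
* A pointwise mixed-model contrast for functional (grid-valued)
  responses: at each grid point a linear mixed model with a subject
  random intercept, with BH correction across grid points.  This is a
  deliberate, documented simplification of a full functional linear
  mixed model: coefficient functions are not smoothed and random slopes
  over normalized time cannot be represented.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

__all__ = ["bh_fdr", "rm_anova", "gg_epsilon",
           "pointwise_functional_contrast", "AnovaResult"]


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Returns (adjusted p-values, boolean rejection mask).  Adjusted
    p-values are monotone non-decreasing in rank; rejection at level q
    is equivalent to ``p_adj <= q``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


@dataclass
class AnovaResult:
    effect: str
    F: float
    df_num: float
    df_den: float
    ss_effect: float
    ss_error: float
    partial_eta_sq: float
    gg_epsilon: float
    p_uncorrected: float
    p_gg: float


def _orthonormal_contrasts(levels: int) -> np.ndarray:
    """levels x (levels-1) orthonormal contrast matrix (Helmert-style),
    columns orthogonal to the unit vector."""
    H = np.zeros((levels, levels - 1))
    for j in range(1, levels):
        H[:j, j - 1] = 1.0
        H[j, j - 1] = -j
        H[:, j - 1] /= np.linalg.norm(H[:, j - 1])
    return H


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the covariance matrix of a
    within-effect's orthonormal contrast scores (Box's epsilon).  Equals
    1 under sphericity and is floored at 1/d."""
    cov = np.asarray(cov, dtype=float)
    d = cov.shape[0]
    if d == 1:
        return 1.0
    tr = np.trace(cov)
    eps = tr ** 2 / (d * float(np.sum(cov * cov)))
    return float(np.clip(eps, 1.0 / d, 1.0))


def _between_design(bdf: pd.DataFrame, between: list[str]) -> tuple[np.ndarray, dict]:
    """Sum-coded between-subjects design matrix with all interactions.

    Returns (X, column-blocks) where blocks maps effect name -> column
    indices (intercept block is '_const')."""
    n = len(bdf)
    mats = {}
    for f_ in between:
        levels = sorted(bdf[f_].unique())
        L = len(levels)
        C = np.zeros((n, L - 1))
        for j, lv in enumerate(levels[:-1]):
            C[:, j] = (bdf[f_] == lv).astype(float) \
                - (bdf[f_] == levels[-1]).astype(float)
        mats[f_] = C
    blocks = {"_const": [0]}
    cols = [np.ones((n, 1))]
    idx = 1
    for r in range(1, len(between) + 1):
        for combo in itertools.combinations(between, r):
            M = mats[combo[0]]
            for f_ in combo[1:]:
                M = np.einsum("ni,nj->nij", M, mats[f_]).reshape(n, -1)
            name = ":".join(combo)
            blocks[name] = list(range(idx, idx + M.shape[1]))
            cols.append(M)
            idx += M.shape[1]
    return np.hstack(cols), blocks


def _type3_ss(X: np.ndarray, blocks: dict, Y: np.ndarray) -> tuple[dict, float]:
    """Type-III sums of squares (pooled over columns of Y) for each
    effect block, plus the pooled residual SS."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    sse = float(np.sum(resid ** 2))
    ss = {}
    for name, cols in blocks.items():
        keep = [c for c in range(X.shape[1]) if c not in cols]
        Xr = X[:, keep]
        br, *_ = np.linalg.lstsq(Xr, Y, rcond=None)
        sse_r = float(np.sum((Y - Xr @ br) ** 2))
        ss[name] = max(sse_r - sse, 0.0)
    return ss, sse


def rm_anova(data: pd.DataFrame, dv: str, subject: str,
             within: list[str], between: list[str] | None = None
             ) -> pd.DataFrame:
    """Mixed-design ANOVA on cell means with GG-corrected p-values.

    ``data`` is long-format; it is first aggregated to one mean per
    subject x within-cell, and subjects missing any within cell are
    dropped listwise.  Returns one row per effect (all main effects and
    interactions of the within and between factors).
    """
    between = between or []
    agg = (data.groupby([subject] + within, observed=True)[dv]
           .mean().reset_index())
    wide = agg.pivot_table(index=subject, columns=within, values=dv)
    wide = wide.dropna(axis=0)
    if wide.shape[0] < 3:
        raise ValueError("need at least 3 complete subjects")
    # within-cell level structure, in the pivot's column order
    if len(within) == 1:
        cell_levels = [[c] for c in wide.columns]
    else:
        cell_levels = [list(c) for c in wide.columns]
    level_lists = [sorted(set(cl[i] for cl in cell_levels))
                   for i in range(len(within))]
    # between-factor values per subject (must be constant within subject)
    bdf = (data[[subject] + between].drop_duplicates()
           .set_index(subject).loc[wide.index].reset_index()
           if between else pd.DataFrame(index=wide.index).reset_index())
    X, blocks = _between_design(bdf, between)
    n_subj = wide.shape[0]
    df_resid_btw = n_subj - X.shape[1]
    if df_resid_btw <= 0:
        raise ValueError("too few subjects for the between design")

    Y = wide.to_numpy(float)
    results = []
    # iterate over subsets of within factors (incl. empty = between part)
    for r in range(len(within) + 1):
        for wsub in itertools.combinations(range(len(within)), r):
            # build orthonormal projection columns for this within effect
            K = np.ones((1, 1))
            d_eff = 1
            for i in range(len(within)):
                L = len(level_lists[i])
                Ci = (_orthonormal_contrasts(L) if i in wsub
                      else np.full((L, 1), 1.0 / np.sqrt(L)))
                K = np.kron(K, Ci) if K.size else Ci
            # map pivot cell order onto the kron ordering
            order = []
            for cl in cell_levels:
                pos = 0
                for i in range(len(within)):
                    pos = pos * len(level_lists[i]) \
                        + level_lists[i].index(cl[i])
                order.append(pos)
            Kfull = np.zeros((len(cell_levels), K.shape[1]))
            Kfull[np.arange(len(cell_levels))] = K[order]
            Z = Y @ Kfull  # subjects x d_eff contrast scores
            d_eff = Z.shape[1]
            ss, sse = _type3_ss(X, blocks, Z)
            df_err = d_eff * df_resid_btw
            wname = ":".join(within[i] for i in wsub)
            # GG epsilon from the contrast-score covariance (within only)
            if wsub:
                resid = Z - X @ np.linalg.lstsq(X, Z, rcond=None)[0]
                cov = (resid.T @ resid) / df_resid_btw
                eps = gg_epsilon(cov)
            else:
                eps = 1.0
            for bname, cols in blocks.items():
                if bname == "_const" and not wsub:
                    continue  # grand mean, not an effect
                df_num = d_eff * len(cols)
                label_parts = ([] if bname == "_const"
                               else bname.split(":"))
                label = ":".join(label_parts + ([wname] if wname else []))
                if not label:
                    continue
                F = (ss[bname] / df_num) / (sse / df_err) if sse > 0 else np.inf
                p = float(f_dist.sf(F, df_num, df_err))
                p_gg = float(f_dist.sf(F, df_num * eps, df_err * eps))
                peta = ss[bname] / (ss[bname] + sse) \
                    if (ss[bname] + sse) > 0 else np.nan
                results.append(AnovaResult(
                    effect=label, F=float(F), df_num=df_num, df_den=df_err,
                    ss_effect=ss[bname], ss_error=sse,
                    partial_eta_sq=peta, gg_epsilon=eps,
                    p_uncorrected=p, p_gg=p_gg if wsub else p))
    return pd.DataFrame([r.__dict__ for r in results])


def pointwise_functional_contrast(X: np.ndarray, grid: np.ndarray,
                                  factors: pd.DataFrame, subject: str,
                                  formula_rhs: str, term: str | None = None,
                                  q: float = 0.05,
                                  prune_lrt: bool = False) -> pd.DataFrame:
    """Pointwise mixed-model contrast along a common grid.

    At each grid point, ``value ~ formula_rhs`` is fitted with a random
    intercept per ``subject``; BH-FDR is applied across grid points
    within each fixed-effect term.  With ``prune_lrt`` the highest-order
    interaction terms are first tested by a likelihood-ratio test on the
    grid-averaged response and dropped when non-significant (a global
    pruning step, applied before the pointwise fits).
    """
    import statsmodels.formula.api as smf
    from scipy.stats import chi2

    X = np.asarray(X, dtype=float)
    df0 = factors.reset_index(drop=True).copy()
    rhs = formula_rhs
    if prune_lrt and "*" in rhs:
        df0["_y"] = X.mean(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = smf.mixedlm(f"_y ~ {rhs}", df0,
                               groups=df0[subject]).fit(reml=False)
            reduced_rhs = rhs.replace("*", "+")
            red = smf.mixedlm(f"_y ~ {reduced_rhs}", df0,
                              groups=df0[subject]).fit(reml=False)
        lr = 2 * (full.llf - red.llf)
        ddf = full.df_modelwc - red.df_modelwc
        if ddf > 0 and chi2.sf(max(lr, 0.0), ddf) > 0.05:
            rhs = reduced_rhs
    rows = []
    for g in range(X.shape[1]):
        df0["_y"] = X[:, g]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = smf.mixedlm(f"_y ~ {rhs}", df0,
                                  groups=df0[subject]).fit(reml=True)
            for name, est, p in zip(fit.fe_params.index, fit.fe_params,
                                    fit.pvalues[:len(fit.fe_params)]):
                if name == "Intercept":
                    continue
                rows.append({"grid": grid[g], "term": name,
                             "estimate": est, "p": p, "converged": True})
        except Exception:
            rows.append({"grid": grid[g], "term": "_failed",
                         "estimate": np.nan, "p": np.nan,
                         "converged": False})
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    out["significant"] = False
    for t in out["term"].unique():
        sel = (out["term"] == t) & out["p"].notna()
        if sel.any():
            padj, rej = bh_fdr(out.loc[sel, "p"].to_numpy(), q=q)
            out.loc[sel, "p_adj"] = padj
            out.loc[sel, "significant"] = rej
    if term is not None:
        out = out[out["term"].str.contains(term, regex=False)]
    return out
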