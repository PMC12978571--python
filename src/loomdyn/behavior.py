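"""Psychophysical models of judged time-to-collision.

Two candidate models relate judged to actual time-to-collision: a
linear baseline jTTC = a + b*aTTC and a Stevens power law
jTTC = alpha * aTTC**beta, where alpha captures overall over/under-
estimation and beta the nonlinearity (beta < 1 = temporal compression).
Both are fitted per participant x condition by least squares; AIC/BIC
under a shared Gaussian-likelihood convention decide the winner, and a
linear mixed-effects model tests treatment/sex/threat effects on the
fitted parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = ["PowerLawFit", "LinearFit", "fit_power_law", "fit_linear",
           "compare_models", "fit_all_subjects", "lme_on_parameters"]


@dataclass
class PowerLawFit:
    subject_id: str
    condition: str
    alpha: float
    beta: float
    sse: float
    r2: float
    aic: float
    bic: float
    n_trials: int
    converged: bool = True


@dataclass
class LinearFit:
    subject_id: str
    condition: str
    intercept: float
    slope: float
    sse: float
    r2: float
    aic: float
    bic: float
    n_trials: int


def _ic(sse: float, n: int, k: int = 2) -> tuple[float, float]:
    # Gaussian likelihood with sigma^2 profiled out; identical k for the
    # linear and power-law models so comparisons reduce to SSE.
    sse = max(sse, 1e-300)
    aic = n * np.log(sse / n) + 2 * k
    bic = n * np.log(sse / n) + k * np.log(n)
    return aic, bic


def _profiled_sse(beta: float, x: np.ndarray, y: np.ndarray
                  ) -> tuple[float, float]:
    """For fixed beta the optimal alpha is available in closed form:
    alpha*(beta) = sum(y x^beta) / sum(x^{2 beta})."""
    xb = x ** beta
    denom = float(xb @ xb)
    alpha = float(y @ xb) / denom if denom > 0 else 0.0
    resid = y - alpha * xb
    return float(resid @ resid), alpha


def fit_power_law(attc, jttc, subject_id: str = "", condition: str = "",
                  min_trials: int = 10,
                  beta_starts=(0.3, 0.5, 1.0, 1.5),
                  beta_bounds: tuple[float, float] = (1e-3, 5.0),
                  tol: float = 1e-10) -> PowerLawFit:
    """Least-squares power-law fit, alpha profiled out analytically and
    beta found by bounded scalar minimization from several starts."""
    x = np.asarray(attc, dtype=float)
    y = np.asarray(jttc, dtype=float)
    if len(x) < min_trials:
        raise ValueError(f"need >= {min_trials} trials, got {len(x)}")
    if np.any(y <= 0) or np.any(x <= 0):
        raise ValueError("power-law fitting requires positive jTTC and aTTC")

    best_beta, best_sse = None, np.inf
    lo, hi = beta_bounds
    starts = sorted(set(list(beta_starts) + [lo, hi]))
    converged = False
    for i in range(len(starts) - 1):
        res = minimize_scalar(lambda b: _profiled_sse(b, x, y)[0],
                              bounds=(starts[i], starts[i + 1]),
                              method="bounded",
                              options={"xatol": tol})
        if res.fun < best_sse:
            best_sse, best_beta = float(res.fun), float(res.x)
            converged = bool(res.success)
    sse, alpha = _profiled_sse(best_beta, x, y)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    aic, bic = _ic(sse, len(x))
    return PowerLawFit(subject_id=subject_id, condition=condition,
                       alpha=alpha, beta=best_beta, sse=sse, r2=r2,
                       aic=aic, bic=bic, n_trials=len(x),
                       converged=converged)


def fit_linear(attc, jttc, subject_id: str = "", condition: str = ""
               ) -> LinearFit:
    """Ordinary least squares jTTC = a + b*aTTC (closed form)."""
    x = np.asarray(attc, dtype=float)
    y = np.asarray(jttc, dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 trials")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: a single aTTC value")
    X = np.column_stack([np.ones(len(x)), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    aic, bic = _ic(sse, len(x))
    return LinearFit(subject_id=subject_id, condition=condition,
                     intercept=float(coef[0]), slope=float(coef[1]),
                     sse=sse, r2=r2, aic=aic, bic=bic, n_trials=len(x))


def compare_models(power: PowerLawFit, linear: LinearFit) -> dict:
    """AIC/BIC comparison of the two fits on the same trials; lower
    wins, ties go to the linear model (simpler interpretation)."""
    if power.n_trials != linear.n_trials:
        raise ValueError("fits must be computed on identical trials")
    d_aic = power.aic - linear.aic
    d_bic = power.bic - linear.bic
    winner = "power" if d_aic < 0 else "linear"
    return {"winner": winner, "delta_aic": d_aic, "delta_bic": d_bic}


def fit_all_subjects(trials: pd.DataFrame, min_trials: int = 10,
                     by_threat: bool = True) -> pd.DataFrame:
    """Per (subject x threat-condition) power-law and linear fits on
    included trials, returned as a tidy table."""
    df = trials
    if "included" in df.columns:
        df = df[df["included"]]
    cond_col = df["is_threat"].map({True: "threat", False: "non-threat"}) \
        if by_threat else pd.Series("all", index=df.index)
    rows = []
    for (sid, cond), g in df.groupby([df["subject_id"], cond_col]):
        if len(g) < min_trials:
            continue
        pf = fit_power_law(g["attc"], g["jttc"], subject_id=sid,
                           condition=cond, min_trials=min_trials)
        lf = fit_linear(g["attc"], g["jttc"], subject_id=sid,
                        condition=cond)
        cmp_ = compare_models(pf, lf)
        rows.append({
            "subject_id": sid, "condition": cond,
            "arm": g["arm"].iloc[0], "sex": g["sex"].iloc[0],
            "alpha": pf.alpha, "beta": pf.beta, "sse": pf.sse,
            "r2": pf.r2, "aic": pf.aic, "bic": pf.bic,
            "lin_intercept": lf.intercept, "lin_slope": lf.slope,
            "lin_sse": lf.sse, "lin_r2": lf.r2,
            "winner": cmp_["winner"], "delta_aic": cmp_["delta_aic"],
            "n_trials": pf.n_trials, "converged": pf.converged,
        })
    return pd.DataFrame(rows)


def lme_on_parameters(fits: pd.DataFrame, parameter: str = "beta",
                      reference_arm: str = "PLC") -> pd.DataFrame:
    """Mixed model on per-(subject x condition) parameter estimates:
    fixed effects Treatment + Sex + IsThreaten and their two-way
    interactions, random intercept per participant (REML).

    Returns the coefficient table (estimate, SE, z, p, CI bounds) plus
    a ``singular`` flag column.
    """
    import statsmodels.formula.api as smf

    if parameter not in fits.columns:
        raise ValueError(f"no column {parameter!r} in fits table")
    df = fits.copy()
    if "converged" in df.columns:
        df = df[df["converged"]]
    df["is_threat"] = (df["condition"] == "threat").astype(int)
    n_cond = df.groupby("subject_id")["condition"].nunique()
    if (n_cond < 2).all():
        raise ValueError("need >= 2 conditions per subject for a random "
                         "intercept to be identified")
    formula = (f"{parameter} ~ C(arm, Treatment('{reference_arm}')) * C(sex) "
               f"+ C(arm, Treatment('{reference_arm}')) * is_threat "
               f"+ C(sex) * is_threat")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["subject_id"])
        fit = model.fit(reml=True)
    singular = bool(np.any(np.diag(fit.cov_re) < 1e-10))
    fe = fit.fe_params
    se = fit.bse_fe
    table = pd.DataFrame({
        "term": fe.index,
        "estimate": fe.values,
        "se": se.values,
    })
    table["z"] = table["estimate"] / table["se"].replace(0, np.nan)
    from scipy.stats import norm
    table["p"] = 2 * norm.sf(np.abs(table["z"]))
    table["ci_low"] = table["estimate"] - 1.96 * table["se"]
    table["ci_high"] = table["estimate"] + 1.96 * table["se"]
    table["singular"] = singular
    return table
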