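"""Synthetic looming-task data with the statistical structure the
analysis pipeline assumes.

The generator produces, per subject: a randomized full-factorial trial
design, power-law behavioural responses with configurable arm/sex/threat
effects, event-locked pupil traces built from a mean function plus three
orthonormal eigenfunction components with condition-dependent scores,
and first-order Markov profile sequences drawn from per-arm transition
matrices.  Everything is driven by a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import PROFILE_LABELS, SimConfig
from .trajectory import warp_time

__all__ = [
    "PupilTrace", "eigenfunction_basis", "mean_function",
    "generate_design", "generate_behavior", "generate_pupil",
    "generate_state_sequences", "generate_dataset",
]


@dataclass
class PupilTrace:
    """One trial's pupil samples on a regular time grid (ms from trial
    start, 0 = fixation onset)."""

    trial_id: str
    t: np.ndarray
    d: np.ndarray
    valid: np.ndarray
    units: str = "diameter_mm"
    baseline_mean: float | None = None
    corrected: bool = False
    excluded: bool = False
    exclude_reason: str | None = None
    meta: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else np.nan


# ----------------------------------------------------------------------
# Functional basis
# ----------------------------------------------------------------------

_FINE_GRID = np.linspace(0.0, 1.0, 401)


def _raw_templates(u: np.ndarray) -> np.ndarray:
    """Three qualitative pupil-response shapes on normalized time.

    1. early steep rise followed by a plateau (sustained vigilance);
    2. initial inhibition with later strong activation (proactive
       engagement);
    3. early peak, mid-period trough, late recovery (cognitive shift).
    The analytic forms are a repository convention; only the qualitative
    shape and orthonormalized span matter downstream.
    """
    f1 = 1.0 - np.exp(-6.0 * u)
    f2 = np.tanh(6.0 * (u - 0.55))
    f3 = np.cos(2.0 * np.pi * (u - 0.12))
    return np.stack([f1, f2, f3])


def eigenfunction_basis(grid: np.ndarray | None = None) -> np.ndarray:
    """Orthonormal (trapezoid quadrature on [0, 1]) 3 x G basis built by
    Gram-Schmidt from the qualitative templates."""
    u = _FINE_GRID if grid is None else np.asarray(grid, dtype=float)
    du = np.diff(u)
    w = np.empty(len(u))  # trapezoid weights
    w[0], w[-1] = du[0] / 2, du[-1] / 2
    w[1:-1] = (du[:-1] + du[1:]) / 2
    raw = _raw_templates(u)
    basis = []
    for f in raw:
        g = f.copy()
        for b in basis:
            g = g - np.sum(w * g * b) * b
        nrm = np.sqrt(np.sum(w * g * g))
        basis.append(g / nrm)
    return np.stack(basis)


def mean_function(u: np.ndarray) -> np.ndarray:
    """Grand-mean baseline-corrected response (mm): saturating task-evoked
    dilation reaching ~0.35 mm."""
    u = np.asarray(u, dtype=float)
    return 0.35 * (1.0 - np.exp(-4.0 * u))


# ----------------------------------------------------------------------
# Design and behaviour
# ----------------------------------------------------------------------

def _subject_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    subs = []
    for arm in config.arms:
        for i in range(config.n_subjects_per_arm):
            subs.append({
                "subject_id": f"{arm}{i + 1:03d}",
                "arm": arm,
                "sex": "F" if rng.random() < 0.5 else "M",
            })
    return pd.DataFrame(subs)


def generate_design(config: SimConfig) -> pd.DataFrame:
    """Full-factorial randomized trial table, one row per trial.

    Each subject receives ``repetitions`` copies of every factorial cell
    (aTTC x category x initial size), shuffled by the seed and split
    into ``n_blocks`` consecutive blocks.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    subjects = _subject_table(config, rng)

    cells = [(a, c, t, f)
             for a in config.attc_levels
             for c, t in config.categories.items()
             for f in config.initial_size_fracs]
    rows = []
    for _, s in subjects.iterrows():
        order = np.repeat(np.arange(len(cells)), config.repetitions)
        rng.shuffle(order)
        n = len(order)
        per_block = int(np.ceil(n / config.n_blocks))
        for pos, ci in enumerate(order):
            attc, cat, is_threat, frac = cells[ci]
            rows.append({
                "subject_id": s.subject_id,
                "arm": s.arm,
                "sex": s.sex,
                "block": pos // per_block + 1,
                "trial_index": pos + 1,
                "category": cat,
                "is_threat": bool(is_threat),
                "attc": float(attc),
                "initial_frac": float(frac),
            })
    df = pd.DataFrame(rows)
    df["trial_id"] = df["subject_id"] + "_t" + df["trial_index"].astype(str)
    return df


def _effective_params(design: pd.DataFrame, config: SimConfig
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial (alpha_eff, beta_eff) composed from the baselines plus
    additive shifts keyed ``arm:<label>``, ``sex:<label>`` or ``threat``."""
    alpha = np.full(len(design), config.alpha_baseline)
    beta = np.full(len(design), config.beta_baseline)
    for effects, target in ((config.alpha_effects, alpha),
                            (config.beta_effects, beta)):
        for key, shift in effects.items():
            if key == "threat":
                mask = design["is_threat"].to_numpy()
            elif key.startswith("arm:"):
                mask = (design["arm"] == key[4:]).to_numpy()
            elif key.startswith("sex:"):
                mask = (design["sex"] == key[4:]).to_numpy()
            else:
                raise ValueError(f"unknown effect key: {key!r}")
            target[mask] += shift
    if (alpha <= 0).any() or (beta <= 0).any():
        raise ValueError("configured effects drive alpha or beta <= 0")
    return alpha, beta


def generate_behavior(design: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Add a jTTC column: jTTC = alpha_eff * aTTC**beta_eff * exp(eps),
    eps ~ N(0, noise_sd_log_jttc).  Multiplicative log-normal noise keeps
    jTTC positive and matches the log-scale clustering downstream."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    alpha, beta = _effective_params(design, config)
    eps = rng.normal(0.0, config.noise_sd_log_jttc, size=len(design))
    out = design.copy()
    out["jttc"] = alpha * design["attc"].to_numpy() ** beta * np.exp(eps)
    out["alpha_true"] = alpha
    out["beta_true"] = beta
    return out


# ----------------------------------------------------------------------
# Pupil traces
# ----------------------------------------------------------------------

def _score_means(row: pd.Series, config: SimConfig) -> np.ndarray:
    mu = np.zeros(3)
    for key, shift in config.score_mean_effects.items():
        if key == "threat":
            hit = bool(row["is_threat"])
        elif key.startswith("arm:"):
            hit = row["arm"] == key[4:]
        elif key.startswith("sex:"):
            hit = row["sex"] == key[4:]
        else:
            raise ValueError(f"unknown effect key: {key!r}")
        if hit:
            mu = mu + np.asarray(shift, dtype=float)
    return mu


def generate_pupil(design: pd.DataFrame, config: SimConfig
                   ) -> list[PupilTrace]:
    """Event-locked pupil traces on a regular ``sample_ms`` grid.

    Trace duration = 300 ms baseline + jTTC.  From stimulus onset the
    signal equals tonic level + grand mean + score-weighted eigenfunctions
    evaluated at the trial's warped time, plus AR(1) noise; blink gaps
    (invalid runs with zeroed samples) are injected at a Poisson rate.
    Requires a ``jttc`` column (from :func:`generate_behavior`).
    """
    if "jttc" not in design.columns:
        raise ValueError("design must carry jTTC; run generate_behavior first")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    phi_fine = eigenfunction_basis()
    traces = []
    for _, row in design.iterrows():
        keypress = config.baseline_ms + 1000.0 * row["jttc"]
        if keypress <= config.baseline_ms:
            raise ValueError("trace shorter than the baseline window")
        t = np.arange(0.0, keypress + config.sample_ms / 2, config.sample_ms)
        tonic = config.tonic_mm + config.tonic_offsets.get(row["arm"], 0.0)
        d = np.full(len(t), tonic)
        scores = rng.normal(_score_means(row, config),
                            np.asarray(config.score_sds))
        post = t >= config.baseline_ms
        u = warp_time(np.clip(t[post], config.baseline_ms, keypress),
                      keypress_ms=keypress)
        signal = mean_function(u)
        for j in range(3):
            signal = signal + scores[j] * np.interp(u, _FINE_GRID, phi_fine[j])
        d[post] += signal
        # AR(1) noise initialized at its stationary distribution
        if config.noise_sd > 0:
            innov_sd = config.noise_sd * np.sqrt(1.0 - config.ar1_coef ** 2)
            e = rng.normal(0.0, innov_sd, size=len(t))
            e[0] = rng.normal(0.0, config.noise_sd)
            noise = lfilter([1.0], [1.0, -config.ar1_coef], e)
            d += noise
        valid = np.ones(len(t), dtype=bool)
        n_blinks = rng.poisson(config.blink_rate)
        for _ in range(n_blinks):
            dur = rng.uniform(*config.blink_dur_ms)
            onset = rng.uniform(0.0, max(t[-1] - dur, 1.0))
            gap = (t >= onset) & (t < onset + dur)
            valid[gap] = False
            d[gap] = 0.0
        traces.append(PupilTrace(
            trial_id=row["trial_id"], t=t, d=d, valid=valid,
            meta={"keypress_ms": keypress, "scores_true": scores,
                  "arm": row["arm"], "tonic_true": tonic}))
    return traces


# ----------------------------------------------------------------------
# State sequences
# ----------------------------------------------------------------------

def _stationary(P: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def generate_state_sequences(config: SimConfig,
                             n_trials: int | None = None) -> pd.DataFrame:
    """Per-subject profile sequences from the arm's transition matrix.

    The first state is drawn from the chain's stationary distribution;
    subsequent states by row sampling.  Returns a long DataFrame with
    columns subject_id, arm, trial_index, state.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    subjects = _subject_table(config, np.random.default_rng(config.seed))
    n = n_trials if n_trials is not None else config.trials_per_subject
    rows = []
    for _, s in subjects.iterrows():
        P = config.transition_matrices[s.arm]
        pi = _stationary(P)
        states = np.empty(n, dtype=int)
        states[0] = rng.choice(8, p=pi)
        # row sampling via inverse CDF on uniforms
        u = rng.random(n - 1)
        cum = np.cumsum(P, axis=1)
        for i in range(1, n):
            states[i] = np.searchsorted(cum[states[i - 1]], u[i - 1])
        for i, st in enumerate(states):
            rows.append({"subject_id": s.subject_id, "arm": s.arm,
                         "trial_index": i + 1,
                         "state": PROFILE_LABELS[st]})
    return pd.DataFrame(rows)


def generate_dataset(config: SimConfig, with_pupil: bool = True
                     ) -> dict:
    """Convenience wrapper: design + behaviour (+ pupil traces + state
    sequences) under one seed."""
    design = generate_design(config)
    trials = generate_behavior(design, config)
    out = {"trials": trials}
    if with_pupil:
        out["pupil"] = generate_pupil(trials, config)
    out["states"] = generate_state_sequences(config)
    return out


def pupil_traces_to_frame(traces: list[PupilTrace]) -> pd.DataFrame:
    """Long-format CSV-ready sample table (trial_id, t_ms, d, valid)."""
    parts = [pd.DataFrame({"trial_id": tr.trial_id, "t_ms": tr.t,
                           "d": tr.d, "valid": tr.valid.astype(int)})
             for tr in traces]
    return pd.concat(parts, ignore_index=True)


def pupil_traces_from_frame(df: pd.DataFrame, units: str = "diameter_mm"
                            ) -> list[PupilTrace]:
    traces = []
    for tid, g in df.groupby("trial_id", sort=False):
        g = g.sort_values("t_ms")
        traces.append(PupilTrace(
            trial_id=str(tid), t=g["t_ms"].to_numpy(float),
            d=g["d"].to_numpy(float),
            valid=g["valid"].to_numpy().astype(bool), units=units))
    return traces
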