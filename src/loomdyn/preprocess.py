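"""Behavioural and pupillary preprocessing.

Behaviour: approach-velocity computation, five-level physical stimulus
velocity (PSV) binning, and per-subject +/-5 SD outlier flagging of
judged time-to-collision.  Pupil: area-to-diameter conversion, artifact
cleaning with blink padding and interpolation, 10-ms downsampling,
pre-stimulus baseline correction and phase-window means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synth import PupilTrace
from .trajectory import STIM_ONSET_MS, STIM_OFFSET_MS


# ----------------------------------------------------------------------
# Stimulus dynamics
# ----------------------------------------------------------------------

def compute_velocity(screen_width_px: float, initial_width_px: float,
                     attc_s: float) -> float:
    """Approach velocity in px/s: (screen width - initial width) / aTTC."""
    if attc_s <= 0:
        raise ValueError("aTTC must be positive")
    if not 0 <= initial_width_px <= screen_width_px:
        raise ValueError("initial width must lie within the screen")
    return (screen_width_px - initial_width_px) / attc_s


def psv_edges(velocities) -> np.ndarray:
    """Six boundaries of the equal-width five-interval PSV partition of
    the observed velocity range.

    For the standard design (1280 px screen, 20%/30% initial sizes,
    aTTC 3-5 s) the exact edges are 179.2, 211.62..., 244.05...,
    276.48, 308.90..., 341.33... px/s; the conventional printed form
    truncates each to one decimal (211.6, 244.0, 276.4, 308.8, 341.3).
    """
    v = np.asarray(velocities, dtype=float)
    return np.linspace(v.min(), v.max(), 6)


def assign_psv(velocity: float, edges) -> int:
    """PSV level 1-5 for a velocity, left-closed/right-open intervals
    with the last interval closed on the right."""
    edges = np.asarray(edges, dtype=float)
    if edges.shape != (6,) or np.any(np.diff(edges) <= 0):
        raise ValueError("need 6 strictly increasing edges")
    if velocity < edges[0] or velocity > edges[-1]:
        raise ValueError(f"velocity {velocity} outside "
                         f"[{edges[0]}, {edges[-1]}]")
    if velocity == edges[-1]:
        return 5
    return int(np.searchsorted(edges, velocity, side="right"))


def add_velocity_bins(trials: pd.DataFrame, screen_width_px: float = 1280.0
                      ) -> pd.DataFrame:
    """Derive velocity and PSV bin columns for a trial table."""
    out = trials.copy()
    w0 = out["initial_frac"].to_numpy() * screen_width_px
    out["velocity"] = (screen_width_px - w0) / out["attc"].to_numpy()
    edges = psv_edges(out["velocity"])
    out["psv_bin"] = [assign_psv(v, edges) for v in out["velocity"]]
    return out


# ----------------------------------------------------------------------
# Behavioural filtering
# ----------------------------------------------------------------------

def filter_jttc_outliers(trials: pd.DataFrame, n_sd: float = 5.0
                         ) -> pd.DataFrame:
    """Flag trials whose jTTC deviates more than ``n_sd`` SD from the
    subject's mean.

    Two-stage: technically bad trials (missing/non-positive jTTC) are
    excluded first; the per-subject mean/SD is then computed over the
    remaining trials only.  A zero SD flags nothing.
    """
    out = trials.copy()
    if "included" not in out.columns:
        out["included"] = True
        out["exclude_reason"] = ""
    bad = ~np.isfinite(out["jttc"]) | (out["jttc"] <= 0)
    out.loc[bad, "included"] = False
    out.loc[bad, "exclude_reason"] = "technical"
    for _, idx in out[out["included"]].groupby("subject_id").groups.items():
        vals = out.loc[idx, "jttc"]
        if len(vals) < 2:
            continue
        mu, sd = vals.mean(), vals.std(ddof=1)
        if sd == 0:
            continue
        flag = (vals - mu).abs() > n_sd * sd
        out.loc[idx[flag], "included"] = False
        out.loc[idx[flag], "exclude_reason"] = "jttc_outlier"
    return out


# ----------------------------------------------------------------------
# Pupil conversion and cleaning
# ----------------------------------------------------------------------

def convert_area_to_diameter(values, alpha_scale: float = 1.0,
                             distance_mm: float = 1.0,
                             units_in: str = "area_px"):
    """Convert recorded pupil area to diameter, d = alpha * L * phi(area).

    The visual angle phi subtended by the pupil is proportional to the
    square root of its imaged area, so the map reduces to
    ``alpha_scale * distance_mm * sqrt(area)`` with any residual
    proportionality constant folded into ``alpha_scale``.  Diameter
    input passes through unchanged.
    """
    if alpha_scale <= 0 or distance_mm <= 0:
        raise ValueError("scaling factor and distance must be positive")
    v = np.asarray(values, dtype=float)
    if units_in == "diameter_mm":
        return v.copy()
    if units_in != "area_px":
        raise ValueError(f"unknown units {units_in!r}")
    if np.any(v < 0):
        raise ValueError("negative pupil area")
    return alpha_scale * distance_mm * np.sqrt(v)


def _interp_invalid(t: np.ndarray, d: np.ndarray, valid: np.ndarray
                    ) -> np.ndarray:
    out = d.astype(float).copy()
    if valid.all():
        return out
    if not valid.any():
        return out
    out[~valid] = np.interp(t[~valid], t[valid], d[valid])
    return out


def clean_trace(trace: PupilTrace, n_sd: float = 5.0,
                pad_ms: float = 100.0,
                plausible: tuple[float, float] | None = (1.5, 9.0),
                max_interp_frac: float = 0.30) -> PupilTrace:
    """Remove signal loss, blinks, implausible values and +/-5 SD
    outliers from a raw regular-rate trace.

    Invalid/zero runs are padded by ``pad_ms`` on each side and linearly
    interpolated; the plausibility band applies only for mm-calibrated
    traces.  The sample count never changes.  Trials with more than
    ``max_interp_frac`` of samples interpolated are flagged for
    exclusion rather than repaired.
    """
    t, d = trace.t, trace.d.astype(float).copy()
    valid = trace.valid.copy() & (d != 0) & np.isfinite(d)
    # pad invalid runs to swallow blink on/offsets
    if pad_ms > 0 and not valid.all():
        bad_idx = np.flatnonzero(~valid)
        keep = np.ones(len(t), dtype=bool)
        for i in bad_idx:
            keep &= ~(np.abs(t - t[i]) <= pad_ms)
        valid &= keep
    if plausible is not None and trace.units == "diameter_mm":
        lo, hi = plausible
        valid &= (d >= lo) & (d <= hi)
    # statistical outliers vs the trial mean of currently valid samples
    if valid.sum() >= 2:
        mu = d[valid].mean()
        sd = d[valid].std(ddof=1)
        if sd > 0:
            valid &= ~(np.abs(d - mu) > n_sd * sd)
    frac_bad = 1.0 - valid.mean()
    cleaned = _interp_invalid(t, d, valid)
    out = PupilTrace(trial_id=trace.trial_id, t=t.copy(), d=cleaned,
                     valid=np.ones(len(t), dtype=bool), units=trace.units,
                     meta={**trace.meta, "frac_interpolated": frac_bad})
    if frac_bad > max_interp_frac:
        out.excluded = True
        out.exclude_reason = "low_quality"
        out.valid = valid
    return out


def downsample(trace: PupilTrace, bin_ms: float = 10.0) -> PupilTrace:
    """Average valid samples into ``bin_ms`` bins; bin timestamp is the
    bin start.  Empty bins carry an invalid flag."""
    t, d, valid = trace.t, trace.d, trace.valid
    if len(t) > 1 and (t[1] - t[0]) > bin_ms:
        raise ValueError("input rate is below the requested bin rate")
    idx = np.floor(t / bin_ms).astype(int)
    n_bins = idx.max() + 1
    counts = np.bincount(idx[valid], minlength=n_bins)
    sums = np.bincount(idx[valid], weights=d[valid], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return PupilTrace(trial_id=trace.trial_id,
                      t=np.arange(n_bins) * bin_ms, d=means,
                      valid=counts > 0, units=trace.units,
                      meta=dict(trace.meta))


def baseline_correct(trace: PupilTrace,
                     window_ms: tuple[float, float] = (0.0, STIM_ONSET_MS)
                     ) -> PupilTrace:
    """Subtract the mean pre-stimulus diameter from every sample.

    Idempotent: a corrected trace has zero baseline mean, so a second
    application subtracts zero.
    """
    window = ((trace.t >= window_ms[0]) & (trace.t < window_ms[1])
              & trace.valid)
    if not window.any():
        out = PupilTrace(trial_id=trace.trial_id, t=trace.t.copy(),
                         d=trace.d.copy(), valid=trace.valid.copy(),
                         units=trace.units, meta=dict(trace.meta))
        out.excluded = True
        out.exclude_reason = "no_baseline"
        return out
    base = float(np.nanmean(trace.d[window]))
    out = PupilTrace(trial_id=trace.trial_id, t=trace.t.copy(),
                     d=trace.d - base, valid=trace.valid.copy(),
                     units=trace.units, baseline_mean=base, corrected=True,
                     meta=dict(trace.meta))
    return out


# ----------------------------------------------------------------------
# Phase windows
# ----------------------------------------------------------------------

def phase_windows(jttc_s: float, min_trial_ms: float = 2300.0
                  ) -> dict[str, tuple[float, float]]:
    """Three half-open analysis windows (ms, absolute trial time).

    Stimulus presentation [300, 1300), early imagination (first 500 ms
    after stimulus offset) and late imagination (last 500 ms before the
    key press at 300 + 1000*jTTC ms).  Trials shorter than
    ``min_trial_ms`` cannot cover all three windows and are rejected.
    """
    keypress = STIM_ONSET_MS + 1000.0 * jttc_s
    if keypress < min_trial_ms:
        raise ValueError("short trial")
    return {
        "stimulus": (STIM_ONSET_MS, STIM_OFFSET_MS),
        "early_imagination": (STIM_OFFSET_MS, STIM_OFFSET_MS + 500.0),
        "late_imagination": (keypress - 500.0, keypress),
    }


def phase_means(trace: PupilTrace, jttc_s: float,
                min_trial_ms: float = 2300.0) -> dict[str, float]:
    """Mean corrected diameter in each phase window of one trial."""
    wins = phase_windows(jttc_s, min_trial_ms=min_trial_ms)
    out = {}
    for name, (a, b) in wins.items():
        sel = (trace.t >= a) & (trace.t < b) & trace.valid
        out[name] = float(np.nanmean(trace.d[sel])) if sel.any() else np.nan
    return out
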