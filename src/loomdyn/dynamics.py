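"""First-order Markov-chain analysis of profile sequences.

Per-subject profile sequences (trial presentation order) are pooled
within treatment group into an 8x8 transition-count matrix; the
row-normalized matrix, its stationary distribution, block entropy of
overlapping state trigrams, chi-squared occupancy contrasts with
adjusted standardized residuals, and subject-level bootstrap confidence
intervals together characterize the group's state dynamics.  Transitions
never span subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .config import PROFILE_LABELS
from .stats import bh_fdr

__all__ = ["TransitionModel", "estimate_transitions",
           "stationary_distribution", "occupancy_contrast",
           "sequence_entropy", "bootstrap_cis", "compare_groups",
           "within_group_significant_transitions", "entropy_contrast",
           "sequences_from_frame"]

N_STATES = len(PROFILE_LABELS)
_STATE_IDX = {s: i for i, s in enumerate(PROFILE_LABELS)}


@dataclass
class TransitionModel:
    counts: np.ndarray
    P: np.ndarray
    pi: np.ndarray | None = None
    entropy_bits: float | None = None
    unobserved_rows: list[int] = field(default_factory=list)
    residuals_z: np.ndarray | None = None
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None


def sequences_from_frame(states: pd.DataFrame) -> list[np.ndarray]:
    """Per-subject integer state sequences in trial order."""
    seqs = []
    for _, g in states.groupby("subject_id", sort=False):
        g = g.sort_values("trial_index")
        seqs.append(np.array([_STATE_IDX[s] for s in g["state"]]))
    return seqs


def _count_matrix(seq: np.ndarray, n_states: int = N_STATES) -> np.ndarray:
    if len(seq) < 2:
        return np.zeros((n_states, n_states))
    pair = seq[:-1] * n_states + seq[1:]
    return np.bincount(pair, minlength=n_states ** 2).reshape(n_states,
                                                              n_states)


def _row_normalize(counts: np.ndarray) -> tuple[np.ndarray, list[int]]:
    rows = counts.sum(axis=1)
    unobserved = [int(i) for i in np.flatnonzero(rows == 0)]
    P = np.divide(counts, rows[:, None],
                  out=np.zeros_like(counts, dtype=float),
                  where=rows[:, None] > 0)
    P[rows == 0] = 0.0
    return P, unobserved


def estimate_transitions(sequences: list[np.ndarray],
                         n_states: int = N_STATES) -> TransitionModel:
    """Pooled transition counts over within-subject consecutive pairs
    and the row-normalized transition matrix.  Rows for states never
    visited are flagged, not imputed."""
    sequences = [np.asarray(s, dtype=int) for s in sequences]
    if not sequences or all(len(s) < 2 for s in sequences):
        raise ValueError("need at least one sequence of length >= 2")
    counts = sum(_count_matrix(s, n_states) for s in sequences)
    P, unobserved = _row_normalize(counts)
    model = TransitionModel(counts=counts, P=P, unobserved_rows=unobserved)
    try:
        model.pi = stationary_distribution(P)
    except ValueError:
        model.pi = None
    try:
        model.entropy_bits = sequence_entropy(sequences, n_states=n_states)
    except ValueError:  # sequences shorter than the block length
        model.entropy_bits = None
    return model


def stationary_distribution(P: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Normalized left eigenvector of the row-stochastic P at eigenvalue
    1; raises when that eigenvalue is not simple."""
    P = np.asarray(P, dtype=float)
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("matrix is not row-stochastic")
    w, v = np.linalg.eig(P.T)
    near_one = np.abs(w - 1.0) < tol
    if near_one.sum() != 1:
        raise ValueError("non-unique stationary distribution")
    pi = np.real(v[:, int(np.flatnonzero(near_one)[0])])
    pi = np.abs(pi)
    return pi / pi.sum()


def adjusted_residuals(table: np.ndarray) -> np.ndarray:
    """Adjusted (margin-corrected) standardized residuals of a
    contingency table: (O-E)/sqrt(E*(1-rowshare)*(1-colshare))."""
    O = np.asarray(table, dtype=float)
    n = O.sum()
    rows = O.sum(axis=1, keepdims=True)
    cols = O.sum(axis=0, keepdims=True)
    E = rows @ cols / n
    denom = np.sqrt(E * (1 - rows / n) * (1 - cols / n))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(denom > 0, (O - E) / denom, 0.0)
    return z


def occupancy_contrast(table: np.ndarray) -> dict:
    """Pearson chi-squared test of a state-occupancy x group table with
    per-cell adjusted residuals; df = (rows-1)(cols-1)."""
    O = np.asarray(table, dtype=float)
    if np.any(O.sum(axis=0) == 0) or np.any(O.sum(axis=1) == 0):
        raise ValueError("empty margin in the contingency table")
    chi2, p, dof, expected = chi2_contingency(O, correction=False)
    if np.any(expected < 1):
        raise ValueError("expected counts below 1; pool states or groups")
    z = adjusted_residuals(O)
    return {"chi2": float(chi2), "df": int(dof), "p": float(p),
            "expected": expected, "residuals_z": z,
            "flagged": np.abs(z) > 1.96}


def sequence_entropy(sequences: list[np.ndarray], block_len: int = 3,
                     n_states: int = N_STATES) -> float:
    """Shannon entropy (bits) of the empirical distribution of
    overlapping length-``block_len`` blocks pooled within the group.
    Blocks never span subjects."""
    if block_len < 1:
        raise ValueError("block length must be >= 1")
    counts: dict[int, int] = {}
    for seq in sequences:
        seq = np.asarray(seq, dtype=int)
        if len(seq) < block_len:
            continue
        code = np.zeros(len(seq) - block_len + 1, dtype=np.int64)
        for i in range(block_len):
            code = code * n_states + seq[i:len(seq) - block_len + 1 + i]
        for c in code:
            counts[int(c)] = counts.get(int(c), 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no block of the requested length")
    p = np.array(list(counts.values()), dtype=float) / total
    return float(-(p * np.log2(p)).sum() + 0.0)


def _per_subject_counts(sequences: list[np.ndarray],
                        n_states: int = N_STATES) -> np.ndarray:
    return np.stack([_count_matrix(np.asarray(s, int), n_states)
                     for s in sequences])


def bootstrap_cis(sequences: list[np.ndarray], statistic=None,
                  n_boot: int = 1000, seed: int = 0,
                  n_states: int = N_STATES
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Percentile 95% bootstrap CIs resampling whole subjects.

    With the default statistic (the transition matrix), per-subject
    count matrices are resampled and summed, so replicates are cheap;
    cells unobserved in a replicate are treated as missing there.
    ``statistic(list_of_sequences) -> array`` may be supplied instead.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 subjects to bootstrap")
    rng = np.random.default_rng(seed)
    n = len(sequences)
    if statistic is None:
        cmats = _per_subject_counts(sequences, n_states)
        reps = np.full((n_boot, n_states, n_states), np.nan)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            counts = cmats[idx].sum(axis=0)
            rows = counts.sum(axis=1)
            P = np.divide(counts, rows[:, None],
                          out=np.full_like(counts, np.nan, dtype=float),
                          where=rows[:, None] > 0)
            reps[b] = P
    else:
        reps = np.stack([
            np.asarray(statistic([sequences[i]
                                  for i in rng.integers(0, n, n)]),
                       dtype=float)
            for b in range(n_boot)])
    lo = np.nanpercentile(reps, 2.5, axis=0)
    hi = np.nanpercentile(reps, 97.5, axis=0)
    return lo, hi


def compare_groups(seqs_a: list[np.ndarray], seqs_b: list[np.ndarray],
                   n_boot: int = 1000, seed: int = 0, fdr: bool = False,
                   n_states: int = N_STATES) -> pd.DataFrame:
    """Per-cell transition-probability differences P_A - P_B with
    bootstrap CIs (independent subject resampling per group); a cell is
    significant when its CI excludes zero.  ``fdr=True`` additionally
    applies BH correction to bootstrap two-sided p-values across the 64
    cells."""
    rng = np.random.default_rng(seed)
    ma = estimate_transitions(seqs_a, n_states)
    mb = estimate_transitions(seqs_b, n_states)
    ca = _per_subject_counts(seqs_a, n_states)
    cb = _per_subject_counts(seqs_b, n_states)

    def boot(cmats):
        idx = rng.integers(0, len(cmats), len(cmats))
        counts = cmats[idx].sum(axis=0)
        rows = counts.sum(axis=1)
        P = np.divide(counts, rows[:, None],
                      out=np.full_like(counts, np.nan, dtype=float),
                      where=rows[:, None] > 0)
        return P

    diffs = np.stack([boot(ca) - boot(cb) for _ in range(n_boot)])
    lo = np.nanpercentile(diffs, 2.5, axis=0)
    hi = np.nanpercentile(diffs, 97.5, axis=0)
    point = ma.P - mb.P
    incomparable = (np.isin(np.arange(n_states), ma.unobserved_rows)[:, None]
                    | np.isin(np.arange(n_states),
                              mb.unobserved_rows)[:, None])
    incomparable = np.broadcast_to(incomparable, point.shape)
    rows = []
    with np.errstate(invalid="ignore"):
        pboot = 2 * np.minimum(np.nanmean(diffs > 0, axis=0),
                               np.nanmean(diffs < 0, axis=0))
    pboot = np.clip(pboot, 1.0 / n_boot, 1.0)
    for i in range(n_states):
        for j in range(n_states):
            rows.append({
                "from": PROFILE_LABELS[i] if n_states == N_STATES else i,
                "to": PROFILE_LABELS[j] if n_states == N_STATES else j,
                "diff": float(point[i, j]),
                "ci_low": float(lo[i, j]), "ci_high": float(hi[i, j]),
                "p_boot": float(pboot[i, j]),
                "incomparable": bool(incomparable[i, j]),
                "significant": bool((lo[i, j] > 0) or (hi[i, j] < 0))
                and not bool(incomparable[i, j]),
            })
    out = pd.DataFrame(rows)
    if fdr:
        ok = ~out["incomparable"]
        padj, rej = bh_fdr(out.loc[ok, "p_boot"].to_numpy())
        out.loc[ok, "p_adj"] = padj
        out.loc[ok, "significant_fdr"] = rej
    return out


def within_group_significant_transitions(model: TransitionModel,
                                         attractor_threshold: float = 0.45,
                                         q: float = 0.05) -> dict:
    """Transition pathways deviating from independence within a group.

    Adjusted residuals of the 8x8 transition-count table are converted
    to two-sided normal p-values and BH-corrected across the 64 cells;
    attractors are states whose self-transition probability exceeds the
    threshold.  A 0.10 visibility cutoff is reported for plotting only.
    """
    from scipy.stats import norm
    z = adjusted_residuals(model.counts)
    p = 2 * norm.sf(np.abs(z))
    padj, rej = bh_fdr(p.ravel(), q=q)
    padj = padj.reshape(z.shape)
    sig = rej.reshape(z.shape)
    attractors = [PROFILE_LABELS[i] for i in range(len(model.P))
                  if model.P[i, i] > attractor_threshold]
    edges = []
    for i in range(len(model.P)):
        for j in range(len(model.P)):
            edges.append({"from": PROFILE_LABELS[i], "to": PROFILE_LABELS[j],
                          "P": float(model.P[i, j]),
                          "z": float(z[i, j]),
                          "p_adj": float(padj[i, j]),
                          "significant": bool(sig[i, j]),
                          "visible": bool(model.P[i, j] > 0.10)})
    return {"edges": edges, "attractors": attractors,
            "residuals_z": z, "p_adj": padj, "significant": sig}


def entropy_contrast(groups: dict[str, list[np.ndarray]],
                     block_len: int = 3, n_boot: int = 1000,
                     seed: int = 0) -> pd.DataFrame:
    """Group block entropies with subject-bootstrap 95% CIs and all
    pairwise differences."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    rng = np.random.default_rng(seed)
    ents, boots = {}, {}
    for name, seqs in groups.items():
        ents[name] = sequence_entropy(seqs, block_len=block_len)
        n = len(seqs)
        boots[name] = np.array([
            sequence_entropy([seqs[i] for i in rng.integers(0, n, n)],
                             block_len=block_len)
            for _ in range(n_boot)])
    rows = []
    for name in groups:
        lo, hi = np.percentile(boots[name], [2.5, 97.5])
        rows.append({"kind": "group", "a": name, "b": "",
                     "value": ents[name], "ci_low": float(lo),
                     "ci_high": float(hi)})
    names = list(groups)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d = boots[a] - boots[b]
            lo, hi = np.percentile(d, [2.5, 97.5])
            rows.append({"kind": "difference", "a": a, "b": b,
                         "value": ents[a] - ents[b],
                         "ci_low": float(lo), "ci_high": float(hi)})
    return pd.DataFrame(rows)
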