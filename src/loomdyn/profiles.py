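"""Two-level clustering of trials into behavioral-pupillary profiles.

Level 1 partitions trials by k-means (k = 2) on log-transformed judged
time-to-collision into early (E) and late (L) responders.  Level 2 runs
k-means on standardized FPCA scores within each behavioral subgroup,
choosing k by the joint rank of the Calinski-Harabasz index and the
silhouette coefficient.  Profile labels (E1..., L1...) are ordered by
descending cluster size within subgroup.  Stability is quantified by
bootstrap adjusted Rand indices and by fold-held-out centroid
classification accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr
from sklearn.cluster import KMeans
from sklearn.metrics import (adjusted_rand_score, calinski_harabasz_score,
                             silhouette_score)

from .stats import bh_fdr

__all__ = ["cluster_level1", "cluster_level2", "two_level_profiles",
           "bootstrap_stability", "cross_validate",
           "proportion_correlations", "pc_sign_summary", "StabilityReport"]


@dataclass
class StabilityReport:
    bootstrap_mean: float
    bootstrap_sd: float
    cv_accuracy_mean: float
    cv_accuracy_sd: float
    n_boot: int
    n_folds: int
    n_skipped: int = 0
    ch_scores: dict = field(default_factory=dict)
    silhouette_scores: dict = field(default_factory=dict)


def _kmeans(X: np.ndarray, k: int, seed: int, n_init: int = 50) -> KMeans:
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    km.fit(X)
    return km


def cluster_level1(log_jttc, seed: int = 0) -> tuple[np.ndarray, np.ndarray, float]:
    """k-means (k=2) on 1-D log jTTC.

    Returns (labels 'E'/'L', centroids sorted ascending, silhouette).
    The cluster with the smaller centroid is always E, so labels are
    invariant to input order and k-means internal numbering.
    """
    x = np.asarray(log_jttc, dtype=float).reshape(-1, 1)
    if np.unique(x).size < 2:
        raise ValueError("degenerate: all log jTTC values identical")
    km = _kmeans(x, 2, seed)
    cents = km.cluster_centers_.ravel()
    early = int(np.argmin(cents))
    labels = np.where(km.labels_ == early, "E", "L")
    sil = float(silhouette_score(x, km.labels_)) if len(x) > 2 else np.nan
    return labels, np.sort(cents), sil


def cluster_level2(scores: np.ndarray, k_range: tuple[int, int] = (2, 6),
                   seed: int = 0, min_per_k: int = 5
                   ) -> tuple[np.ndarray, int, dict, dict, np.ndarray]:
    """k-means over standardized scores with k chosen by the maximal
    rank-sum of Calinski-Harabasz and silhouette (ties -> smaller k).

    Returns (labels 1..k ordered by descending cluster size, chosen k,
    CH dict, silhouette dict, centroids in label order on the
    standardized scale).
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    k_lo, k_hi = k_range
    if len(X) < k_hi * min_per_k:
        k_hi = max(k_lo, len(X) // min_per_k)
        if len(X) < k_lo * min_per_k:
            raise ValueError("subgroup too small to cluster")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    ch, sil, fits = {}, {}, {}
    for k in range(k_lo, k_hi + 1):
        km = _kmeans(Xs, k, seed)
        if len(np.unique(km.labels_)) < k:
            continue
        ch[k] = float(calinski_harabasz_score(Xs, km.labels_))
        sil[k] = float(silhouette_score(Xs, km.labels_))
        fits[k] = km
    if not fits:
        raise ValueError("no valid clustering in the k range")
    ks = sorted(fits)
    ch_rank = {k: r for r, k in enumerate(sorted(ks, key=lambda k: ch[k]))}
    sil_rank = {k: r for r, k in enumerate(sorted(ks, key=lambda k: sil[k]))}
    best_k = max(ks, key=lambda k: (ch_rank[k] + sil_rank[k], -k))
    km = fits[best_k]
    # relabel by descending cluster size -> 1..k
    sizes = np.bincount(km.labels_, minlength=best_k)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(best_k, dtype=int)
    remap[order] = np.arange(1, best_k + 1)
    labels = remap[km.labels_]
    centroids = km.cluster_centers_[order]
    return labels, best_k, ch, sil, centroids


def two_level_profiles(trials: pd.DataFrame, scores: np.ndarray,
                       k_range: tuple[int, int] = (2, 6), seed: int = 0
                       ) -> pd.DataFrame:
    """Full two-level assignment: E/L on log jTTC, then score clusters
    within each subgroup.  Returns the trial table with level1, level2
    and profile_label columns."""
    out = trials.reset_index(drop=True).copy()
    scores = np.asarray(scores, dtype=float)
    if len(out) != len(scores):
        raise ValueError("trials and scores are misaligned")
    lab1, _, _ = cluster_level1(np.log(out["jttc"].to_numpy()), seed=seed)
    out["level1"] = lab1
    out["level2"] = 0
    for grp in ("E", "L"):
        sel = out["level1"] == grp
        lab2, *_ = cluster_level2(scores[sel.to_numpy()], k_range=k_range,
                                  seed=seed)
        out.loc[sel, "level2"] = lab2
    out["profile_label"] = out["level1"] + out["level2"].astype(str)
    return out


def _match_labels(ref: np.ndarray, pred: np.ndarray) -> float:
    """Agreement after optimal cluster-label matching (Hungarian)."""
    ref_lv = np.unique(ref)
    pred_lv = np.unique(pred)
    cm = np.zeros((len(ref_lv), len(pred_lv)))
    for i, a in enumerate(ref_lv):
        for j, b in enumerate(pred_lv):
            cm[i, j] = np.sum((ref == a) & (pred == b))
    ri, ci = linear_sum_assignment(-cm)
    return float(cm[ri, ci].sum() / len(ref))


def bootstrap_stability(X: np.ndarray, ref_labels: np.ndarray,
                        n_boot: int = 1000, seed: int = 0) -> tuple[float, float, int]:
    """Bootstrap adjusted Rand index of a reference k-means clustering.

    Each replicate refits k-means (same k) on a resample and compares
    its assignment of the resampled points against the reference labels
    on the points present in the resample.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    ref_labels = np.asarray(ref_labels)
    k = len(np.unique(ref_labels))
    rng = np.random.default_rng(seed)
    aris, skipped = [], 0
    for b in range(n_boot):
        idx = rng.integers(0, len(X), len(X))
        try:
            km = _kmeans(X[idx], k, int(rng.integers(2**31)), n_init=5)
        except Exception:
            skipped += 1
            continue
        uniq = np.unique(idx)
        pred = km.predict(X[uniq])
        aris.append(adjusted_rand_score(ref_labels[uniq], pred))
    return float(np.mean(aris)), float(np.std(aris, ddof=1)), skipped


def cross_validate(X: np.ndarray, ref_labels: np.ndarray, n_folds: int = 5,
                   seed: int = 0) -> tuple[float, float, int]:
    """k-fold held-out accuracy of the clustering.

    Per fold: k-means on the training portion, held-out points assigned
    to the nearest training centroid, accuracy scored against the
    reference labels after exact optimal label matching.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    ref_labels = np.asarray(ref_labels)
    k = len(np.unique(ref_labels))
    if len(X) < n_folds * k:
        raise ValueError("too few points for the requested folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(X))
    folds = np.array_split(perm, n_folds)
    accs, skipped = [], 0
    for f_ in range(n_folds):
        test = folds[f_]
        train = np.concatenate([folds[i] for i in range(n_folds) if i != f_])
        km = _kmeans(X[train], k, int(rng.integers(2**31)), n_init=10)
        if len(np.unique(km.labels_)) < k:
            skipped += 1
            continue
        d = ((X[test][:, None, :] - km.cluster_centers_[None]) ** 2).sum(-1)
        pred = d.argmin(axis=1)
        accs.append(_match_labels(ref_labels[test], pred))
    return float(np.mean(accs)), float(np.std(accs, ddof=1)), skipped


def proportion_correlations(assignments: pd.DataFrame, fits: pd.DataFrame,
                            q: float = 0.05) -> pd.DataFrame:
    """Pearson correlations between each subject's early/late trial
    proportions and their fitted power-law parameters, BH-corrected
    within the family of four tests."""
    props = (assignments.groupby("subject_id")["level1"]
             .apply(lambda s: (s == "E").mean()).rename("prop_E"))
    params = fits.groupby("subject_id")[["alpha", "beta"]].mean()
    df = params.join(props, how="inner")
    df["prop_L"] = 1.0 - df["prop_E"]
    rows = []
    for sub in ("E", "L"):
        for par in ("alpha", "beta"):
            x = df[f"prop_{sub}"]
            if x.nunique() < 2:
                rows.append({"subgroup": sub, "parameter": par,
                             "r": np.nan, "p": np.nan, "n": len(df)})
                continue
            r, p = pearsonr(x, df[par])
            rows.append({"subgroup": sub, "parameter": par,
                         "r": float(r), "p": float(p), "n": len(df)})
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    if ok.any():
        padj, rej = bh_fdr(out.loc[ok, "p"].to_numpy(), q=q)
        out.loc[ok, "p_adj"] = padj
        out.loc[ok, "significant"] = rej
    return out


def pc_sign_summary(assignments: pd.DataFrame, scores: np.ndarray,
                    zero_band: float = 0.2) -> pd.DataFrame:
    """Per-profile sign pattern of standardized mean component scores:
    '+', '-' or '~0' when |mean z| < ``zero_band``."""
    scores = np.asarray(scores, dtype=float)
    sd = scores.std(axis=0)
    sd[sd == 0] = 1.0
    z = (scores - scores.mean(axis=0)) / sd
    rows = []
    for prof, idx in assignments.groupby("profile_label").groups.items():
        pos = assignments.index.get_indexer(idx)
        mz = z[pos].mean(axis=0)
        rows.append({"profile": prof,
                     **{f"PC{j + 1}": ("~0" if abs(m) < zero_band
                                       else "+" if m > 0 else "-")
                        for j, m in enumerate(mz)},
                     **{f"PC{j + 1}_meanz": m for j, m in enumerate(mz)}})
    return pd.DataFrame(rows).sort_values("profile").reset_index(drop=True)
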