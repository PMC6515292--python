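"""Laplacian-corrected Naive Bayesian benchmarking of activity signatures.

The classifier scores a compound by summing per-feature weights

    w_i = ln[(A_i + 1) / (T_i * p + 1)]

where ``A_i`` counts training actives containing feature i, ``T_i``
counts all training compounds containing it, and ``p`` is the prior
active fraction. The +1 Laplacian shrinkage pulls rare features toward
the prior (a feature never seen in training contributes exactly zero),
and as counts grow with a fixed enrichment ratio r = P(active|i)/p the
weight tends to ln(r).

Leave-one-out cross validation is computed in closed form: removing
compound c changes only the prior and the counts of c's own features, so
the held-out score of every active (inactive) compound is a single sparse
matrix product with an actives-adjusted (inactives-adjusted) weight
vector — exactly equal to retraining without c.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import rankdata

from .datamodel import SignatureMatrix, ValidationError

log = logging.getLogger(__name__)


@dataclass
class NBModel:
    """Trained Laplacian-corrected Naive Bayes classifier."""

    p_base: float
    #: feature -> (A_i, T_i)
    counts: dict = field(repr=False)

    def weight(self, feature) -> float:
        a, t = self.counts.get(feature, (0, 0))
        return math.log((a + 1) / (t * self.p_base + 1))

    def score(self, features) -> float:
        """Sum of weights over the compound's features; unseen features add 0."""
        return sum(self.weight(f) for f in features if f in self.counts)

    def weight_table(self) -> pd.DataFrame:
        rows = [
            {"feature": f, "A": a, "T": t, "weight": self.weight(f)}
            for f, (a, t) in self.counts.items()
        ]
        return pd.DataFrame(rows, columns=["feature", "A", "T", "weight"])


def train_nb(features: list[frozenset], labels: np.ndarray, category: str = "") -> NBModel:
    """Train on per-compound feature sets and binary labels.

    Requires at least one active and one inactive compound; a single-class
    input is an error naming the category.
    """
    y = np.asarray(labels, dtype=int)
    if len(y) != len(features):
        raise ValidationError("features and labels differ in length")
    n_active = int(y.sum())
    if n_active == 0 or n_active == len(y):
        raise ValidationError(
            f"cannot train on a single class (category={category or 'unnamed'}; "
            f"{n_active} of {len(y)} active)"
        )
    counts: dict = {}
    for feats, yi in zip(features, y):
        for f in feats:
            a, t = counts.get(f, (0, 0))
            counts[f] = (a + yi, t + 1)
    return NBModel(p_base=n_active / len(y), counts=counts)


def _feature_matrix(features: list[frozenset]) -> tuple[sparse.csr_matrix, list]:
    """Binary incidence matrix (compounds x features) over the feature union."""
    index: dict = {}
    indptr = [0]
    indices = []
    for feats in features:
        for f in feats:
            indices.append(index.setdefault(f, len(index)))
        indptr.append(len(indices))
    mat = sparse.csr_matrix(
        (np.ones(len(indices), dtype=np.float64), indices, indptr),
        shape=(len(features), len(index)),
    )
    return mat, list(index)


def loo_cv_scores(features: list[frozenset], labels: np.ndarray) -> np.ndarray:
    """Held-out NB score for every compound via count decrement.

    Equivalent to retraining without each compound in turn. When holding a
    compound out leaves a single-class training set, its score falls back
    to a clamped prior (p bounded away from 0/1 by 1/(2(n-1))) and the
    event is logged.
    """
    y = np.asarray(labels, dtype=float)
    n = len(y)
    if n < 3:
        raise ValidationError("leave-one-out needs at least 3 compounds")
    n_active = y.sum()
    if n_active == 0 or n_active == n:
        raise ValidationError("leave-one-out needs both classes present")
    X, _ = _feature_matrix(features)
    a_f = np.asarray(X.multiply(y[:, None]).sum(axis=0)).ravel()
    t_f = np.asarray(X.sum(axis=0)).ravel()

    eps = 1.0 / (2.0 * (n - 1))
    p_wo_active = (n_active - 1) / (n - 1)
    p_wo_inactive = n_active / (n - 1)
    for label, p in (("active", p_wo_active), ("inactive", p_wo_inactive)):
        if not 0.0 < p < 1.0:
            log.warning(
                "holding out an %s compound leaves a single-class set; "
                "scoring with clamped prior", label,
            )
    p_wo_active = min(max(p_wo_active, eps), 1 - eps)
    p_wo_inactive = min(max(p_wo_inactive, eps), 1 - eps)

    # holding out an active: A_f -> A_f - 1 for its own features (so A_f+1 -> A_f),
    # T_f -> T_f - 1; only features present in the held-out compound are summed,
    # and those have A_f >= 1, so the masked log is never used
    w_active = np.log(np.where(a_f > 0, a_f, 1.0)) - np.log((t_f - 1) * p_wo_active + 1.0)
    w_inactive = np.log(a_f + 1.0) - np.log((t_f - 1) * p_wo_inactive + 1.0)
    s_active = X @ w_active
    s_inactive = X @ w_inactive
    return np.where(y == 1, s_active, s_inactive)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC as the Mann-Whitney pair statistic.

    Fraction of (active, inactive) pairs where the active scores higher,
    with ties credited 0.5; identical to trapezoidal integration of the
    empirical ROC curve.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_active = int(y.sum())
    n_inactive = len(y) - n_active
    if n_active == 0 or n_inactive == 0:
        raise ValidationError("ROC undefined with a single class")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_active * (n_active + 1) / 2) / (n_active * n_inactive))


def enrichment(scores: np.ndarray, labels: np.ndarray, fraction: float) -> float:
    """Enrichment factor of actives in the top-scoring fraction.

    ``(actives in top-k / k) / (actives / n)`` with ``k = ceil(f * n)``;
    ranking ties are broken by original order (stable sort), documented as
    the deterministic convention.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_active = int(y.sum())
    if n_active == 0:
        raise ValidationError("enrichment undefined with no actives")
    n = len(y)
    k = math.ceil(fraction * n)
    order = np.argsort(-s, kind="stable")
    top_actives = int(y[order[:k]].sum())
    return (top_actives / k) / (n_active / n)


@dataclass
class RandomizedControl:
    """Label-permutation null: mean LOO ROC and the per-repetition values."""

    mean_roc: float
    per_rep: np.ndarray


def randomized_control(
    features: list[frozenset],
    labels: np.ndarray,
    reps: int = 10,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> RandomizedControl:
    """Mean LOO ROC after uniformly permuting labels (active count preserved)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    y = np.asarray(labels, dtype=int)
    rocs = np.empty(reps)
    for r in range(reps):
        perm = rng.permutation(y)
        rocs[r] = roc_auc(loo_cv_scores(features, perm), perm)
    return RandomizedControl(mean_roc=float(rocs.mean()), per_rep=rocs)


def benchmark_column(
    features: list[frozenset],
    labels: np.ndarray,
    randomized_reps: int = 10,
    rng: np.random.Generator | None = None,
) -> dict:
    scores = loo_cv_scores(features, labels)
    out = {
        "n": len(labels),
        "n_active": int(np.asarray(labels).sum()),
        "roc": roc_auc(scores, labels),
        "ef1": enrichment(scores, labels, 0.01),
        "ef5": enrichment(scores, labels, 0.05),
        "ef10": enrichment(scores, labels, 0.10),
    }
    if randomized_reps > 0:
        out["roc_randomized"] = randomized_control(
            features, labels, reps=randomized_reps, rng=rng
        ).mean_roc
    else:
        out["roc_randomized"] = np.nan
    return out


def benchmark_all(
    matrices: dict[str, dict[str, SignatureMatrix]],
    feature_sets: dict[str, frozenset],
    randomized_reps: int = 10,
    min_actives: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """LOO ROC/enrichment benchmark for every signature column.

    One row per (dense set, category, column). Columns with fewer than
    ``min_actives`` actives (or inactives) are reported with a skip
    reason; compounds without features are dropped with a logged count.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for set_label, cats in matrices.items():
        for category, mat in cats.items():
            cids = [c for c in mat.values.index if c in feature_sets]
            missing = len(mat.values) - len(cids)
            if missing:
                log.warning(
                    "%s/%s: dropped %d compounds without structures",
                    set_label, category, missing,
                )
            feats = [feature_sets[c] for c in cids]
            sub = mat.values.loc[cids]
            for col in mat.values.columns:
                labels = sub[col].to_numpy()
                base = {"set": set_label, "category": category, "column": col}
                n_active = int(labels.sum())
                n_inactive = len(labels) - n_active
                if n_active < min_actives or n_inactive < min_actives:
                    rows.append({
                        **base, "n": len(labels), "n_active": n_active,
                        "roc": np.nan, "ef1": np.nan, "ef5": np.nan, "ef10": np.nan,
                        "roc_randomized": np.nan,
                        "skip_reason": f"needs >= {min_actives} per class",
                    })
                    continue
                res = benchmark_column(feats, labels, randomized_reps=randomized_reps, rng=rng)
                rows.append({**base, **res, "skip_reason": ""})
    return pd.DataFrame(rows)
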