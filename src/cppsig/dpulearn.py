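"""Deterministic positive-unlabeled learning (dPULearn).

Given a feature matrix with a small positive class, a handful of known
negatives, and a large unlabeled pool, dPULearn selects "reliable
negatives" from the pool without any randomness: the feature space is
compressed by PCA, per-component selection quotas are allocated
proportionally to explained variance, and for each retained component
the unlabeled samples farthest (1-D absolute distance) from the mean
coordinate of the positive class are selected.  Re-running the procedure
always yields the identical selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC


@dataclass(frozen=True)
class PULearnConfig:
    """dPULearn parameters.

    n_components
        Either an integer PC count, or a variance fraction in (0, 1]:
        the smallest number of PCs whose cumulative explained-variance
        ratio reaches the fraction (default 0.8).
    standardize
        z-score feature columns before PCA (default on; PCA is
        scale-sensitive even for features bounded in [0, 1]).
    """

    n_components: Union[int, float] = 0.8
    standardize: bool = True

    def __post_init__(self):
        nc = self.n_components
        if isinstance(nc, int):
            if nc < 1:
                raise ValueError("integer n_components must be >= 1")
        elif not (0 < nc <= 1):
            raise ValueError("fractional n_components must be in (0, 1]")


@dataclass
class PUResult:
    selected_ids: List[str]
    per_pc_quota: List[int]
    explained_variance_ratio: List[float]
    positive_mean_per_pc: List[float]


def balance_quota(n_pos: int, n_neg_known: int) -> int:
    """Negatives still needed to balance positives against known negatives."""
    if n_neg_known > n_pos:
        raise ValueError(
            f"already {n_neg_known} negatives for {n_pos} positives; "
            "nothing to identify"
        )
    if n_neg_known < 0:
        raise ValueError("negative counts must be >= 0")
    return n_pos - n_neg_known


def largest_remainder_quotas(ratios: Sequence[float], total: int) -> List[int]:
    """Allocate ``total`` proportionally to ``ratios`` (earlier index wins ties)."""
    ratios = np.asarray(ratios, dtype=float)
    if ratios.sum() <= 0:
        raise ValueError("ratios must have positive sum")
    exact = ratios / ratios.sum() * total
    floors = np.floor(exact).astype(int)
    remainder = total - floors.sum()
    # distribute leftovers by descending fractional part, earlier PC first
    order = sorted(range(len(ratios)), key=lambda i: (-(exact[i] - floors[i]), i))
    for i in order[:remainder]:
        floors[i] += 1
    return floors.tolist()


def identify_negatives(
    matrix: pd.DataFrame,
    labels: pd.Series,
    n_needed: int,
    cfg: PULearnConfig = PULearnConfig(),
) -> PUResult:
    """Select ``n_needed`` reliable negatives from the unlabeled pool.

    ``labels`` maps sample id to one of ``positive`` / ``negative`` /
    ``unlabeled``.  PCA is fit on all samples.  Per retained PC (in order
    of explained variance), the not-yet-selected unlabeled samples with
    the largest |PC value - mean PC value of positives| are picked, up to
    that PC's quota; distance ties are broken by the smaller sample id.
    """
    labels = labels.reindex(matrix.index)
    pos_mask = (labels == "positive").to_numpy()
    unl_mask = (labels == "unlabeled").to_numpy()
    if pos_mask.sum() < 2:
        raise ValueError("need >= 2 positive samples")
    if n_needed < 0:
        raise ValueError("n_needed must be >= 0")
    if unl_mask.sum() < n_needed:
        raise ValueError(
            f"unlabeled pool ({unl_mask.sum()}) smaller than requested "
            f"selection ({n_needed}); shortfall {n_needed - unl_mask.sum()}"
        )
    X = matrix.to_numpy(dtype=float)
    X = np.where(np.isnan(X), np.nanmean(X, axis=0), X)
    if cfg.standardize:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    pca = PCA(svd_solver="full", random_state=0)
    Z = pca.fit_transform(X)
    evr = pca.explained_variance_ratio_
    if isinstance(cfg.n_components, int):
        m = min(cfg.n_components, Z.shape[1])
    else:
        m = int(np.searchsorted(np.cumsum(evr), cfg.n_components - 1e-12) + 1)
        m = min(m, Z.shape[1])
    if n_needed == 0:
        return PUResult([], [0] * m, evr[:m].tolist(), [])
    quotas = largest_remainder_quotas(evr[:m], n_needed)
    ids = matrix.index.to_numpy()
    pos_means = [float(Z[pos_mask, j].mean()) for j in range(m)]
    chosen: List[str] = []
    chosen_set = set()
    for j in range(m):
        if quotas[j] == 0:
            continue
        dist = np.abs(Z[:, j] - pos_means[j])
        cands = [
            (  # farthest first; ties by smaller sample id
                -dist[i],
                str(ids[i]),
            )
            for i in np.nonzero(unl_mask)[0]
            if ids[i] not in chosen_set
        ]
        cands.sort()
        for _, sid in cands[: quotas[j]]:
            chosen.append(sid)
            chosen_set.add(sid)
    return PUResult(
        selected_ids=chosen,
        per_pc_quota=quotas,
        explained_variance_ratio=evr[:m].tolist(),
        positive_mean_per_pc=pos_means,
    )


def pu_benchmark(
    matrix: pd.DataFrame,
    labels: pd.Series,
    cfg: PULearnConfig = PULearnConfig(),
    n_needed: Optional[int] = None,
    n_repeats: int = 20,
    seed: int = 0,
) -> Dict[str, object]:
    """Compare dPULearn negatives with uniformly random negatives.

    A support vector machine is scored by stratified 5-fold CV balanced
    accuracy on positives + selected negatives.  The random-negative
    draws (seeded) are compared with the deterministic dPULearn point
    value by a two-sided one-sample t-test.
    """
    labels = labels.reindex(matrix.index)
    n_pos = int((labels == "positive").sum())
    n_neg = int((labels == "negative").sum())
    if n_needed is None:
        n_needed = balance_quota(n_pos, n_neg)
    res = identify_negatives(matrix, labels, n_needed, cfg)

    def score(neg_ids: Sequence[str]) -> float:
        keep = labels.index[(labels == "positive") | (labels == "negative")].tolist()
        keep += list(neg_ids)
        X = matrix.loc[keep].to_numpy(dtype=float)
        X = np.where(np.isnan(X), 0.0, X)
        y = (labels.reindex(keep) == "positive").astype(int).to_numpy()
        cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        return float(
            cross_val_score(SVC(), X, y, cv=cv, scoring="balanced_accuracy").mean()
        )

    dpul_score = score(res.selected_ids)
    rng = np.random.default_rng(seed)
    pool = labels.index[labels == "unlabeled"].to_numpy()
    random_scores = np.array(
        [
            score(rng.choice(pool, size=n_needed, replace=False))
            for _ in range(n_repeats)
        ]
    )
    t, p = stats.ttest_1samp(random_scores, dpul_score)
    return {
        "dpulearn_score": dpul_score,
        "random_mean": float(random_scores.mean()),
        "random_sd": float(random_scores.std(ddof=1)),
        "random_scores": random_scores.tolist(),
        "t_statistic": float(t),
        "p_value": float(p),
        "selected_ids": res.selected_ids,
    }
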