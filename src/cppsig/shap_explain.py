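"""Per-feature and per-residue explanation of prediction scores.

SHAP values are computed with the exact tree explainer (``treeshap``)
for the tree-based model types only, retrained on the complete training
dataset over several seeded rounds; per-sample, per-feature values are
averaged across models and rounds.  The *feature impact* of a training
protein is its average SHAP row normalized by the sum of absolute
values (signs preserved, absolute values summing to 1).

For a protein that is absent from the training data, *fuzzy labeling*
includes it in training with a label that flips between rounds: it is
labeled positive in ``floor(score x n_rounds)`` of the rounds (the
first rounds, deterministically) and negative otherwise, so that the
resulting SHAP value sum tracks its prediction score.

Per-residue explanation distributes each feature's impact equally over
its resolved positions in the fixed TMD-JMD reference frame, mirroring
the CPP profile convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import treeshap
from .cpp_core import Feature
from .ml_pipeline import ModelSpec, default_registry


@dataclass
class ImpactResult:
    sample_ids: List[str]
    feature_ids: List[str]
    shap: np.ndarray  # (n_samples, n_features) mean SHAP values
    base_value: float

    @property
    def shap_value_sum(self) -> np.ndarray:
        """Base value plus summed feature impacts, per sample."""
        return self.base_value + self.shap.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.shap, index=self.sample_ids, columns=self.feature_ids)

    def row(self, sample_id: str) -> pd.Series:
        return self.to_frame().loc[sample_id]


def _tree_specs(registry: Optional[Mapping[str, ModelSpec]]) -> List[ModelSpec]:
    registry = registry if registry is not None else default_registry()
    specs = [s for s in registry.values() if s.tree]
    if not specs:
        raise ValueError("registry contains no tree-based models")
    return specs


def mean_shap(models: Sequence[object], X: pd.DataFrame) -> ImpactResult:
    """Average exact SHAP values of tree models over a shared feature space.

    All models must be tree-based (probability output equal to an average
    of leaf class frequencies); anything else raises ``TypeError``.
    """
    if not models:
        raise ValueError("need at least one model")
    for m in models:
        if not treeshap.is_tree_model(m):
            raise TypeError(
                f"{type(m).__name__} is not a tree model; only tree-based "
                "models are explained"
            )
    Xv = X.fillna(X.mean()).to_numpy(dtype=float)
    phi = np.zeros((X.shape[0], X.shape[1]))
    base = 0.0
    for m in models:
        p, b = treeshap.shap_values(m, Xv)
        phi += p
        base += b
    return ImpactResult(
        sample_ids=[str(i) for i in X.index],
        feature_ids=list(X.columns),
        shap=phi / len(models),
        base_value=base / len(models),
    )


def explain_dataset(
    X: pd.DataFrame,
    y: Sequence[int],
    registry: Optional[Mapping[str, ModelSpec]] = None,
    n_rounds: int = 5,
    seed_base: int = 0,
) -> ImpactResult:
    """Retrain the tree model types per round on the full dataset and
    average their exact SHAP values across models and rounds."""
    specs = _tree_specs(registry)
    y = np.asarray(y, dtype=int)
    Xv = X.fillna(X.mean())
    models = []
    for r in range(n_rounds):
        for spec in specs:
            models.append(spec.factory(seed_base + r).fit(Xv.to_numpy(), y))
    return mean_shap(models, Xv)


def additivity_residual(model, X: pd.DataFrame) -> float:
    """Max |base + sum(SHAP) - predict_proba| over samples, for one model."""
    Xv = X.fillna(X.mean()).to_numpy(dtype=float)
    phi, base = treeshap.shap_values(model, Xv)
    pred = model.predict_proba(Xv)[:, 1]
    return float(np.max(np.abs(base + phi.sum(axis=1) - pred)))


def normalize_impacts(row: Sequence[float]) -> Tuple[np.ndarray, bool]:
    """Divide each value by the sum of absolute values (signs preserved).

    Returns the normalized row and a degenerate flag; an all-zero row is
    returned unchanged with the flag set.
    """
    row = np.asarray(row, dtype=float)
    denom = np.abs(row).sum()
    if denom == 0:
        return row.copy(), True
    return row / denom, False


def shap_feature_importance(impact: ImpactResult) -> pd.DataFrame:
    """Per-feature mean |SHAP| over samples, with percentage of total."""
    imp = np.abs(impact.shap).mean(axis=0)
    total = imp.sum()
    pct = imp / total * 100 if total > 0 else np.zeros_like(imp)
    return pd.DataFrame(
        {"importance": imp, "importance_pct": pct}, index=impact.feature_ids
    )


def fuzzy_positive_rounds(score: float, n_rounds: int) -> int:
    """floor(score x n_rounds): rounds in which the protein is labeled positive."""
    if not (0 <= score <= 1):
        raise ValueError("score must be in [0, 1]")
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    return int(math.floor(score * n_rounds + 1e-9))


def fuzzy_schedule(score: float, n_rounds: int) -> List[int]:
    """Per-round labels (1/0); the positive labels fill the first rounds."""
    k = fuzzy_positive_rounds(score, n_rounds)
    return [1] * k + [0] * (n_rounds - k)


def fuzzy_shap(
    X: pd.DataFrame,
    y: pd.Series,
    protein_id: str,
    protein_features: pd.Series,
    score: float,
    registry: Optional[Mapping[str, ModelSpec]] = None,
    n_rounds: int = 25,
    seed_base: int = 0,
) -> ImpactResult:
    """Fuzzy-labeled SHAP explanation of one unlabeled protein.

    The protein joins the training dataset with a per-round label from
    :func:`fuzzy_schedule`; the tree model types are retrained each round
    and the protein's SHAP values averaged over models and rounds.
    """
    if protein_id in set(map(str, y.index)):
        raise ValueError(
            f"{protein_id} is already labeled; use mean_shap/explain_dataset"
        )
    specs = _tree_specs(registry)
    schedule = fuzzy_schedule(score, n_rounds)
    X_all = pd.concat([X, protein_features.to_frame(protein_id).T])
    X_all = X_all.fillna(X_all.mean())
    x_row = X_all.loc[[protein_id]]
    phi = np.zeros(X.shape[1])
    base = 0.0
    n_models = 0
    for r, label in enumerate(schedule):
        y_all = np.concatenate([np.asarray(y, dtype=int), [label]])
        for spec in specs:
            m = spec.factory(seed_base + r).fit(X_all.to_numpy(), y_all)
            p, b = treeshap.shap_values(m, x_row.to_numpy(dtype=float))
            phi += p[0]
            base += b
            n_models += 1
    return ImpactResult(
        sample_ids=[protein_id],
        feature_ids=list(X.columns),
        shap=(phi / n_models)[None, :],
        base_value=base / n_models,
    )


def explanation_tables(
    impact_row: pd.Series,
    features: Sequence[Feature],
    frame_len: int = 40,
    top: int = 15,
) -> Dict[str, pd.DataFrame]:
    """Ranking table, per-residue impact profile, and heatmap tables.

    ``impact_row`` maps feature id to impact; ``features`` supply
    positions, mean differences, and subcategories.  The profile
    distributes each feature's impact equally over its positions, so the
    profile total equals the summed impact of the mapped features.
    """
    by_id = {f.feature_id: f for f in features}
    rows = []
    for fid, imp in impact_row.items():
        f = by_id.get(fid)
        if f is None:
            continue
        rows.append(
            {
                "feature_id": fid,
                "impact": float(imp),
                "abs_impact": abs(float(imp)),
                "sign": "+" if imp >= 0 else "-",
                "subcategory": f.subcategory,
                "category": f.category,
                "mean_dif": f.mean_dif,
                "positions": ",".join(map(str, f.positions)),
            }
        )
    ranking = (
        pd.DataFrame(rows)
        .sort_values(["abs_impact", "feature_id"], ascending=[False, True])
        .reset_index(drop=True)
    )
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    profile = np.zeros(frame_len)
    heat_imp: Dict[Tuple[str, int], float] = {}
    heat_dif: Dict[Tuple[str, int], List[float]] = {}
    for r in rows:
        f = by_id[r["feature_id"]]
        if not f.positions:
            continue
        share = r["impact"] / len(f.positions)
        for p in f.positions:
            if 1 <= p <= frame_len:
                profile[p - 1] += share
                key = (f.subcategory, p)
                heat_imp[key] = heat_imp.get(key, 0.0) + share
                heat_dif.setdefault(key, []).append(f.mean_dif)
    profile_df = pd.DataFrame(
        {"position": np.arange(1, frame_len + 1), "impact": profile}
    )
    heat_rows = [
        {
            "subcategory": sc,
            "position": p,
            "impact": heat_imp[(sc, p)],
            "mean_dif": float(np.mean(heat_dif[(sc, p)])),
        }
        for (sc, p) in sorted(heat_imp)
    ]
    return {
        "ranking": ranking.head(top),
        "ranking_full": ranking,
        "profile": profile_df,
        "heatmap": pd.DataFrame(heat_rows),
    }
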