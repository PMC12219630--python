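"""Monte-Carlo ensemble training, score aggregation, and evaluation.

Substrate prediction uses 10 classification model types — four
tree-based (decision tree, random forest, extra trees, bagged trees),
two linear (logistic regression, SGD logistic), one kernel-based (RBF
SVM), one neural network (MLP), and two boosting ensembles (AdaBoost,
gradient boosting).  Training runs ``n_rounds`` (default 25) seeded
Monte-Carlo rounds; each round draws a stratified 80/20 split, performs
iterative feature elimination and small-grid hyperparameter selection by
5-fold cross-validation on the training split, and records held-out
predictions.  The default configuration therefore fits 25 x 10 = 250
final models.

Prediction scores are mean positive-class probabilities over models;
for proteins that were part of the training data, only rounds in which
the protein was held out contribute (out-of-fold discipline).  Scores
from several dataset/annotation "approaches" are aggregated as mean and
sample standard deviation, and mapped to confidence classes
(HC substrate >= 0.8, LC substrate >= 0.5, LC non-substrate > 0.2,
HC non-substrate <= 0.2).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import (
    LeaveOneOut,
    StratifiedKFold,
    cross_val_predict,
    cross_val_score,
    train_test_split,
)
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

RELEVANCE_FACTORS = (
    "new_pathway_link",
    "new_disease_link",
    "mutated_tmd_jmd",
    "new_protein_family",
    "dissimilar_tmd_jmd",
)

CONFIDENCE_CLASSES = (
    "HC substrate",
    "LC substrate",
    "LC non-substrate",
    "HC non-substrate",
)


@dataclass(frozen=True)
class ModelSpec:
    name: str
    factory: Callable[[int], object]  # seed -> unfitted estimator
    grid: Mapping[str, Sequence] = field(default_factory=dict)
    tree: bool = False  # flagged for importance / SHAP use
    role: str = ""


def default_registry() -> Dict[str, ModelSpec]:
    """The 10-model registry: 4 tree, 2 linear, 1 kernel, 1 neural, 2 ensemble."""
    specs = [
        ModelSpec(
            "decision_tree",
            lambda s: DecisionTreeClassifier(random_state=s),
            {"max_depth": [3, 5]},
            tree=True,
            role="tree",
        ),
        ModelSpec(
            "random_forest",
            lambda s: RandomForestClassifier(n_estimators=50, random_state=s),
            {},
            tree=True,
            role="tree",
        ),
        ModelSpec(
            "extra_trees",
            lambda s: ExtraTreesClassifier(n_estimators=50, random_state=s),
            {},
            tree=True,
            role="tree",
        ),
        ModelSpec(
            "bagging_trees",
            lambda s: BaggingClassifier(
                estimator=DecisionTreeClassifier(random_state=s),
                n_estimators=25,
                random_state=s,
            ),
            {},
            tree=True,
            role="tree",
        ),
        ModelSpec(
            "logistic",
            lambda s: LogisticRegression(max_iter=2000),
            {"C": [0.1, 1.0]},
            role="linear",
        ),
        ModelSpec(
            "sgd_logistic",
            lambda s: SGDClassifier(loss="log_loss", random_state=s),
            {"alpha": [1e-4, 1e-3]},
            role="linear",
        ),
        ModelSpec(
            "svm_rbf",
            lambda s: CalibratedClassifierCV(
                SVC(random_state=s), cv=3, ensemble=False
            ),
            {},
            role="kernel",
        ),
        ModelSpec(
            "mlp",
            lambda s: MLPClassifier(
                hidden_layer_sizes=(16,), max_iter=500, random_state=s
            ),
            {},
            role="neural",
        ),
        ModelSpec(
            "adaboost",
            lambda s: AdaBoostClassifier(n_estimators=50, random_state=s),
            {},
            role="ensemble",
        ),
        ModelSpec(
            "gradient_boosting",
            lambda s: GradientBoostingClassifier(n_estimators=50, random_state=s),
            {},
            role="ensemble",
        ),
    ]
    registry = {s.name: s for s in specs}
    assert len(registry) == 10 and sum(s.tree for s in specs) == 4
    return registry


@dataclass(frozen=True)
class TrainConfig:
    n_rounds: int = 25
    test_fraction: float = 0.2
    cv_folds: int = 5
    #: top-k feature pre-selection candidates evaluated per round
    feature_preselect_grid: Tuple[int, ...] = (100, 50)
    seed_base: int = 0

    def __post_init__(self):
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must be in (0, 1)")

    def round_seeds(self) -> List[int]:
        return [self.seed_base + r for r in range(self.n_rounds)]


@dataclass
class FittedModel:
    name: str
    estimator: object
    feature_subset: List[str]
    params: Dict[str, object]
    cv_score: Optional[float]
    holdout_balanced_accuracy: float


@dataclass
class RoundResult:
    seed: int
    train_ids: List[str]
    test_ids: List[str]
    models: Dict[str, FittedModel]
    test_proba: pd.DataFrame  # test samples x model names


@dataclass
class Bundle:
    rounds: List[RoundResult]
    feature_names: List[str]
    registry: Dict[str, ModelSpec]
    cfg: TrainConfig
    labels: pd.Series  # training labels (0/1) by sample id

    @property
    def n_final_models(self) -> int:
        return sum(len(r.models) for r in self.rounds)

    def tree_models(self) -> List[Tuple[int, str, object]]:
        out = []
        for i, r in enumerate(self.rounds):
            for name, fm in r.models.items():
                if self.registry[name].tree:
                    out.append((i, name, fm))
        return out


def _eliminate_features(
    X: pd.DataFrame, y: np.ndarray, grid: Sequence[int], seed: int
) -> Dict[int, List[str]]:
    """Iterative importance-based elimination down to each top-k in the grid.

    Halves the feature set each step (never below the target k), re-ranking
    with a random forest after every elimination.
    """
    ks = sorted({min(k, X.shape[1]) for k in grid}, reverse=True)
    current = list(X.columns)
    out: Dict[int, List[str]] = {}
    for k in ks:
        while len(current) > k:
            rf = RandomForestClassifier(n_estimators=50, random_state=seed)
            rf.fit(X[current].to_numpy(), y)
            order = np.argsort(rf.feature_importances_)[::-1]
            n_next = max(k, len(current) // 2)
            current = [current[i] for i in order[:n_next]]
        out[k] = list(current)
    return out


def _candidate_grid(spec: ModelSpec) -> List[Dict[str, object]]:
    if not spec.grid:
        return [{}]
    keys = list(spec.grid)
    return [
        dict(zip(keys, combo))
        for combo in itertools.product(*(spec.grid[k] for k in keys))
    ]


def monte_carlo_train(
    X: pd.DataFrame,
    y: Union[pd.Series, Sequence[int]],
    registry: Optional[Dict[str, ModelSpec]] = None,
    cfg: TrainConfig = TrainConfig(),
) -> Bundle:
    """Run the seeded Monte-Carlo training rounds and return the bundle."""
    registry = registry if registry is not None else default_registry()
    y = pd.Series(np.asarray(y, dtype=int), index=X.index)
    if set(y.unique()) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    Xv = X.fillna(X.mean())
    rounds: List[RoundResult] = []
    for seed in cfg.round_seeds():
        tr_idx, te_idx = train_test_split(
            np.arange(len(Xv)),
            test_size=cfg.test_fraction,
            stratify=y.to_numpy(),
            random_state=seed,
        )
        y_tr, y_te = y.iloc[tr_idx].to_numpy(), y.iloc[te_idx].to_numpy()
        if len(set(y_tr)) < 2 or len(set(y_te)) < 2:
            raise RuntimeError(
                f"round seed {seed}: a class is absent from the train or "
                "test split; dataset too small or too imbalanced"
            )
        X_tr, X_te = Xv.iloc[tr_idx], Xv.iloc[te_idx]
        subsets = _eliminate_features(X_tr, y_tr, cfg.feature_preselect_grid, seed)
        cv = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=seed)
        models: Dict[str, FittedModel] = {}
        proba_cols = {}
        for name, spec in registry.items():
            candidates = [
                (k, params)
                for k in sorted(subsets)
                for params in _candidate_grid(spec)
            ]
            if len(candidates) > 1:
                best, best_score = None, -np.inf
                for k, params in candidates:
                    est = clone(spec.factory(seed)).set_params(**params)
                    score = cross_val_score(
                        est,
                        X_tr[subsets[k]].to_numpy(),
                        y_tr,
                        cv=cv,
                        scoring="balanced_accuracy",
                    ).mean()
                    if score > best_score:
                        best, best_score = (k, params), float(score)
                (k, params), cv_score = best, best_score
            else:
                (k, params), cv_score = candidates[0], None
            est = clone(spec.factory(seed)).set_params(**params)
            est.fit(X_tr[subsets[k]].to_numpy(), y_tr)
            proba = est.predict_proba(X_te[subsets[k]].to_numpy())[:, 1]
            proba_cols[name] = proba
            models[name] = FittedModel(
                name=name,
                estimator=est,
                feature_subset=subsets[k],
                params=params,
                cv_score=cv_score,
                holdout_balanced_accuracy=float(
                    balanced_accuracy_score(y_te, (proba >= 0.5).astype(int))
                ),
            )
        rounds.append(
            RoundResult(
                seed=seed,
                train_ids=[str(i) for i in Xv.index[tr_idx]],
                test_ids=[str(i) for i in Xv.index[te_idx]],
                models=models,
                test_proba=pd.DataFrame(proba_cols, index=Xv.index[te_idx]),
            )
        )
    return Bundle(
        rounds=rounds,
        feature_names=list(X.columns),
        registry=registry,
        cfg=cfg,
        labels=y,
    )


def predict_score(
    bundle: Bundle,
    X: pd.DataFrame,
    return_contributions: bool = False,
):
    """Mean positive-class probability per sample over the model ensemble.

    Samples that appear in the bundle's training labels contribute only
    out-of-fold: rounds whose training split contained them are skipped.
    A training sample that was never held out falls back to all rounds
    (flagged in the contributions).
    """
    missing = [c for c in bundle.feature_names if c not in X.columns]
    if missing:
        raise KeyError(f"missing features: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    Xv = X[bundle.feature_names].fillna(X[bundle.feature_names].mean())
    training_ids = set(bundle.labels.index.astype(str))
    sample_ids = [str(i) for i in Xv.index]
    # batch probabilities: one predict_proba call per (round, model)
    cols: List[Tuple[int, str]] = []
    proba_blocks: List[np.ndarray] = []
    for ri, rnd in enumerate(bundle.rounds):
        for name, fm in rnd.models.items():
            cols.append((ri, name))
            proba_blocks.append(
                fm.estimator.predict_proba(Xv[fm.feature_subset].to_numpy())[:, 1]
            )
    P = np.column_stack(proba_blocks)  # samples x (round, model)
    round_of_col = np.array([ri for ri, _ in cols])
    scores = {}
    contributions: Dict[str, List[Tuple[int, str]]] = {}
    for si, sid in enumerate(sample_ids):
        blocked_rounds = {
            ri
            for ri, rnd in enumerate(bundle.rounds)
            if sid in training_ids and sid in rnd.train_ids
        }
        mask = ~np.isin(round_of_col, list(blocked_rounds))
        if not mask.any():  # never held out: fall back to all rounds
            mask[:] = True
        scores[sid] = float(P[si, mask].mean())
        contributions[sid] = [cols[j] for j in np.nonzero(mask)[0]]
    series = pd.Series(scores, name="score")
    if return_contributions:
        return series, contributions
    return series


def aggregate_approaches(per_approach_scores: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Aggregate per-approach scores: mean, sample sd, confidence class."""
    if not per_approach_scores:
        raise ValueError("need at least one approach")
    df = pd.DataFrame(per_approach_scores)
    out = pd.DataFrame(index=df.index)
    out["score"] = df.mean(axis=1)
    out["sd"] = df.std(axis=1, ddof=1) if df.shape[1] > 1 else 0.0
    out["confidence_class"] = out["score"].map(confidence_class)
    return pd.concat([out, df.add_prefix("approach_")], axis=1)


def confidence_class(score: float) -> str:
    """Confidence-based substrate class for a prediction score in [0, 1]."""
    if not (0 <= score <= 1):
        raise ValueError(f"score {score} outside [0, 1]")
    if score >= 0.8:
        return "HC substrate"
    if score >= 0.5:
        return "LC substrate"
    if score > 0.2:
        return "LC non-substrate"
    return "HC non-substrate"


def _model_importances(fm: FittedModel) -> np.ndarray:
    est = fm.estimator
    if hasattr(est, "feature_importances_"):
        return np.asarray(est.feature_importances_, dtype=float)
    if isinstance(est, BaggingClassifier):
        return np.mean(
            [t.feature_importances_ for t in est.estimators_], axis=0
        )
    raise TypeError(f"{type(est).__name__} exposes no feature importances")


def tree_feature_importance(bundle: Bundle) -> pd.Series:
    """Importance per feature, averaged over all tree models and rounds.

    Each model's importances (defined on its selected feature subset) are
    normalized to sum 1, mapped back to the full feature space, averaged,
    and renormalized so the result sums to 1.
    """
    tree_models = bundle.tree_models()
    if not tree_models:
        raise ValueError("no tree-based models in bundle")
    total = pd.Series(0.0, index=bundle.feature_names)
    for _, _, fm in tree_models:
        imp = _model_importances(fm)
        s = imp.sum()
        if s > 0:
            imp = imp / s
        total.loc[fm.feature_subset] += imp
    total /= len(tree_models)
    if total.sum() > 0:
        total /= total.sum()
    return total


def evaluate_holdout(y_true: Sequence[int], y_pred: Sequence[int]) -> Dict[str, float]:
    """Balanced accuracy (mean of sensitivity and specificity) + confusion."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(set(y_true)) < 2:
        raise ValueError("need both classes in the evaluation data")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return {
        "balanced_accuracy": (sens + spec) / 2,
        "sensitivity": sens,
        "specificity": spec,
        "tp": tp,
        "fn": fn,
        "tn": tn,
        "fp": fp,
    }


def evaluate_bundle(bundle: Bundle) -> pd.DataFrame:
    """Held-out balanced accuracy per round and model, plus the mean row."""
    rows = []
    for ri, rnd in enumerate(bundle.rounds):
        for name, fm in rnd.models.items():
            rows.append(
                {"round": ri, "model": name,
                 "balanced_accuracy": fm.holdout_balanced_accuracy}
            )
    return pd.DataFrame(rows)


def evaluate_loocv(estimator, X: pd.DataFrame, y: Sequence[int]) -> Dict[str, float]:
    """Leave-one-out CV evaluation, refitting per left-out sample."""
    y = np.asarray(y, dtype=int)
    if len(set(y)) < 2:
        raise ValueError("need both classes")
    pred = cross_val_predict(
        estimator, X.fillna(X.mean()).to_numpy(), y, cv=LeaveOneOut()
    )
    return evaluate_holdout(y, pred)


def relevance_score(factors: Union[Mapping[str, bool], Sequence[bool]]) -> float:
    """Mean of the five binary relevance factors.

    Factors: new pathway link, new disease link, mutated TMD-JMD, new
    protein family, dissimilar TMD-JMD (< 30% identity to any known
    substrate).
    """
    if isinstance(factors, Mapping):
        missing = set(RELEVANCE_FACTORS) - set(factors)
        extra = set(factors) - set(RELEVANCE_FACTORS)
        if missing or extra:
            raise ValueError(f"missing factors {sorted(missing)}, unknown {sorted(extra)}")
        vals = [bool(factors[k]) for k in RELEVANCE_FACTORS]
    else:
        vals = [bool(v) for v in factors]
        if len(vals) != 5:
            raise ValueError(f"expected exactly 5 factors, got {len(vals)}")
    return float(np.mean(vals))
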