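"""Comparative physicochemical profiling (CPP).

CPP compares a *test* set of protein sequences against a *reference* set
and returns the most discriminative physicochemical features.  A CPP
feature is a (part, split, scale) triple whose value for one protein is
the mean normalized scale value over the split-selected residues of that
protein's part.  The algorithm has four steps:

1. **Creation** — all part x split x scale combinations (e.g. 3 parts x
   330 splits x 133 scales = 131,670 features).
2. **Pre-filtering** — drop features whose standard deviation over the
   test set exceeds ``max_std_test``; among the survivors keep the
   ``floor(pct_pre_filter x n_created)`` features with the largest
   absolute mean difference between test and reference.
3. **Ranking** — descending absolute *adjusted AUC* (rank-sum AUC of
   test vs reference minus 0.5, in [-0.5, 0.5]).
4. **Redundancy filtering** — greedy scan in rank order; a candidate is
   rejected iff an accepted feature overlaps it positionally (Jaccard >
   ``max_overlap``) and is redundant in scale space (same subcategory or
   absolute scale correlation > ``max_cor``); stops at ``n_filter``.

The whole pipeline is deterministic: no randomness, stable tie-breaks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import splits as splits_mod
from .scales import ScaleSet
from .sequence_parts import (
    DEFAULT_FEATURE_PARTS,
    PartConfig,
    ProteinEntry,
    derive_parts,
    reference_part_lengths,
    reference_part_offsets,
)
from .splits import NotApplicable, SplitSpec


@dataclass(frozen=True)
class CPPConfig:
    """CPP parameters; defaults follow the published workflow."""

    n_filter: int = 100
    max_std_test: float = 0.2
    pct_pre_filter: float = 0.05
    max_overlap: float = 0.5
    max_cor: float = 0.5
    parts: Tuple[str, ...] = DEFAULT_FEATURE_PARTS
    #: redundancy predicate: positional overlap AND scale redundancy
    #: (set False for overlap OR scale redundancy)
    conjunctive_redundancy: bool = True
    #: reference TMD length for the positional frame (10 + 20 + 10 = 40)
    ref_tmd_len: int = 20

    def __post_init__(self):
        if not (0 < self.pct_pre_filter <= 1):
            raise ValueError("pct_pre_filter must be in (0, 1]")
        if not (0 <= self.max_overlap <= 1 and 0 <= self.max_cor <= 1):
            raise ValueError("max_overlap/max_cor must be in [0, 1]")
        if self.n_filter < 1:
            raise ValueError("n_filter must be >= 1")


@dataclass
class Feature:
    """A (part, split, scale) triple with computed statistics."""

    feature_id: str
    part_id: str
    split_id: int  # 1-based id within the split universe
    split: SplitSpec
    scale_id: str
    subcategory: str = ""
    category: str = ""
    positions: Tuple[int, ...] = ()  # global TMD-JMD frame, reference length
    mean_test: float = np.nan
    mean_ref: float = np.nan
    mean_dif: float = np.nan
    std_test: float = np.nan
    adjusted_auc: float = np.nan
    importance: float = 0.0


def make_feature_id(part_id: str, split: SplitSpec, scale_id: str) -> str:
    return f"{part_id}|{split.describe()}|{scale_id}"


def create_feature_space(
    part_ids: Sequence[str],
    split_specs: Sequence[SplitSpec],
    scale_set: ScaleSet,
    part_cfg: PartConfig = PartConfig(),
    ref_tmd_len: int = 20,
) -> List[Feature]:
    """All |parts| x |splits| x |scales| features in part-major order."""
    if not (part_ids and split_specs and len(scale_set)):
        raise ValueError("parts, splits, and scales must be non-empty")
    ref_len = reference_part_lengths(ref_tmd_len, part_cfg)
    ref_off = reference_part_offsets(ref_tmd_len, part_cfg)
    subcat = {s.id: s.subcategory for s in scale_set}
    cat = {s.id: s.category for s in scale_set}
    features = []
    for part_id in part_ids:
        L = ref_len[part_id]
        off = ref_off[part_id]
        for split_id, spec in enumerate(split_specs, start=1):
            try:
                pos = tuple(off + i - 1 for i in splits_mod.resolve(L, spec))
            except NotApplicable:
                pos = ()
            for scale in scale_set:
                features.append(
                    Feature(
                        feature_id=make_feature_id(part_id, spec, scale.id),
                        part_id=part_id,
                        split_id=split_id,
                        split=spec,
                        scale_id=scale.id,
                        subcategory=subcat[scale.id],
                        category=cat[scale.id],
                        positions=pos,
                    )
                )
    return features


def compute_feature_matrix(
    entries: Sequence[ProteinEntry],
    features: Sequence[Feature],
    scale_set: ScaleSet,
    part_cfg: PartConfig = PartConfig(),
) -> pd.DataFrame:
    """Samples x features matrix of mean scale values in [0, 1].

    Cells where a split is not applicable (part shorter than the split
    span) are NaN, never 0.  Exploits the part-major/scale-minor feature
    order: for one (part, split) pair the values for all scales are a
    single vectorized mean over the scale matrix.
    """
    scale_ids = scale_set.ids()
    scale_index = {sid: i for i, sid in enumerate(scale_ids)}
    S = scale_set.matrix()  # (n_scales, 20)
    aa_idx = {aa: i for i, aa in enumerate(scale_set.scales[0].values)}
    # group contiguous features by (part, split); verify scale-minor layout
    groups: List[Tuple[str, SplitSpec, List[int], List[int]]] = []
    for key, grp in itertools.groupby(
        enumerate(features), key=lambda kv: (kv[1].part_id, kv[1].split_id)
    ):
        idx_cols, idx_scales = [], []
        spec = None
        for col, f in grp:
            spec = f.split
            idx_cols.append(col)
            idx_scales.append(scale_index[f.scale_id])
        groups.append((key[0], spec, idx_cols, idx_scales))

    n, m = len(entries), len(features)
    M = np.full((n, m), np.nan, dtype=np.float64)
    # encode each needed part of each protein once
    part_ids_needed = sorted({f.part_id for f in features})
    encoded: List[Dict[str, np.ndarray]] = []
    for e in entries:
        parts = derive_parts(e, part_cfg)
        encoded.append(
            {
                pid: np.array([aa_idx[c] for c in parts.part(pid)], dtype=np.intp)
                for pid in part_ids_needed
            }
        )
    resolve_cache: Dict[Tuple[int, int], Optional[np.ndarray]] = {}
    split_key = {id(g[1]): i for i, g in enumerate(groups)}
    for part_id, spec, idx_cols, idx_scales in groups:
        cols = np.asarray(idx_cols, dtype=np.intp)
        srow = np.asarray(idx_scales, dtype=np.intp)
        for i, enc in enumerate(encoded):
            seq = enc[part_id]
            ck = (len(seq), split_key[id(spec)])
            if ck not in resolve_cache:
                try:
                    resolve_cache[ck] = (
                        np.asarray(splits_mod.resolve(len(seq), spec), dtype=np.intp)
                        - 1
                    )
                except NotApplicable:
                    resolve_cache[ck] = None
            idx = resolve_cache[ck]
            if idx is None or len(idx) == 0:
                continue
            M[i, cols] = S[srow][:, seq[idx]].mean(axis=1)
    return pd.DataFrame(
        M, index=[e.id for e in entries], columns=[f.feature_id for f in features]
    )


def adjusted_auc(test_values: Sequence[float], ref_values: Sequence[float]) -> float:
    """Rank-sum AUC of test vs reference minus 0.5 (ties count 1/2).

    Positive values mean the test set is systematically higher; the
    bounds -0.5 / +0.5 are attained when the two samples fully separate.
    """
    t = np.asarray(test_values, dtype=float)
    r = np.asarray(ref_values, dtype=float)
    if t.size == 0 or r.size == 0:
        raise ValueError("both samples must be non-empty")
    ranks = rankdata(np.concatenate([t, r]))
    u = ranks[: t.size].sum() - t.size * (t.size + 1) / 2
    return float(u / (t.size * r.size) - 0.5)


def _adjusted_auc_columns(T: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Column-wise adjusted AUC for test block T and reference block R."""
    out = np.empty(T.shape[1])
    stacked = np.vstack([T, R])
    nan_cols = np.isnan(stacked).any(axis=0)
    if (~nan_cols).any():
        ranks = rankdata(stacked[:, ~nan_cols], axis=0)
        u = ranks[: T.shape[0]].sum(axis=0) - T.shape[0] * (T.shape[0] + 1) / 2
        out[~nan_cols] = u / (T.shape[0] * R.shape[0]) - 0.5
    for j in np.nonzero(nan_cols)[0]:
        t = T[:, j][~np.isnan(T[:, j])]
        r = R[:, j][~np.isnan(R[:, j])]
        out[j] = adjusted_auc(t, r) if t.size and r.size else np.nan
    return out


def prefilter(
    features: Sequence[Feature],
    matrix: pd.DataFrame,
    test_ids: Sequence[str],
    ref_ids: Sequence[str],
    cfg: CPPConfig,
    n_created: Optional[int] = None,
) -> List[Feature]:
    """Std filter on the test set, then top-k by absolute mean difference.

    k = floor(pct_pre_filter x n_created) where n_created defaults to the
    number of features passed in (the size of the created feature space).
    Ties are broken by feature position in the created order.
    """
    if set(test_ids) & set(ref_ids):
        raise ValueError("test and reference sets must be disjoint")
    if not (len(test_ids) and len(ref_ids)):
        raise ValueError("test and reference sets must be non-empty")
    n_created = n_created if n_created is not None else len(features)
    k = int(np.floor(cfg.pct_pre_filter * n_created))
    T = matrix.loc[list(test_ids)].to_numpy(dtype=float)
    R = matrix.loc[list(ref_ids)].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        mean_t = np.nanmean(T, axis=0)
        mean_r = np.nanmean(R, axis=0)
        std_t = np.nanstd(T, axis=0)
    mean_dif = mean_t - mean_r
    # in-place stat assignment (Feature is mutable); avoids copying 1e5 objects
    for j, f in enumerate(features):
        f.mean_test = float(mean_t[j])
        f.mean_ref = float(mean_r[j])
        f.mean_dif = float(mean_dif[j])
        f.std_test = float(std_t[j])
    survivors = [
        j
        for j, f in enumerate(features)
        if np.isfinite(std_t[j]) and std_t[j] <= cfg.max_std_test
    ]
    survivors.sort(key=lambda j: (-abs(features[j].mean_dif), j))
    return [features[j] for j in survivors[:k]]


def rank_features(
    features: Sequence[Feature],
    matrix: Optional[pd.DataFrame] = None,
    test_ids: Optional[Sequence[str]] = None,
    ref_ids: Optional[Sequence[str]] = None,
) -> List[Feature]:
    """Rank by descending |adjusted AUC|; ties by |mean_dif|, then id.

    If a matrix and id sets are given, adjusted AUCs are (re)computed
    first; otherwise the stored statistics are used.
    """
    feats = list(features)
    if matrix is not None:
        cols = [f.feature_id for f in feats]
        T = matrix.loc[list(test_ids), cols].to_numpy(dtype=float)
        R = matrix.loc[list(ref_ids), cols].to_numpy(dtype=float)
        aucs = _adjusted_auc_columns(T, R)
        for f, a in zip(feats, aucs):
            f.adjusted_auc = float(a)
    return sorted(
        feats,
        key=lambda f: (-abs(f.adjusted_auc), -abs(f.mean_dif), f.feature_id),
    )


def _jaccard(a: Tuple[int, ...], b: Tuple[int, ...]) -> float:
    if not a or not b:
        return 0.0
    sa, sb = set(a), set(b)
    return len(sa & sb) / len(sa | sb)


def redundancy_filter(
    ranked: Sequence[Feature], cfg: CPPConfig, scale_set: ScaleSet
) -> List[Feature]:
    """Greedy redundancy filter in rank order, capped at ``n_filter``."""
    ids = scale_set.ids()
    pos = {sid: i for i, sid in enumerate(ids)}
    C = np.corrcoef(scale_set.matrix())
    accepted: List[Feature] = []
    for cand in ranked:
        if len(accepted) >= cfg.n_filter:
            break
        redundant = False
        for acc in accepted:
            overlap = _jaccard(cand.positions, acc.positions) > cfg.max_overlap
            scale_red = (
                cand.subcategory == acc.subcategory
                or abs(C[pos[cand.scale_id], pos[acc.scale_id]]) > cfg.max_cor
            )
            if (
                (overlap and scale_red)
                if cfg.conjunctive_redundancy
                else (overlap or scale_red)
            ):
                redundant = True
                break
        if not redundant:
            accepted.append(cand)
    return accepted


@dataclass
class CPPResult:
    features: List[Feature]  # final ranked, redundancy-filtered features
    matrix: pd.DataFrame  # full samples x created-features matrix
    n_created: int
    n_prefiltered: int

    def feature_table(self) -> pd.DataFrame:
        rows = [
            {
                "feature_id": f.feature_id,
                "part": f.part_id,
                "split": f.split.describe(),
                "scale_id": f.scale_id,
                "subcategory": f.subcategory,
                "category": f.category,
                "mean_dif": f.mean_dif,
                "std_test": f.std_test,
                "adjusted_auc": f.adjusted_auc,
                "importance": f.importance,
                "positions": ",".join(map(str, f.positions)),
            }
            for f in self.features
        ]
        return pd.DataFrame(rows)


def run_cpp(
    entries: Sequence[ProteinEntry],
    scale_set: ScaleSet,
    test_ids: Sequence[str],
    ref_ids: Sequence[str],
    cfg: CPPConfig = CPPConfig(),
    part_cfg: PartConfig = PartConfig(),
) -> CPPResult:
    """Run the four CPP steps end to end (fully deterministic)."""
    universe = splits_mod.enumerate_all()
    features = create_feature_space(
        cfg.parts, universe, scale_set, part_cfg, cfg.ref_tmd_len
    )
    matrix = compute_feature_matrix(entries, features, scale_set, part_cfg)
    pre = prefilter(features, matrix, test_ids, ref_ids, cfg)
    ranked = rank_features(pre, matrix, test_ids, ref_ids)
    final = redundancy_filter(ranked, cfg, scale_set)
    return CPPResult(
        features=final,
        matrix=matrix,
        n_created=len(features),
        n_prefiltered=len(pre),
    )


def positional_aggregation(
    features: Sequence[Feature],
    frame_len: int = 40,
    value: str = "importance",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-residue profile and per-(subcategory, position) feature map.

    Each feature's importance (or any numeric attribute named by
    ``value``) is divided equally among its positions in the fixed
    reference frame; the profile sums these shares per position, so the
    profile total equals the total importance of the input features.
    The feature map reports the mean ``mean_dif`` and the summed
    importance share per subcategory and position.
    """
    profile = np.zeros(frame_len)
    map_dif: Dict[Tuple[str, int], List[float]] = {}
    map_imp: Dict[Tuple[str, int], float] = {}
    for f in features:
        if not f.positions:
            continue
        share = getattr(f, value) / len(f.positions)
        for p in f.positions:
            if not (1 <= p <= frame_len):
                continue
            profile[p - 1] += share
            map_dif.setdefault((f.subcategory, p), []).append(f.mean_dif)
            map_imp[(f.subcategory, p)] = map_imp.get((f.subcategory, p), 0.0) + share
    profile_df = pd.DataFrame(
        {"position": np.arange(1, frame_len + 1), value: profile}
    )
    rows = [
        {
            "subcategory": sc,
            "position": p,
            "mean_dif": float(np.mean(v)),
            value: map_imp[(sc, p)],
        }
        for (sc, p), v in sorted(map_dif.items())
    ]
    return profile_df, pd.DataFrame(rows)
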