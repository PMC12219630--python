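"""Amino-acid property scales: normalization, classification, selection.

A scale assigns one number to each of the 20 canonical residues (e.g.
hydrophobicity, charge, volume).  Scales are min-max normalized to [0,1]
and carry a category/subcategory classification (AAontology-style),
consumed here as input metadata.  Redundancy reduction follows the
AAclust idea: agglomerative clustering (complete linkage) on
1 - Pearson correlation between scale vectors, keeping one medoid per
cluster, with the number of clusters grown until every subcategory of
the input is represented at least once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .sequence_parts import AMINO_ACIDS
from .splits import NotApplicable

AA_ORDER = tuple(AMINO_ACIDS)  # alphabetical one-letter codes
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}


@dataclass(frozen=True)
class Scale:
    """One min-max normalized amino-acid property scale."""

    id: str
    values: Dict[str, float]
    category: str = ""
    subcategory: str = ""

    def vector(self) -> np.ndarray:
        return np.array([self.values[aa] for aa in AA_ORDER], dtype=float)


@dataclass
class ScaleSet:
    scales: List[Scale]
    provenance: str = ""

    def __post_init__(self):
        ids = [s.id for s in self.scales]
        if len(set(ids)) != len(ids):
            raise ValueError("scale ids must be unique")

    def __len__(self) -> int:
        return len(self.scales)

    def __iter__(self):
        return iter(self.scales)

    def ids(self) -> List[str]:
        return [s.id for s in self.scales]

    def matrix(self) -> np.ndarray:
        """(n_scales, 20) array in AA_ORDER."""
        return np.stack([s.vector() for s in self.scales])

    def by_id(self) -> Dict[str, Scale]:
        return {s.id: s for s in self.scales}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix(), index=self.ids(), columns=list(AA_ORDER))
        df.insert(0, "scale_id", df.index)
        df["category"] = [s.category for s in self.scales]
        df["subcategory"] = [s.subcategory for s in self.scales]
        return df.reset_index(drop=True)


def _normalize(values: Dict[str, float]) -> Dict[str, float]:
    arr = np.array([values[aa] for aa in AA_ORDER], dtype=float)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        raise ValueError("constant scale cannot be normalized")
    return dict(zip(AA_ORDER, (arr - lo) / (hi - lo)))


def load_and_normalize(table: pd.DataFrame, provenance: str = "") -> ScaleSet:
    """Build a normalized ScaleSet from a scale table.

    Expected columns: ``scale_id``, the 20 residue columns (one-letter
    codes), and optionally ``category`` / ``subcategory``.  Scales with
    missing values, constant scales, and exact duplicates (after
    normalization) are dropped; drop counts are recorded in provenance.
    """
    missing_cols = [aa for aa in AA_ORDER if aa not in table.columns]
    if missing_cols:
        raise ValueError(f"missing residue columns: {missing_cols}")
    if "scale_id" not in table.columns:
        raise ValueError("missing scale_id column")
    n_missing = n_constant = n_dup = 0
    seen: Dict[bytes, str] = {}
    scales: List[Scale] = []
    for _, row in table.iterrows():
        vals = row[list(AA_ORDER)].astype(float)
        if vals.isna().any():
            n_missing += 1
            continue
        raw = dict(zip(AA_ORDER, vals.to_numpy()))
        try:
            norm = _normalize(raw)
        except ValueError:
            n_constant += 1
            continue
        key = np.round(np.array([norm[aa] for aa in AA_ORDER]), 12).tobytes()
        if key in seen:
            n_dup += 1
            continue
        seen[key] = str(row["scale_id"])
        scales.append(
            Scale(
                id=str(row["scale_id"]),
                values=norm,
                category=str(row.get("category", "")),
                subcategory=str(row.get("subcategory", "")),
            )
        )
    note = (
        f"{provenance} (dropped: {n_missing} with missing values, "
        f"{n_constant} constant, {n_dup} duplicates)"
    )
    return ScaleSet(scales=scales, provenance=note.strip())


def feature_value(
    part_sequence: str, indices: Sequence[int], scale: Scale
) -> float:
    """Mean scale value over the selected residues (1-based indices)."""
    if not indices:
        raise NotApplicable("empty index set")
    vals = []
    for i in indices:
        if not (1 <= i <= len(part_sequence)):
            raise IndexError(f"index {i} outside part of length {len(part_sequence)}")
        vals.append(scale.values[part_sequence[i - 1]])
    return float(np.mean(vals))


def aaclust_select(scale_set: ScaleSet) -> ScaleSet:
    """Redundancy-reduce a scale set, covering every subcategory.

    Complete-linkage agglomerative clustering on 1 - Pearson correlation;
    the medoid (scale with highest mean correlation to its cluster,
    ties broken by lexicographically smallest id) represents each
    cluster.  k is the smallest cluster count, scanned upward from the
    number of subcategories, for which the representatives cover every
    subcategory present in the input.
    """
    scales = sorted(scale_set.scales, key=lambda s: s.id)  # order-invariance
    subcats = sorted({s.subcategory for s in scales})
    for sc in subcats:
        if not any(s.subcategory == sc for s in scales):  # pragma: no cover
            raise ValueError(f"subcategory {sc!r} has no scale")
    n = len(scales)
    if n == 0:
        raise ValueError("empty scale set")
    X = np.stack([s.vector() for s in scales])
    C = np.corrcoef(X)
    D = np.clip(1.0 - C, 0.0, None)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="complete")

    def representatives(k: int) -> List[Scale]:
        labels = fcluster(Z, t=k, criterion="maxclust")
        reps = []
        for c in sorted(set(labels)):
            members = [i for i in range(n) if labels[i] == c]
            # medoid: highest mean correlation to cluster members
            best = None
            for i in members:
                score = float(np.mean([C[i, j] for j in members]))
                key = (-score, scales[i].id)
                if best is None or key < best[0]:
                    best = (key, i)
            reps.append(scales[best[1]])
        return reps

    k_min = min(len(subcats), n)
    for k in range(k_min, n + 1):
        reps = representatives(k)
        if {s.subcategory for s in reps} >= set(subcats):
            return ScaleSet(
                scales=sorted(reps, key=lambda s: s.id),
                provenance=f"aaclust k={k} from {n} scales",
            )
    # full set always covers everything
    return ScaleSet(scales=scales, provenance=f"aaclust k={n} (no reduction)")


def read_scale_tsv(path) -> ScaleSet:
    """Load scales from the TSV dialect (scale_id, A..Y, category, subcategory)."""
    return load_and_normalize(pd.read_csv(path, sep="\t"), provenance=str(path))
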