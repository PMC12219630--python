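"""Synthetic single-span membrane proteins with a plantable signature.

The generator emulates the structure of a protease-substrate study:
a small positive class (substrates), a handful of known negatives,
and a large unlabeled pool, all single-span N-out proteins with
10-residue juxtamembrane domains.  Background TMDs are biased to the
hydrophobic core residues (L, I, V, F, A); juxtamembrane domains use a
mixed composition.  Positives additionally carry, with per-position
probability ``effect_size``, a physicochemical signature:

* anchor (first 4 JMD-C residues) drawn from {K, R} — basic anchors,
* TMD-N residues drawn from {G, A, S} — small/flexible residues,
* cleavage window (last 4 TMD residues) drawn from {V, I, T}.

At ``effect_size = 0`` positives are indistinguishable from background;
at 1 the signature is deterministic.  A configurable fraction of the
unlabeled pool are true positives, exercising the positive-unlabeled
setting.  Everything is seeded and byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .cpp_core import Feature
from .scales import AA_ORDER, Scale, ScaleSet
from .sequence_parts import Label, PartConfig, ProteinEntry, validate_entry

#: hydrophobic-core biased TMD composition
TMD_COMPOSITION: Dict[str, float] = {
    "L": 0.24, "I": 0.15, "V": 0.15, "F": 0.10, "A": 0.10,
    "G": 0.06, "S": 0.05, "T": 0.05, "M": 0.04, "W": 0.02,
    "Y": 0.02, "C": 0.02,
}
#: mixed juxtamembrane composition (moderate charge content)
JMD_COMPOSITION: Dict[str, float] = {
    "S": 0.08, "T": 0.06, "N": 0.05, "Q": 0.05, "E": 0.08, "D": 0.06,
    "K": 0.06, "R": 0.05, "H": 0.03, "P": 0.06, "G": 0.07, "A": 0.08,
    "L": 0.09, "V": 0.06, "I": 0.05, "F": 0.03, "Y": 0.02, "M": 0.02,
}

ANCHOR_POOL = "KR"
TMD_N_POOL = "GAS"
CLEAVAGE_POOL = "VIT"


@dataclass(frozen=True)
class SynthConfig:
    n_pos: int = 63
    n_neg: int = 14
    n_unlabeled: int = 631
    tmd_len_range: Tuple[int, int] = (19, 25)
    jmd_len: int = 10
    effect_size: float = 1.0
    seed: int = 0
    #: fraction of the unlabeled pool that are true positives
    unlabeled_true_pos_fraction: float = 0.2

    def __post_init__(self):
        if min(self.n_pos, self.n_neg, self.n_unlabeled) < 0:
            raise ValueError("counts must be >= 0")
        if not (0 <= self.effect_size <= 1):
            raise ValueError("effect_size must be in [0, 1]")


@dataclass
class GroundTruth:
    """Planted regions (reference 40-residue frame) and true classes."""

    true_class: Dict[str, str]  # id -> "pos" | "neg"
    planted_positions: Dict[str, Set[int]] = field(default_factory=dict)

    def planted_union(self) -> Set[int]:
        out: Set[int] = set()
        for s in self.planted_positions.values():
            out |= s
        return out


def _default_planted_positions(
    ref_tmd_len: int = 20, jmd_len: int = 10
) -> Dict[str, Set[int]]:
    tmd_lo = jmd_len + 1
    tmd_hi = jmd_len + ref_tmd_len
    n_half = (ref_tmd_len + 1) // 2
    return {
        "tmd_n": set(range(tmd_lo, tmd_lo + n_half)),
        "cleavage_window": set(range(tmd_hi - 3, tmd_hi + 1)),
        "anchor": set(range(tmd_hi + 1, tmd_hi + 5)),
    }


def _draw(rng: np.random.Generator, comp: Mapping[str, float], n: int) -> List[str]:
    letters = list(comp)
    p = np.array([comp[a] for a in letters], dtype=float)
    p /= p.sum()
    return list(rng.choice(letters, size=n, p=p))


def _make_sequence(
    rng: np.random.Generator, tmd_len: int, jmd_len: int, positive: bool, eps: float
) -> str:
    jmd_n = _draw(rng, JMD_COMPOSITION, jmd_len)
    tmd = _draw(rng, TMD_COMPOSITION, tmd_len)
    jmd_c = _draw(rng, JMD_COMPOSITION, jmd_len)
    if positive and eps > 0:
        n_half = (tmd_len + 1) // 2
        for i in range(n_half):  # TMD-N: small residues
            if rng.random() < eps:
                tmd[i] = TMD_N_POOL[rng.integers(len(TMD_N_POOL))]
        for i in range(tmd_len - 4, tmd_len):  # cleavage window
            if rng.random() < eps:
                tmd[i] = CLEAVAGE_POOL[rng.integers(len(CLEAVAGE_POOL))]
        for i in range(4):  # TMD-C anchor
            if rng.random() < eps:
                jmd_c[i] = ANCHOR_POOL[rng.integers(len(ANCHOR_POOL))]
    return "".join(jmd_n + tmd + jmd_c)


def generate_dataset(cfg: SynthConfig) -> Tuple[List[ProteinEntry], GroundTruth]:
    """Generate labeled and unlabeled entries plus the ground truth."""
    rng = np.random.default_rng(cfg.seed)
    entries: List[ProteinEntry] = []
    true_class: Dict[str, str] = {}

    def add(prefix: str, k: int, label: Label, positive: bool):
        for j in range(k):
            tmd_len = int(rng.integers(cfg.tmd_len_range[0], cfg.tmd_len_range[1] + 1))
            seq = _make_sequence(rng, tmd_len, cfg.jmd_len, positive, cfg.effect_size)
            pid = f"{prefix}{j:04d}"
            entry = ProteinEntry(
                id=pid,
                sequence=seq,
                tmd_start=cfg.jmd_len + 1,
                tmd_stop=cfg.jmd_len + tmd_len,
                label=label,
            )
            assert validate_entry(entry, PartConfig(jmd_len=cfg.jmd_len)).accepted
            entries.append(entry)
            true_class[pid] = "pos" if positive else "neg"

    add("POS", cfg.n_pos, Label.POSITIVE, True)
    add("NEG", cfg.n_neg, Label.NEGATIVE, False)
    n_hidden_pos = int(round(cfg.unlabeled_true_pos_fraction * cfg.n_unlabeled))
    # hidden positives are interleaved first, then plain background
    add("UNK", n_hidden_pos, Label.UNLABELED, True)
    for j in range(n_hidden_pos, cfg.n_unlabeled):
        tmd_len = int(rng.integers(cfg.tmd_len_range[0], cfg.tmd_len_range[1] + 1))
        seq = _make_sequence(rng, tmd_len, cfg.jmd_len, False, cfg.effect_size)
        pid = f"UNK{j:04d}"
        entries.append(
            ProteinEntry(
                id=pid,
                sequence=seq,
                tmd_start=cfg.jmd_len + 1,
                tmd_stop=cfg.jmd_len + tmd_len,
                label=Label.UNLABELED,
            )
        )
        true_class[pid] = "neg"
    truth = GroundTruth(
        true_class=true_class,
        planted_positions=_default_planted_positions(jmd_len=cfg.jmd_len),
    )
    return entries, truth


def generate_scaleset(
    n_scales: int = 20, n_subcategories: int = 5, seed: int = 0
) -> ScaleSet:
    """Random min-max normalized scales with subcategory labels.

    Always includes a charge-like scale (K, R high) and a size-like scale
    (G, A, S low) so the planted signature is detectable; a branched-
    aliphatic scale (V, I, T high) covers the cleavage-window pool.
    """
    if n_scales < n_subcategories:
        raise ValueError("n_scales must be >= n_subcategories")
    rng = np.random.default_rng(seed)
    scales: List[Scale] = []

    def norm(vals: np.ndarray) -> Dict[str, float]:
        vals = (vals - vals.min()) / (vals.max() - vals.min())
        return dict(zip(AA_ORDER, vals))

    charge = np.array(
        [1.0 if aa in "KR" else (0.6 if aa == "H" else 0.1) for aa in AA_ORDER]
    ) + rng.normal(0, 0.02, 20)
    scales.append(Scale("charge_like", norm(charge), "Energy", "Charge"))
    size = np.array(
        [0.05 if aa in "GAS" else (0.5 if aa in "VTCP" else 0.9) for aa in AA_ORDER]
    ) + rng.normal(0, 0.02, 20)
    scales.append(Scale("size_like", norm(size), "Structure-Activity", "Volume"))
    branched = np.array(
        [1.0 if aa in "VIT" else 0.2 for aa in AA_ORDER]
    ) + rng.normal(0, 0.02, 20)
    scales.append(
        Scale("branched_like", norm(branched), "Conformation", "Beta-strand")
    )
    subcats = [f"subcat_{i}" for i in range(n_subcategories)]
    # keep the three planted-signal subcategories among the requested ones
    fixed_subcats = ["Charge", "Volume", "Beta-strand"]
    for i in range(n_scales - 3):
        vals = rng.random(20)
        sc = (fixed_subcats + subcats)[i % (len(fixed_subcats) + len(subcats))]
        cat = "Conformation" if "strand" in sc.lower() else "Others"
        scales.append(Scale(f"scale_{i:03d}", norm(vals), cat, sc))
    return ScaleSet(scales=scales[:n_scales], provenance=f"synthetic seed={seed}")


def positional_recall(
    features: Sequence[Feature], truth: GroundTruth, top: int = 10
) -> float:
    """Fraction of the top features' positions inside planted regions."""
    planted = truth.planted_union()
    n_in = n_tot = 0
    for f in list(features)[:top]:
        for p in f.positions:
            n_tot += 1
            n_in += p in planted
    return n_in / n_tot if n_tot else float("nan")


def truth_report(
    truth: GroundTruth,
    cpp_features: Optional[Sequence[Feature]] = None,
    predictions: Optional[pd.Series] = None,
    top: int = 10,
) -> Dict[str, float]:
    """Recovery metrics against the planted ground truth."""
    out: Dict[str, float] = {}
    if cpp_features is not None:
        out["top_feature_positional_recall"] = positional_recall(
            cpp_features, truth, top
        )
        planted = truth.planted_union()
        covered = set()
        for f in list(cpp_features)[:top]:
            covered |= set(f.positions) & planted
        out["planted_position_coverage"] = (
            len(covered) / len(planted) if planted else float("nan")
        )
    if predictions is not None:
        ids = [str(i) for i in predictions.index]
        unknown = [i for i in ids if i not in truth.true_class]
        if unknown:
            raise KeyError(f"ids without ground truth: {unknown[:5]}")
        y_true = np.array([truth.true_class[i] == "pos" for i in ids], dtype=int)
        y_pred = (predictions.to_numpy() >= 0.5).astype(int)
        from .ml_pipeline import evaluate_holdout

        out.update(
            {
                f"pred_{k}": v
                for k, v in evaluate_holdout(y_true, y_pred).items()
                if k in ("balanced_accuracy", "sensitivity", "specificity")
            }
        )
    return out
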