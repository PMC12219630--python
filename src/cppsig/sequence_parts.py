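"""Sequence parts of single-span membrane proteins.

A validated protein entry is decomposed into a fixed set of sequence parts
around its transmembrane domain (TMD): the TMD itself, its N-/C-terminal
halves (TMD-N, TMD-C), the TMD extended by a few residues on both sides
(TMD-E), the flanking juxtamembrane domains (JMD-N, JMD-C, default 10
residues each), and the combined parts JMD-N-TMD-N, TMD-C-JMD-C and
TMD-JMD.  The first four residues of the JMD-C are the "TMD-C anchor",
typically basic residues anchoring the helix at the membrane interface.

Coordinates are 1-based and inclusive on both ends (UniProt convention).
For odd TMD lengths the N-terminal half receives the extra residue
(TMD-N has ceil(L/2) residues); this rule is fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: canonical part identifiers
PART_IDS = (
    "jmd_n",
    "tmd_n",
    "tmd_c",
    "tmd",
    "tmd_e",
    "jmd_c",
    "jmd_n_tmd_n",
    "tmd_c_jmd_c",
    "tmd_jmd",
)

#: default part set used for feature engineering
DEFAULT_FEATURE_PARTS = ("tmd", "jmd_n_tmd_n", "tmd_c_jmd_c")


class Label(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNLABELED = "unlabeled"


class StructuralError(ValueError):
    """Malformed entry (indices out of range, bad alphabet)."""


@dataclass(frozen=True)
class ProteinEntry:
    """One single-span membrane protein with TMD boundaries and a label."""

    id: str
    sequence: str
    tmd_start: int  # 1-based inclusive
    tmd_stop: int  # 1-based inclusive
    label: Label = Label.UNLABELED
    name: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "label", Label(self.label))


@dataclass(frozen=True)
class PartConfig:
    """Coordinate convention for part extraction.

    jmd_len
        Number of flanking residues taken as juxtamembrane domain on each
        side of the TMD (default 10, must be >= 4 so the anchor exists).
    ext_len
        Number of residues the TMD is expanded by on each side for TMD-E
        (default 4).
    """

    jmd_len: int = 10
    ext_len: int = 4

    def __post_init__(self):
        if self.jmd_len < 4:
            raise ValueError("jmd_len must be >= 4 (anchor must exist)")
        if self.ext_len < 0:
            raise ValueError("ext_len must be >= 0")


@dataclass(frozen=True)
class Verdict:
    accepted: bool
    reason: str = ""


@dataclass(frozen=True)
class SequenceParts:
    """All parts of one protein, plus part offsets in TMD-JMD coordinates."""

    jmd_n: str
    tmd: str
    tmd_n: str
    tmd_c: str
    tmd_e: str
    jmd_c: str
    jmd_n_tmd_n: str
    tmd_c_jmd_c: str
    tmd_jmd: str
    anchor: str
    part_offsets: Dict[str, int] = field(default_factory=dict)

    def part(self, part_id: str) -> str:
        if part_id not in PART_IDS:
            raise KeyError(f"unknown part id: {part_id!r}")
        return getattr(self, part_id)


def validate_entry(entry: ProteinEntry, cfg: PartConfig = PartConfig()) -> Verdict:
    """Accept an entry iff >= jmd_len residues flank the TMD on both sides.

    Malformed indices or non-canonical residues raise :class:`StructuralError`
    (distinct from the short-JMD rejection, which returns a verdict).
    """
    n = len(entry.sequence)
    if not entry.sequence:
        raise StructuralError(f"{entry.id}: empty sequence")
    bad = set(entry.sequence) - _AA_SET
    if bad:
        raise StructuralError(f"{entry.id}: non-canonical residues {sorted(bad)}")
    if not (1 <= entry.tmd_start <= entry.tmd_stop <= n):
        raise StructuralError(
            f"{entry.id}: invalid TMD bounds {entry.tmd_start}..{entry.tmd_stop} "
            f"for sequence of length {n}"
        )
    n_flank = entry.tmd_start - 1
    c_flank = n - entry.tmd_stop
    if n_flank < cfg.jmd_len:
        return Verdict(False, f"short-JMD-N ({n_flank} < {cfg.jmd_len})")
    if c_flank < cfg.jmd_len:
        return Verdict(False, f"short-JMD-C ({c_flank} < {cfg.jmd_len})")
    return Verdict(True)


def derive_parts(entry: ProteinEntry, cfg: PartConfig = PartConfig()) -> SequenceParts:
    """Extract all sequence parts of a validated entry."""
    verdict = validate_entry(entry, cfg)
    if not verdict.accepted:
        raise ValueError(f"{entry.id}: entry rejected ({verdict.reason})")
    seq = entry.sequence
    start, stop = entry.tmd_start, entry.tmd_stop  # 1-based inclusive
    tmd = seq[start - 1 : stop]
    L = len(tmd)
    n_half = (L + 1) // 2  # ceil-rule: TMD-N gets the extra residue
    tmd_n = tmd[:n_half]
    tmd_c = tmd[n_half:]
    jmd_n = seq[start - 1 - cfg.jmd_len : start - 1]
    jmd_c = seq[stop : stop + cfg.jmd_len]
    e_lo = max(start - cfg.ext_len, 1)
    e_hi = min(stop + cfg.ext_len, len(seq))
    tmd_e = seq[e_lo - 1 : e_hi]
    jl = cfg.jmd_len
    # 1-based start offset of each part within the JMD-N|TMD|JMD-C frame
    offsets = {
        "jmd_n": 1,
        "tmd": jl + 1,
        "tmd_n": jl + 1,
        "tmd_c": jl + n_half + 1,
        "tmd_e": jl - (start - e_lo) + 1,
        "jmd_c": jl + L + 1,
        "jmd_n_tmd_n": 1,
        "tmd_c_jmd_c": jl + n_half + 1,
        "tmd_jmd": 1,
    }
    return SequenceParts(
        jmd_n=jmd_n,
        tmd=tmd,
        tmd_n=tmd_n,
        tmd_c=tmd_c,
        tmd_e=tmd_e,
        jmd_c=jmd_c,
        jmd_n_tmd_n=jmd_n + tmd_n,
        tmd_c_jmd_c=tmd_c + jmd_c,
        tmd_jmd=jmd_n + tmd + jmd_c,
        anchor=jmd_c[:4],
        part_offsets=offsets,
    )


def tmd_jmd_position(parts: SequenceParts, part_id: str, part_local_index: int) -> int:
    """Map a 1-based position within a part to the TMD-JMD frame (1-based)."""
    part_seq = parts.part(part_id)
    if not (1 <= part_local_index <= len(part_seq)):
        raise IndexError(
            f"position {part_local_index} out of range for part {part_id!r} "
            f"of length {len(part_seq)}"
        )
    return parts.part_offsets[part_id] + part_local_index - 1


def reference_part_lengths(
    tmd_len: int = 20, cfg: PartConfig = PartConfig()
) -> Dict[str, int]:
    """Part lengths in a fixed reference frame (default 10+20+10 = 40)."""
    n_half = (tmd_len + 1) // 2
    jl = cfg.jmd_len
    return {
        "jmd_n": jl,
        "tmd": tmd_len,
        "tmd_n": n_half,
        "tmd_c": tmd_len - n_half,
        "tmd_e": tmd_len + 2 * cfg.ext_len,
        "jmd_c": jl,
        "jmd_n_tmd_n": jl + n_half,
        "tmd_c_jmd_c": (tmd_len - n_half) + jl,
        "tmd_jmd": 2 * jl + tmd_len,
    }


def reference_part_offsets(
    tmd_len: int = 20, cfg: PartConfig = PartConfig()
) -> Dict[str, int]:
    """1-based part start offsets in the same fixed reference frame."""
    n_half = (tmd_len + 1) // 2
    jl = cfg.jmd_len
    return {
        "jmd_n": 1,
        "tmd": jl + 1,
        "tmd_n": jl + 1,
        "tmd_c": jl + n_half + 1,
        "tmd_e": jl - cfg.ext_len + 1,
        "jmd_c": jl + tmd_len + 1,
        "jmd_n_tmd_n": 1,
        "tmd_c_jmd_c": jl + n_half + 1,
        "tmd_jmd": 1,
    }


def filter_valid(
    entries: List[ProteinEntry], cfg: PartConfig = PartConfig()
) -> tuple[List[ProteinEntry], List[tuple[str, str]]]:
    """Split entries into accepted ones and (id, reason) rejections."""
    kept, dropped = [], []
    for e in entries:
        v = validate_entry(e, cfg)
        if v.accepted:
            kept.append(e)
        else:
            dropped.append((e.id, v.reason))
    return kept, dropped
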