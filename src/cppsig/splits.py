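"""The split universe: segments, patterns, and periodic patterns.

A *split* is a rule that selects a subset of residue positions from a
sequence part of given length:

* **Segments** — the i-th of n equally sized continuous chunks, for
  n = 1..15; 120 splits in total.
* **Patterns** — discontinuous subsets of 2-4 residues separated by 3 or 4
  positions (the face periodicity of an alpha-helix), anchored at either
  terminus, with the overall span capped at 15 residues; 182 splits.
* **Periodic patterns** — every 3rd, every 4th, or alternating 3rd/4th
  residue across a whole part, from either terminus; 28 splits.

The default universe therefore has 330 splits.  Enumeration order is
deterministic (kind, then lexicographic parameters) so split ids are
stable across runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import List, Optional, Tuple

SPAN_MAX = 15

#: periodic step variants: name -> step cycle
PERIODIC_VARIANTS = {
    "3-only": (3,),
    "4-only": (4,),
    "alt-3-first": (3, 4),
    "alt-4-first": (4, 3),
}


class NotApplicable(Exception):
    """Raised when a split's span exceeds the part length.

    The feature value is *undefined* for such a part, never 0.
    """


@dataclass(frozen=True)
class SplitSpec:
    """One split rule; exactly one parameter group is populated per kind."""

    kind: str  # "segment" | "pattern" | "periodic"
    # segment
    i_th: Optional[int] = None
    n_segments: Optional[int] = None
    # pattern / periodic
    terminus: Optional[str] = None  # "N" | "C"
    start_offset: Optional[int] = None
    steps: Optional[Tuple[int, ...]] = None  # pattern: literal step sequence
    variant: Optional[str] = None  # periodic: key of PERIODIC_VARIANTS

    @property
    def span(self) -> Optional[int]:
        """Minimal part length required (None = any length works)."""
        if self.kind == "segment":
            return None
        if self.kind == "pattern":
            return self.start_offset + sum(self.steps)
        return self.start_offset  # periodic needs the start residue only

    def describe(self) -> str:
        if self.kind == "segment":
            return f"Segment({self.i_th}/{self.n_segments})"
        if self.kind == "pattern":
            steps = "-".join(map(str, self.steps))
            return f"Pattern({self.terminus},{self.start_offset},{steps})"
        return f"Periodic({self.terminus},{self.start_offset},{self.variant})"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.describe()


def enumerate_segments(n_min: int = 1, n_max: int = 15) -> List[SplitSpec]:
    """All (i, n) segment splits for n = n_min..n_max; defaults give 120."""
    if not (1 <= n_min <= n_max):
        raise ValueError("require 1 <= n_min <= n_max")
    return [
        SplitSpec(kind="segment", i_th=i, n_segments=n)
        for n in range(n_min, n_max + 1)
        for i in range(1, n + 1)
    ]


def resolve_segment(L: int, spec: SplitSpec) -> List[int]:
    """Indices of segment i of n on a part of length L (1-based).

    Segment boundaries follow floor((i-1)*L/n)+1 .. floor(i*L/n), which
    partitions 1..L; a segment may be empty only when n > L.
    """
    if L < 1:
        raise ValueError("part length must be >= 1")
    i, n = spec.i_th, spec.n_segments
    lo = (i - 1) * L // n + 1
    hi = i * L // n
    return list(range(lo, hi + 1))


def enumerate_patterns(
    steps: Tuple[int, ...] = (3, 4),
    n_res: Tuple[int, ...] = (2, 3, 4),
    span_max: int = SPAN_MAX,
    termini: Tuple[str, ...] = ("N", "C"),
) -> List[SplitSpec]:
    """All pattern splits; defaults give 182 (91 per terminus)."""
    out = []
    for terminus in termini:
        for size in n_res:
            for step_seq in itertools.product(sorted(steps), repeat=size - 1):
                span = 1 + sum(step_seq)
                if span > span_max:
                    continue
                for start in range(1, span_max - span + 2):
                    out.append(
                        SplitSpec(
                            kind="pattern",
                            terminus=terminus,
                            start_offset=start,
                            steps=step_seq,
                        )
                    )
    return out


def _mirror(indices: List[int], L: int) -> List[int]:
    return sorted(L - p + 1 for p in indices)


def resolve_pattern(L: int, spec: SplitSpec) -> List[int]:
    """Indices selected by a pattern on a part of length L.

    N-anchored: {s, s+steps[0], ...} with s = start_offset.  C-anchored:
    the mirror image (p -> L-p+1), returned ascending.  A part shorter
    than the pattern span raises :class:`NotApplicable`.
    """
    span = spec.span
    if L < span:
        raise NotApplicable(f"part length {L} < pattern span {span}")
    idx = [spec.start_offset]
    for step in spec.steps:
        idx.append(idx[-1] + step)
    if spec.terminus == "C":
        return _mirror(idx, L)
    return idx


def enumerate_periodic(termini: Tuple[str, ...] = ("N", "C")) -> List[SplitSpec]:
    """All periodic-pattern splits; defaults give 28 (14 per terminus)."""
    out = []
    for terminus in termini:
        for variant, cycle in PERIODIC_VARIANTS.items():
            for start in range(1, cycle[0] + 1):
                out.append(
                    SplitSpec(
                        kind="periodic",
                        terminus=terminus,
                        start_offset=start,
                        variant=variant,
                    )
                )
    return out


def resolve_periodic(L: int, spec: SplitSpec) -> List[int]:
    """Indices selected by a periodic pattern across a whole part."""
    if L < spec.start_offset:
        raise NotApplicable(f"part length {L} < start offset {spec.start_offset}")
    cycle = PERIODIC_VARIANTS[spec.variant]
    idx = [spec.start_offset]
    k = 0
    while True:
        nxt = idx[-1] + cycle[k % len(cycle)]
        if nxt > L:
            break
        idx.append(nxt)
        k += 1
    if spec.terminus == "C":
        return _mirror(idx, L)
    return idx


def resolve(L: int, spec: SplitSpec) -> List[int]:
    """Resolve any split kind to its ordered index set on length L."""
    if spec.kind == "segment":
        return resolve_segment(L, spec)
    if spec.kind == "pattern":
        return resolve_pattern(L, spec)
    if spec.kind == "periodic":
        return resolve_periodic(L, spec)
    raise ValueError(f"unknown split kind {spec.kind!r}")


def enumerate_all() -> List[SplitSpec]:
    """The full default split universe: 120 + 182 + 28 = 330 splits.

    Order is segments, patterns, periodic patterns; split ids are the
    1-based positions in this list.
    """
    return enumerate_segments() + enumerate_patterns() + enumerate_periodic()
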