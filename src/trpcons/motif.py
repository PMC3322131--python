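"""Degenerate basic-motif grammar and scanning.

The tubulin-binding stretch of TRPV1 reduces to a two-symbol grammar over
``{+, X}``: ``'+'`` positions demand a positively charged residue (lysine or
arginine by default — histidine is selectively excluded from this stretch),
``'X'`` positions accept anything except negatively charged residues and
helix breakers (D, E, P by default). The canonical 21-mer is
``+XXX+XX++XX+XX+XXXXXX``. Matching is per-position and can be relaxed to a
fraction of satisfied positions for cross-channel scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

#: the canonical tubulin-binding stretch grammar (21 positions)
TBS1_PATTERN = "+XXX+XX++XX+XX+XXXXXX"
#: '+' positions (1-based) generating :data:`TBS1_PATTERN` on a 21-mer
TBS1_PLUS_POSITIONS = (1, 5, 8, 9, 12, 15)

#: stricter helix-breaker preset (adds glycine)
X_EXCLUDED_STRICT = frozenset("DEPG")
#: wheel-consistent positive set (includes histidine)
PLUS_SET_KRH = frozenset("KRH")


@dataclass(frozen=True)
class MotifPattern:
    pattern: str
    plus_set: frozenset[str] = frozenset("KR")
    x_excluded: frozenset[str] = frozenset("DEP")
    min_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("pattern must be non-empty")
        bad = set(self.pattern) - {"+", "X"}
        if bad:
            raise ValueError(f"pattern symbols must be '+' or 'X', got {sorted(bad)}")
        if not (0.0 < self.min_fraction <= 1.0):
            raise ValueError("min_fraction must be in (0, 1]")

    def __len__(self) -> int:
        return len(self.pattern)


def match_at(
    sequence: str, offset: int, pattern: MotifPattern
) -> tuple[float, list[bool]]:
    """Evaluate the pattern at a 0-based offset.

    Position i passes if the symbol is '+' and the residue is in
    ``plus_set``, or the symbol is 'X' and the residue is not in
    ``x_excluded``. Returns (fraction passed, per-position flags).
    """
    if offset < 0 or offset + len(pattern) > len(sequence):
        raise ValueError(
            f"offset {offset} + pattern length {len(pattern)} exceeds "
            f"sequence length {len(sequence)}"
        )
    flags = []
    for sym, residue in zip(pattern.pattern, sequence[offset : offset + len(pattern)]):
        if sym == "+":
            flags.append(residue in pattern.plus_set)
        else:
            flags.append(residue not in pattern.x_excluded)
    return sum(flags) / len(flags), flags


def scan(
    sequence: str,
    pattern: MotifPattern,
    min_fraction: float | None = None,
) -> list[tuple[int, float]]:
    """Slide the pattern over the sequence; report (offset, fraction) hits
    with fraction >= the threshold (``pattern.min_fraction`` unless
    overridden — an override of 0 reports every offset). Hits sort by
    descending fraction, then ascending offset. A sequence shorter than the
    pattern yields no hits."""
    threshold = pattern.min_fraction if min_fraction is None else min_fraction
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("min_fraction must be in [0, 1]")
    hits = []
    for offset in range(len(sequence) - len(pattern) + 1):
        fraction, _ = match_at(sequence, offset, pattern)
        if fraction >= threshold:
            hits.append((offset, fraction))
    hits.sort(key=lambda h: (-h[1], h[0]))
    return hits


def pattern_from_positions(
    length: int,
    plus_positions: Sequence[int],
    plus_set: frozenset[str] = frozenset("KR"),
    x_excluded: frozenset[str] = frozenset("DEP"),
    min_fraction: float = 1.0,
) -> MotifPattern:
    """Build a pattern with '+' at the given 1-based positions, 'X' elsewhere
    (the grammar-from-conserved-basic-positions constructor)."""
    symbols = ["X"] * length
    for pos in plus_positions:
        if not (1 <= pos <= length):
            raise ValueError(f"plus position {pos} outside 1..{length}")
        symbols[pos - 1] = "+"
    return MotifPattern(
        pattern="".join(symbols),
        plus_set=plus_set,
        x_excluded=x_excluded,
        min_fraction=min_fraction,
    )
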