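"""Reference-anchored region mapping and extraction.

Domain coordinates live on the ungapped reference sequence; a single global
MSA carries every species. The column map translates each reference residue
index to its alignment column, a region then becomes a column span, and each
species' slice is that span of its own row. Column-span semantics mean that
insertions relative to the reference (columns where the reference is gapped)
inside the span are part of the slice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import Alignment, RegionDef

logger = logging.getLogger(__name__)


class CoordinateError(ValueError):
    """Region coordinates incompatible with the reference."""


@dataclass(frozen=True)
class ColumnMap:
    """Maps 1-based ungapped reference positions to 1-based alignment columns."""

    reference_id: str
    columns: tuple[int, ...]

    def __post_init__(self) -> None:
        cols = np.asarray(self.columns)
        if cols.size and not np.all(np.diff(cols) > 0):
            raise CoordinateError("column map must be strictly increasing")

    def __len__(self) -> int:
        return len(self.columns)

    def column(self, position: int) -> int:
        if not (1 <= position <= len(self.columns)):
            raise CoordinateError(
                f"reference position {position} outside 1..{len(self.columns)}"
            )
        return self.columns[position - 1]


@dataclass(frozen=True)
class RegionSlice:
    """One species' extract of a region.

    ``columns`` is the gapped column-wise string over the region span (used
    for pairwise distances); ``subsequence`` is the same with gaps removed;
    ``coverage`` is the fraction of span columns holding a real residue
    (non-gap, non-X) in this species.
    """

    region: str
    species: str
    columns: str
    subsequence: str
    coverage: float


def build_column_map(alignment: Alignment, reference_id: str) -> ColumnMap:
    """Locate each ungapped reference residue's alignment column."""
    row = alignment.get(reference_id).sequence  # KeyError if absent
    cols = tuple(i + 1 for i, ch in enumerate(row) if ch != "-")
    return ColumnMap(reference_id=reference_id, columns=cols)


def extract_region(
    alignment: Alignment, cmap: ColumnMap, region: RegionDef
) -> list[RegionSlice]:
    """Extract one :class:`RegionSlice` per species over the region's columns."""
    if region.end > len(cmap):
        raise CoordinateError(
            f"region {region.name!r} ends at {region.end} but reference "
            f"{cmap.reference_id!r} has {len(cmap)} residues"
        )
    lo = cmap.column(region.start) - 1
    hi = cmap.column(region.end)  # exclusive
    span = hi - lo
    slices = []
    for rec in alignment:
        chunk = rec.sequence[lo:hi]
        residues = sum(1 for ch in chunk if ch not in "-X")
        slices.append(
            RegionSlice(
                region=region.name,
                species=rec.id,
                columns=chunk,
                subsequence=chunk.replace("-", ""),
                coverage=residues / span,
            )
        )
    return slices


def filter_slices(
    slices: list[RegionSlice], min_coverage: float = 0.5
) -> list[RegionSlice]:
    """Drop slices below the coverage threshold (partial sequences are
    expected and excluded per region rather than globally). Excluded species
    are logged."""
    if not (0.0 <= min_coverage <= 1.0):
        raise ValueError("min_coverage must be in [0, 1]")
    kept = [s for s in slices if s.coverage >= min_coverage]
    excluded = [s.species for s in slices if s.coverage < min_coverage]
    if excluded:
        region = slices[0].region if slices else "?"
        logger.info(
            "region %s: excluded %d species below coverage %.2f: %s",
            region, len(excluded), min_coverage, ", ".join(excluded),
        )
    return kept
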