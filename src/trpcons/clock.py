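"""Amino-acid molecular clock: changes per 100 residues versus time.

Lineage pairs spanning known divergence events (mammal radiation,
bird/amphibian split, fish/amphibian split, ...) each contribute one point:
100 x mean pairwise-deletion p-distance over the stated sequence pairs,
against the event's age in million years. An ordinary-least-squares line
through the points gives the substitution pace; its time-axis crossing reads
out the protein's apparent origin, and a positive Y-intercept at time zero
reads out how far (in time at the current pace) the protein still is from a
fully settled sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .conservation import p_distance
from .io import Alignment, ProteinRecord


@dataclass(frozen=True)
class ClockPoint:
    """One lineage-comparison observation."""

    label: str
    changes_per_100: float
    divergence_time_mya: float
    pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.changes_per_100 <= 100.0):
            raise ValueError("changes_per_100 must be in [0, 100]")
        if self.divergence_time_mya < 0:
            raise ValueError("divergence time must be >= 0")


@dataclass(frozen=True)
class ClockFit:
    """OLS line through clock points."""

    slope: float  # changes per 100 aa per MY
    intercept: float  # changes per 100 aa at time 0
    residuals: tuple[float, ...]
    n_points: int

    @property
    def time_axis_intercept(self) -> float:
        """Time at which the fitted line crosses zero change (the apparent
        origin when negative times are read as 'MYA before the youngest
        comparison')."""
        if self.slope == 0:
            return float("nan")
        return -self.intercept / self.slope


def lineage_rate(
    pairs: Sequence[tuple[ProteinRecord, ProteinRecord]],
    alignment: Alignment,
) -> float:
    """Average amino-acid changes per 100 residues over the given pairs,
    each computed column-wise on the alignment with pairwise deletion."""
    if not pairs:
        raise ValueError("need at least one pair")
    values = []
    for a, b in pairs:
        row_a = alignment.get(a.id).sequence
        row_b = alignment.get(b.id).sequence
        d = p_distance(row_a, row_b, pair=(a.id, b.id))
        if not d.defined:
            raise ValueError(f"pair ({a.id}, {b.id}): no comparable sites")
        values.append(100.0 * d.p)
    return float(np.mean(values))


def fit_clock(points: Sequence[ClockPoint], anchor_zero: bool = False) -> ClockFit:
    """OLS fit of changes-per-100 against divergence time.

    ``anchor_zero`` adds the (0 MY, 0 changes) self-comparison point — the
    youngest lineage compared with itself — before fitting.
    """
    pts = list(points)
    if anchor_zero:
        pts.append(ClockPoint(label="present", changes_per_100=0.0,
                              divergence_time_mya=0.0))
    if len(pts) < 2:
        raise ValueError("need at least two points")
    t = np.array([p.divergence_time_mya for p in pts])
    y = np.array([p.changes_per_100 for p in pts])
    if np.all(t == t[0]):
        raise ValueError("all divergence times equal: degenerate fit")
    slope, intercept = np.polyfit(t, y, 1)
    residuals = tuple(float(r) for r in (y - (slope * t + intercept)))
    return ClockFit(slope=float(slope), intercept=float(intercept),
                    residuals=residuals, n_points=len(pts))


def compare_proteins(fits: Mapping[str, ClockFit]) -> list[dict[str, object]]:
    """Order protein families by clock slope, slowest (most conserved) first."""
    if not fits:
        raise ValueError("no fits to compare")
    rows = [
        {
            "family": name,
            "slope": fit.slope,
            "intercept": fit.intercept,
            "time_axis_intercept": fit.time_axis_intercept,
            "n_points": fit.n_points,
        }
        for name, fit in fits.items()
    ]
    rows.sort(key=lambda r: r["slope"])
    for rank, row in enumerate(rows, start=1):
        row["rank"] = rank
    return rows
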