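"""Helical-wheel projection and angular charge-clustering statistics.

A peptide is projected down a helix axis: residue i sits at angle
``(i-1) * 360 * turns / steps`` degrees (mod 360). The study setting is
steps=18, turns=7 (140°/residue); the canonical alpha-helix (3.6
residues/turn, 100°/residue) is steps=18, turns=5 and is selectable.
Positively charged residues (K, R, H) from all species are pooled on one
wheel and their angular clustering is quantified as the fraction captured by
the best-placed arc of fixed width, plus simple quadrant counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .regions import RegionSlice

#: residues counted as positively charged on the wheel
POSITIVE_RESIDUES = frozenset("KRH")


@dataclass(frozen=True)
class WheelProjection:
    species: str
    region: str
    steps: int
    turns: int
    #: (position from 1, residue, angle in [0, 360))
    residues: tuple[tuple[int, str, float], ...]

    def positive_angles(self) -> list[float]:
        return [a for _, r, a in self.residues if r in POSITIVE_RESIDUES]


@dataclass(frozen=True)
class ArcCoverage:
    """Best fixed-width arc over a pooled angle set.

    ``defined`` is False when there were no positive residues to cover.
    """

    width: float
    start: float
    covered: int
    total: int
    defined: bool = True

    @property
    def fraction(self) -> float:
        return self.covered / self.total if self.total else float("nan")


@dataclass(frozen=True)
class QuadrantCounts:
    """Positive-residue counts in the four quadrants anchored at 0°."""

    counts: tuple[int, int, int, int]

    @property
    def total(self) -> int:
        return sum(self.counts)


def project_wheel(
    slice_: RegionSlice, steps: int = 18, turns: int = 7
) -> WheelProjection:
    """Project a region slice's ungapped subsequence onto a helical wheel.

    'X' placeholders keep their position on the wheel but are never counted
    as charged.
    """
    if steps < 1 or turns < 1:
        raise ValueError("steps and turns must be positive integers")
    if not slice_.subsequence:
        raise ValueError(
            f"empty subsequence for {slice_.species!r} in region {slice_.region!r}"
        )
    step_angle = 360.0 * turns / steps
    residues = tuple(
        (i + 1, ch, (i * step_angle) % 360.0)
        for i, ch in enumerate(slice_.subsequence)
    )
    return WheelProjection(
        species=slice_.species,
        region=slice_.region,
        steps=steps,
        turns=turns,
        residues=residues,
    )


def superimpose(
    projections: Sequence[WheelProjection],
) -> list[tuple[float, str, str]]:
    """Pool positive residues of same-region, same-parameter wheels.

    Returns (angle, residue, species) triples; multiplicity is preserved so
    superimposing k identical species multiplies every count by k.
    """
    if not projections:
        raise ValueError("no projections to superimpose")
    key = (projections[0].region, projections[0].steps, projections[0].turns)
    pooled = []
    for proj in projections:
        if (proj.region, proj.steps, proj.turns) != key:
            raise ValueError(
                "projections mix regions or wheel parameters: "
                f"{key} vs {(proj.region, proj.steps, proj.turns)}"
            )
        for _, residue, angle in proj.residues:
            if residue in POSITIVE_RESIDUES:
                pooled.append((angle, residue, proj.species))
    return pooled


def best_arc_coverage(angles: Sequence[float], width: float) -> ArcCoverage:
    """Maximal fraction of angles inside an arc ``[a, a+width)`` (wrap-around
    allowed). Candidate starts are the pooled angles themselves, which is
    sufficient for the discrete optimum; ties break to the smallest start."""
    if not (0.0 < width <= 360.0):
        raise ValueError("width must be in (0, 360]")
    if len(angles) == 0:
        return ArcCoverage(width=width, start=float("nan"), covered=0, total=0,
                           defined=False)
    arr = np.asarray(angles, dtype=float) % 360.0
    best_start, best_count = None, -1
    for a in np.unique(arr):  # unique() sorts, so ties keep the smallest start
        count = int(np.sum((arr - a) % 360.0 < width))
        if count > best_count:
            best_start, best_count = float(a), count
    return ArcCoverage(width=width, start=best_start, covered=best_count,
                       total=len(arr))


def quadrant_counts(angles: Sequence[float]) -> QuadrantCounts:
    """Counts in [0,90), [90,180), [180,270), [270,360)."""
    arr = np.asarray(angles, dtype=float) % 360.0
    bins = np.floor_divide(arr, 90.0).astype(int)
    counts = tuple(int(np.sum(bins == q)) for q in range(4))
    return QuadrantCounts(counts=counts)


def plot_wheel(
    pooled: Sequence[tuple[float, str, str]],
    arc: Optional[ArcCoverage] = None,
    title: str = "",
    path: str | None = None,
):
    """Superimposed wheel figure: pooled positive residues as dots, the best
    arc shaded. Saves to ``path`` when given, returns the figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    colors = {"K": "red", "R": "green", "H": "indigo"}
    for angle, residue, _ in pooled:
        ax.plot(np.deg2rad(angle), 1.0, "o", color=colors.get(residue, "gray"),
                alpha=0.5)
    if arc is not None and arc.defined:
        theta = np.deg2rad(np.linspace(arc.start, arc.start + arc.width, 100))
        ax.fill_between(theta, 0, 1.1, color="gray", alpha=0.2)
    ax.set_yticklabels([])
    ax.set_title(title)
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
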