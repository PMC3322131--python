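"""Per-region conservation statistics.

The conservation measure is the uncorrected amino-acid p-distance — the
proportion of differing sites between two aligned sequences — computed with
pairwise deletion: a column is dropped for a pair exactly when either member
holds a gap or an unknown residue there. Per region, the distribution of all
unordered pairwise distances is summarized by its median (lower = more
conserved), variances come from column bootstrap, and regions are compared
with the Kruskal–Wallis rank test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .regions import RegionSlice

_MISSING = {"-", "X"}


class InsufficientDataError(ValueError):
    """Too few usable sequences for a statistic."""


@dataclass(frozen=True)
class PDistance:
    """Pairwise p-distance after pairwise deletion.

    ``p`` is NaN (``defined`` False) when no columns survive deletion.
    """

    pair: tuple[str, str]
    p: float
    n_compared: int

    @property
    def defined(self) -> bool:
        return self.n_compared > 0


@dataclass
class RegionDistanceSet:
    """All unordered pairwise distances of one region's retained species."""

    region: str
    distances: list[PDistance]
    bootstrap_variances: Optional[dict[tuple[str, str], float]] = None

    def _values(self) -> np.ndarray:
        return np.array([d.p for d in self.distances if d.defined])

    @property
    def median_p(self) -> float:
        vals = self._values()
        return float(np.median(vals)) if vals.size else float("nan")

    @property
    def mean_p(self) -> float:
        vals = self._values()
        return float(np.mean(vals)) if vals.size else float("nan")

    def quartiles(self) -> tuple[float, float]:
        vals = self._values()
        if not vals.size:
            return float("nan"), float("nan")
        q1, q3 = np.percentile(vals, [25, 75])
        return float(q1), float(q3)


@dataclass(frozen=True)
class KruskalWallisResult:
    H: float
    df: int
    p_value: float
    #: group name -> mean rank of its values in the pooled ranking
    mean_ranks: Mapping[str, float] = field(default_factory=dict)


def p_distance(seq_a: str, seq_b: str, pair: tuple[str, str] = ("a", "b")) -> PDistance:
    """Column-wise p-distance between two equal-length (aligned) strings.

    Columns where either symbol is ``'-'`` or ``'X'`` are excluded
    (pairwise deletion); ``p`` = differing / compared.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"aligned strings must have equal length ({len(seq_a)} != {len(seq_b)})"
        )
    compared = 0
    differing = 0
    for x, y in zip(seq_a, seq_b):
        if x in _MISSING or y in _MISSING:
            continue
        compared += 1
        if x != y:
            differing += 1
    p = differing / compared if compared else float("nan")
    return PDistance(pair=tuple(sorted(pair)), p=p, n_compared=compared)


def bootstrap_variance(
    seq_a: str, seq_b: str, replicates: int = 1000, seed: int = 0
) -> float:
    """Variance of p over column-bootstrap replicates (resample alignment
    columns with replacement, recompute p each time)."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned strings must have equal length")
    rng = np.random.default_rng(seed)
    a = np.frombuffer(seq_a.encode(), dtype="S1")
    b = np.frombuffer(seq_b.encode(), dtype="S1")
    missing = np.isin(a, [b"-", b"X"]) | np.isin(b, [b"-", b"X"])
    diff = (a != b) & ~missing
    n = len(seq_a)
    ps = []
    for _ in range(replicates):
        idx = rng.integers(0, n, size=n)
        compared = int(np.sum(~missing[idx]))
        if compared == 0:
            continue
        ps.append(float(np.sum(diff[idx])) / compared)
    if len(ps) < 2:
        return 0.0
    return float(np.var(ps, ddof=1))


def region_distances(
    slices: Sequence[RegionSlice],
    bootstrap_replicates: int | None = None,
    seed: int = 0,
) -> RegionDistanceSet:
    """All unordered pairwise distances over a region's aligned columns."""
    if len(slices) < 2:
        region = slices[0].region if slices else "?"
        raise InsufficientDataError(
            f"region {region!r}: need >= 2 retained sequences, got {len(slices)}"
        )
    region = slices[0].region
    distances = []
    variances: dict[tuple[str, str], float] = {}
    for sa, sb in itertools.combinations(slices, 2):
        d = p_distance(sa.columns, sb.columns, pair=(sa.species, sb.species))
        distances.append(d)
        if bootstrap_replicates:
            variances[d.pair] = bootstrap_variance(
                sa.columns, sb.columns, bootstrap_replicates, seed=seed
            )
    return RegionDistanceSet(
        region=region,
        distances=distances,
        bootstrap_variances=variances or None,
    )


def _kruskal_h(values: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Tie-corrected Kruskal–Wallis H (used for permutation replicates)."""
    n = values.size
    ranks = stats.rankdata(values)
    h = 0.0
    for g in range(k):
        r = ranks[labels == g]
        h += r.sum() ** 2 / r.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie if tie > 0 else 0.0


def kruskal_wallis(
    groups: Mapping[str, Sequence[float]],
    permutation: bool = False,
    n_permutations: int = 9999,
    seed: int = 0,
) -> KruskalWallisResult:
    """Kruskal–Wallis rank ANOVA across named groups.

    Default p-value is the chi-square approximation with df = groups - 1;
    ``permutation=True`` replaces it with a seeded Monte-Carlo label
    permutation p (useful for tiny groups).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    labels = np.concatenate([np.full(a.size, i) for i, a in enumerate(arrays)])
    ranks = stats.rankdata(pooled)
    mean_ranks = {
        name: float(ranks[labels == i].mean()) for i, name in enumerate(names)
    }
    df = len(names) - 1
    if np.all(pooled == pooled[0]):
        # all observations tied: zero evidence of a location difference
        return KruskalWallisResult(H=0.0, df=df, p_value=1.0, mean_ranks=mean_ranks)
    H, p = stats.kruskal(*arrays)
    if permutation:
        rng = np.random.default_rng(seed)
        k = len(names)
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(labels)
            if _kruskal_h(pooled, perm, k) >= H - 1e-12:
                exceed += 1
        p = (exceed + 1) / (n_permutations + 1)
    return KruskalWallisResult(H=float(H), df=df, p_value=float(p), mean_ranks=mean_ranks)


def conservation_report(
    region_sets: Sequence[RegionDistanceSet],
) -> list[dict[str, object]]:
    """Boxplot-ready rows: region, median, quartiles, pair count.

    Rows keep the caller's ordering; pooled full-length or comparison-protein
    sets are passed in as additional :class:`RegionDistanceSet` entries.
    """
    if not region_sets:
        raise InsufficientDataError("no region sets to report")
    rows = []
    for rs in region_sets:
        q1, q3 = rs.quartiles()
        rows.append(
            {
                "region": rs.region,
                "n_pairs": sum(1 for d in rs.distances if d.defined),
                "median_p": rs.median_p,
                "mean_p": rs.mean_p,
                "q1": q1,
                "q3": q3,
            }
        )
    return rows
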