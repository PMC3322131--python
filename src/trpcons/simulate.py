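"""Synthetic protein families with known conservation structure.

The generator emits a star phylogeny: every tip is derived independently from
one ancestral sequence, each site mutating with probability
``base_rate * relative_rate(site)``. Region definitions carve the sequence
into spans with their own relative rates (0 = invariant), so the realized
per-region divergence ranking is known by construction. A motif region can be
declared with a ``{+, X}`` grammar: ``'+'`` sites carry only K/R (in the
ancestor and under substitution) at a strongly reduced rate, ``'X'`` sites
never carry the excluded residues. Indels are applied only outside declared
regions and are emitted as gap columns of the true alignment, so region
extraction can be tested without running an aligner.

The emitted statistical structure is deliberately minimal: uniform random
replacement, no exchangeability matrix, no rate heterogeneity beyond the
per-region factors, no tree shape beyond the star — the downstream statistics
depend only on per-site identity versus difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import AA20, Alignment, ProteinRecord, RegionDef

_AA = sorted(AA20)

_GROUP_CYCLE = ("mammal", "bird_reptile", "fish", "amphibian")


class FamilyParamError(ValueError):
    """Inconsistent simulation parameters."""


@dataclass
class FamilyParams:
    """Parameters of a simulated homologous protein family.

    relative_rate scales the per-site substitution probability inside each
    region; sites outside all regions evolve at relative rate 1. When regions
    overlap, the later entry in ``regions`` wins at the shared sites.
    """

    n_species: int = 32
    length: int = 839
    regions: Sequence[tuple[RegionDef, float]] = field(default_factory=list)
    base_rate: float = 0.3
    motif_spec: Optional[tuple[str, str]] = None  # (region name, pattern over {+,X})
    motif_conservation: float = 0.1  # multiplies relative_rate at '+' sites
    plus_set: frozenset[str] = frozenset("KR")
    x_excluded: frozenset[str] = frozenset("DEP")
    indel_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 1 or self.length < 1:
            raise FamilyParamError("n_species and length must be positive")
        if not (0.0 <= self.base_rate <= 1.0):
            raise FamilyParamError("base_rate must be a probability")
        if not (0.0 <= self.indel_rate <= 1.0):
            raise FamilyParamError("indel_rate must be a probability")
        for region, rate in self.regions:
            if rate < 0:
                raise FamilyParamError(f"region {region.name!r}: negative rate")
            if region.start < 1 or region.end > self.length:
                raise FamilyParamError(
                    f"region {region.name!r} exceeds sequence length {self.length}"
                )
        if self.motif_spec is not None:
            name, pattern = self.motif_spec
            if not pattern or set(pattern) - {"+", "X"}:
                raise FamilyParamError("motif pattern must be non-empty over {+,X}")
            region = self._find_region(name)
            if region.span != len(pattern):
                raise FamilyParamError(
                    f"motif pattern length {len(pattern)} != span of {name!r}"
                )

    def _find_region(self, name: str) -> RegionDef:
        for region, _ in self.regions:
            if region.name == name:
                return region
        raise FamilyParamError(f"motif region {name!r} not among regions")


@dataclass
class FamilyTruth:
    """Ground truth of a simulated family."""

    ancestor: str
    #: region name -> species id -> realized substitution count
    region_substitutions: dict[str, dict[str, int]]
    #: 1-based positions carrying the motif's positive charge
    motif_positions: list[int]


def _species_id(i: int) -> str:
    return f"sp{i:03d}"


def simulate_family(
    params: FamilyParams,
) -> tuple[list[ProteinRecord], Alignment, FamilyTruth]:
    """Simulate a star-phylogeny protein family.

    Returns ungapped tip records, the true gapped alignment, and the
    :class:`FamilyTruth`. Tip 0 is emitted indel-free so it can serve as a
    complete reference for coordinate mapping, the way the analysis anchors
    on a complete template sequence. Deterministic under ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    L = params.length

    rel = np.ones(L)
    in_region = np.zeros(L, dtype=bool)
    for region, rate in params.regions:
        rel[region.start - 1 : region.end] = rate
        in_region[region.start - 1 : region.end] = True

    plus_pos: list[int] = []
    x_pos: list[int] = []
    if params.motif_spec is not None:
        name, pattern = params.motif_spec
        region = params._find_region(name)
        for i, sym in enumerate(pattern):
            pos = region.start - 1 + i  # 0-based
            (plus_pos if sym == "+" else x_pos).append(pos)
        rel[plus_pos] = rel[plus_pos] * params.motif_conservation

    plus_alphabet = sorted(params.plus_set)
    x_alphabet = sorted(AA20 - params.x_excluded)

    ancestor = rng.choice(_AA, size=L)
    if plus_pos:
        ancestor[plus_pos] = rng.choice(plus_alphabet, size=len(plus_pos))
    if x_pos:
        ancestor[x_pos] = rng.choice(x_alphabet, size=len(x_pos))

    p_site = np.clip(params.base_rate * rel, 0.0, 1.0)

    plus_set = set(plus_pos)
    x_set = set(x_pos)
    tips = np.empty((params.n_species, L), dtype=ancestor.dtype)
    for s in range(params.n_species):
        tip = ancestor.copy()
        hit = np.nonzero(rng.random(L) < p_site)[0]
        for pos in hit:
            if pos in plus_set:
                pool = [a for a in plus_alphabet if a != tip[pos]]
            elif pos in x_set:
                pool = [a for a in x_alphabet if a != tip[pos]]
            else:
                pool = [a for a in _AA if a != tip[pos]]
            if pool:
                tip[pos] = pool[rng.integers(len(pool))]
        tips[s] = tip

    # indels outside regions: deletions blank a tip's cell; insertions add a
    # private column after the site (gap everywhere else)
    gapped = tips.astype(object)
    insertions: dict[int, list[tuple[int, str]]] = {}
    if params.indel_rate > 0:
        outside = np.nonzero(~in_region)[0]
        for s in range(1, params.n_species):  # tip 0 = indel-free reference
            dels = outside[rng.random(outside.size) < params.indel_rate / 2]
            gapped[s, dels] = "-"
            ins = outside[rng.random(outside.size) < params.indel_rate / 2]
            for pos in ins:
                insertions.setdefault(int(pos), []).append(
                    (s, _AA[rng.integers(len(_AA))])
                )

    region_subs: dict[str, dict[str, int]] = {}
    for region, _ in params.regions:
        sl = slice(region.start - 1, region.end)
        region_subs[region.name] = {
            _species_id(s): int(np.sum(tips[s, sl] != ancestor[sl]))
            for s in range(params.n_species)
        }

    rows = ["" for _ in range(params.n_species)]
    for col in range(L):
        for s in range(params.n_species):
            rows[s] += gapped[s, col]
        for owner, residue in insertions.get(col, []):
            for s in range(params.n_species):
                rows[s] += residue if s == owner else "-"

    groups = [_GROUP_CYCLE[s % len(_GROUP_CYCLE)] for s in range(params.n_species)]
    aligned = [
        ProteinRecord(
            id=_species_id(s),
            sequence=rows[s],
            species=f"species-{s}",
            group=groups[s],
        )
        for s in range(params.n_species)
    ]
    records = [
        ProteinRecord(id=r.id, sequence=r.ungapped, species=r.species, group=r.group)
        for r in aligned
    ]
    truth = FamilyTruth(
        ancestor="".join(ancestor),
        region_substitutions=region_subs,
        motif_positions=sorted(p + 1 for p in plus_pos),
    )
    return records, Alignment(aligned), truth


def simulate_pair(
    length: int, p_sub: float, seed: int
) -> tuple[ProteinRecord, ProteinRecord]:
    """A sequence and a mutated copy differing at Binomial(length, p_sub)
    sites; every mutated site is forced to a different residue, so the
    aligned p-distance estimates ``p_sub`` directly."""
    if not (0.0 <= p_sub <= 1.0):
        raise FamilyParamError("p_sub must be a probability")
    rng = np.random.default_rng(seed)
    a = rng.choice(_AA, size=length)
    b = a.copy()
    hit = np.nonzero(rng.random(length) < p_sub)[0]
    for pos in hit:
        pool = [x for x in _AA if x != b[pos]]
        b[pos] = pool[rng.integers(len(pool))]
    return (
        ProteinRecord(id="pair_a", sequence="".join(a)),
        ProteinRecord(id="pair_b", sequence="".join(b)),
    )
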