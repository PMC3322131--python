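import math

import numpy as np
import pytest

from trpcons.regions import RegionSlice
from trpcons.wheel import (
    best_arc_coverage,
    project_wheel,
    quadrant_counts,
    superimpose,
)


def _slice(seq, species="s", region="r"):
    return RegionSlice(region=region, species=species, columns=seq,
                       subsequence=seq.replace("-", ""), coverage=1.0)


def brute_force_arc(angles, width, grid=0.1):
    """Independent oracle: scan arc starts on a fine grid."""
    arr = np.asarray(angles) % 360.0
    best = 0
    for a in np.arange(0.0, 360.0, grid):
        best = max(best, int(np.sum((arr - a) % 360.0 < width)))
    return best


class TestProjectWheel:
    def test_first_residue_anchored_at_zero(self):
        proj = project_wheel(_slice("KALKR"), steps=18, turns=7)
        assert proj.residues[0] == (1, "K", 0.0)

    @pytest.mark.parametrize(
        "steps,turns,angle2", [(18, 7, 140.0), (18, 5, 100.0)],
        ids=["study-setting", "canonical-helix"],
    )
    def test_second_residue_angle(self, steps, turns, angle2):
        proj = project_wheel(_slice("KA"), steps=steps, turns=turns)
        assert proj.residues[1][2] == pytest.approx(angle2)

    def test_angle_formula_invariant(self):
        proj = project_wheel(_slice("A" * 25), steps=18, turns=7)
        for i, _, angle in proj.residues:
            assert angle == pytest.approx(((i - 1) * 360.0 * 7 / 18) % 360.0)
            assert 0 <= angle < 360

    def test_empty_subsequence_rejected(self):
        with pytest.raises(ValueError):
            project_wheel(_slice("---"))

    def test_positive_residues_are_k_r_h(self):
        proj = project_wheel(_slice("KRHADE"))
        assert len(proj.positive_angles()) == 3


class TestSuperimpose:
    def test_single_projection_is_its_own_pool(self):
        proj = project_wheel(_slice("KAK"))
        pooled = superimpose([proj])
        assert [(r, s) for _, r, s in pooled] == [("K", "s"), ("K", "s")]

    def test_identical_species_double_counts(self):
        p1 = project_wheel(_slice("KAK", species="a"))
        p2 = project_wheel(_slice("KAK", species="b"))
        pooled = superimpose([p1, p2])
        assert len(pooled) == 4
        assert sorted({a for a, _, _ in pooled}) == sorted(
            {a for a, _, _ in superimpose([p1])}
        )

    def test_mixed_parameters_rejected(self):
        p1 = project_wheel(_slice("KAK"), turns=7)
        p2 = project_wheel(_slice("KAK"), turns=5)
        with pytest.raises(ValueError):
            superimpose([p1, p2])


class TestBestArcCoverage:
    def test_full_circle_covers_everything(self):
        arc = best_arc_coverage([0, 77, 191, 300], 360.0)
        assert arc.fraction == 1.0

    def test_three_spread_angles_width_120(self):
        arc = best_arc_coverage([0, 100, 200], 120.0)
        assert arc.fraction == pytest.approx(2 / 3)
        assert arc.start == 0.0  # tie broken to the smallest start

    def test_wrap_around_arc(self):
        arc = best_arc_coverage([350, 10], 30.0)
        assert arc.fraction == 1.0 and arc.start == 350.0

    def test_no_positives_flagged_undefined(self):
        arc = best_arc_coverage([], 120.0)
        assert not arc.defined and math.isnan(arc.fraction)

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            best_arc_coverage([0.0], 0.0)

    def test_agrees_with_grid_brute_force(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            angles = rng.uniform(0, 360, size=rng.integers(1, 25)).tolist()
            width = float(rng.uniform(10, 350))
            arc = best_arc_coverage(angles, width)
            assert arc.covered == brute_force_arc(angles, width)

    def test_fraction_monotone_in_width(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            angles = rng.uniform(0, 360, size=12).tolist()
            fracs = [best_arc_coverage(angles, w).fraction
                     for w in (30, 60, 120, 180, 270, 360)]
            assert all(a <= b + 1e-12 for a, b in zip(fracs, fracs[1:]))
            assert fracs[-1] == 1.0


class TestQuadrantCounts:
    def test_empty(self):
        assert quadrant_counts([]).counts == (0, 0, 0, 0)

    def test_boundary_convention(self):
        assert quadrant_counts([0, 90, 180, 270]).counts == (1, 1, 1, 1)

    def test_uniform_angles_split_evenly(self):
        rng = np.random.default_rng(6)
        counts = quadrant_counts(rng.uniform(0, 360, 1000)).counts
        se = math.sqrt(1000 * 0.25 * 0.75)
        assert all(abs(c - 250) < 3 * se for c in counts)
        assert sum(counts) == 1000


def test_clustered_motif_family_recovers_designed_sector():
    """A family whose '+' sites project inside a 120-degree sector (and whose
    X sites never carry basic residues) concentrates all pooled positives in
    that sector."""
    from trpcons.io import RegionDef
    from trpcons.simulate import FamilyParams, simulate_family
    from trpcons.regions import build_column_map, extract_region

    region = RegionDef("helix", 11, 28)
    # steps=18, turns=7: positions 1,4,9,12,14,17 sit at 0,60,40,100,20,80 deg
    pattern = "+XX+XXXX+XX+X+XX+X"
    params = FamilyParams(
        n_species=8, length=60, base_rate=0.3,
        regions=[(region, 0.8)],
        motif_spec=("helix", pattern),
        x_excluded=frozenset("DEPKRH"),
        seed=3,
    )
    _, aln, _ = simulate_family(params)
    cmap = build_column_map(aln, "sp000")
    slices = extract_region(aln, cmap, region)
    pooled = superimpose([project_wheel(s, 18, 7) for s in slices])
    arc = best_arc_coverage([a for a, _, _ in pooled], 120.0)
    assert arc.total == 6 * 8  # only '+' sites are positive, all species
    assert arc.fraction == 1.0
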