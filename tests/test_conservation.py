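import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trpcons.conservation import (
    InsufficientDataError,
    bootstrap_variance,
    conservation_report,
    kruskal_wallis,
    p_distance,
    region_distances,
)
from trpcons.io import RegionDef
from trpcons.regions import RegionSlice
from trpcons.simulate import FamilyParams, simulate_family


def _slice(name, species, cols):
    return RegionSlice(region=name, species=species, columns=cols,
                       subsequence=cols.replace("-", ""),
                       coverage=1.0)


class TestPDistance:
    @pytest.mark.parametrize(
        "a,b,p,n",
        [
            ("AAAA", "AAAA", 0.0, 4),
            ("AAAA", "AATT", 0.5, 4),
            ("A-CD", "ABCD", 0.0, 3),
            ("AXCD", "AACD", 0.0, 3),
            ("----", "AAAA", None, 0),
        ],
        ids=["identity", "half", "gap-deleted", "x-deleted", "undefined"],
    )
    def test_hand_counted_cases(self, a, b, p, n):
        d = p_distance(a, b)
        assert d.n_compared == n
        if p is None:
            assert not d.defined and math.isnan(d.p)
        else:
            assert d.p == p

    def test_unequal_length_rejected(self):
        with pytest.raises(ValueError):
            p_distance("AAA", "AAAA")

    @given(
        st.lists(
            st.tuples(
                st.sampled_from("ACDKLX-"), st.sampled_from("ACDKLX-")
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_symmetry(self, pairs):
        a = "".join(x for x, _ in pairs)
        b = "".join(y for _, y in pairs)
        da, db = p_distance(a, b), p_distance(b, a)
        assert da.n_compared == db.n_compared
        assert (math.isnan(da.p) and math.isnan(db.p)) or da.p == db.p

    @given(
        st.lists(
            st.tuples(st.sampled_from("ACDKL-"), st.sampled_from("ACDKL-")),
            min_size=2,
            max_size=30,
        )
    )
    def test_column_removal_never_increases_n_compared(self, pairs):
        a = "".join(x for x, _ in pairs)
        b = "".join(y for _, y in pairs)
        full = p_distance(a, b).n_compared
        assert p_distance(a[1:], b[1:]).n_compared <= full

    def test_mean_over_seeds_tracks_substitution_probability(self):
        from trpcons.simulate import simulate_pair

        ps = []
        for seed in range(100):
            a, b = simulate_pair(200, 0.3, seed=seed)
            ps.append(p_distance(a.sequence, b.sequence).p)
        se = math.sqrt(0.3 * 0.7 / 200) / math.sqrt(100)
        assert abs(np.mean(ps) - 0.3) < 3 * se


class TestBootstrapVariance:
    def test_identical_sequences_zero_variance(self):
        assert bootstrap_variance("AAAA", "AAAA", 100, seed=0) == 0.0

    def test_matches_binomial_closed_form(self):
        # p(1-p)/n = 0.25/4 = 0.0625 for "AAAA" vs "AATT"
        v = bootstrap_variance("AAAA", "AATT", replicates=10000, seed=1)
        assert abs(v - 0.0625) / 0.0625 < 0.2

    def test_deterministic_under_seed(self):
        kwargs = dict(replicates=500, seed=7)
        assert bootstrap_variance("AKCD", "AKTT", **kwargs) == bootstrap_variance(
            "AKCD", "AKTT", **kwargs
        )


class TestRegionDistances:
    def test_identical_slices_all_zero(self):
        rs = region_distances([_slice("r", f"s{i}", "MKWL") for i in range(3)])
        assert len(rs.distances) == 3  # k(k-1)/2
        assert rs.median_p == 0.0 and rs.mean_p == 0.0

    def test_single_slice_rejected(self):
        with pytest.raises(InsufficientDataError):
            region_distances([_slice("r", "a", "MKWL")])

    def test_invariant_region_median_zero(self):
        params = FamilyParams(
            n_species=5, length=60, base_rate=0.5,
            regions=[(RegionDef("frozen", 11, 40), 0.0)], seed=2,
        )
        _, aln, _ = simulate_family(params)
        slices = [_slice("frozen", r.id, r.sequence[10:40]) for r in aln]
        assert region_distances(slices).median_p == 0.0

    def test_medians_increase_with_simulated_rate(self):
        rates = [0.2, 1.0, 2.0]
        regions = [
            (RegionDef(f"r{i}", 1 + 60 * i, 60 * (i + 1)), rate)
            for i, rate in enumerate(rates)
        ]
        ok = 0
        for seed in range(5):
            params = FamilyParams(n_species=8, length=180, base_rate=0.25,
                                  regions=regions, seed=seed)
            _, aln, _ = simulate_family(params)
            medians = []
            for i in range(3):
                lo, hi = 60 * i, 60 * (i + 1)
                slices = [_slice(f"r{i}", r.id, r.sequence[lo:hi]) for r in aln]
                medians.append(region_distances(slices).median_p)
            ok += medians[0] < medians[1] < medians[2]
        assert ok >= 4


class TestKruskalWallis:
    def test_hand_ranked_two_group_case(self):
        res = kruskal_wallis({"g1": [1, 2, 3], "g2": [4, 5, 6]})
        assert res.H == pytest.approx(3.857, abs=5e-4)
        assert res.df == 1
        assert 0 <= res.p_value <= 1

    def test_identical_groups_tie_corrected_to_zero(self):
        res = kruskal_wallis({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert res.H == 0.0 and res.p_value == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis({"only": [1, 2, 3]})

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        groups = {f"g{i}": rng.normal(i, 1, size=12).tolist() for i in range(3)}
        transformed = {k: list(np.exp(v)) for k, v in groups.items()}
        assert kruskal_wallis(groups).H == pytest.approx(
            kruskal_wallis(transformed).H
        )

    def test_permutation_p_close_to_asymptotic(self):
        rng = np.random.default_rng(1)
        groups = {
            "a": rng.normal(0, 1, 15).tolist(),
            "b": rng.normal(0.8, 1, 15).tolist(),
        }
        asym = kruskal_wallis(groups)
        perm = kruskal_wallis(groups, permutation=True, n_permutations=2000,
                              seed=5)
        assert perm.H == asym.H
        assert abs(perm.p_value - asym.p_value) < 0.05


class TestConservationReport:
    def test_single_region_row(self):
        rs = region_distances([_slice("r", f"s{i}", "MKWL") for i in range(3)])
        rows = conservation_report([rs])
        assert rows[0]["region"] == "r" and rows[0]["median_p"] == 0.0

    def test_invariant_region_ranks_below_mutated(self):
        quiet = region_distances([_slice("q", f"s{i}", "MKWL") for i in range(3)])
        noisy = region_distances(
            [_slice("n", "s0", "MKWL"), _slice("n", "s1", "MKAA"),
             _slice("n", "s2", "TTWL")]
        )
        rows = {r["region"]: r["median_p"] for r in conservation_report([quiet, noisy])}
        assert rows["q"] < rows["n"]

    def test_empty_report_rejected(self):
        with pytest.raises(InsufficientDataError):
            conservation_report([])
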