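import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isoniche.standardization import (
    IncomparableBaselineError,
    baseline_summary,
    check_baseline_comparability,
    standardize_community,
    superimpose,
)
from isoniche.io import CommunityDataset


def _community(make_group, species_points, baseline):
    groups = {
        sp: make_group(pts, species=sp, role="baseline" if sp == baseline else "consumer")
        for sp, pts in species_points.items()
    }
    return CommunityDataset("eco", groups, baseline_species=baseline)


class TestBaselineSummary:
    def test_zero_variance_gives_degenerate_interval(self, make_group):
        g = make_group([(1.5, 3.0)] * 4, species="plant", role="baseline")
        s = baseline_summary(g)
        assert s.mean_d15N == 3.0
        assert s.ci95_d15N == (3.0, 3.0)
        assert s.ci95_d13C == (1.5, 1.5)

    def test_two_point_interval_matches_long_hand_t_oracle(self, make_group):
        # d15N = {0, 2}: mean 1, sd sqrt(2), se 1, t_{0.975, df=1} = 12.7062047...
        g = make_group([(5.0, 0.0), (5.0, 2.0)], role="baseline")
        s = baseline_summary(g)
        t975_df1 = 12.706204736174698
        assert s.ci95_d15N == pytest.approx((1 - t975_df1, 1 + t975_df1), abs=1e-9)

    def test_single_sample_rejected(self, make_group):
        with pytest.raises(ValueError, match="n >= 2"):
            baseline_summary(make_group([(0.0, 0.0)]))

    def test_fixture_baseline_mean_within_printed_range(self, arreo):
        target, _ = arreo
        std = standardize_community(target)
        s = baseline_summary(std.baseline)
        assert -0.4 <= s.mean_d15N <= 0.6  # macrophyte's published span


class TestComparability:
    def test_identical_summaries_comparable(self, make_group):
        s = baseline_summary(make_group([(0, 0), (1, 1), (2, 2)], role="baseline"))
        assert check_baseline_comparability(s, s).verdict == "comparable"

    def test_disjoint_nitrogen_intervals_not_comparable(self, make_group):
        lo = baseline_summary(make_group([(0, 0.0), (0, 0.01)], role="baseline"))
        hi = baseline_summary(make_group([(0, 10.0), (0, 10.01)], role="baseline"))
        res = check_baseline_comparability(lo, hi)
        assert not res.overlap_d15N and res.overlap_d13C
        assert res.verdict == "not_comparable"

    def test_touching_endpoints_count_as_overlap(self, make_group):
        import dataclasses

        a = baseline_summary(make_group([(0, 0), (0, 2)], role="baseline"))
        b = dataclasses.replace(
            a, ci95_d15N=(a.ci95_d15N[1], a.ci95_d15N[1] + 5.0)
        )
        assert check_baseline_comparability(a, b).verdict == "comparable"

    def test_symmetry(self, make_group):
        rng = np.random.default_rng(0)
        a = baseline_summary(make_group(rng.normal(size=(5, 2)), role="baseline"))
        b = baseline_summary(make_group(rng.normal(1.0, 1.0, (5, 2)), role="baseline"))
        ab, ba = check_baseline_comparability(a, b), check_baseline_comparability(b, a)
        assert ab.verdict == ba.verdict


class TestStandardize:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        shift=st.tuples(
            st.floats(-50, 50, allow_nan=False), st.floats(-50, 50, allow_nan=False)
        ),
        seed=st.integers(0, 10_000),
    )
    def test_shift_invariance_and_idempotence(self, shift, seed):
        from isoniche.io import IsotopeSample, SpeciesGroup

        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(6, 2))

        def build(offset):
            def grp(name, p, role):
                return SpeciesGroup(name, [
                    IsotopeSample(name, "eco", role,
                                  d13C=float(c) + offset[0],
                                  d15N=float(n) + offset[1])
                    for c, n in p
                ])
            return CommunityDataset(
                "eco",
                {"fish": grp("fish", pts[:4], "consumer"),
                 "plant": grp("plant", pts[4:], "baseline")},
                baseline_species="plant",
            )

        std0 = standardize_community(build((0.0, 0.0)))
        std1 = standardize_community(build(shift))
        np.testing.assert_allclose(
            std0.group("fish").xy, std1.group("fish").xy, atol=1e-9
        )
        # idempotence: re-standardizing subtracts a ~zero baseline mean
        std2 = standardize_community(std1)
        np.testing.assert_allclose(
            std1.group("fish").xy, std2.group("fish").xy, atol=1e-9
        )

    def test_baseline_centered_and_means_recorded(self, arreo):
        target, _ = arreo
        std = standardize_community(target)
        np.testing.assert_allclose(std.baseline.xy.mean(axis=0), 0.0, atol=1e-9)
        raw_mean = target.baseline.xy.mean(axis=0)
        assert std.baseline_mean_d13C == pytest.approx(raw_mean[0])
        assert std.baseline_mean_d15N == pytest.approx(raw_mean[1])

    def test_missing_baseline_raises(self, make_group):
        ds = CommunityDataset("eco", {"fish": make_group([(0, 0), (1, 1)])}, None)
        with pytest.raises(KeyError, match="baseline"):
            standardize_community(ds)


class TestSuperimpose:
    def test_adds_donor_group_without_touching_residents(self, arreo):
        target, donors = arreo
        std = standardize_community(target)
        donor = standardize_community(donors["A. anguilla"])
        combined = superimpose(std, donor, "A. anguilla")
        assert set(combined.groups) == set(std.groups) | {"A. anguilla"}
        assert combined.group("A. anguilla").n == 45
        assert combined.group("A. anguilla").provenance == "donor"
        for sp in std.groups:  # residents bitwise untouched
            np.testing.assert_array_equal(
                combined.group(sp).xy, std.group(sp).xy
            )
        # donor values not re-centered on combine
        np.testing.assert_array_equal(
            combined.group("A. anguilla").xy, donor.group("A. anguilla").xy
        )

    def test_double_superimposition_conflicts(self, arreo):
        target, donors = arreo
        std = standardize_community(target)
        donor = standardize_community(donors["T. tinca"])
        once = superimpose(std, donor, "T. tinca")
        with pytest.raises(ValueError, match="already present"):
            superimpose(once, donor, "T. tinca")

    def test_unknown_species_not_found(self, arreo):
        target, donors = arreo
        std = standardize_community(target)
        donor = standardize_community(donors["T. tinca"])
        with pytest.raises(KeyError, match="not found"):
            superimpose(std, donor, "A. pallipes")

    def test_incomparable_baselines_need_explicit_flag(self, make_group):
        a = baseline_summary(make_group([(0, 0.0), (0, 0.01)], role="baseline"))
        b = baseline_summary(make_group([(0, 9.0), (0, 9.01)], role="baseline"))
        comp = check_baseline_comparability(a, b)
        std_t = standardize_community(
            _community(make_group, {"x": [(0, 0)] * 3, "p": [(0, 0)] * 2}, "p")
        )
        std_d = standardize_community(
            _community(make_group, {"y": [(1, 1)] * 3, "p": [(0, 0)] * 2}, "p")
        )
        with pytest.raises(IncomparableBaselineError):
            superimpose(std_t, std_d, "y", comparability=comp)
        forced = superimpose(
            std_t, std_d, "y", comparability=comp, allow_incomparable=True
        )
        assert forced.audit["superimposed"][0]["comparability"] == "not_comparable"
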