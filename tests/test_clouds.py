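import numpy as np
import pytest
from scipy import stats

from dpsircloud import (
    AllZeroMembershipError,
    Cloud,
    DegeneracyWarning,
    GradeInterval,
    GradeScheme,
    aggregate_cloud,
    classify_grade,
    estimate_cloud,
    fixture_tables,
    generate_droplets,
    membership,
    membership_vector,
    standard_clouds,
)
from dpsircloud._util import round_half_up


class TestStandardClouds:
    def test_default_scheme_reproduces_published_parameters(self, grades):
        clouds = standard_clouds(grades)
        np.testing.assert_allclose([c.ex for c in clouds],
                                   [0.1, 0.3, 0.5, 0.7, 0.9], atol=1e-15)
        np.testing.assert_allclose([c.en for c in clouds], 1 / 30, atol=1e-15)
        assert all(c.he == grades.hyper_entropy_constant for c in clouds)

    def test_interval_midpoint_and_sixth_width(self):
        gs = GradeScheme(grades=(
            GradeInterval("lo", 0.0, 0.3), GradeInterval("hi", 0.3, 1.0)))
        lo, hi = standard_clouds(gs)
        assert (lo.ex, lo.en) == (pytest.approx(0.15), pytest.approx(0.05))
        assert (hi.ex, hi.en) == (pytest.approx(0.65), pytest.approx(0.7 / 6))


class TestBackwardEstimation:
    def test_zero_dispersion_sample(self):
        c = estimate_cloud([0.5, 0.5, 0.5, 0.5])
        assert (c.ex, c.en, c.he) == (0.5, 0.0, 0.0)

    def test_two_point_sample_hand_computation(self):
        # mean 0.5; S^2 = 0.02; En = sqrt(pi/2)*0.1; He = sqrt(S^2 - En^2)
        c = estimate_cloud([0.4, 0.6])
        assert c.ex == pytest.approx(0.5)
        assert c.en == pytest.approx(np.sqrt(np.pi / 2) * 0.1, abs=1e-12)
        assert c.he == pytest.approx(np.sqrt(0.02 - np.pi / 2 * 0.01), abs=1e-12)

    def test_negative_variance_excess_clamps_hyper_entropy(self):
        # bimodal two-point data: S^2 < En^2, He must clamp to 0 with warning
        with pytest.warns(DegeneracyWarning, match="clamped"):
            c = estimate_cloud([0.0, 1.0, 0.0, 1.0])
        assert c.he == 0.0

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            estimate_cloud([0.5])


class TestForwardGenerator:
    def test_determinism_under_fixed_seed(self):
        c = Cloud(0.5, 0.1, 0.01)
        a = generate_droplets(c, 500, seed=123)
        b = generate_droplets(c, 500, seed=123)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)

    def test_certainty_is_gaussian_kernel_of_x(self):
        c = Cloud(0.3, 0.08, 0.02)
        d = generate_droplets(c, 2000, seed=5)
        np.testing.assert_allclose(
            d.y, np.exp(-((d.x - c.ex) ** 2) / (2 * d.en_prime**2)), atol=1e-12)
        assert ((d.y > 0) & (d.y <= 1)).all()

    def test_zero_hyper_entropy_fixes_width_and_matches_moments(self):
        c = Cloud(0.5, 0.1, 0.0)
        n = 20_000
        d = generate_droplets(c, n, seed=9)
        assert (d.en_prime == 0.1).all()
        assert d.x.mean() == pytest.approx(0.5, abs=3 * 0.1 / np.sqrt(n))
        assert d.x.std(ddof=1) == pytest.approx(0.1, rel=0.05)

    def test_point_cloud_degenerates_to_certainty_one(self):
        d = generate_droplets(Cloud(0.4, 0.0, 0.0), 10, seed=0)
        assert (d.x == 0.4).all() and (d.y == 1.0).all()

    def test_x_histogram_normal_when_hyper_entropy_zero(self):
        c = Cloud(0.5, 0.1, 0.0)
        d = generate_droplets(c, 10_000, seed=3)
        ks = stats.kstest(d.x, "norm", args=(c.ex, c.en)).statistic
        assert ks < 1.63 / np.sqrt(10_000)  # 1% critical value

    def test_invalid_requests_rejected(self):
        with pytest.raises(ValueError):
            generate_droplets(Cloud(0.5, 0.1, 0.0), 0, seed=0)
        with pytest.raises(ValueError):
            generate_droplets(Cloud(0.5, 0.0, 0.1), 10, seed=0)

    @pytest.mark.parametrize("seed", range(20))
    def test_backward_forward_roundtrip(self, seed):
        """estimate_cloud recovers (Ex, En) of generated droplets within 3 SE."""
        c = Cloud(0.5, 0.1, 0.01)
        n = 10_000
        d = generate_droplets(c, n, seed=seed)
        est = estimate_cloud(d.x)
        sigma = np.hypot(c.en, c.he)  # total sd of x
        se_ex = sigma / np.sqrt(n)
        se_en = np.sqrt(np.pi / 2 - 1) * sigma / np.sqrt(n)
        assert est.ex == pytest.approx(c.ex, abs=3 * se_ex)
        assert est.en == pytest.approx(c.en, abs=3 * se_en)


class TestAggregation:
    def test_identity_for_single_cloud(self):
        c = Cloud(0.4, 0.1, 0.02)
        agg = aggregate_cloud([c], [1.0])
        assert (agg.ex, agg.en, agg.he) == (c.ex, c.en, c.he)

    def test_two_equal_clouds_halve_entropy_by_sqrt2(self):
        c = Cloud(0.4, 0.12, 0.03)
        agg = aggregate_cloud([c, c], [0.5, 0.5])
        assert agg.ex == pytest.approx(0.4)
        assert agg.en == pytest.approx(0.12 / np.sqrt(2))
        assert agg.he == pytest.approx(0.03 / np.sqrt(2))

    def test_expectation_linear_in_weights(self):
        clouds = [Cloud(0.2, 0.1, 0.01), Cloud(0.8, 0.05, 0.02)]
        w = np.array([0.3, -0.7])
        base = aggregate_cloud(clouds, w)
        scaled = aggregate_cloud(clouds, 0.5 * w)
        assert scaled.ex == pytest.approx(0.5 * base.ex)

    def test_published_long_term_table_with_corrected_sign(self, grades):
        """Signed aggregation over the published long-term-operation rows
        (R3 negative, per its mean score 0.33 < 0.5) gives Ex = 0.3332."""
        rows = fixture_tables()["LOP_corrected"]
        agg = aggregate_cloud(
            [Cloud(ex, en, he) for _, _, ex, en, he in rows],
            [w for _, w, _, _, _ in rows])
        assert round_half_up(agg.ex, 4) == 0.3332

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            aggregate_cloud([Cloud(0.5, 0.1, 0.0)], [0.5, 0.5])


class TestMembershipAndGrading:
    @pytest.mark.parametrize("ex, grade_idx, expected", [
        (0.0362, 0, 0.1601),   # construction-period expectation vs Grade I
        (0.3332, 1, 0.6090),   # long-term expectation vs Grade II
        (0.1229, 0, 0.7898),   # short-term CI lower bound vs Grade I
    ])
    def test_published_membership_values(self, grades, ex, grade_idx, expected):
        std = standard_clouds(grades)[grade_idx]
        assert round_half_up(membership(ex, std), 4) == expected

    def test_kernel_peaks_at_centre_and_decreases_symmetrically(self, grades):
        std = standard_clouds(grades)[2]
        assert membership(std.ex, std) == 1.0
        for d in (0.01, 0.05, 0.1):
            lo, hi = membership(std.ex - d, std), membership(std.ex + d, std)
            assert lo == pytest.approx(hi, abs=1e-15)
            assert lo < membership(std.ex - d / 2, std)

    def test_degenerate_standard_cloud(self):
        std = Cloud(0.5, 0.0, 0.0)
        assert membership(0.5, std) == 1.0
        assert membership(0.4, std) == 0.0

    def test_maximum_membership_classification(self, grades):
        assert classify_grade({"I": 0.1601, "II": 0, "III": 0, "IV": 0, "V": 0},
                              grades) == "I"
        assert classify_grade({"I": 0, "II": 0, "III": 1, "IV": 0, "V": 0},
                              grades) == "III"

    def test_ties_break_toward_more_severe_grade(self, grades):
        assert classify_grade({"I": 0.3, "II": 0.3, "III": 0, "IV": 0, "V": 0},
                              grades) == "II"

    def test_all_zero_membership_raises_with_fallback_advice(self, grades):
        zeros = {lab: 0.0 for lab in grades.labels}
        with pytest.raises(AllZeroMembershipError, match="interval"):
            classify_grade(zeros, grades)

    def test_membership_vector_keys_follow_scheme(self, grades):
        mv = membership_vector(0.25, grades)
        assert list(mv) == grades.labels
        assert max(mv, key=mv.get) == "II"
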