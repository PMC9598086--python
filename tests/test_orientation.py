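import numpy as np
import pytest

from osteotrace.core import MarkRecord
from osteotrace.errors import DegenerateCloudError, ValidationError
from osteotrace.orientation import (
    OrientationSample,
    circular_summary,
    false_positive_risk,
    mww_test,
    principal_axis,
    radial_normal,
    rayleigh_p,
    rayleigh_test,
    rose_histogram,
    score_angle,
    scores_to_sample,
)
from osteotrace.simulate import make_template, sample_scores


def _score(endpoints):
    ep = np.asarray(endpoints, float)
    return MarkRecord(
        mark_id="M1", specimen_id="S", template_id="T", mark_type="score",
        position=ep.mean(axis=0), endpoints=ep,
    )


class TestPrincipalAxis:
    def test_tube_axis(self, template):
        axis = principal_axis(template)
        assert np.degrees(np.arccos(abs(axis[0]))) < 1.0

    def test_rotated_tube(self, template):
        a = np.deg2rad(40.0)
        rot = np.array(
            [[np.cos(a), 0, np.sin(a)], [0, 1, 0], [-np.sin(a), 0, np.cos(a)]]
        )
        axis = principal_axis(template.points @ rot.T)
        expected = rot @ np.array([1.0, 0.0, 0.0])
        ang = np.degrees(np.arccos(np.clip(abs(axis @ expected), -1, 1)))
        assert ang < 1.0

    def test_sphere_rejected(self, rng):
        pts = rng.normal(size=(500, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        with pytest.raises(DegenerateCloudError, match="no dominant axis"):
            principal_axis(pts)


class TestScoreAngle:
    X = np.array([1.0, 0.0, 0.0])

    @pytest.mark.parametrize("d,expected", [
        ((1, 0, 0), 0.0), ((0, 1, 0), 90.0), ((1, 1, 0), 45.0),
    ])
    def test_basic_angles(self, d, expected):
        score = _score([(0, 0, 0), d])
        assert score_angle(score, self.X) == pytest.approx(expected, abs=1e-9)

    def test_endpoint_swap_invariance(self):
        normal = np.array([0.0, 0.0, 1.0])
        fwd = _score([(0, 0, 0), (1, 0.6, 0)])
        back = _score([(1, 0.6, 0), (0, 0, 0)])
        for nrm in (None, normal):
            assert score_angle(fwd, self.X, nrm) == pytest.approx(
                score_angle(back, self.X, nrm), abs=1e-9
            )

    def test_signed_range_with_normal(self):
        normal = np.array([0.0, 0.0, 1.0])
        up = _score([(0, 0, 0), (1, 1, 0)])
        down = _score([(0, 0, 0), (1, -1, 0)])
        a_up = score_angle(up, self.X, normal)
        a_down = score_angle(down, self.X, normal)
        assert a_up == pytest.approx(45.0)
        assert a_down == pytest.approx(135.0)

    def test_punctual_rejected(self):
        pit = MarkRecord(
            mark_id="M1", specimen_id="S", template_id="T", mark_type="pit",
            position=np.zeros(3),
        )
        with pytest.raises(ValidationError):
            score_angle(pit, self.X)

    def test_joint_rotation_invariance(self):
        tpl = make_template("femur", "left", 200, 10, (20, 22), 2000, seed=3)
        marks = sample_scores(tpl, 30, 60.0, 4.0, seed=4)
        before = scores_to_sample(marks, tpl).angles

        a = np.deg2rad(25.0)
        rot = np.array(
            [[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]]
        )
        tpl.points = tpl.points @ rot.T
        for m in marks:
            m.endpoints = m.endpoints @ rot.T
            m.position = m.position @ rot.T
        after = scores_to_sample(marks, tpl).angles
        dev = np.minimum(np.abs(after - before), 180 - np.abs(after - before))
        assert dev.max() < 0.5


class TestCircularSummary:
    def test_degenerate_concentration(self):
        cs = circular_summary(OrientationSample(np.array([30.0, 30.0, 30.0])))
        assert cs.rbar == pytest.approx(1.0)
        assert cs.variance == pytest.approx(0.0, abs=1e-12)
        assert cs.central_deg[0] == pytest.approx(30.0)
        assert cs.central_deg[1] == pytest.approx(-150.0)
        assert np.isnan(cs.dispersion) and np.isnan(cs.skewness)

    def test_four_compass_points_cancel(self):
        cs = circular_summary(OrientationSample(np.array([0.0, 45.0, 90.0, 135.0])))
        assert cs.rbar == pytest.approx(0.0, abs=1e-12)
        assert cs.variance == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_sample_zero_skewness(self, rng):
        center = 50.0
        half = rng.uniform(0.0, 40.0, 64)
        angles = np.concatenate([center + half, center - half]) % 180.0
        cs = circular_summary(OrientationSample(angles))
        assert abs(cs.skewness) < 1e-9

    def test_central_pair_180_apart(self, rng):
        angles = rng.uniform(0, 180, 50)
        cs = circular_summary(OrientationSample(angles))
        assert cs.central_deg[0] - cs.central_deg[1] == pytest.approx(180.0)

    def test_needs_two(self):
        with pytest.raises(ValidationError):
            circular_summary(OrientationSample(np.array([10.0])))


class TestRayleigh:
    def test_zero_rbar(self):
        result = rayleigh_test(rbar=0.0, n=20)
        assert result.p == pytest.approx(1.0)

    def test_statistic_is_rbar(self):
        result = rayleigh_test(rbar=0.5, n=20)
        assert result.statistic == pytest.approx(0.5)

    def test_invalid_rbar(self):
        with pytest.raises(ValidationError):
            rayleigh_test(rbar=1.5, n=20)

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            rayleigh_test(rbar=0.5, n=3)

    def test_sample_route_matches_pair_route(self, rng):
        angles = rng.uniform(0, 180, 40)
        sample = OrientationSample(angles)
        theta = 2 * np.deg2rad(angles)
        rbar = float(np.hypot(np.cos(theta).mean(), np.sin(theta).mean()))
        assert rayleigh_test(sample).p == pytest.approx(
            rayleigh_p(rbar, 40), rel=1e-12
        )


class TestMww:
    def test_identical_samples(self):
        values = np.array([10.0, 35.0, 70.0, 110.0, 150.0])
        a, b = OrientationSample(values), OrientationSample(values.copy())
        with pytest.warns(UserWarning, match="midranks"):
            result = mww_test(a, b, n_rand=199, seed=1)
        assert result.statistic < 1e-9
        assert result.p >= 0.5

    def test_concentrated_difference_detected(self, rng):
        a = OrientationSample(rng.vonmises(0.0, 8.0, 30) % np.pi * 180 / np.pi)
        b = OrientationSample(
            (rng.vonmises(np.pi, 8.0, 30) % (2 * np.pi)) / 2 * 180 / np.pi
        )
        result = mww_test(a, b, n_rand=499, seed=2)
        assert result.p < 0.01

    def test_small_sample_rejected(self):
        a = OrientationSample(np.array([1.0, 2.0, 3.0]))
        b = OrientationSample(np.array([5.0, 6.0, 7.0, 8.0]))
        with pytest.raises(ValidationError):
            mww_test(a, b)

    def test_determinism(self, rng):
        a = OrientationSample(rng.uniform(0, 180, 20))
        b = OrientationSample(rng.uniform(0, 180, 20))
        r1 = mww_test(a, b, n_rand=99, seed=11)
        r2 = mww_test(a, b, n_rand=99, seed=11)
        assert r1.p == r2.p


class TestFpr:
    def test_closed_form(self):
        result = false_positive_risk(0.05, prior_h1=0.5)
        assert result.statistic == pytest.approx(0.2894, abs=1e-4)

    def test_wild_tibia_consistency(self):
        # p = 5.0e-7 must satisfy the < 0.008% bound
        result = false_positive_risk(5.0e-7, prior_h1=0.5)
        assert result.statistic == pytest.approx(2.0e-5, rel=0.05)
        assert result.statistic < 8e-5

    def test_monotone_in_p(self):
        grid = np.linspace(1e-6, 1 / np.e - 1e-6, 40)
        values = [false_positive_risk(p).statistic for p in grid]
        assert np.all(np.diff(values) > 0)

    def test_uninformative_bound(self):
        result = false_positive_risk(0.5)
        assert np.isnan(result.statistic)
        assert "not informative" in result.details["note"]

    def test_invalid_p(self):
        with pytest.raises(ValidationError):
            false_positive_risk(0.0)


class TestRoseHistogram:
    def test_single_angle(self):
        counts = rose_histogram(OrientationSample(np.array([0.0])), 36)
        assert counts[0] == 1 and counts[18] == 1 and counts.sum() == 2

    def test_near_flat_for_uniform(self):
        sample = OrientationSample(np.arange(0.0, 180.0, 1.0))
        counts = rose_histogram(sample, 36)  # 180 angles, 10 deg sectors, doubled
        assert counts.min() == 10 and counts.max() == 10

    def test_sum_is_2n(self, rng):
        sample = OrientationSample(rng.uniform(0, 180, 57))
        assert rose_histogram(sample, 36).sum() == 114

    def test_odd_sectors_rejected(self):
        with pytest.raises(ValidationError):
            rose_histogram(OrientationSample(np.array([0.0])), 35)


def test_radial_normal_perpendicular_to_axis():
    axis = np.array([1.0, 0.0, 0.0])
    nrm = radial_normal(np.array([50.0, 10.0, 0.0]), axis, np.zeros(3))
    assert nrm @ axis == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(nrm, [0.0, 1.0, 0.0])
    assert radial_normal(np.array([50.0, 0.0, 0.0]), axis, np.zeros(3)) is None
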