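import numpy as np
import pytest

from osteotrace.errors import EmptyCropError, ValidationError
from osteotrace.simulate import make_crop_set
from osteotrace.survivorship import (
    CropMask,
    crop_interval,
    crop_polygonal,
    full_mask,
    mask_from_cloud,
    max_interval_overlap,
    mne_report,
    superimpose,
)


def _ray_cast_inside(px, py, verts):
    """Even-odd rule oracle (boundary handling not exercised by the fixture)."""
    inside = False
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_at = x1 + (py - y1) / (y2 - y1) * (x2 - x1)
            if px < x_at:
                inside = not inside
    return inside


class TestCropPolygonal:
    def test_full_rectangle_keeps_all(self, template):
        lo, hi = template.bbox
        rect = [(lo[0] - 1, lo[1] - 1), (hi[0] + 1, lo[1] - 1),
                (hi[0] + 1, hi[1] + 1), (lo[0] - 1, hi[1] + 1)]
        mask = crop_polygonal(template, rect, "xy", "inside")
        assert mask.retained.all()

    def test_half_rectangle_matches_oracle(self, template):
        lo, hi = template.bbox
        mid = (lo[0] + hi[0]) / 2.0
        rect = [(lo[0] - 1, lo[1] - 1), (mid, lo[1] - 1),
                (mid, hi[1] + 1), (lo[0] - 1, hi[1] + 1)]
        mask = crop_polygonal(template, rect, "xy", "inside")
        oracle = np.array(
            [_ray_cast_inside(p[0], p[1], rect) for p in template.points]
        )
        np.testing.assert_array_equal(mask.retained, oracle)

    def test_irregular_polygon_matches_oracle(self, template):
        verts = [(-80.0, -40.0), (40.0, -35.0), (90.0, 10.0), (0.0, 45.0),
                 (-60.0, 20.0)]
        mask = crop_polygonal(template, verts, "xz", "inside")
        pts2 = template.points[:, [0, 2]]
        oracle = np.array([_ray_cast_inside(x, z, verts) for x, z in pts2])
        np.testing.assert_array_equal(mask.retained, oracle)

    def test_keep_outside_complements(self, template):
        verts = [(-50.0, -20.0), (50.0, -20.0), (0.0, 30.0)]
        inside = crop_polygonal(template, verts, "xy", "inside")
        outside = crop_polygonal(template, verts, "xy", "outside")
        assert not np.any(inside.retained & outside.retained)
        assert np.all(inside.retained | outside.retained)

    def test_empty_region_raises(self, template):
        with pytest.raises(EmptyCropError):
            crop_polygonal(
                template, [(1e4, 1e4), (1e4 + 1, 1e4), (1e4, 1e4 + 1)], "xy"
            )

    def test_self_intersecting_rejected(self, template):
        bowtie = [(0, 0), (10, 10), (10, 0), (0, 10)]
        with pytest.raises(ValidationError):
            crop_polygonal(template, bowtie, "xy")

    def test_too_few_vertices(self, template):
        with pytest.raises(ValidationError):
            crop_polygonal(template, [(0, 0), (1, 1)], "xy")


class TestCropInterval:
    def test_full_interval(self, template):
        assert crop_interval(template, "x", 0.0, 1.0).retained.all()

    def test_halves_partition(self, template):
        a = crop_interval(template, "x", 0.0, 0.5)
        b = crop_interval(template, "x", 0.5, 1.0)
        assert not np.any(a.retained & b.retained)
        assert np.all(a.retained | b.retained)

    def test_uniform_tube_fraction(self, uniform_tube):
        mask = crop_interval(uniform_tube, "x", 0.4, 0.6)
        frac = mask.n_retained / uniform_tube.n_points
        assert abs(frac - 0.2) < 0.02

    def test_inverted_interval(self, template):
        with pytest.raises(ValidationError):
            crop_interval(template, "x", 0.6, 0.4)


class TestSuperimpose:
    def test_two_full_masks(self, template):
        field = superimpose([full_mask(template, "a"), full_mask(template, "b")])
        assert (field.counts == 2).all()
        assert field.mne == 2

    def test_complementary_halves(self, template):
        masks = [crop_interval(template, "x", 0.0, 0.5),
                 crop_interval(template, "x", 0.5, 1.0)]
        assert superimpose(masks).mne == 1

    def test_known_stabbing_count(self, template):
        intervals = [(0.1, 0.7), (0.2, 0.8), (0.3, 0.9), (0.0, 0.65), (0.35, 1.0)]
        masks, truth = make_crop_set(template, 5, intervals, seed=1)
        assert superimpose(masks).mne == truth["max_overlap"] == 5

    def test_mixed_templates_rejected(self, template, uniform_tube):
        with pytest.raises(ValidationError, match="mixed"):
            superimpose([full_mask(template), full_mask(uniform_tube)])

    def test_order_invariance(self, template, rng):
        intervals = [(s, min(s + 0.3, 1.0)) for s in rng.uniform(0, 0.7, 8)]
        masks, _ = make_crop_set(template, 8, intervals, seed=1)
        shuffled = [masks[i] for i in rng.permutation(8)]
        assert superimpose(masks).mne == superimpose(shuffled).mne

    def test_point_permutation_invariance(self, template, rng):
        intervals = [(0.0, 0.6), (0.3, 1.0), (0.2, 0.7)]
        masks, _ = make_crop_set(template, 3, intervals, seed=1)
        perm = rng.permutation(template.n_points)
        permuted = [
            CropMask(m.specimen_id, m.template_id, m.retained[perm]) for m in masks
        ]
        assert superimpose(permuted).mne == superimpose(masks).mne

    def test_complete_specimen_increments(self, template):
        masks = [crop_interval(template, "x", 0.0, 0.5),
                 crop_interval(template, "x", 0.25, 0.75)]
        before = superimpose(masks)
        after = superimpose(masks + [full_mask(template)])
        np.testing.assert_array_equal(after.counts, before.counts + 1)
        assert after.mne == before.mne + 1

    def test_k_complete_is_constant(self, template):
        field = superimpose([full_mask(template) for _ in range(4)])
        assert (field.counts == 4).all()


class TestMneReport:
    def test_groups(self, template, uniform_tube):
        groups = {
            ("femur", "left"): [full_mask(template, "a"), full_mask(template, "b")],
            ("tibia", "right"): [
                crop_interval(uniform_tube, "x", 0.0, 0.5, specimen_id="c"),
                crop_interval(uniform_tube, "x", 0.5, 1.0, specimen_id="d"),
            ],
        }
        report = mne_report(None, groups)
        femur = report[report.element == "femur"].iloc[0]
        tibia = report[report.element == "tibia"].iloc[0]
        assert femur.mne == 2 and tibia.mne == 1

    def test_single_complete(self, template):
        report = mne_report(None, {("femur", "left"): [full_mask(template)]})
        assert report.iloc[0].mne == 1

    def test_empty_group_warns(self, template):
        with pytest.warns(UserWarning, match="omitted"):
            report = mne_report(None, {("femur", "left"): []})
        assert len(report) == 0

    def test_random_fixture_matches_analytic(self, template, rng):
        intervals = []
        for _ in range(10):
            lo = rng.uniform(0, 0.8)
            intervals.append((lo, min(lo + rng.uniform(0.1, 0.5), 1.0)))
        masks, truth = make_crop_set(template, 10, intervals, seed=1)
        report = mne_report(None, {("femur", "left"): masks})
        assert report.iloc[0].mne == truth["max_overlap"]


def test_mask_from_cloud_round_trip(template):
    mask = crop_interval(template, "x", 0.2, 0.8, specimen_id="SPX")
    cloud = template.points[mask.retained]
    recovered, n_unmatched = mask_from_cloud(template, cloud, specimen_id="SPX")
    assert n_unmatched == 0
    np.testing.assert_array_equal(recovered.retained, mask.retained)


def test_mask_from_cloud_rejects_far_points(template):
    cloud = np.vstack([template.points[:10], [[1e3, 1e3, 1e3]]])
    with pytest.warns(UserWarning, match="rejected"):
        mask, n_unmatched = mask_from_cloud(template, cloud)
    assert n_unmatched == 1
    assert mask.n_retained == 10


def test_max_interval_overlap():
    assert max_interval_overlap([(0.0, 1.0), (0.0, 1.0)]) == 2
    assert max_interval_overlap([(0.0, 0.5), (0.5, 1.0)]) == 1
    assert max_interval_overlap([(0.0, 0.6), (0.4, 1.0), (0.4, 0.6)]) == 3
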