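import numpy as np
import pytest
from scipy.spatial.distance import cdist

from mercquant import (
    CLASS_ER,
    Calibration,
    LabelMask,
    MercParams,
    classify_contact_pixels,
    er_contour_distance_field,
    group_contacts,
    label_objects,
    nm_to_px,
    summarize_mercs,
    trace_contour,
)
from mercquant.merc import CONTACT_CLOSE, CONTACT_LOOSE, CONTACT_NONE, er_contour_pixels

from conftest import blob_label_mask, random_label_mask

CAL1 = Calibration(1.0)


def brute_force_er_distance(mask: LabelMask) -> np.ndarray:
    """Exhaustive pairwise minimum over ER contour pixel centers, in nm."""
    seeds = er_contour_pixels(mask)
    h, w = mask.shape
    if seeds.shape[0] == 0:
        return np.full((h, w), np.inf)
    grid = np.argwhere(np.ones((h, w), dtype=bool))
    d = cdist(grid.astype(float), seeds.astype(float)).min(axis=1)
    return d.reshape(h, w) * mask.calibration.pixel_size_nm


class TestNmToPx:
    def test_tem_scale_conversions(self):
        cal = Calibration(0.38)
        assert nm_to_px(80, cal) == 211
        assert nm_to_px(15, cal) == 39
        assert nm_to_px(0, cal) == 0

    def test_half_rounds_away_from_zero(self):
        assert nm_to_px(2.5, Calibration(1.0)) == 3

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            nm_to_px(-1, CAL1)


class TestMercParams:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            MercParams(close_nm=80, loose_nm=15)
        with pytest.raises(ValueError):
            MercParams(close_nm=0, loose_nm=10)


class TestDistanceField:
    def test_no_er_gives_all_infinite(self):
        labels = np.zeros((6, 6), dtype=np.uint8)
        labels[1:3, 1:3] = 1
        field = er_contour_distance_field(LabelMask(labels, CAL1))
        assert np.isinf(field.distances).all()

    def test_rect_scene_facing_distance(self, rect_mask):
        field = er_contour_distance_field(rect_mask)
        assert field.distances[4, 5] == pytest.approx(4.0)

    def test_zero_exactly_at_er_contour(self, rect_mask):
        field = er_contour_distance_field(rect_mask)
        seeds = er_contour_pixels(rect_mask)
        assert (field.distances[seeds[:, 0], seeds[:, 1]] == 0).all()
        on_contour = np.zeros(rect_mask.shape, dtype=bool)
        on_contour[seeds[:, 0], seeds[:, 1]] = True
        assert (field.distances[~on_contour] > 0).all()

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_masks(self, seed):
        mask = random_label_mask(seed, shape=(32, 32), p=(0.9, 0.05, 0.05))
        field = er_contour_distance_field(mask)
        expected = brute_force_er_distance(mask)
        assert np.allclose(field.distances, expected, atol=1e-9)


class TestClassify:
    def test_rect_scene_bottom_edge_loose(self, rect_mask):
        params = MercParams(close_nm=2, loose_nm=5)
        contour = trace_contour(label_objects(rect_mask, 1)[0])
        field = er_contour_distance_field(rect_mask)
        labels = classify_contact_pixels(contour, field, params)
        loose_pts = {tuple(p) for p in contour.points[labels == CONTACT_LOOSE]}
        assert loose_pts == {(4, c) for c in range(1, 11)}
        assert (labels == CONTACT_CLOSE).sum() == 0

    def test_tiny_loose_threshold_gives_all_none(self, rect_mask):
        params = MercParams(close_nm=1e-9, loose_nm=1e-6)
        contour = trace_contour(label_objects(rect_mask, 1)[0])
        field = er_contour_distance_field(rect_mask)
        assert (classify_contact_pixels(contour, field, params) == CONTACT_NONE).all()

    def test_strict_boundary_semantics_at_loose_threshold(self, rect_mask):
        # facing gap is exactly 4 nm
        contour = trace_contour(label_objects(rect_mask, 1)[0])
        field = er_contour_distance_field(rect_mask)
        strict = classify_contact_pixels(
            contour, field, MercParams(close_nm=2, loose_nm=4)
        )
        assert (strict[field.distances[contour.points[:, 0], contour.points[:, 1]] == 4]
                == CONTACT_NONE).all()
        inclusive = classify_contact_pixels(
            contour, field, MercParams(close_nm=2, loose_nm=4, strict_inequality=False)
        )
        assert (inclusive == CONTACT_LOOSE).sum() == 10

    def test_partition_close_loose_union(self, rect_mask):
        params = MercParams(close_nm=3, loose_nm=6)
        contour = trace_contour(label_objects(rect_mask, 1)[0])
        field = er_contour_distance_field(rect_mask)
        labels = classify_contact_pixels(contour, field, params)
        d = field.distances[contour.points[:, 0], contour.points[:, 1]]
        assert set(np.flatnonzero(labels != CONTACT_NONE)) == set(
            np.flatnonzero(d < params.loose_nm)
        )
        assert not (set(np.flatnonzero(labels == CONTACT_CLOSE))
                    & set(np.flatnonzero(labels == CONTACT_LOOSE)))

    def test_point_outside_field_rejected(self, rect_mask):
        contour = trace_contour(label_objects(rect_mask, 1)[0])
        from mercquant import DistanceField

        small = DistanceField(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            classify_contact_pixels(contour, small, MercParams())


class TestGroupContacts:
    def test_collinear_run_length(self, rect_mask):
        params = MercParams(close_nm=2, loose_nm=5)
        contour = trace_contour(label_objects(rect_mask, 1)[0])
        field = er_contour_distance_field(rect_mask)
        labels = classify_contact_pixels(contour, field, params)
        segs = group_contacts(labels, contour, field, CAL1, params)
        assert len(segs) == 1
        assert segs[0].contact_type == "loose"
        assert segs[0].n_pixels == 10
        assert segs[0].length_nm == pytest.approx(9.0)
        assert segs[0].min_distance_nm == pytest.approx(4.0)

    def test_all_none_gives_empty_list(self, rect_mask):
        params = MercParams(close_nm=1e-9, loose_nm=1e-6)
        contour = trace_contour(label_objects(rect_mask, 1)[0])
        field = er_contour_distance_field(rect_mask)
        labels = classify_contact_pixels(contour, field, params)
        assert group_contacts(labels, contour, field, CAL1, params) == []

    def test_wrap_around_run_counts_once(self, rect_mask):
        params = MercParams(close_nm=2, loose_nm=5)
        contour = trace_contour(label_objects(rect_mask, 1)[0])
        field = er_contour_distance_field(rect_mask)
        n = len(contour)
        labels = np.full(n, CONTACT_NONE, dtype=np.int8)
        for i in (n - 2, n - 1, 0, 1):
            labels[i] = CONTACT_LOOSE
        segs = group_contacts(labels, contour, field, CAL1, params)
        assert len(segs) == 1
        assert segs[0].n_pixels == 4
        assert sorted(segs[0].pixel_indices) == [0, 1, n - 2, n - 1]

    def test_fully_contacted_contour_is_one_full_perimeter_segment(self):
        labels = np.zeros((9, 9), dtype=np.uint8)
        labels[3:6, 3:6] = 1
        labels[1, 1:8] = 2  # ER close above
        mask = LabelMask(labels, CAL1)
        params = MercParams(close_nm=50, loose_nm=80)
        report = summarize_mercs(mask, params)
        assert report.n_close == 1 and report.n_loose == 0
        assert report.len_close_nm == pytest.approx(report.total_mito_contour_nm)

    def test_per_segment_mode_merges_types_by_min_distance(self, rect_mask):
        # close band on the middle of the bottom edge, loose at its flanks
        params = MercParams(
            close_nm=4.5, loose_nm=6, classification_mode="per_segment"
        )
        contour = trace_contour(label_objects(rect_mask, 1)[0])
        field = er_contour_distance_field(rect_mask)
        labels = classify_contact_pixels(contour, field, params)
        segs = group_contacts(labels, contour, field, CAL1, params)
        # bottom edge (d=4) and the two adjacent corner-ish pixels of the
        # side columns (d=sqrt(17)<6) form one run typed by min distance
        assert len(segs) == 1
        assert segs[0].contact_type == "close"


class TestSummarize:
    def test_rect_scene_end_to_end(self, rect_mask):
        report = summarize_mercs(rect_mask, MercParams(close_nm=2, loose_nm=5))
        assert report.n_mitochondria == 1
        assert report.n_er_objects == 1
        assert report.mito_area_nm2 == pytest.approx(40.0)
        assert report.er_area_nm2 == pytest.approx(30.0)
        assert report.n_close == 0
        assert report.n_loose == 1
        assert report.len_loose_nm == pytest.approx(9.0)

    def test_empty_mask_all_zero(self):
        report = summarize_mercs(LabelMask(np.zeros((8, 8), dtype=np.uint8), CAL1))
        assert (
            report.n_mitochondria,
            report.n_er_objects,
            report.n_close,
            report.n_loose,
        ) == (0, 0, 0, 0)
        assert report.mito_area_nm2 == 0 and report.len_loose_nm == 0

    def test_mito_without_er_has_areas_but_no_contacts(self):
        labels = np.zeros((8, 8), dtype=np.uint8)
        labels[2:5, 2:5] = 1
        report = summarize_mercs(LabelMask(labels, CAL1))
        assert report.mito_area_nm2 > 0
        assert report.n_close == report.n_loose == 0
        assert report.len_close_nm == report.len_loose_nm == 0

    def test_translation_invariance(self, rect_mask):
        params = MercParams(close_nm=2, loose_nm=5)
        base = summarize_mercs(rect_mask, params)
        shifted = np.zeros((20, 20), dtype=np.uint8)
        shifted[4:16, 5:17] = rect_mask.labels
        moved = summarize_mercs(LabelMask(shifted, CAL1, "rect"), params)
        assert moved == base

    @pytest.mark.parametrize("seed", range(4))
    def test_conservation_and_threshold_monotonicity(self, seed):
        mask = blob_label_mask(seed)
        r40 = summarize_mercs(mask, MercParams(close_nm=15, loose_nm=40))
        r80 = summarize_mercs(mask, MercParams(close_nm=15, loose_nm=80))
        assert r40.len_close_nm + r40.len_loose_nm <= r40.total_mito_contour_nm + 1e-9
        assert r80.len_close_nm + r80.len_loose_nm <= r80.total_mito_contour_nm + 1e-9
        assert (
            r80.len_close_nm + r80.len_loose_nm
            >= r40.len_close_nm + r40.len_loose_nm - 1e-9
        )
        # raising close_nm never decreases L_C1
        r_c20 = summarize_mercs(mask, MercParams(close_nm=20, loose_nm=80))
        assert r_c20.len_close_nm >= r80.len_close_nm - 1e-9
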