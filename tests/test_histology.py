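"""Stain detection, size filtering, resolution matching, lesion surveys."""

import numpy as np
import pytest

from ferromap.histology import (
    DetectionMask,
    _build_objects,
    count_cells_in_clusters,
    detect_positive,
    downsample_mask,
    filter_objects,
    iron_positive_percent,
    match_clusters,
    segment_lesions,
    survey_lesions,
)
from ferromap.synthetic import (
    CellDeposit,
    HistologySlide,
    Lesion,
    SlideSpec,
    make_slide,
    random_slide_spec,
)


def _mask_dm(mask: np.ndarray, scale: float = 1.0) -> DetectionMask:
    return DetectionMask(mask=mask, objects=_build_objects(mask, scale), scale=scale)


def _white_slide(h=120, w=120, scale=1.0, stain="prussian_blue") -> HistologySlide:
    return HistologySlide(rgb=np.full((h, w, 3), 255, dtype=np.uint8), scale=scale, stain=stain)


class TestDetectPositive:
    def test_white_slide_empty_mask(self):
        dm = detect_positive(_white_slide())
        assert not dm.mask.any()
        assert dm.objects == []

    def test_planted_blobs_detected_exactly(self):
        spec = random_slide_spec(n_lesions=6, n_positive=2, seed=3)
        slide, truth = make_slide(spec)
        dm = detect_positive(slide)
        assert np.array_equal(dm.mask, truth.stain_mask)

    def test_counterstain_only_rejected(self):
        spec = random_slide_spec(n_lesions=5, n_positive=0, seed=6)
        slide, _ = make_slide(spec)
        dm = detect_positive(slide)
        assert not dm.mask.any()

    def test_unknown_stain_rejected(self):
        with pytest.raises(ValueError):
            detect_positive(_white_slide(stain="hematoxylin"))


class TestFilterObjects:
    def test_size_threshold_is_strict(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[5:10, 5:10] = True  # 25 um^2 at 1 um/px -> kept
        mask[30:33, 30:35] = True  # 15 um^2 -> removed
        out = filter_objects(_mask_dm(mask), min_area=20.0)
        assert len(out.objects) == 1
        assert out.objects[0].area_um2 == pytest.approx(25.0)

    def test_exactly_20_um2_removed(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:10, 5:9] = True  # exactly 20 px = 20 um^2
        out = filter_objects(_mask_dm(mask), min_area=20.0)
        assert len(out.objects) == 0
        assert not out.mask.any()

    def test_empty_mask_unchanged(self):
        out = filter_objects(_mask_dm(np.zeros((30, 30), dtype=bool)), min_area=20.0)
        assert not out.mask.any()
        assert out.objects == []

    def test_scale_enters_area(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:8, 5:8] = True  # 9 px; at 2 um/px that is 36 um^2
        out = filter_objects(_mask_dm(mask, scale=2.0), min_area=20.0)
        assert len(out.objects) == 1
        assert out.objects[0].area_um2 == pytest.approx(36.0)


class TestDownsampleMask:
    def test_full_block_gives_one(self):
        mask = np.zeros((200, 200), dtype=bool)
        mask[0:100, 0:100] = True
        mcm = downsample_mask(_mask_dm(mask), 100)
        assert mcm.values.shape == (2, 2)
        assert mcm.values[0, 0] == pytest.approx(1.0)
        assert mcm.values[1, 1] == pytest.approx(0.0)

    def test_half_block_gives_half(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[:, :50] = True
        mcm = downsample_mask(_mask_dm(mask), 100)
        assert mcm.values[0, 0] == pytest.approx(0.5, abs=0.01)

    def test_values_bounded_and_mass_conserved(self):
        rng = np.random.default_rng(2)
        mask = rng.random((300, 300)) < 0.3
        mcm = downsample_mask(_mask_dm(mask), 100)
        assert mcm.values.min() >= 0.0
        assert mcm.values.max() <= 1.0
        assert abs(mcm.values.mean() - mask.mean()) <= 0.01

    def test_reduced_pixel_area(self):
        mask = np.zeros((200, 200), dtype=bool)
        mcm = downsample_mask(_mask_dm(mask, scale=1.0), 100)
        # 100 px at 1 um/px -> 0.1 mm -> 0.01 mm^2 per reduced pixel
        assert mcm.reduced_pixel_area == pytest.approx(0.01)

    def test_image_smaller_than_block_rejected(self):
        with pytest.raises(ValueError):
            downsample_mask(_mask_dm(np.zeros((50, 50), dtype=bool)), 100)


class TestMatchClusters:
    def test_empty_map_no_clusters(self):
        mcm = downsample_mask(_mask_dm(np.zeros((200, 200), dtype=bool)), 100)
        assert len(match_clusters(mcm)) == 0

    def test_single_deposit_cluster_scale(self):
        """A 100x100 um deposit downsampled 1:100 is a ~0.01 mm^2 cluster,
        at the bottom of the 0.01-0.1 mm^2 deposit scale."""
        mask = np.zeros((400, 400), dtype=bool)
        mask[100:200, 100:200] = True
        cs = match_clusters(downsample_mask(_mask_dm(mask), 100))
        assert len(cs) == 1
        assert cs.clusters[0].area_mm2 == pytest.approx(0.01)

    def test_separation_controls_merging(self):
        # two deposits 300 um apart -> distinct reduced pixels, 2 clusters
        far = np.zeros((600, 600), dtype=bool)
        far[0:40, 0:40] = True
        far[340:380, 340:380] = True
        assert len(match_clusters(downsample_mask(_mask_dm(far), 100))) == 2
        # 50 um apart -> same/adjacent reduced pixels, 1 merged cluster
        near = np.zeros((600, 600), dtype=bool)
        near[100:140, 100:140] = True
        near[100:140, 190:230] = True
        assert len(match_clusters(downsample_mask(_mask_dm(near), 100))) == 1

    def test_planted_count_recovered_when_separated(self):
        """Deposits farther apart than one reduced pixel (> scale_factor *
        scale um) always map to distinct clusters."""
        rng = np.random.default_rng(21)
        for _ in range(10):
            mask = np.zeros((900, 900), dtype=bool)
            n = int(rng.integers(2, 5))
            # block-grid placement with >= 2 empty blocks between deposits
            cells = rng.choice(9, size=n, replace=False)
            for cell in cells:
                r, c = divmod(int(cell), 3)
                r0, c0 = 300 * r + int(rng.integers(0, 40)), 300 * c + int(rng.integers(0, 40))
                mask[r0 : r0 + 50, c0 : c0 + 50] = True
            cs = match_clusters(downsample_mask(_mask_dm(mask), 100))
            assert len(cs) == n


class TestCountCells:
    def test_no_clusters_empty_counts(self):
        mcm = downsample_mask(_mask_dm(np.zeros((200, 200), dtype=bool)), 100)
        cs = match_clusters(mcm)
        assert count_cells_in_clusters(_mask_dm(np.zeros((200, 200), dtype=bool)), cs, 100) == {}

    def test_planted_deposit_count(self):
        centers = [
            (250.0 + 14.0 * r, 250.0 + 14.0 * c) for r in (-1, 0, 1) for c in (-1.5, -0.5, 0.5, 1.5)
        ]
        spec = SlideSpec(
            width=512,
            height=512,
            lesions=[Lesion(row=250, col=250, radius=45)],
            deposits=[CellDeposit(lesion_index=0, centers=centers, areas_um2=[30.0] * 12)],
        )
        slide, truth = make_slide(spec)
        dm = filter_objects(detect_positive(slide), 20.0)
        cs = match_clusters(downsample_mask(dm, 100))
        counts = count_cells_in_clusters(dm, cs, 100)
        assert sum(counts.values()) == truth.cell_counts[0] == 12

    def test_totals_conserved_across_seeds(self):
        for seed in range(5):
            spec = random_slide_spec(n_lesions=5, n_positive=3, width=512, height=512, seed=seed)
            slide, truth = make_slide(spec)
            dm = filter_objects(detect_positive(slide), 20.0)
            cs = match_clusters(downsample_mask(dm, 100))
            counts = count_cells_in_clusters(dm, cs, 100)
            assert sum(counts.values()) == sum(truth.cell_counts)
            assert len(dm.objects) == sum(truth.cell_counts)


class TestSegmentLesions:
    def test_blank_slide_zero_lesions(self):
        ls = segment_lesions(_white_slide())
        assert ls.n_lesions == 0
        assert ls.table.empty

    def test_planted_lesions_recovered_with_high_iou(self):
        spec = random_slide_spec(n_lesions=10, n_positive=3, seed=7)
        slide, truth = make_slide(spec)
        ls = segment_lesions(slide)
        assert ls.n_lesions == 10
        for lid in range(1, 11):
            seg = ls.labels == lid
            ious = [
                (seg & (truth.lesion_labels == t)).sum() / (seg | (truth.lesion_labels == t)).sum()
                for t in range(1, 11)
            ]
            assert max(ious) >= 0.9

    def test_touching_lesions_merge(self):
        spec = SlideSpec(
            width=200,
            height=200,
            lesions=[Lesion(row=100, col=80, radius=30), Lesion(row=100, col=130, radius=30)],
        )
        slide, _ = make_slide(spec)
        assert segment_lesions(slide).n_lesions == 1

    def test_holes_from_stained_deposits_filled(self):
        spec = SlideSpec(
            width=200,
            height=200,
            lesions=[Lesion(row=100, col=100, radius=40)],
            deposits=[CellDeposit(lesion_index=0, centers=[(100.0, 100.0)], areas_um2=[60.0])],
        )
        slide, truth = make_slide(spec)
        ls = segment_lesions(slide)
        assert ls.n_lesions == 1
        # the blue blob's pixels belong to the filled lesion
        assert np.all(ls.labels[truth.stain_mask] == 1)


class TestSurvey:
    def test_percentages_floor_rounded(self):
        assert iron_positive_percent(42, 169) == 24
        assert iron_positive_percent(86, 105) == 81
        assert iron_positive_percent(3, 10) == 30
        assert iron_positive_percent(0, 7) == 0
        assert iron_positive_percent(0, 0) is None

    def test_floor_rule_arbitrary_pairs(self):
        rng = np.random.default_rng(30)
        for _ in range(200):
            total = int(rng.integers(1, 500))
            pos = int(rng.integers(0, total + 1))
            assert iron_positive_percent(pos, total) == int(100 * pos // total)

    def test_survey_on_synthetic_slide(self):
        spec = random_slide_spec(n_lesions=10, n_positive=3, seed=7)
        slide, truth = make_slide(spec)
        dm = filter_objects(detect_positive(slide), 20.0)
        mcm = downsample_mask(dm, 100)
        ls = segment_lesions(slide)
        table, pct = survey_lesions(ls, dm, mcm)
        assert pct == 30
        assert int(table["iron_positive"].sum()) == 3
        assert int(table["hlm_count"].sum()) == sum(truth.cell_counts)

    def test_survey_empty_slide(self):
        slide = _white_slide(200, 200)
        dm = detect_positive(slide)
        mcm = downsample_mask(dm, 100)
        table, pct = survey_lesions(segment_lesions(slide), dm, mcm)
        assert table.empty
        assert pct is None
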