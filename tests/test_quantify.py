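"""Nucleus segmentation, background estimation, intensity integration, flags."""

from collections import deque
from dataclasses import replace

import numpy as np
import pytest

from chipcyto.errors import UnusableFieldError
from chipcyto.quantify import (
    NucleusRecord,
    estimate_background,
    flag_clumps,
    measure_nuclei,
    records_to_frame,
    segment_nuclei,
)
from chipcyto.simulate import FieldImage, render_field, sample_dna_contents


def _field(pixels, detector_max=65535):
    return FieldImage(
        pixels=np.asarray(pixels), exposure_ms=5.0, detector_max=detector_max
    )


def _disk_image(shape, centres, radius, value, background):
    px = np.full(shape, background, dtype=np.int64)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for r, c in centres:
        px[(yy - r) ** 2 + (xx - c) ** 2 <= radius**2] = value
    return px


class TestEstimateBackground:
    def test_constant_image_returns_constant(self):
        image = _field(np.full((32, 32), 40))
        assert estimate_background(image, np.zeros((32, 32), int)) == 40.0
        assert estimate_background(image) == 40.0

    def test_median_robust_to_small_bright_disk(self):
        px = _disk_image((64, 64), [(32, 32)], 8, 5000, 40)
        assert estimate_background(_field(px)) == 40.0

    def test_recovers_generator_background_level(self, rendered_field, small_optics):
        image, truth = rendered_field
        est = estimate_background(image, foreground_mask=truth.labels)
        assert abs(est - small_optics.background_mean) < 2.0

    def test_all_foreground_mask_is_an_error(self):
        image = _field(np.full((32, 32), 40))
        with pytest.raises(UnusableFieldError):
            estimate_background(image, np.ones((32, 32), int))


def _flood_fill_objects(binary):
    """Brute-force 8-connected component oracle: list of pixel-index sets."""
    seen = np.zeros_like(binary, dtype=bool)
    objects = []
    rows, cols = binary.shape
    for r0 in range(rows):
        for c0 in range(cols):
            if binary[r0, c0] and not seen[r0, c0]:
                comp = set()
                queue = deque([(r0, c0)])
                seen[r0, c0] = True
                while queue:
                    r, c = queue.popleft()
                    comp.add((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (
                                0 <= rr < rows
                                and 0 <= cc < cols
                                and binary[rr, cc]
                                and not seen[rr, cc]
                            ):
                                seen[rr, cc] = True
                                queue.append((rr, cc))
                objects.append(comp)
    return objects


class TestSegmentNuclei:
    def test_five_separated_disks_give_five_labels(self):
        centres = [(20, 20), (20, 60), (60, 20), (60, 60), (40, 40)]
        px = _disk_image((80, 80), centres, 6, 1000, 50)
        labels = segment_nuclei(_field(px), grow_px=0)
        assert labels.max() == 5

    def test_blank_noise_field_gives_zero_labels(self):
        rng = np.random.default_rng(0)
        px = np.rint(rng.normal(100, 3, (128, 128))).astype(np.int64)
        for method in ("background", "otsu"):
            labels = segment_nuclei(_field(px), threshold_method=method)
            assert labels.max() == 0

    def test_label_count_and_centroids_match_ground_truth(
        self, rendered_field
    ):
        image, truth = rendered_field
        labels = segment_nuclei(image)
        assert labels.max() == len(truth.table)
        hits = set()
        for _, row in truth.table.iterrows():
            lab = labels[int(round(row.centroid_row)), int(round(row.centroid_col))]
            assert lab > 0
            hits.add(lab)
        assert len(hits) == len(truth.table)

    def test_matches_flood_fill_oracle_on_disjoint_disks(self):
        centres = [(15, 15), (15, 45), (45, 15), (45, 48)]
        px = _disk_image((64, 64), centres, 5, 800, 20)
        image = _field(px)
        labels = segment_nuclei(image, min_area=10, grow_px=0)
        oracle = _flood_fill_objects(px > 400)
        assert labels.max() == len(oracle)
        oracle_sums = sorted(
            sum(int(px[r, c]) for r, c in comp) for comp in oracle
        )
        label_sums = sorted(
            int(px[labels == lab].sum()) for lab in range(1, labels.max() + 1)
        )
        assert label_sums == oracle_sums


class TestMeasureNuclei:
    def test_integrated_intensity_arithmetic(self):
        px = np.full((16, 16), 10, dtype=np.int64)
        labels = np.zeros((16, 16), dtype=np.int32)
        labels[4:6, 4:6] = 1
        px[4:6, 4:6] = 110
        records = measure_nuclei(_field(px), labels, background=10.0)
        assert len(records) == 1
        assert records[0].integrated_intensity == 400.0
        assert records[0].area_px == 4

    def test_negative_sum_clamps_to_zero(self):
        px = np.full((16, 16), 5, dtype=np.int64)
        labels = np.zeros((16, 16), dtype=np.int32)
        labels[3:5, 3:5] = 1
        records = measure_nuclei(_field(px), labels, background=50.0)
        assert records[0].integrated_intensity == 0.0

    def test_saturated_and_edge_flags(self):
        px = np.full((32, 32), 10, dtype=np.int64)
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[10:14, 10:14] = 1
        px[10:14, 10:14] = 4095
        labels[0:3, 20:23] = 2
        px[0:3, 20:23] = 500
        records = measure_nuclei(_field(px, detector_max=4095), labels, 10.0)
        by_id = {r.id: r for r in records}
        assert "saturated" in by_id[1].flags
        assert "edge" in by_id[2].flags
        assert by_id[2].flags == frozenset({"edge"})

    def test_mismatched_shapes_rejected(self):
        image = _field(np.full((16, 16), 10))
        with pytest.raises(ValueError):
            measure_nuclei(image, np.zeros((8, 8), dtype=np.int32), 0.0)

    def test_intensity_slope_recovers_gain_times_exposure(
        self, cycling_mixture, small_optics
    ):
        optics = replace(small_optics, cells_per_field=25, seed=31)
        contents = sample_dna_contents(cycling_mixture, 25, seed=31)
        image, truth = render_field(contents, optics)
        labels = segment_nuclei(image)
        background = estimate_background(image, foreground_mask=labels)
        records = measure_nuclei(image, labels, background)
        # match each record to truth via its centroid's truth label
        measured, true_content = [], []
        for rec in records:
            lab = truth.labels[int(round(rec.centroid[0])), int(round(rec.centroid[1]))]
            if lab > 0:
                measured.append(rec.integrated_intensity)
                true_content.append(truth.table.iloc[lab - 1].content)
        slope = np.polyfit(true_content, measured, 1)[0]
        expected = optics.gain * optics.exposure_ms
        assert slope == pytest.approx(expected, rel=0.05)

    def test_background_shift_invariance(self):
        rng = np.random.default_rng(1)
        px = np.rint(rng.normal(100, 2, (64, 64))).astype(np.int64)
        px[20:26, 20:26] += 2000
        labels = np.zeros((64, 64), dtype=np.int32)
        labels[20:26, 20:26] = 1
        img_a, img_b = _field(px), _field(px + 7)
        bg_a = estimate_background(img_a, foreground_mask=labels)
        bg_b = estimate_background(img_b, foreground_mask=labels)
        assert bg_b - bg_a == 7.0
        rec_a = measure_nuclei(img_a, labels, bg_a)[0]
        rec_b = measure_nuclei(img_b, labels, bg_b)[0]
        assert rec_a.integrated_intensity == rec_b.integrated_intensity


class TestFlagClumps:
    @staticmethod
    def _rec(i, area):
        return NucleusRecord(
            id=i, centroid=(0.0, 0.0), area_px=area, integrated_intensity=1.0
        )

    def test_area_outlier_flagged(self):
        records = [self._rec(i, a) for i, a in enumerate((100, 100, 100, 250))]
        flagged = flag_clumps(records, clump_factor=2.0)
        assert ["clump" in r.flags for r in flagged] == [False, False, False, True]

    def test_equal_areas_unflagged(self):
        records = [self._rec(i, 120) for i in range(6)]
        assert all(r.ok for r in flag_clumps(records))

    def test_too_few_records_is_noop_with_warning(self):
        records = [self._rec(0, 100), self._rec(1, 500)]
        with pytest.warns(UserWarning):
            flagged = flag_clumps(records)
        assert all(r.ok for r in flagged)

    def test_clump_confusion_matrix_on_rendered_field(
        self, cycling_mixture, small_optics
    ):
        """Merged placements are caught, singletons are spared."""
        optics = replace(
            small_optics,
            field_shape=(600, 600),
            cells_per_field=60,
            clump_prob=0.1,
            seed=37,
        )
        merged_hits = merged_total = single_flagged = single_total = 0
        for seed in (101, 202, 303):
            contents = sample_dna_contents(cycling_mixture, 60, seed=seed)
            image, truth = render_field(contents, replace(optics, seed=seed))
            labels = segment_nuclei(image)
            background = estimate_background(image, foreground_mask=labels)
            records = flag_clumps(measure_nuclei(image, labels, background))
            # a detected object is a true merger when it contains >= 2 truth centroids
            counts = {}
            for _, row in truth.table.iterrows():
                lab = labels[
                    int(round(row.centroid_row)), int(round(row.centroid_col))
                ]
                counts[lab] = counts.get(lab, 0) + 1
            for rec in records:
                n_truth = counts.get(rec.id, 0)
                if n_truth >= 2:
                    merged_total += 1
                    merged_hits += "clump" in rec.flags
                elif n_truth == 1:
                    single_total += 1
                    single_flagged += "clump" in rec.flags
        assert merged_total > 0
        assert merged_hits / merged_total >= 0.8
        assert single_flagged / single_total <= 0.05

    def test_records_frame_roundtrip(self):
        records = [self._rec(1, 50)]
        frame = records_to_frame(flag_clumps(records * 3))
        assert list(frame.columns) == [
            "id",
            "centroid_row",
            "centroid_col",
            "area_px",
            "integrated_intensity",
            "flags",
        ]
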