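"""Classical nucleus/signal detectors, assignment and IoU matching."""

import dataclasses
import math

import numpy as np
import pytest

from her2fish.annotations import BoundingBox, NucleusClass, SignalClass, crop
from her2fish.detection import (
    DEFAULT_PARAMS,
    NucleusDetection,
    SignalDetection,
    assign_signals,
    classify_nucleus_appearance,
    detect_nuclei,
    detect_signals,
    detection_metrics,
    match_detections,
)
from her2fish.synthetic import GeneratorConfig, planted_counts, render, sample_spec


def blank_image(w=300, h=200, color=(5, 5, 20)):
    image = np.empty((h, w, 3), dtype=np.uint8)
    image[:] = color
    return image


class TestDetectNuclei:
    def test_background_only_image_gives_no_detections(self):
        assert detect_nuclei(blank_image()) == []

    def test_non_rgb_input_rejected(self):
        with pytest.raises(TypeError):
            detect_nuclei(np.zeros((50, 50), dtype=np.uint8))

    def test_clean_scene_detected_at_high_iou(self, small_scene):
        spec, image, nuclei_ann, _ = small_scene
        detections = detect_nuclei(image)
        precision, recall, matching = detection_metrics(
            [d.box for d in detections], nuclei_ann.boxes(), iou_threshold=0.5
        )
        assert precision == 1.0 and recall == 1.0
        assert all(iou >= 0.8 for *_, iou in matching.pairs)

    def test_deterministic(self, small_scene):
        _, image, _, _ = small_scene
        assert detect_nuclei(image) == detect_nuclei(image)

    def test_appearance_read_recovers_planted_classes(self, small_config):
        """The intensity-based first read agrees with the planted class on
        clean imagery (it never sees the spot counts)."""
        correct = total = 0
        for seed in range(8):
            spec = sample_spec(small_config, 40 + seed)
            image, nuclei_ann, _ = render(spec)
            detections = detect_nuclei(image)
            _, _, matching = detection_metrics(
                [d.box for d in detections], nuclei_ann.boxes()
            )
            for pi, ti, _ in matching.pairs:
                total += 1
                correct += detections[pi].appearance_class is spec.nuclei[ti].true_class
        assert total > 20
        assert correct / total >= 0.95


class TestAppearanceClassifier:
    def test_pure_background_crop_is_artifact(self):
        image = blank_image()
        cls, conf = classify_nucleus_appearance(image, BoundingBox(10, 10, 110, 110))
        assert cls is NucleusClass.ARTIFACT
        assert 0.0 <= conf <= 1.0

    def test_cluster_nucleus_reads_high(self, small_config):
        cfg = dataclasses.replace(
            small_config,
            class_mixture=(("normal", 0.0), ("low", 0.0), ("high", 1.0),
                           ("uncertain", 0.0), ("artifact", 0.0)),
            cluster_probability=1.0,
        )
        spec = sample_spec(cfg, 9)
        image, nuclei_ann, _ = render(spec)
        for box in nuclei_ann.boxes():
            cls, _ = classify_nucleus_appearance(image, box)
            assert cls is NucleusClass.HIGH


class TestDetectSignals:
    def test_uniform_crop_gives_no_signals(self):
        assert detect_signals(blank_image(120, 120)) == []

    def test_planted_spots_recovered_with_classes(self, small_scene):
        spec, image, _, signal_sets = small_scene
        for nuc, sigs in zip(spec.nuclei, signal_sets):
            if nuc.cluster_regions:
                continue
            sub, (ox, oy) = crop(image, nuc.tight_box(spec.image_size), 10)
            found = [s.shift(ox, oy) for s in detect_signals(sub)]
            n_her2 = sum(s.signal_class is SignalClass.HER2 for s in found)
            n_cen17 = sum(s.signal_class is SignalClass.CEN17 for s in found)
            assert n_her2 == len(nuc.her2_positions)
            assert n_cen17 == len(nuc.cen17_positions)

    def test_cluster_detected_and_exclusive(self, small_config):
        """A planted cluster yields one HER2_cluster box and suppresses
        single-HER2 detections inside it."""
        cfg = dataclasses.replace(
            small_config,
            class_mixture=(("normal", 0.0), ("low", 0.0), ("high", 1.0),
                           ("uncertain", 0.0), ("artifact", 0.0)),
            cluster_probability=1.0,
        )
        found_cluster = False
        for seed in (3, 4, 5):
            spec = sample_spec(cfg, seed)
            image, _, _ = render(spec)
            for nuc in spec.nuclei:
                sub, _ = crop(image, nuc.tight_box(spec.image_size), 10)
                found = detect_signals(sub)
                clusters = [s for s in found if s.signal_class is SignalClass.HER2_CLUSTER]
                singles = [s for s in found if s.signal_class is SignalClass.HER2]
                assert len(clusters) >= 1
                found_cluster = True
                for single in singles:
                    assert not any(
                        c.box.contains_point(*single.box.center) for c in clusters
                    )
        assert found_cluster


def _sig(x, y, cls=SignalClass.HER2):
    return SignalDetection(BoundingBox(x - 3, y - 3, x + 3, y + 3), cls, 0.9)


class TestAssignSignals:
    NUCLEI = [BoundingBox(0, 0, 50, 50), BoundingBox(40, 0, 90, 50)]

    def test_no_signals(self):
        counts, unassigned = assign_signals(self.NUCLEI, [])
        assert [c.n_her2 + c.n_cen17 + c.n_cluster for c in counts] == [0, 0]
        assert unassigned == []

    def test_center_containment_counting(self):
        signals = [
            _sig(10, 10), _sig(20, 20), _sig(30, 30),        # 3 HER2 inside first
            _sig(200, 40),                                   # outside everything
            _sig(12, 40, SignalClass.CEN17), _sig(25, 12, SignalClass.CEN17),
        ]
        counts, unassigned = assign_signals([self.NUCLEI[0]], signals)
        assert (counts[0].n_her2, counts[0].n_cen17, counts[0].n_cluster) == (3, 2, 0)
        assert unassigned == [3]

    def test_overlap_resolved_to_nearest_box_center(self):
        # box centers: (25, 25) and (65, 25); x=46 lies inside both boxes but
        # closer to the second center, x=44 closer to the first
        counts, _ = assign_signals(self.NUCLEI, [_sig(46, 25)])
        assert (counts[0].n_her2, counts[1].n_her2) == (0, 1)
        counts, _ = assign_signals(self.NUCLEI, [_sig(44, 25)])
        assert (counts[0].n_her2, counts[1].n_her2) == (1, 0)

    def test_exact_tie_goes_to_lower_nucleus_index(self):
        counts, _ = assign_signals(self.NUCLEI, [_sig(45, 25)])
        assert (counts[0].n_her2, counts[1].n_her2) == (1, 0)

    def test_every_signal_assigned_at_most_once(self, rng):
        for _ in range(30):
            nuclei = []
            for _ in range(int(rng.integers(1, 5))):
                x0 = int(rng.integers(0, 150)); y0 = int(rng.integers(0, 150))
                nuclei.append(BoundingBox(x0, y0, x0 + int(rng.integers(20, 60)),
                                          y0 + int(rng.integers(20, 60))))
            signals = [
                _sig(int(rng.integers(5, 200)), int(rng.integers(5, 200)))
                for _ in range(int(rng.integers(0, 12)))
            ]
            counts, unassigned = assign_signals(nuclei, signals)
            assigned = sum(c.n_her2 for c in counts)
            assert assigned + len(unassigned) == len(signals)


def greedy_oracle(preds, truths, threshold):
    """Repeated global argmax matching — the definitional counterpart of the
    sorted-candidate implementation."""
    pairs = []
    used_p, used_t = set(), set()
    while True:
        best = None
        for i, p in enumerate(preds):
            if i in used_p:
                continue
            for j, t in enumerate(truths):
                if j in used_t:
                    continue
                iou = p.iou(t)
                if iou >= threshold and (best is None or iou > best[0] or
                                         (iou == best[0] and (i, j) < best[1:])):
                    best = (iou, i, j)
        if best is None:
            return pairs
        _, i, j = best
        pairs.append((i, j))
        used_p.add(i)
        used_t.add(j)


class TestMatching:
    def test_identical_lists_match_perfectly(self):
        boxes = [BoundingBox(0, 0, 10, 10), BoundingBox(20, 20, 40, 40)]
        m = match_detections(boxes, boxes)
        assert [(i, j) for i, j, _ in m.pairs] == [(0, 0), (1, 1)]
        assert all(iou == 1.0 for *_, iou in m.pairs)

    def test_disjoint_boxes_are_unmatched(self):
        a = [BoundingBox(0, 0, 10, 10)]
        b = [BoundingBox(50, 50, 60, 60)]
        m = match_detections(a, b)
        assert m.pairs == ()
        assert m.unmatched_predictions == (0,)
        assert m.unmatched_truths == (0,)

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            match_detections([], [], iou_threshold=0.0)

    def test_matches_repeated_argmax_oracle_on_random_scenes(self, rng):
        for _ in range(50):
            def boxes(n):
                out = []
                for _ in range(n):
                    x0 = int(rng.integers(0, 60)); y0 = int(rng.integers(0, 60))
                    out.append(BoundingBox(x0, y0, x0 + int(rng.integers(5, 30)),
                                           y0 + int(rng.integers(5, 30))))
                return out

            preds = boxes(int(rng.integers(0, 7)))
            truths = boxes(int(rng.integers(0, 7)))
            got = match_detections(preds, truths, 0.3)
            expected = greedy_oracle(preds, truths, 0.3)
            assert [(i, j) for i, j, _ in got.pairs] == expected
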