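"""Copy-paste dataset forging, annotation serialization, IoU/PR/AP scoring."""

import numpy as np
import pytest

from ethotrace.forge import (ForgeConfig, PRCurve, average_precision,
                             forge_dataset, iou, load_annotations,
                             match_detections, serialize_annotations,
                             RECALL_LEVELS)
from ethotrace.segment import Detection
from ethotrace.synthetic import SceneSpec, clutter_background, generate_video


def ap_oracle(outcomes, n_targets):
    """Direct 11-point evaluation from a ranked TP/FP outcome list."""
    tp = fp = 0
    prec, rec = [], []
    for is_tp in outcomes:
        tp += is_tp
        fp += 1 - is_tp
        prec.append(tp / (tp + fp))
        rec.append(tp / n_targets)
    total = 0.0
    for r in RECALL_LEVELS:
        candidates = [p for p, rr in zip(prec, rec) if rr >= r - 1e-12]
        total += max(candidates) if candidates else 0.0
    return total / len(RECALL_LEVELS)


def _det(cx, cy, score, w=2.0, h=2.0):
    return Detection(box=(cx, cy, w, h), score=score)


class TestIou:
    def test_identical_boxes(self):
        assert iou((5, 5, 4, 4), (5, 5, 4, 4)) == 1.0

    def test_disjoint_boxes(self):
        assert iou((0, 0, 2, 2), (10, 10, 2, 2)) == 0.0

    def test_half_offset_unit_squares(self):
        assert iou((0.0, 0.0, 1.0, 1.0), (0.5, 0.0, 1.0, 1.0)) == pytest.approx(1 / 3)

    def test_zero_area_errors(self):
        with pytest.raises(ValueError):
            iou((0, 0, 0, 2), (0, 0, 2, 2))


class TestMatching:
    def test_perfect_detections(self):
        targets = [_det(i * 10.0, 0.0, None) for i in range(4)]
        preds = [_det(i * 10.0, 0.0, 0.9) for i in range(4)]
        assert match_detections(preds, targets, 0.5) == (4, 0, 0)

    def test_no_detections_all_fn(self):
        targets = [_det(0.0, 0.0, None), _det(10.0, 0.0, None)]
        assert match_detections([], targets, 0.5) == (0, 0, 2)

    def test_double_detection_single_match(self):
        targets = [_det(0.0, 0.0, None)]
        preds = [_det(0.0, 0.0, 0.9), _det(0.1, 0.0, 0.8)]
        assert match_detections(preds, targets, 0.5) == (1, 1, 0)


class TestAveragePrecision:
    def test_perfect_detector_ap_one(self):
        targets = [_det(i * 10.0, 0.0, None) for i in range(3)]
        preds = [_det(i * 10.0, 0.0, 1.0) for i in range(3)]
        assert average_precision(preds, targets, 0.5).ap == pytest.approx(1.0)

    def test_all_fp_ap_zero(self):
        targets = [_det(0.0, 0.0, None)]
        preds = [_det(100.0, 100.0, 0.9), _det(200.0, 100.0, 0.8)]
        assert average_precision(preds, targets, 0.5).ap == 0.0

    def test_ranked_tp_fp_tp_fp_matches_hand_evaluation(self):
        targets = [_det(0.0, 0.0, None), _det(50.0, 0.0, None)]
        preds = [_det(0.0, 0.0, 0.9),        # TP
                 _det(100.0, 100.0, 0.8),    # FP
                 _det(50.0, 0.0, 0.7),       # TP
                 _det(200.0, 100.0, 0.6)]    # FP
        curve = average_precision(preds, targets, 0.5)
        assert curve.ap == pytest.approx(ap_oracle([1, 0, 1, 0], 2))

    def test_random_ranked_lists_match_oracle(self, rng):
        for _ in range(30):
            n_t = int(rng.integers(1, 6))
            targets = [_det(i * 20.0, 0.0, None) for i in range(n_t)]
            preds = []
            outcomes = []
            hit = set()
            score = 1.0
            for _j in range(int(rng.integers(1, 10))):
                score -= 0.01
                if rng.uniform() < 0.5 and len(hit) < n_t:
                    i = min(set(range(n_t)) - hit)
                    hit.add(i)
                    preds.append(_det(i * 20.0, 0.0, score))
                    outcomes.append(1)
                else:
                    preds.append(_det(1000.0 + _j * 50, 0.0, score))
                    outcomes.append(0)
            curve = average_precision(preds, targets, 0.5)
            assert curve.ap == pytest.approx(ap_oracle(outcomes, n_t), abs=1e-12)

    def test_recall_nondecreasing_interp_nonincreasing(self, rng):
        targets = [_det(i * 20.0, 0.0, None) for i in range(4)]
        preds = [_det(i * 20.0 if i % 2 else 500.0 + i, 0.0, 1 - 0.01 * i)
                 for i in range(8)]
        curve = average_precision(preds, targets, 0.5)
        assert (np.diff(curve.recall) >= 0).all()
        assert (np.diff(curve.interpolated) <= 1e-12).all()
        assert 0 <= curve.ap <= 1

    def test_relabeling_tp_as_fp_never_increases_ap(self, rng):
        n_t = 4
        outcomes = [1, 0, 1, 1, 0, 1]
        base = ap_oracle(outcomes, n_t)
        for i, o in enumerate(outcomes):
            if o == 1:
                worse = list(outcomes)
                worse[i] = 0
                assert ap_oracle(worse, n_t) <= base + 1e-12

    def test_zero_targets_errors(self):
        with pytest.raises(ValueError):
            average_precision([], [], 0.5)


@pytest.fixture(scope="module")
def source_video(tmp_path_factory):
    d = tmp_path_factory.mktemp("forge_src")
    p = d / "src.avi"
    generate_video(SceneSpec(n_blobs=3, duration=30, seed=2), p)
    return p


@pytest.fixture(scope="module")
def background_pool():
    rng = np.random.default_rng(99)
    return [clutter_background(320, 240, rng) for _ in range(4)]


class TestForgeDataset:
    def test_image_and_annotation_counts(self, source_video, background_pool):
        cfg = ForgeConfig(source_video=source_video, backgrounds=background_pool,
                          n_images=10, seed=1)
        images, records = forge_dataset(cfg)
        assert len(images) == 10 and len(records) == 10

    def test_copy_paste_pixel_fidelity(self, source_video, background_pool):
        cfg = ForgeConfig(source_video=source_video, backgrounds=background_pool,
                          n_images=3, seed=4)
        images, records = forge_dataset(cfg)
        for img, rec in zip(images, records):
            for obj in rec.objects:
                pts = np.asarray(obj.mask)
                vals = img[pts[:, 1], pts[:, 0]]
                # pasted animal pixels are bright against any background
                assert vals.mean() > 150

    def test_same_seed_byte_identical(self, source_video, background_pool):
        cfg = ForgeConfig(source_video=source_video, backgrounds=background_pool,
                          n_images=5, seed=7)
        img1, rec1 = forge_dataset(cfg)
        img2, rec2 = forge_dataset(cfg)
        for a, b in zip(img1, img2):
            np.testing.assert_array_equal(a, b)
        assert [(o.box, o.label) for r in rec1 for o in r.objects] == \
               [(o.box, o.label) for r in rec2 for o in r.objects]

    def test_self_consistency_fp_fn_zero_ap_one(self, source_video, background_pool):
        cfg = ForgeConfig(source_video=source_video, backgrounds=background_pool,
                          n_images=5, seed=3)
        _, records = forge_dataset(cfg)
        for rec in records:
            dets = [Detection(box=o.box, score=1.0) for o in rec.objects]
            tp, fp, fn = match_detections(dets, rec.objects, 0.5)
            assert fp == 0 and fn == 0
            if rec.objects:
                assert average_precision(dets, rec.objects, 0.5).ap == 1.0

    def test_empty_background_pool_rejected(self, source_video):
        with pytest.raises(ValueError):
            ForgeConfig(source_video=source_video, backgrounds=[], n_images=1)


class TestSerialization:
    def test_round_trip_lossless(self, source_video, background_pool, tmp_path):
        cfg = ForgeConfig(source_video=source_video, backgrounds=background_pool,
                          n_images=4, seed=2)
        _, records = forge_dataset(cfg)
        path = tmp_path / "ann.json"
        serialize_annotations(records, path)
        back = load_annotations(path)
        assert [r.image_id for r in back] == [r.image_id for r in records]
        for a, b in zip(records, back):
            for oa, ob in zip(a.objects, b.objects):
                assert oa.box == ob.box and oa.label == ob.label
                np.testing.assert_array_equal(np.asarray(oa.mask), np.asarray(ob.mask))

    def test_empty_record_set(self, tmp_path):
        path = tmp_path / "empty.json"
        serialize_annotations([], path)
        assert load_annotations(path) == []

    def test_two_objects_under_one_image(self, tmp_path):
        import json

        from ethotrace.forge import AnnotationRecord, ObjectAnnotation

        rec = AnnotationRecord("image0", [
            ObjectAnnotation(box=(5.0, 5.0, 4.0, 4.0), label="animal",
                             mask=np.array([[4, 4], [5, 5]])),
            ObjectAnnotation(box=(20.0, 20.0, 4.0, 4.0), label="animal",
                             mask=np.array([[20, 20]])),
        ])
        path = tmp_path / "two.json"
        serialize_annotations([rec], path)
        doc = json.loads(path.read_text())
        assert len(doc["image0"]) == 2
        assert doc["image0"]["object0"]["box"]["center"] == {"x": 5.0, "y": 5.0}
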