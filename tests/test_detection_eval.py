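"""Detection metrics, matching rules, the proxy detector and benchmark."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from domainmatch import (Annotation, Detection, PRESETS, average_precision,
                         evaluate, generate_domain, iou, match_detections,
                         run_benchmark, train_proxy_detector)
from domainmatch.detection_eval import segment_candidates
from domainmatch.domain_matching import emit_training_manifest
from domainmatch.imageio_features import record_pixels, to_grayscale


def det(image_id, conf, bbox=(0.5, 0.5, 0.2, 0.2), class_id=0):
    return Detection(image_id=image_id, class_id=class_id, bbox=bbox,
                     confidence=conf)


def ann(bbox=(0.5, 0.5, 0.2, 0.2), class_id=0):
    return Annotation(class_id=class_id, bbox=bbox)


class TestIoU:
    def test_identical_boxes(self):
        assert iou((0.5, 0.5, 0.2, 0.3), (0.5, 0.5, 0.2, 0.3)) == 1.0

    def test_disjoint_boxes(self):
        assert iou((0.2, 0.2, 0.1, 0.1), (0.8, 0.8, 0.1, 0.1)) == 0.0

    def test_corner_overlap_one_seventh(self):
        # squares (0,0)-(2,2) and (1,1)-(3,3): intersection 1, union 7
        a = (0.25, 0.25, 0.5, 0.5)
        b = (0.5, 0.5, 0.5, 0.5)
        assert iou(a, b) == pytest.approx(1 / 7)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.1, 0.9), st.floats(0.1, 0.9),
           st.floats(0.05, 0.5), st.floats(0.05, 0.5))
    def test_bounded_and_symmetric(self, cx, cy, w, h):
        a = (cx, cy, min(w, 1), min(h, 1))
        b = (0.5, 0.5, 0.4, 0.4)
        v = iou(a, b)
        assert 0.0 <= v <= 1.0
        assert v == iou(b, a)


class TestMatching:
    def test_perfect_detections(self):
        truths = {"i": [ann((0.3, 0.3, 0.2, 0.2)), ann((0.7, 0.7, 0.2, 0.2))]}
        dets = [det("i", 0.9, (0.3, 0.3, 0.2, 0.2)),
                det("i", 0.8, (0.7, 0.7, 0.2, 0.2))]
        curve = match_detections(dets, truths)
        assert curve.tp_cum[-1] == 2 and curve.fp_cum[-1] == 0
        assert curve.fn_at_end == 0

    def test_single_match_leaves_fn(self):
        truths = {"i": [ann((0.3, 0.3, 0.2, 0.2)), ann((0.7, 0.7, 0.2, 0.2))]}
        # IoU ~0.6 with the first truth only
        dets = [det("i", 0.9, (0.3, 0.33, 0.2, 0.2))]
        curve = match_detections(dets, truths)
        assert curve.tp_cum[-1] == 1
        assert curve.fn_at_end == 1

    def test_one_match_per_truth(self):
        truths = {"i": [ann()]}
        dets = [det("i", 0.9, (0.5, 0.5, 0.2, 0.2)),
                det("i", 0.8, (0.5, 0.51, 0.2, 0.2))]
        curve = match_detections(dets, truths)
        assert curve.tp_cum[-1] == 1 and curve.fp_cum[-1] == 1

    def test_class_mismatch_is_fp(self):
        truths = {"i": [ann(class_id=1)]}
        dets = [det("i", 0.9, class_id=0)]
        curve = match_detections(dets, truths)
        assert curve.fp_cum[-1] == 1

    def test_recall_nondecreasing_and_tp_fn_conservation(self):
        rng = np.random.default_rng(0)
        truths = {"i": [ann((x, x, 0.1, 0.1)) for x in np.linspace(0.1, 0.9, 5)]}
        dets = [det("i", rng.uniform(), (x + rng.uniform(-0.05, 0.05), x, 0.1, 0.1))
                for x in np.linspace(0.1, 0.9, 8)]
        curve = match_detections(dets, truths)
        assert np.all(np.diff(curve.recall) >= 0)
        assert curve.tp_cum[-1] + curve.fn_at_end == curve.n_pos


class TestAveragePrecision:
    def test_perfect_detector(self):
        truths = {"i": [ann((0.3, 0.3, 0.2, 0.2)), ann((0.7, 0.7, 0.2, 0.2))]}
        dets = [det("i", 0.9, (0.3, 0.3, 0.2, 0.2)),
                det("i", 0.8, (0.7, 0.7, 0.2, 0.2))]
        assert average_precision(match_detections(dets, truths)) == 1.0

    def test_no_detections(self):
        curve = match_detections([], {"i": [ann()]})
        assert average_precision(curve) == 0.0

    def test_tp_then_fp_over_two_truths(self):
        truths = {"i": [ann((0.3, 0.3, 0.2, 0.2)), ann((0.7, 0.7, 0.2, 0.2))]}
        dets = [det("i", 0.9, (0.3, 0.3, 0.2, 0.2)),   # TP at recall 0.5
                det("i", 0.8, (0.1, 0.8, 0.05, 0.05))]  # FP
        assert average_precision(match_detections(dets, truths)) == 0.5

    def test_zero_ground_truth_undefined(self):
        curve = match_detections([det("i", 0.9)], {"i": []})
        with pytest.raises(ValueError, match="undefined"):
            average_precision(curve)

    def test_ap_bounded_by_max_precision(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            truths = {"i": [ann((x, x, 0.1, 0.1))
                            for x in np.linspace(0.1, 0.9, 4)]}
            dets = []
            for k, x in enumerate(np.linspace(0.1, 0.9, 6)):
                good = rng.uniform() < 0.5
                bbox = (x, x, 0.1, 0.1) if good and k < 4 else (x, 0.95, 0.04, 0.04)
                dets.append(det("i", rng.uniform(), bbox))
            curve = match_detections(dets, truths)
            ap = average_precision(curve)
            assert ap <= curve.precision.max() + 1e-12
            perfect = np.any((curve.precision == 1.0) & (curve.recall == 1.0))
            assert (ap == 1.0) == bool(perfect)


class TestEvaluate:
    def test_operating_point_arithmetic(self):
        # 10 truths, 8 matched + 2 stray detections -> P = R = 0.8
        xs = np.linspace(0.05, 0.95, 10)
        truths = {"i": [ann((x, 0.3, 0.08, 0.08)) for x in xs]}
        dets = [det("i", 0.9, (x, 0.3, 0.08, 0.08)) for x in xs[:8]]
        dets += [det("i", 0.8, (x, 0.8, 0.05, 0.05)) for x in xs[:2]]
        report = evaluate(dets, truths, label_space=("intact",))
        assert report.precision == pytest.approx(0.8)
        assert report.recall == pytest.approx(0.8)

    def test_map_is_mean_of_class_aps(self):
        truths = {"i": [ann((0.3, 0.3, 0.2, 0.2), class_id=0),
                        ann((0.7, 0.7, 0.2, 0.2), class_id=1),
                        ann((0.7, 0.3, 0.2, 0.2), class_id=1)]}
        dets = [det("i", 0.9, (0.3, 0.3, 0.2, 0.2), class_id=0),   # class 0: AP 1
                det("i", 0.9, (0.7, 0.7, 0.2, 0.2), class_id=1),   # class 1 TP
                det("i", 0.8, (0.1, 0.1, 0.05, 0.05), class_id=1)]  # class 1 FP
        report = evaluate(dets, truths)
        assert report.per_class_ap["intact"] == 1.0
        assert report.per_class_ap["cracked"] == 0.5
        assert report.map50 == 0.75

    def test_absent_class_excluded_from_map(self):
        truths = {"i": [ann(class_id=0)]}
        dets = [det("i", 0.9, class_id=0)]
        report = evaluate(dets, truths)
        assert report.skipped_classes == ["cracked"]
        assert report.map50 == 1.0

    def test_zero_detections_convention(self):
        report = evaluate([], {"i": [ann()]}, label_space=("intact",))
        assert report.precision == 0.0
        assert report.recall == 0.0


@pytest.fixture(scope="module")
def trained(tmp_path_factory):
    dom = generate_domain(PRESETS["d2"], 12, seed=31)
    out = tmp_path_factory.mktemp("train")
    manifest = emit_training_manifest(["d2"], [dom], out, mode="SDT")
    return manifest, train_proxy_detector(manifest, seed=0)


@pytest.fixture(scope="module")
def suite():
    known = [generate_domain(PRESETS[k], 6, seed=55) for k in ("d1", "d2", "d3")]
    unknown = generate_domain(PRESETS["d4"], 4, seed=99)
    return known, unknown


class TestProxyDetector:
    def test_blank_image_no_candidates(self):
        blank = np.full((120, 120), 70.0)
        assert segment_candidates(blank) == []

    def test_candidates_on_rendered_frame(self):
        dom = generate_domain(PRESETS["d3"], 1, seed=5)
        gray = to_grayscale(record_pixels(dom.records[0]))
        cands = segment_candidates(gray)
        assert len(cands) >= len(dom.records[0].annotations) * 0.7

    def test_learnability_floor(self, trained):
        _, detector = trained
        test = generate_domain(replace(PRESETS["d2"], name="d2t"), 5, seed=77)
        dets = detector.detect(test.records)
        report = evaluate(dets, {r.image_id: r.annotations for r in test.records})
        assert report.recall > 0

    def test_deterministic_given_seed(self, trained):
        manifest, first = trained
        second = train_proxy_detector(manifest, seed=0)
        test = generate_domain(replace(PRESETS["d2"], name="d2t"), 3, seed=78)
        assert first.detect(test.records) == second.detect(test.records)


class TestRunBenchmark:
    def test_contamination_guard(self, suite):
        known, _ = suite
        with pytest.raises(ValueError, match="contamination"):
            run_benchmark(known, known[0], modes=("SDT",))

    def test_row_structure_and_table(self, suite):
        known, unknown = suite
        res = run_benchmark(known, unknown,
                            modes=("SDT", "MDT_all_pairs", "ADT"), seeds=(0,))
        methods = res.table["method"].tolist()
        assert methods.count("SDT") == 3
        assert methods.count("MDT") == 3
        assert methods.count("ADT") == 1
        assert set(res.table["map50"].between(0, 1)) == {True}
        text = res.to_text_table()
        assert "mAP.5" in text and "d1" in text
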