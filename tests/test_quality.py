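"""Quality features, SVM classifier, scoring rule and adequacy tabulation."""

import dataclasses

import numpy as np
import pytest

from retimorph import (QualityFeatures, SyntheticSpec, VesselMask,
                       fit_quality_classifier, generate_retina,
                       quality_features, score_image, tabulate_adequacy)
from retimorph.quality import QualityModel, label_from_probability
from retimorph.segmentation import segment_vessels


class TestFeatures:
    def test_empty_mask_convention(self):
        f = quality_features(VesselMask(np.zeros((64, 64), bool)))
        assert (f.area, f.fragmentation, f.complexity) == (0.0, 0.0, 0.0)

    def test_solid_square_counting(self):
        m = np.zeros((100, 100), bool)
        m[10:20, 10:20] = True
        f = quality_features(VesselMask(m))
        assert f.area == pytest.approx(0.01)
        assert f.fragmentation == pytest.approx(1 / 100)

    def test_occlusion_shrinks_area(self):
        spec = SyntheticSpec.default((256, 256), seed=11)
        img, _ = generate_retina(spec)
        occluded, _ = generate_retina(dataclasses.replace(spec,
                                                          degradation="occlusion"))
        a = quality_features(segment_vessels(img, post=False)).area
        b = quality_features(segment_vessels(occluded, post=False)).area
        assert b < a


def toy_separable_set():
    rng = np.random.default_rng(0)
    good = [QualityFeatures(0.10 + 0.01 * rng.random(), 0.001, 0.2)
            for _ in range(10)]
    bad = [QualityFeatures(0.005 + 0.002 * rng.random(), 0.05, 0.9)
           for _ in range(10)]
    feats = good + bad
    labels = ["adequate"] * 10 + ["inadequate"] * 10
    return feats, labels


class TestClassifier:
    def test_separable_toy_set_is_learned_perfectly(self):
        feats, labels = toy_separable_set()
        model = fit_quality_classifier(feats, labels, folds=5, seed=0)
        pred = ["inadequate" if model.classify(f).label == "inadequate"
                else "adequate" for f in feats]
        assert pred == labels

    def test_training_is_deterministic(self):
        feats, labels = toy_separable_set()
        a = fit_quality_classifier(feats, labels, seed=3)
        b = fit_quality_classifier(feats, labels, seed=3)
        x = np.array([[0.05, 0.01, 0.5]])
        assert a.p_inadequate(x) == b.p_inadequate(x)
        assert a.to_dict() == b.to_dict()

    def test_single_class_rejected(self):
        feats, _ = toy_separable_set()
        with pytest.raises(ValueError):
            fit_quality_classifier(feats, ["adequate"] * len(feats))

    def test_json_round_trip_is_bit_exact(self, tmp_path):
        feats, labels = toy_separable_set()
        model = fit_quality_classifier(feats, labels, seed=1)
        p = tmp_path / "model.json"
        model.save(p)
        loaded = QualityModel.load(p)
        assert loaded.to_dict() == model.to_dict()
        x = np.array([[0.08, 0.002, 0.3]])
        assert loaded.p_inadequate(x)[0] == model.p_inadequate(x)[0]
        loaded.save(tmp_path / "model2.json")
        assert (tmp_path / "model2.json").read_bytes() == p.read_bytes()


class TestScoringRule:
    def test_zero_probability_is_adequate(self):
        f = QualityFeatures(0.1, 0.001, 0.2)
        res = label_from_probability(f, 0.0, threshold=0.9)
        assert res.score == 1.0 and res.label == "adequate"

    def test_boundary_score_is_inadequate(self):
        """The cutoff is inclusive: a score of exactly 0.48 fails the gate."""
        f = QualityFeatures(0.02, 0.01, 0.4)
        res = label_from_probability(f, 1 - 0.48, threshold=0.48)
        assert res.score == pytest.approx(0.48)
        assert res.label == "inadequate"

    def test_score_and_probability_are_complementary(self):
        f = QualityFeatures(0.05, 0.002, 0.3)
        for p in (0.0, 0.25, 0.48, 0.9, 1.0):
            res = label_from_probability(f, p)
            assert res.score + res.p_inadequate == 1.0

    def test_raising_threshold_is_monotone(self):
        """Once a score fails the gate, any stricter threshold also fails it."""
        f = QualityFeatures(0.05, 0.002, 0.3)
        labels = [label_from_probability(f, 0.6, t).label
                  for t in (0.1, 0.3, 0.5, 0.7, 0.9)]
        seen_bad = False
        for l in labels:
            if l == "inadequate":
                seen_bad = True
            assert not (seen_bad and l == "adequate")
        assert "inadequate" in labels  # score 0.4 fails the stricter gates

    def test_blank_image_is_gated_out(self):
        """A featureless image maps to (0,0,0) and fails a realistic gate."""
        from retimorph.synthetic import generate_quality_cohort
        from retimorph.quality import quality_features as qf
        feats, labels = [], []
        for spec in generate_quality_cohort(40, seed=21, image_size=(192, 192)):
            img, truth = generate_retina(spec)
            feats.append(qf(segment_vessels(img, post=False)))
            labels.append(truth.quality_label)
        model = fit_quality_classifier(feats, labels, seed=0)
        blank = np.full((128, 128, 3), 0.5)
        res = score_image(blank, model)
        assert res.features.area == 0.0
        assert res.label == "inadequate"


class TestTabulation:
    def test_small_example(self):
        out = tabulate_adequacy([("a", "adequate"), ("b", "inadequate")])
        assert out["0"] == 1 and out[">=1"] == 1 and out["participants"] == 2

    def test_empty_input(self):
        out = tabulate_adequacy([])
        assert all(out[k] == 0 for k in ("0", "1", "2", ">=1", ">=3"))

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(9)
        results = []
        truth = {}
        for pid in range(100):
            n_img = rng.integers(1, 6)
            n_ok = 0
            for _ in range(n_img):
                ok = rng.random() < 0.7
                n_ok += ok
                results.append((pid, "adequate" if ok else "inadequate"))
            truth[pid] = n_ok
        out = tabulate_adequacy(results)
        vals = list(truth.values())
        assert out["0"] == sum(v == 0 for v in vals)
        assert out["1"] == sum(v == 1 for v in vals)
        assert out["2"] == sum(v == 2 for v in vals)
        assert out[">=1"] == sum(v >= 1 for v in vals)
        assert out[">=3"] == sum(v >= 3 for v in vals)
        assert out["0"] + out[">=1"] == out["participants"]
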