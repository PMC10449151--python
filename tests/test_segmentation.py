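"""Line detector, hysteresis reconstruction, pre/post-processing."""

import numpy as np
import pytest

from retimorph import (LineDetectorConfig, VesselMask, hysteresis_reconstruct,
                       line_response, postprocess_mask, preprocess_bright,
                       segment_vessels)
from retimorph.evaluation import pixelwise_eval


def bfs_hysteresis(response, low, high):
    """Independent flood-fill oracle: low-mask components reachable from seeds."""
    low_mask = response >= low
    seeds = list(zip(*np.nonzero(response >= high)))
    out = np.zeros_like(low_mask)
    stack = [s for s in seeds if low_mask[s]]
    seen = set(stack)
    h, w = response.shape
    while stack:
        r, c = stack.pop()
        out[r, c] = True
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and low_mask[rr, cc] \
                        and (rr, cc) not in seen:
                    seen.add((rr, cc))
                    stack.append((rr, cc))
    return out


class TestLineResponse:
    def test_flat_field_gives_zero_response(self):
        assert line_response(np.full((64, 64), 0.37)).max() == 0.0

    def test_argmax_orientation_matches_a_drawn_line(self):
        """A dark straight line's best orientation is the line's own (±1 bin)."""
        cfg = LineDetectorConfig()
        n = cfg.n_orientations
        for oi_true in range(0, n, 3):
            theta = oi_true * np.pi / n
            img = np.full((64, 64), 0.8)
            rr, cc = np.mgrid[0:64, 0:64].astype(float)
            d = np.abs((rr - 32) * -np.cos(theta) + (cc - 32) * np.sin(theta))
            along = np.abs((rr - 32) * np.sin(theta) + (cc - 32) * np.cos(theta))
            img[(d <= 1.5) & (along < 25)] = 0.2
            resp, orient = line_response(img, cfg, return_orientation=True)
            centre_bins = orient[(d <= 0.8) & (along < 15)]
            diff = np.abs(centre_bins - oi_true)
            diff = np.minimum(diff, n - diff)   # orientation is cyclic mod pi
            assert np.median(diff) <= 1

    def test_multiscale_max_dominates_single_scales(self):
        rng = np.random.default_rng(0)
        img = rng.random((48, 48))
        multi = line_response(img, LineDetectorConfig(line_lengths=(5, 9, 15)))
        for length in (5, 9, 15):
            single = line_response(img, LineDetectorConfig(line_lengths=(length,)))
            assert np.all(multi >= single - 1e-12)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            line_response(np.ones((8, 8)))

    def test_response_invariant_to_constant_shift(self):
        rng = np.random.default_rng(1)
        img = rng.random((48, 48))
        a = line_response(img)
        b = line_response(img + 0.7)
        assert np.allclose(a, b, atol=1e-12)


class TestHysteresis:
    def test_high_above_global_max_gives_empty_mask(self):
        rng = np.random.default_rng(2)
        resp = rng.random((32, 32))
        assert not hysteresis_reconstruct(resp, 0.2, 2.0).data.any()

    def test_low_must_be_below_high(self):
        with pytest.raises(ValueError):
            hysteresis_reconstruct(np.ones((8, 8)), 0.5, 0.5)

    def test_matches_bfs_oracle_on_random_fields(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            resp = rng.random((16, 16))
            got = hysteresis_reconstruct(resp, 0.2, 0.5).data
            assert np.array_equal(got, bfs_hysteresis(resp, 0.2, 0.5))

    def test_near_collapse_approaches_plain_threshold(self):
        rng = np.random.default_rng(4)
        resp = rng.random((32, 32))
        eps = 1e-12
        got = hysteresis_reconstruct(resp, 0.5 - eps, 0.5).data
        assert np.array_equal(got, bfs_hysteresis(resp, 0.5 - eps, 0.5))


class TestPreprocess:
    def test_identity_when_nothing_is_bright(self):
        img = np.full((32, 32), 0.4)   # constant: nothing exceeds the cutoff
        assert np.array_equal(preprocess_bright(img, 95), img)

    def test_non_bright_pixels_untouched(self):
        img = np.random.default_rng(5).random((32, 32))
        out = preprocess_bright(img, 95)
        cutoff = np.percentile(img, 95)
        assert np.array_equal(out[img <= cutoff], img[img <= cutoff])

    def test_percentile_100_is_identity(self):
        img = np.random.default_rng(6).random((32, 32))
        assert np.array_equal(preprocess_bright(img, 100), img)

    def test_saturated_blob_is_flattened(self):
        img = np.full((64, 64), 0.5)
        img[20:30, 20:30] = 1.0
        out = preprocess_bright(img, 95)
        cutoff = np.percentile(out, 95)
        assert np.all(out[20:30, 20:30] <= cutoff + 1e-9)

    def test_invalid_percentile(self):
        with pytest.raises(ValueError):
            preprocess_bright(np.ones((8, 8)), 40)


class TestPostprocess:
    def test_small_object_removed(self):
        m = np.zeros((32, 32), bool)
        m[5:6, 5:10] = True    # 5 px blob
        out = postprocess_mask(VesselMask(m), min_object_area=10)
        assert not out.data.any()

    def test_identity_without_criteria(self):
        m = np.zeros((32, 32), bool)
        m[5:9, 5:20] = True
        out = postprocess_mask(VesselMask(m), min_object_area=0)
        assert np.array_equal(out.data, m)

    def test_output_subset_of_input(self):
        rng = np.random.default_rng(7)
        m = rng.random((64, 64)) > 0.6
        out = postprocess_mask(VesselMask(m), min_object_area=4,
                               fovea_centre=(32, 32), fovea_radius=10)
        assert not (out.data & ~m).any()

    def test_fovea_disc_cleared(self):
        m = np.ones((64, 64), bool)
        out = postprocess_mask(VesselMask(m), 0, fovea_centre=(32, 32),
                               fovea_radius=8)
        assert not out.data[32, 32]
        assert out.data[0, 0]


class TestSegmentVessels:
    def test_blank_image_yields_empty_mask(self):
        img = np.full((128, 128, 3), 0.5)
        assert not segment_vessels(img).data.any()

    def test_detects_synthetic_vessels(self, default_retina):
        img, truth = default_retina
        mask = segment_vessels(img, fovea_centre=truth.fovea_centre)
        c = pixelwise_eval(mask.data, truth.vessel_mask)
        sens = c.tp / (c.tp + c.fn)
        spec = c.tn / (c.tn + c.fp)
        assert sens >= 0.70
        assert spec >= 0.97

    def test_postprocessing_never_adds_false_positives(self, default_retina):
        img, truth = default_retina
        without = segment_vessels(img, post=False)
        with_post = segment_vessels(img, post=True,
                                    fovea_centre=truth.fovea_centre)
        fp_without = (without.data & ~truth.vessel_mask).sum()
        fp_with = (with_post.data & ~truth.vessel_mask).sum()
        assert fp_with <= fp_without
        assert with_post.postprocessed and not without.postprocessed
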