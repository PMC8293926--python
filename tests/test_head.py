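"""Concatenated-GAP head: dimensions, freezing, optimization, composition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrcam import (HRCAM, HeadWeights, TapSpec, TrainConfig, build_head,
                   compose_map, concatenated_length, hrcam_explain,
                   zhou_cam)
from hrcam.backbone import FeatureBundle
from hrcam.head import fit_dense_softmax
from tests.test_maps import bilinear_closed_form


def random_tapspec(rng, max_taps=4, max_ch=8, max_side=16):
    k = int(rng.integers(1, max_taps + 1))
    chans = [int(rng.integers(1, max_ch + 1)) for _ in range(k)]
    sides = sorted((int(rng.integers(2, max_side + 1)) for _ in range(k)),
                   reverse=True)
    return TapSpec([f"t{i}" for i in range(k)], chans,
                   [(s, s) for s in sides])


class TestConcatenatedLength:
    def test_examples(self):
        spec = TapSpec(["a", "b", "c"], [64, 128, 256],
                       [(8, 8), (4, 4), (2, 2)])
        assert concatenated_length(spec) == 448
        single = TapSpec(["z"], [2048], [(7, 7)])
        assert concatenated_length(single) == 2048

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**20))
    def test_matches_accumulation_loop(self, seed):
        spec = random_tapspec(np.random.default_rng(seed))
        total = 0
        for m in spec.channels:
            total += m
        assert concatenated_length(spec) == total

    def test_empty_tapspec_rejected(self):
        with pytest.raises(ValueError):
            TapSpec([], [], [])


class TestBuildHead:
    def test_final_tap_only_is_zhou_configuration(self, tiny_model):
        spec = tiny_model.tap_spec
        final = TapSpec([spec.layer_ids[-1]], [spec.channels[-1]],
                        [spec.spatial_sizes[-1]])
        head = build_head(tiny_model, final)
        assert head.n == spec.channels[-1]

    def test_dimensions_and_freezing(self, tiny_model):
        head = build_head(tiny_model)
        assert head.W.shape == (2, 56)
        assert all(not layer.trainable
                   for layer in tiny_model.network.layers())

    def test_tap_offsets_match_cumsum_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            spec = random_tapspec(rng)
            head = HeadWeights(tap_spec=spec, class_count=2,
                               W=np.zeros((2, concatenated_length(spec))),
                               bias=np.zeros(2))
            expected, acc = [], 0
            for m in spec.channels:
                expected.append(acc)
                acc += m
            assert head.tap_offsets == expected

    def test_unknown_tap_rejected(self, tiny_model):
        bad = TapSpec(["not_a_layer"], [8], [(32, 32)])
        with pytest.raises(ValueError, match="not present"):
            build_head(tiny_model, bad)


class TestHeadTraining:
    def test_backbone_fingerprint_bit_identical(self, tiny_model,
                                                tiny_dataset):
        fp = tiny_model.fingerprint()
        HRCAM(tiny_model).fit(tiny_dataset,
                              TrainConfig(epochs=3, seed=1))
        assert tiny_model.fingerprint() == fp

    def test_linearly_separable_feature_reaches_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        n = 60
        y = np.repeat([0, 1], n // 2)
        x = rng.normal(size=(n, 5)) * 0.01
        x[:, 2] = np.where(y == 1, 1.0, -1.0)  # one separating coordinate
        w, b, hist = fit_dense_softmax(x[::2], y[::2], x[1::2], y[1::2],
                                       TrainConfig(epochs=50, seed=0))
        pred = (x[1::2] @ w.T + b).argmax(axis=1)
        assert (pred == y[1::2]).mean() == 1.0

    def test_trained_loss_beats_grid_search_oracle(self):
        """Convexity check: on a two-sample, one-feature problem the
        Adam-trained head must reach at least the loss of an exhaustive
        grid search over the head parameters."""
        from hrcam._nn import softmax_cross_entropy

        x = np.array([[-1.0], [1.0]])
        y = np.array([0, 1])
        cfg = TrainConfig(epochs=600, batch_size=2, learning_rate=0.1,
                          early_stop_patience=600, weight_decay=0.0, seed=0)
        w, b, _ = fit_dense_softmax(x, y, x, y, cfg)
        trained_loss, _ = softmax_cross_entropy(x @ w.T + b, y)
        # symmetric 2-parameter grid: W = [[-a],[a]], bias = [-c, c]
        grid_best = np.inf
        for a in np.linspace(-4, 4, 81):
            for c in np.linspace(-4, 4, 81):
                logits = x @ np.array([[-a], [a]]).T + np.array([-c, c])
                loss, _ = softmax_cross_entropy(logits, y)
                grid_best = min(grid_best, loss)
        assert grid_best >= trained_loss - 1e-3

    def test_untrained_or_unfrozen_model_rejected(self, tiny_dataset):
        import hrcam
        model = hrcam.build_backbone("simple", (32, 32), 2)
        head = build_head(model)
        with pytest.raises(ValueError, match="stage-1"):
            hrcam.train_head(head, model, tiny_dataset)


class TestComposeMap:
    def test_single_identity_term(self):
        spec = TapSpec(["t"], [1], [(2, 2)])
        head = HeadWeights(tap_spec=spec, class_count=1,
                           W=np.array([[2.0]]), bias=np.zeros(1),
                           trained=True)
        bundle = FeatureBundle(taps=[np.eye(2)[None, :, :]], tap_spec=spec)
        out = compose_map(bundle, head, 0, (2, 2))
        np.testing.assert_array_equal(out.values, [[2.0, 0.0], [0.0, 2.0]])
        assert not out.normalized

    def test_zero_weights_give_zero_map(self):
        rng = np.random.default_rng(1)
        spec = random_tapspec(rng)
        n = concatenated_length(spec)
        head = HeadWeights(tap_spec=spec, class_count=2,
                           W=np.zeros((2, n)), bias=np.zeros(2), trained=True)
        bundle = FeatureBundle(
            taps=[rng.random((m, *s)) for m, s in
                  zip(spec.channels, spec.spatial_sizes)], tap_spec=spec)
        out = compose_map(bundle, head, 0, (20, 20))
        np.testing.assert_array_equal(out.values, 0.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**20))
    def test_matches_bruteforce_accumulation_oracle(self, seed):
        """Triple loop (tap -> channel -> pixel) accumulating
        weight x per-channel-upsampled value."""
        rng = np.random.default_rng(seed)
        spec = random_tapspec(rng, max_taps=3, max_ch=4, max_side=8)
        n = concatenated_length(spec)
        out_size = (max(s[0] for s in spec.spatial_sizes) + 2,) * 2
        head = HeadWeights(tap_spec=spec, class_count=2,
                           W=rng.normal(size=(2, n)), bias=np.zeros(2),
                           trained=True)
        bundle = FeatureBundle(
            taps=[rng.normal(size=(m, *s)) for m, s in
                  zip(spec.channels, spec.spatial_sizes)], tap_spec=spec)
        expected = np.zeros(out_size)
        flat = 0
        for tap in bundle.taps:
            for ch in range(tap.shape[0]):
                up = bilinear_closed_form(tap[ch], out_size)
                w = head.W[1, flat]
                for i in range(out_size[0]):
                    for j in range(out_size[1]):
                        expected[i, j] += w * up[i, j]
                flat += 1
        out = compose_map(bundle, head, 1, out_size)
        np.testing.assert_allclose(out.values, expected, atol=1e-6)

    def test_linear_in_head_weights(self):
        rng = np.random.default_rng(3)
        spec = random_tapspec(rng, max_taps=2)
        n = concatenated_length(spec)
        bundle = FeatureBundle(
            taps=[rng.normal(size=(m, *s)) for m, s in
                  zip(spec.channels, spec.spatial_sizes)], tap_spec=spec)
        w1, w2 = rng.normal(size=(1, n)), rng.normal(size=(1, n))

        def mk(w):
            return HeadWeights(tap_spec=spec, class_count=1, W=w,
                               bias=np.zeros(1), trained=True)

        a, b = 0.7, -1.3
        combo = mk(a * w1 + b * w2)
        lhs = compose_map(bundle, combo, 0, (18, 18)).values
        rhs = (a * compose_map(bundle, mk(w1), 0, (18, 18)).values
               + b * compose_map(bundle, mk(w2), 0, (18, 18)).values)
        np.testing.assert_allclose(lhs, rhs, atol=1e-6)

    def test_mismatched_bundle_rejected(self, tiny_model):
        head = build_head(tiny_model)
        other = TapSpec(["x"], [3], [(4, 4)])
        bundle = FeatureBundle(taps=[np.zeros((3, 4, 4))], tap_spec=other)
        with pytest.raises(ValueError, match="tap layout"):
            compose_map(bundle, head, 0, (32, 32))
        good = FeatureBundle(
            taps=[np.zeros((m, *s)) for m, s in
                  zip(head.tap_spec.channels, head.tap_spec.spatial_sizes)],
            tap_spec=head.tap_spec)
        with pytest.raises(ValueError, match="class id"):
            compose_map(good, head, 5, (32, 32))


class TestExplain:
    def test_k1_head_with_model_weights_equals_zhou(self, tiny_model,
                                                    tiny_dataset):
        """Degenerate-tap equivalence: a one-tap head carrying the
        model's own GAP-head weights reproduces Zhou-CAM bit for bit."""
        from hrcam.baselines import zhou_head

        head = zhou_head(tiny_model)
        img = tiny_dataset[-1]
        ours = hrcam_explain(tiny_model, head, img, class_id=1)
        zhou = zhou_cam(tiny_model, img, class_id=1)
        np.testing.assert_array_equal(ours.values, zhou.values)

    def test_output_normalized(self, pipeline):
        amap = pipeline.stage2.explain(pipeline.test_images[-1], class_id=1)
        assert amap.normalized
        assert amap.values.min() == 0.0 and amap.values.max() == 1.0
        assert amap.shape == (64, 64)

    def test_peak_activation_falls_inside_dilated_mask(self, pipeline):
        """On abnormal test images the strongest HR-CAM pixel should sit
        inside the ground-truth mask dilated by one final-layer stride
        (4 px) for at least 90% of 50 images."""
        from scipy.ndimage import binary_dilation

        yy, xx = np.mgrid[-4:5, -4:5]
        disk = (yy ** 2 + xx ** 2) <= 16
        abnormal = [im for im in pipeline.test_images if im.label == 1][:50]
        hits = 0
        for im in abnormal:
            amap = pipeline.stage2.explain(im, class_id=1)
            peak = np.unravel_index(np.argmax(amap.values), amap.shape)
            dilated = binary_dilation(im.mask, structure=disk)
            hits += bool(dilated[peak])
        assert hits / len(abnormal) >= 0.9


def test_head_checkpoint_round_trip(tmp_path, tiny_model, tiny_dataset):
    res = HRCAM(tiny_model).fit(tiny_dataset, TrainConfig(epochs=3, seed=2))
    res.head.save(tmp_path / "head")
    back = HeadWeights.load(tmp_path / "head")
    np.testing.assert_array_equal(back.W, res.head.W)
    assert back.tap_offsets == res.head.tap_offsets
    assert back.trained
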