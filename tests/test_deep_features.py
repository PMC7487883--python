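import numpy as np
import pytest

from ihcloc._nn import SELU, Conv2d, Linear, MaxPool2d, cross_entropy, softmax
from ihcloc.deep_features import (
    BACKBONE_ORDER,
    COMBINED_DIM,
    BackboneConfigError,
    BackboneSpec,
    GapNet,
    build_backbone,
    build_gapnet,
    combine_features,
    combined_block_index,
    extract_deep,
    fine_tune,
    image_deep_vector,
)
from ihcloc.patching import PatchSet


def _patchset(n, size=32, seed=0):
    rng = np.random.default_rng(seed)
    return PatchSet(image_ref="x", size=size, coords=[(0, 0)] * n,
                    scores=[0.0] * n,
                    protein_windows=[rng.random((size, size)) for _ in range(n)],
                    dna_windows=[rng.random((size, size)) for _ in range(n)])


class TestLayerGradients:
    """Finite-difference checks of the building-block backward passes."""

    @pytest.mark.parametrize("layer_factory,shape", [
        (lambda: Conv2d(2, 3, rng=np.random.default_rng(0)), (2, 2, 6, 6)),
        (lambda: MaxPool2d(2), (2, 3, 6, 6)),
        (lambda: SELU(), (2, 3, 4, 4)),
        (lambda: Linear(5, 4, rng=np.random.default_rng(0)), (3, 5)),
    ])
    def test_input_gradient_matches_finite_difference(self, layer_factory, shape):
        rng = np.random.default_rng(1)
        layer = layer_factory()
        x = rng.normal(0, 1, shape)
        g_out = rng.normal(0, 1, layer.forward(x).shape)
        layer.forward(x)
        g_in = layer.backward(g_out)
        eps = 1e-6
        idx = tuple(rng.integers(0, s) for s in shape)
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        num = ((layer.forward(xp) * g_out).sum() - (layer.forward(xm) * g_out).sum()) / (2 * eps)
        assert abs(g_in[idx] - num) < 1e-4

    def test_softmax_cross_entropy_gradient(self):
        rng = np.random.default_rng(2)
        z = rng.normal(0, 1, (4, 3))
        y = np.array([0, 2, 1, 1])
        _, grad = cross_entropy(z, y)
        eps = 1e-6
        for idx in [(0, 0), (1, 2), (3, 1)]:
            zp, zm = z.copy(), z.copy()
            zp[idx] += eps
            zm[idx] -= eps
            num = (cross_entropy(zp, y)[0] - cross_entropy(zm, y)[0]) / (2 * eps)
            assert abs(grad[idx] - num) < 1e-5
        assert np.allclose(softmax(z).sum(axis=1), 1.0)


class TestGapNetArchitecture:
    def test_audited_layer_counts(self):
        g = build_gapnet(3, base_width=4)
        assert g.n_conv == 8
        assert g.n_pool == 5
        assert g.n_fc == 3

    def test_selu_only_no_batchnorm_no_relu(self):
        g = build_gapnet(3, base_width=4)
        assert g.activation_types() == {"SELU"}
        module_names = {type(l).__name__ for l in
                        g.conv_layers + g.pool_layers + g.fc_layers + g.acts}
        assert "ReLU" not in module_names
        assert not any("BatchNorm" in n for n in module_names)

    def test_penultimate_width_256_at_224_input(self):
        g = build_gapnet(3, base_width=4, seed=0)
        x = np.random.default_rng(0).random((1, 3, 224, 224))
        f = g.forward(x, return_features=True)
        assert f.shape == (1, 256)

    def test_feature_width_independent_of_input_side(self):
        g = build_gapnet(3, base_width=4, seed=0)
        rng = np.random.default_rng(1)
        dims = {g.forward(rng.random((1, 3, side, side)),
                          return_features=True).shape[1]
                for side in (64, 128, 224)}
        assert dims == {256}

    def test_logit_width_follows_n_classes(self):
        g = build_gapnet(5, base_width=4)
        out = g.forward(np.random.default_rng(0).random((2, 3, 64, 64)))
        assert out.shape == (2, 5)


class TestExtractDeep:
    def test_backbone_feature_dims(self):
        ps = _patchset(3)
        for name, dim in [("gapnet_pl", 256), ("resnet50", 1000)]:
            spec = BackboneSpec(name=name, input_side=32, seed=0,
                                gapnet_base_width=4)
            F = extract_deep(ps, spec)
            assert F.shape == (3, dim)

    def test_all_seven_slots_constructible_with_declared_dims(self):
        for name in BACKBONE_ORDER:
            spec = BackboneSpec(name=name, input_side=32, seed=1, gapnet_base_width=4)
            model = build_backbone(spec)
            f = model.forward(np.random.default_rng(0).random((1, 3, 32, 32)),
                              return_features=True)
            assert f.shape[1] == spec.feature_dim

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError, match="unknown backbone"):
            BackboneSpec(name="vgg16")

    def test_pretrained_without_plugin_is_config_error(self):
        spec = BackboneSpec(name="resnet18", weights="pretrained")
        with pytest.raises(BackboneConfigError, match="random"):
            build_backbone(spec)

    def test_deterministic_for_fixed_weights(self):
        ps = _patchset(2)
        spec = BackboneSpec(name="googlenet", input_side=32, seed=5)
        model = build_backbone(spec)
        a = extract_deep(ps, spec, model=model)
        b = extract_deep(ps, spec, model=model)
        assert np.array_equal(a, b)

    def test_image_vector_is_patch_mean(self):
        rng = np.random.default_rng(0)
        F = rng.random((35, 256))
        got = image_deep_vector(F)
        expected = np.zeros(256)
        for row in F:
            expected += row
        expected /= 35
        assert np.allclose(got, expected, atol=1e-12)
        single = image_deep_vector(F[:1])
        assert np.array_equal(single, F[0])


@pytest.fixture(scope="module")
def separable_patches():
    rng = np.random.default_rng(0)
    xs = np.concatenate([rng.normal(0.2, 0.05, (16, 3, 32, 32)),
                         rng.normal(0.8, 0.05, (16, 3, 32, 32))])
    return xs, np.array([0] * 16 + [1] * 16)


class TestFineTune:
    def test_one_epoch_reduces_loss_and_head_width(self, separable_patches):
        xs, ys = separable_patches
        g = build_gapnet(3, base_width=4, seed=2)
        g, trace = fine_tune(g, xs, ys, epochs=1, seed=0)
        assert trace[-1] < trace[0]
        assert g.fc_layers[2].W.shape[0] == 3

    def test_reaches_80pct_train_accuracy_within_20_epochs(self, separable_patches):
        xs, ys = separable_patches
        g = build_gapnet(3, base_width=4, seed=1)
        g, _ = fine_tune(g, xs, ys, epochs=20, seed=0)
        acc = (g.forward(xs).argmax(axis=1) == ys).mean()
        assert acc >= 0.8

    def test_no_labels_rejected(self):
        g = build_gapnet(3, base_width=4)
        with pytest.raises(ValueError, match="labels"):
            fine_tune(g, np.zeros((0, 3, 32, 32)), [], epochs=1)


class TestCombineFeatures:
    def _deep(self):
        rng = np.random.default_rng(0)
        d = {n: rng.random(1000) for n in BACKBONE_ORDER if n != "gapnet_pl"}
        d["gapnet_pl"] = rng.random(256)
        return d

    def test_total_dimension_7104(self):
        v = combine_features(np.zeros(848), self._deep())
        assert v.shape == (7104,) == (COMBINED_DIM,)

    def test_block_offsets(self):
        idx = combined_block_index()
        assert idx["engineered"] == (0, 848)
        assert idx["deep.googlenet"] == (848, 1848)
        assert idx["deep.gapnet_pl"] == (6848, 7104)

    def test_missing_block_raises(self):
        deep = self._deep()
        del deep["resnet101"]
        with pytest.raises(ValueError, match="resnet101"):
            combine_features(np.zeros(848), deep)

    def test_wrong_block_length_names_block(self):
        deep = self._deep()
        deep["gapnet_pl"] = np.zeros(1000)
        with pytest.raises(ValueError, match="gapnet_pl"):
            combine_features(np.zeros(848), deep)
        with pytest.raises(ValueError, match="engineered"):
            combine_features(np.zeros(847), self._deep())
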