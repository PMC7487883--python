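"""Convolutional feature extraction: GapNet-PL and six named backbone slots.

Seven backbone slots are defined.  ``gapnet_pl`` is the fully-specified
shallow architecture for protein-localization imagery: 8 convolutional
layers, 5 pooling layers (4 max pools plus one global average pooling
module), and 3 fully-connected head layers; SELU activations throughout, no
batch normalization and no ReLU; feature maps at three depths are reduced to
one pixel each by global average pooling and concatenated into the 256-unit
penultimate layer whose activation is the extracted feature vector.

The six ImageNet-named slots (googlenet, resnet18, resnet50, resnet101,
inception_v3, densenet201) emit the canonical 1000-unit penultimate vector
of those classifiers.  In this package they are lightweight random-weight
convolutional extractors built on the same layer framework — adequate for
every dimensional, aggregation and pipeline contract, and usable as fixed
random-projection features.  Actual pretrained weights can be supplied by
registering a callable through :func:`register_torch_plugin` when a
deep-learning framework with the real architectures is available;
``weights="pretrained"`` without such a plugin raises a configuration error.

Per-patch vectors are averaged within an image to form the image-level deep
feature vector; the combined engineered+deep description of a patch or image
is the fixed-order 848 + 6x1000 + 256 = 7104-column concatenation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from ._nn import (
    SGD,
    Conv2d,
    GlobalAvgPool,
    Layer,
    Linear,
    MaxPool2d,
    ReLU,
    SELU,
    Sequential,
    cross_entropy,
)
from .engineered_features import N_ENGINEERED
from .patching import PatchSet

logger = logging.getLogger(__name__)

#: fixed backbone order used everywhere (score vectors, combined features)
BACKBONE_ORDER = ("googlenet", "resnet18", "resnet50", "resnet101",
                  "inception_v3", "densenet201", "gapnet_pl")
FEATURE_DIMS = {name: 1000 for name in BACKBONE_ORDER}
FEATURE_DIMS["gapnet_pl"] = 256
INPUT_SIDES = {name: 224 for name in BACKBONE_ORDER}
INPUT_SIDES["inception_v3"] = 299  # native side; 224 patches are resized

COMBINED_DIM = N_ENGINEERED + 6 * 1000 + 256  # 7104

_torch_plugin = None


def register_torch_plugin(loader) -> None:
    """Register ``loader(name) -> feature_fn`` providing pretrained backbones."""
    global _torch_plugin
    _torch_plugin = loader


class BackboneConfigError(RuntimeError):
    pass


@dataclass
class BackboneSpec:
    """Identity and weight policy of one backbone slot."""

    name: str
    weights: str = "random"  # random | pretrained | file
    input_side: int = 0
    feature_dim: int = 0
    seed: int = 0
    gapnet_base_width: int = 32

    def __post_init__(self) -> None:
        if self.name not in BACKBONE_ORDER:
            raise ValueError(f"unknown backbone {self.name!r}; choose from {BACKBONE_ORDER}")
        if self.input_side == 0:
            self.input_side = INPUT_SIDES[self.name]
        self.feature_dim = FEATURE_DIMS[self.name]


class GapNet:
    """GapNet-style shallow CNN with multi-depth global-average-pool taps.

    Trunk: conv pairs of widths (w, w, 2w, 2w, 4w, 4w, 8w, 8w) with a max
    pool after every pair; GAP taps after conv 4, conv 6 and after the final
    pool; the concatenated taps feed fc1 (256 units, the penultimate layer),
    fc2 (128) and the ``n_classes`` output.  SELU after every learned layer
    except the output.  Width ``w`` defaults to 32; the 256-unit penultimate
    layer is fixed regardless of ``w``.
    """

    PENULTIMATE_DIM = 256

    def __init__(self, n_classes: int = 3, base_width: int = 32, seed: int = 0):
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        rng = np.random.default_rng(seed)
        w = base_width
        widths = [w, w, 2 * w, 2 * w, 4 * w, 4 * w, 8 * w, 8 * w]
        self.conv_layers: list[Conv2d] = []
        in_ch = 3
        for out_ch in widths:
            self.conv_layers.append(Conv2d(in_ch, out_ch, rng=rng))
            in_ch = out_ch
        self.acts = [SELU() for _ in range(10)]  # 8 conv + 2 hidden fc
        self.pool_layers: list[Layer] = [MaxPool2d(2) for _ in range(4)]
        self.gap = GlobalAvgPool()
        self.pool_layers.append(self.gap)
        tap_dim = widths[3] + widths[5] + widths[7]
        self.fc_layers = [
            Linear(tap_dim, self.PENULTIMATE_DIM, rng=rng),
            Linear(self.PENULTIMATE_DIM, 128, rng=rng),
            Linear(128, n_classes, rng=rng),
        ]
        self.n_classes = n_classes
        self._cache = None

    # --- architecture audit -------------------------------------------------
    @property
    def n_conv(self) -> int:
        return len(self.conv_layers)

    @property
    def n_pool(self) -> int:
        return len(self.pool_layers)

    @property
    def n_fc(self) -> int:
        return len(self.fc_layers)

    def activation_types(self) -> set[str]:
        return {type(a).__name__ for a in self.acts}

    def params(self):
        layers = self.conv_layers + self.fc_layers
        return [p for l in layers for p in l.params()]

    def grads(self):
        layers = self.conv_layers + self.fc_layers
        return [g for l in layers for g in l.grads()]

    def forward(self, x: np.ndarray, return_features: bool = False) -> np.ndarray:
        """NCHW input -> logits (or the 256-unit penultimate features)."""
        taps = []
        pool_idx = 0
        h = x
        for i, conv in enumerate(self.conv_layers):
            h = self.acts[i].forward(conv.forward(h))
            if i in (3, 5):  # taps after conv4 and conv6
                taps.append(GlobalAvgPool())
                taps[-1]._out = taps[-1].forward(h)
            if i % 2 == 1:  # pool after every conv pair
                h = self.pool_layers[pool_idx].forward(h)
                pool_idx += 1
        final_tap = self.gap.forward(h)
        feat_in = np.concatenate([taps[0]._out, taps[1]._out, final_tap], axis=1)
        self._cache = {"taps": taps}
        z = self.acts[8].forward(self.fc_layers[0].forward(feat_in))
        if return_features:
            return z
        z2 = self.acts[9].forward(self.fc_layers[1].forward(z))
        return self.fc_layers[2].forward(z2)

    def backward(self, g_logits: np.ndarray) -> None:
        g = self.fc_layers[2].backward(g_logits)
        g = self.fc_layers[1].backward(self.acts[9].backward(g))
        g = self.fc_layers[0].backward(self.acts[8].backward(g))
        taps = self._cache["taps"]
        w4 = taps[0]._out.shape[1]
        w6 = taps[1]._out.shape[1]
        gA, gB, gC = g[:, :w4], g[:, w4:w4 + w6], g[:, w4 + w6:]
        # trunk gradient, walked backwards with tap injections
        g_h = self.gap.backward(gC)
        g_h = self.pool_layers[3].backward(g_h)
        g_h = self.acts[7].backward(g_h)
        g_h = self.conv_layers[7].backward(g_h)
        g_h = self.acts[6].backward(g_h)
        g_h = self.conv_layers[6].backward(g_h)
        g_h = self.pool_layers[2].backward(g_h)
        g_h = g_h + taps[1].backward(gB)
        g_h = self.acts[5].backward(g_h)
        g_h = self.conv_layers[5].backward(g_h)
        g_h = self.acts[4].backward(g_h)
        g_h = self.conv_layers[4].backward(g_h)
        g_h = self.pool_layers[1].backward(g_h)
        g_h = g_h + taps[0].backward(gA)
        g_h = self.acts[3].backward(g_h)
        g_h = self.conv_layers[3].backward(g_h)
        g_h = self.acts[2].backward(g_h)
        g_h = self.conv_layers[2].backward(g_h)
        g_h = self.pool_layers[0].backward(g_h)
        g_h = self.acts[1].backward(g_h)
        g_h = self.conv_layers[1].backward(g_h)
        g_h = self.acts[0].backward(g_h)
        self.conv_layers[0].backward(g_h)

    def replace_head(self, n_classes: int, seed: int = 0) -> None:
        self.fc_layers[2] = Linear(128, n_classes, rng=np.random.default_rng(seed))
        self.n_classes = n_classes


def build_gapnet(n_classes: int = 3, base_width: int = 32, seed: int = 0) -> GapNet:
    """Construct the GapNet architecture (8 conv / 5 pool / 3 fc, SELU)."""
    return GapNet(n_classes=n_classes, base_width=base_width, seed=seed)


class _SurrogateBackbone:
    """Random-weight convolutional extractor with a fixed output width.

    Three conv/ReLU stages with aggressive pooling, a global average pool
    and a linear head.  Used as a deterministic random-projection feature
    extractor for the six ImageNet-named slots when no pretrained weights
    are available.
    """

    def __init__(self, feature_dim: int, n_classes: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.trunk = Sequential([
            Conv2d(3, 8, rng=rng), ReLU(), MaxPool2d(4),
            Conv2d(8, 16, rng=rng), ReLU(), MaxPool2d(4),
            Conv2d(16, 32, rng=rng), ReLU(), GlobalAvgPool(),
        ])
        self.feat = Linear(32, feature_dim, rng=rng)
        self.head = Linear(feature_dim, n_classes, rng=rng)
        self._feat_act = ReLU()
        self.n_classes = n_classes

    def params(self):
        return self.trunk.params() + self.feat.params() + self.head.params()

    def grads(self):
        return self.trunk.grads() + self.feat.grads() + self.head.grads()

    def forward(self, x, return_features: bool = False):
        h = self._feat_act.forward(self.feat.forward(self.trunk.forward(x)))
        if return_features:
            return h
        return self.head.forward(h)

    def backward(self, g_logits):
        g = self.head.backward(g_logits)
        g = self.feat.backward(self._feat_act.backward(g))
        self.trunk.backward(g)

    def replace_head(self, n_classes: int, seed: int = 0) -> None:
        self.head = Linear(self.head.W.shape[1], n_classes,
                           rng=np.random.default_rng(seed))
        self.n_classes = n_classes


def build_backbone(spec: BackboneSpec, n_classes: int = 3):
    """Instantiate the model behind one backbone slot."""
    if spec.weights == "pretrained":
        if _torch_plugin is None:
            raise BackboneConfigError(
                f"pretrained weights for {spec.name!r} require a registered "
                "framework plugin (register_torch_plugin); use weights='random' "
                "for offline/contract runs"
            )
        return _torch_plugin(spec.name)
    if spec.name == "gapnet_pl":
        return build_gapnet(n_classes=n_classes, base_width=spec.gapnet_base_width,
                            seed=spec.seed)
    return _SurrogateBackbone(feature_dim=spec.feature_dim, n_classes=n_classes,
                              seed=spec.seed)


def _prepare_batch(windows: list[np.ndarray], side: int) -> np.ndarray:
    """Stack single-channel windows as NCHW, resized and replicated to 3 channels."""
    out = np.empty((len(windows), 3, side, side))
    for i, w in enumerate(windows):
        w = np.asarray(w, dtype=np.float64)
        peak = w.max()
        if peak > 0:
            w = w / peak
        if w.shape != (side, side):
            w = resize(w, (side, side), order=1, anti_aliasing=False,
                       preserve_range=True)
        out[i] = w[None, :, :]
    return out


def extract_deep(patches: PatchSet, spec: BackboneSpec, model=None,
                 batch_size: int = 16) -> np.ndarray:
    """Per-patch feature matrix (n_patches x feature_dim) from one backbone.

    Patches are the protein-channel windows, peak-normalized, resized to the
    backbone's input side with bilinear interpolation and replicated across
    the three input channels.  Deterministic for fixed weights.
    """
    if model is None:
        model = build_backbone(spec)
    wins = patches.protein_windows
    if not wins:
        raise ValueError("empty PatchSet")
    feats = []
    for i in range(0, len(wins), batch_size):
        batch = _prepare_batch(wins[i:i + batch_size], spec.input_side)
        feats.append(model.forward(batch, return_features=True))
    F = np.vstack(feats)
    if F.shape[1] != spec.feature_dim:  # pragma: no cover - architecture contract
        raise AssertionError(f"{spec.name} emitted {F.shape[1]} != {spec.feature_dim}")
    return F


def image_deep_vector(patch_features: np.ndarray) -> np.ndarray:
    """Image-level deep vector: mean over its patch vectors."""
    F = np.asarray(patch_features, dtype=np.float64)
    if F.ndim != 2 or F.shape[0] == 0:
        raise ValueError("need a non-empty n_patches x dim matrix")
    return F.mean(axis=0)


def fine_tune(model, patches: np.ndarray, labels, epochs: int = 10, seed: int = 0,
              lr: float = 1e-3, batch_size: int = 32, n_classes: int = 3
              ) -> tuple[object, list[float]]:
    """Fine-tune a backbone on labelled NCHW patches with momentum SGD.

    The output layer is replaced with an ``n_classes``-way head; all
    parameters train.  Returns (model, per-epoch mean training loss), the
    epoch-0 entry being the pre-training loss.
    """
    y = np.asarray(labels, dtype=int)
    if len(y) == 0:
        raise ValueError("no labels provided")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    x = np.asarray(patches, dtype=np.float64)
    model.replace_head(n_classes, seed=seed)
    opt = SGD(model.params(), model.grads(), lr=lr, momentum=0.9)
    rng = np.random.default_rng(seed)
    loss0, _ = cross_entropy(model.forward(x), y)
    trace = [loss0]
    for _ in range(epochs):
        order = rng.permutation(len(y))
        for i in range(0, len(y), batch_size):
            idx = order[i:i + batch_size]
            logits = model.forward(x[idx])
            _, grad = cross_entropy(logits, y[idx])
            model.backward(grad)
            opt.step()
        # post-epoch loss on the full set, so trace[k] is after k epochs
        loss, _ = cross_entropy(model.forward(x), y)
        trace.append(float(loss))
    return model, trace


def combined_block_index() -> dict[str, tuple[int, int]]:
    index = {"engineered": (0, N_ENGINEERED)}
    start = N_ENGINEERED
    for name in BACKBONE_ORDER:
        dim = FEATURE_DIMS[name]
        index[f"deep.{name}"] = (start, start + dim)
        start += dim
    return index


def combine_features(engineered: np.ndarray, deep: dict[str, np.ndarray]) -> np.ndarray:
    """Fixed-order concatenation [engineered | 6x1000 ImageNet slots | gapnet_pl].

    ``deep`` maps backbone name -> vector; a missing or wrongly-sized block
    raises rather than silently shrinking the 7104-column contract.
    """
    engineered = np.asarray(engineered, dtype=np.float64)
    if engineered.shape[-1] != N_ENGINEERED:
        raise ValueError(
            f"engineered block has {engineered.shape[-1]} columns, expected {N_ENGINEERED}")
    parts = [engineered]
    for name in BACKBONE_ORDER:
        if name not in deep:
            raise ValueError(f"missing deep feature block {name!r}")
        v = np.asarray(deep[name], dtype=np.float64)
        if v.shape[-1] != FEATURE_DIMS[name]:
            raise ValueError(
                f"block {name!r} has {v.shape[-1]} columns, expected {FEATURE_DIMS[name]}")
        parts.append(v)
    out = np.concatenate(parts, axis=-1)
    assert out.shape[-1] == COMBINED_DIM
    return out
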