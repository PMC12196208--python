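"""CNN feature extraction and fusion models.

CNN1 is the per-modality extractor: four 3x3 convolution blocks (batch norm,
ReLU, 2x2/stride-2 max-pool) with 32/64/128/256 filters, then dense(10) ->
dense(50); the 50-unit layer is the feature vector fed to the fusion stage.
CNN2 is the fusion classifier: the three 50-vectors stacked into a 3x50
single-depth image, two convolution blocks (64/128 filters, pooling along
the 50-axis only), then a small dense head with softmax.

Training follows clinical-imaging practice: Adam (1e-3, 0.9/0.999),
reduce-on-plateau (x0.5 after 10 stagnant epochs, floor 1e-6), early
stopping (patience 20), L2 1e-4 on conv/dense weights, batch 32, and
image-space augmentation (rotation +-15 deg, scale 0.9-1.1, additive
Gaussian noise sigma=0.01).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import affine_transform

from . import nn


@dataclass
class CNN1Spec:
    """Per-modality extractor architecture.

    The 10->50 dense ordering is deliberate (feature layer last, 50 units);
    ``widen_feature_first=True`` switches to 50->10 with the 50-unit layer
    first for ablations.
    """

    input_hw: tuple = (128, 128)
    in_channels: int = 19
    conv_filters: tuple = (32, 64, 128, 256)
    dense_units: tuple = (10, 50)
    feature_units: int = 50
    widen_feature_first: bool = False
    input_pool: int = 1  # >1 prepends a coarsening max-pool (desk-scale profile)


@dataclass
class CNN2Spec:
    """Fusion classifier architecture over the 3x50 feature image."""

    input_hw: tuple = (3, 50)
    conv_filters: tuple = (64, 128)
    dense_units: tuple = (10,)
    pool: tuple = (1, 2)  # pool only along the feature axis


@dataclass
class TrainConfig:
    """Optimisation settings; every random draw derives from ``seed``."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    plateau_patience: int = 10
    plateau_factor: float = 0.5
    min_lr: float = 1e-6
    max_epochs: int = 150
    early_stop_patience: int = 20
    l2: float = 1e-4
    batch_size: int = 32
    augment: bool = True
    rotation_deg: float = 15.0
    scale_range: tuple = (0.9, 1.1)
    noise_sigma: float = 0.01
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.early_stop_patience >= self.max_epochs and self.max_epochs > 1:
            # patience beyond the horizon is inert; keep it strictly inside
            self.early_stop_patience = self.max_epochs
        if self.lr <= 0 or self.min_lr <= 0:
            raise ValueError("learning rates must be positive")


@dataclass
class FeatureTriple:
    """The three 50-element modality features and their 3x50 fusion."""

    f_spec: np.ndarray
    f_scal: np.ndarray
    f_hht: np.ndarray

    def __post_init__(self):
        for v in (self.f_spec, self.f_scal, self.f_hht):
            if v.shape != self.f_spec.shape:
                raise ValueError("feature vectors must share a common length")

    @property
    def fused(self) -> np.ndarray:
        """Rows in fixed order: spectrogram, scalogram, Hilbert spectrum."""
        return np.stack([self.f_spec, self.f_scal, self.f_hht], axis=0)


def build_cnn1(spec: CNN1Spec | None = None, n_classes: int = 3,
               seed: int = 0) -> nn.Sequential:
    """Build the per-modality extractor; deterministic given ``seed``.

    Input ``(N, H, W, in_channels)``; exposes the 50-unit feature layer via
    ``model.features``. Four stride-2 poolings take 128 -> 8 spatially.
    """
    spec = spec or CNN1Spec()
    rng = np.random.default_rng(seed)
    layers = []
    c_prev = spec.in_channels
    h, w = spec.input_hw
    if spec.input_pool > 1:
        layers.append(nn.MaxPool(spec.input_pool, spec.input_pool, name="pool0"))
        h, w = h // spec.input_pool, w // spec.input_pool
    for i, c in enumerate(spec.conv_filters):
        layers += [
            nn.Conv2D(c_prev, c, rng=rng, name=f"conv{i + 1}"),
            nn.BatchNorm(c, name=f"bn{i + 1}"),
            nn.ReLU(),
            nn.MaxPool(2, 2, name=f"pool{i + 1}"),
        ]
        c_prev = c
        h, w = h // 2, w // 2
    layers.append(nn.Flatten())
    d_prev = h * w * c_prev
    dense_units = spec.dense_units
    if spec.widen_feature_first:
        dense_units = tuple(reversed(dense_units))
    feature_layer = None
    for i, u in enumerate(dense_units):
        layers.append(nn.Dense(d_prev, u, rng=rng, name=f"dense{i + 1}"))
        layers.append(nn.ReLU())
        if u == spec.feature_units:
            feature_layer = len(layers) - 1  # post-activation features
        d_prev = u
    layers.append(nn.Dense(d_prev, n_classes, rng=rng, name="head"))
    if feature_layer is None:
        raise ValueError("no dense layer matches feature_units")
    return nn.Sequential(layers, feature_layer=feature_layer)


def build_cnn2(spec: CNN2Spec | None = None, n_classes: int = 3,
               seed: int = 0) -> nn.Sequential:
    """Build the fusion classifier over ``(N, 3, 50, 1)`` inputs."""
    spec = spec or CNN2Spec()
    rng = np.random.default_rng(seed)
    layers = []
    c_prev = 1
    h, w = spec.input_hw
    ph, pw = spec.pool
    for i, c in enumerate(spec.conv_filters):
        layers += [
            nn.Conv2D(c_prev, c, rng=rng, name=f"conv{i + 1}"),
            nn.BatchNorm(c, name=f"bn{i + 1}"),
            nn.ReLU(),
            nn.MaxPool(ph, pw, name=f"pool{i + 1}"),
        ]
        c_prev = c
        h, w = h // ph, w // pw
    layers.append(nn.Flatten())
    d_prev = h * w * c_prev
    for i, u in enumerate(spec.dense_units):
        layers.append(nn.Dense(d_prev, u, rng=rng, name=f"dense{i + 1}"))
        layers.append(nn.ReLU())
        d_prev = u
    layers.append(nn.Dense(d_prev, n_classes, rng=rng, name="head"))
    return nn.Sequential(layers)


def make_augmenter(cfg: TrainConfig):
    """Batch augmentation closure: random rotate/scale (zero fill) + noise."""

    def augment(xb, rng):
        out = np.empty_like(xb)
        for i in range(len(xb)):
            theta = np.deg2rad(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg))
            s = rng.uniform(*cfg.scale_range)
            c, si = np.cos(theta), np.sin(theta)
            # inverse map for affine_transform: output -> input coordinates
            m2 = np.array([[c, -si], [si, c]]) / s
            h, w = xb.shape[1], xb.shape[2]
            center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
            mat = np.eye(3)
            mat[:2, :2] = m2
            offset = np.zeros(3)
            offset[:2] = center - m2 @ center
            out[i] = affine_transform(xb[i], mat, offset=offset, order=1,
                                      mode="constant", cval=0.0)
        out += rng.normal(0.0, cfg.noise_sigma, size=out.shape).astype(out.dtype)
        return out

    return augment


def train(model: nn.Sequential, x, y, cfg: TrainConfig | None = None,
          x_val=None, y_val=None, verbose: bool = False):
    """Train a model per the shared optimisation recipe; returns history."""
    cfg = cfg or TrainConfig()
    augment_fn = make_augmenter(cfg) if cfg.augment else None
    return nn.train_model(
        model, x, y, x_val=x_val, y_val=y_val,
        epochs=cfg.max_epochs, batch_size=cfg.batch_size, lr=cfg.lr,
        l2=cfg.l2, plateau_patience=cfg.plateau_patience,
        plateau_factor=cfg.plateau_factor, min_lr=cfg.min_lr,
        early_stop_patience=cfg.early_stop_patience,
        augment_fn=augment_fn, seed=cfg.seed,
        val_fraction=cfg.val_fraction, verbose=verbose,
    )


def extract_features(cnn1_models, stacks) -> list:
    """Run the three frozen extractors over per-frame stacks.

    ``cnn1_models`` is the (spectrogram, scalogram, Hilbert) triple of
    trained CNN1 handles; ``stacks`` the matching triple of
    ``(N, H, W, C)`` arrays. Returns one :class:`FeatureTriple` per frame.
    """
    if len(cnn1_models) != 3 or len(stacks) != 3:
        raise ValueError("expected three models and three stack arrays")
    feats = []
    for model, xs in zip(cnn1_models, stacks):
        xs = np.asarray(xs)
        if xs.ndim != 4:
            raise ValueError("stack array must be 4-D (N, H, W, C)")
        first_conv = next(l for l in model.layers if isinstance(l, nn.Conv2D))
        if xs.shape[-1] != first_conv.params["W"].shape[2]:
            raise ValueError("stack depth does not match the model's input channels")
        feats.append(model.features(xs.astype(np.float32, copy=False)))
    f1, f2, f3 = feats
    if not (len(f1) == len(f2) == len(f3)):
        raise ValueError("modality stacks disagree on frame count")
    return [FeatureTriple(f1[i], f2[i], f3[i]) for i in range(len(f1))]


def fused_inputs(triples) -> np.ndarray:
    """Stack FeatureTriples into the (N, 3, 50, 1) CNN2 input tensor."""
    return np.stack([t.fused for t in triples])[..., None].astype(np.float32)


def predict_frames(cnn2: nn.Sequential, triples):
    """Classify frames from their fused features.

    Returns ``(labels, probabilities)``; argmax ties break toward the lower
    class index (numpy argmax convention, documented contract).
    """
    if len(triples) == 0:
        return np.array([], dtype=int), np.zeros((0, 0))
    probs = cnn2.predict_proba(fused_inputs(triples))
    return probs.argmax(axis=1), probs
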