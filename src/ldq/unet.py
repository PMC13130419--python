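"""3D U-Net segmentation engine: architecture, training and cross-validation.

The network is the classic encoder-decoder with skip connections: each
encoder level applies convolution + ReLU then 2x2x2 max-pooling; the
decoder mirrors it with nearest-neighbour upsampling, skip concatenation
and convolution. The head is a 1x1x1 convolution to one channel per
structure plus background; training uses per-channel sigmoid + binary
cross-entropy against the one-hot target, the Adam optimiser, and early
stopping that restores the weights of the epoch with minimum validation
loss. Inference reduces the channel stack to a single label map by argmax,
with ties broken toward background.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
from sklearn.base import BaseEstimator

from .geometry import Geometry, GeometryMismatchError
from .nn import Adam, Conv3d, InstanceNorm, MaxPool2, ReLU, Upsample2, bce_with_logits
from .volumes import MUSCLE_CODES, DixonVolume, LabelMap, onehot_encode

__all__ = ["UNetConfig", "TrainingHistory", "UNet3D", "UNetSegmenter", "build_model", "train", "predict", "mc_cross_validate"]


class LeakageError(RuntimeError):
    """A validation subject would contribute to training."""


@dataclass(frozen=True)
class UNetConfig:
    """Architecture and optimisation settings for the 3D U-Net.

    ``levels`` counts encoder (= decoder) stages; the first stage has
    ``base_filters`` convolutional filters, growing by ``growth`` per
    level down to the bottleneck. ``full_scale()`` is the configuration
    documented for full-resolution Dixon volumes (~2.4 M parameters);
    ``desk()`` is a reduced configuration for small phantom grids, with a
    larger learning rate appropriate to its few hundred gradient steps.
    """

    levels: int = 4
    base_filters: int = 16
    in_channels: int = 1
    out_channels: int = len(MUSCLE_CODES) + 1
    growth: float = 2.0
    kernel_size: int = 3
    convs_per_block: int = 1
    learning_rate: float = 1e-4
    batch_size: int = 1
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.levels < 1 or self.base_filters < 1:
            raise ValueError("levels and base_filters must be >= 1")
        if self.out_channels < 2:
            raise ValueError("out_channels must include background + >= 1 structure")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")

    def filters_at(self, level: int) -> int:
        return max(1, int(round(self.base_filters * self.growth**level)))

    @classmethod
    def full_scale(cls) -> "UNetConfig":
        return cls(levels=4, base_filters=16, learning_rate=1e-4)

    @classmethod
    def desk(cls) -> "UNetConfig":
        return cls(levels=3, base_filters=8, learning_rate=1e-2, max_epochs=30, patience=5)


@dataclass
class TrainingHistory:
    """Per-epoch losses plus the early-stopping outcome."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False

    def as_dict(self) -> dict:
        return asdict(self)


class UNet3D:
    """Plain-numpy 3D U-Net; see :class:`UNetConfig` for the layout."""

    def __init__(self, config: UNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        k = config.kernel_size
        self.enc_blocks: list[list] = []
        self.pools: list[MaxPool2] = []
        ch = config.in_channels
        for lvl in range(config.levels):
            f = config.filters_at(lvl)
            block = []
            for _ in range(config.convs_per_block):
                block += [Conv3d(ch, f, k, rng), InstanceNorm(f), ReLU()]
                ch = f
            self.enc_blocks.append(block)
            self.pools.append(MaxPool2())
        fb = config.filters_at(config.levels)
        self.bottleneck = []
        for _ in range(config.convs_per_block):
            self.bottleneck += [Conv3d(ch, fb, k, rng), InstanceNorm(fb), ReLU()]
            ch = fb
        self.ups: list[Upsample2] = []
        self.up_compress: list[Conv3d] = []
        self.dec_blocks: list[list] = []
        for lvl in reversed(range(config.levels)):
            f = config.filters_at(lvl)
            # 1x1 conv halving the feature channels before upsampling (the
            # classic U-Net up-convolution), applied at the lower resolution
            self.up_compress.append(Conv3d(ch, f, 1, rng, scale=np.sqrt(2.0 / ch)))
            self.ups.append(Upsample2())
            block = []
            cin = 2 * f  # compressed upsample + skip
            for _ in range(config.convs_per_block):
                block += [Conv3d(cin, f, k, rng), InstanceNorm(f), ReLU()]
                cin = f
            self.dec_blocks.append(block)
            ch = f
        # Head biases start at the background/foreground prior logits so the
        # initial prediction is "all background" with moderate confidence.
        head_bias = np.full(config.out_channels, -2.0, dtype=np.float32)
        head_bias[0] = 2.0
        self.head = Conv3d(ch, config.out_channels, 1, rng, scale=np.sqrt(1.0 / ch), bias_init=head_bias)
        self._skip_channels = [config.filters_at(l) for l in range(config.levels)]

    # -- parameters ---------------------------------------------------------

    def _layers(self):
        for block in self.enc_blocks:
            yield from block
        yield from self.bottleneck
        for comp, block in zip(self.up_compress, self.dec_blocks):
            yield comp
            yield from block
        yield self.head

    def params(self):
        out = []
        for layer in self._layers():
            if isinstance(layer, (Conv3d, InstanceNorm)):
                out.extend(layer.params())
        return out

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self._layers() if isinstance(l, (Conv3d, InstanceNorm)))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (p, _), w in zip(self.params(), weights):
            p[...] = w

    # -- forward / backward -------------------------------------------------

    def _check_shape(self, spatial: tuple[int, ...]) -> None:
        div = 2**self.config.levels
        bad = [i for i, s in enumerate(spatial) if s % div != 0]
        if bad:
            pads = {
                "xyz"[i]: (div - spatial[i] % div) % div for i in bad
            }
            raise GeometryMismatchError(
                f"input spatial shape {spatial} not divisible by 2^levels={div}; "
                f"pad by {pads} voxels (axis: padding)"
            )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._check_shape(x.shape[1:])
        skips = []
        h = x.astype(np.float32)
        for block, pool in zip(self.enc_blocks, self.pools):
            for layer in block:
                h = layer.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        for layer in self.bottleneck:
            h = layer.forward(h, train)
        for comp, up, block, skip in zip(self.up_compress, self.ups, self.dec_blocks, reversed(skips)):
            h = comp.forward(h, train)
            h = up.forward(h, train)
            h = np.concatenate([h, skip], axis=0)
            for layer in block:
                h = layer.forward(h, train)
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips = []
        for comp, up, block in zip(
            reversed(self.up_compress), reversed(self.ups), reversed(self.dec_blocks)
        ):
            for layer in reversed(block):
                d = layer.backward(d)
            # split concat: first channels came from upsample, rest from skip;
            # backward visits decoder blocks shallowest-first (level 0 upward)
            n_skip = self._skip_channels[len(dskips)]
            d, dskip = d[:-n_skip], d[-n_skip:]
            dskips.append(dskip)
            d = up.backward(d)
            d = comp.backward(d)
        for layer in reversed(self.bottleneck):
            d = layer.backward(d)
        for pool, block, dskip in zip(reversed(self.pools), reversed(self.enc_blocks), reversed(dskips)):
            d = pool.backward(d)
            d = d + dskip
            for layer in reversed(block):
                d = layer.backward(d)


def build_model(config: UNetConfig) -> tuple[UNet3D, int]:
    """Construct the network and report its parameter count."""
    model = UNet3D(config)
    return model, model.n_params


# ---------------------------------------------------------------------------
# Training


def normalize_input(volume: DixonVolume) -> np.ndarray:
    """Z-score the in-phase channel; returns a (1, X, Y, Z) float32 array."""
    x = volume.in_phase.astype(np.float32)
    sd = float(x.std())
    x = (x - x.mean()) / (sd if sd > 0 else 1.0)
    return x[None]


def _as_sample(vol: DixonVolume, lmap: LabelMap) -> tuple[np.ndarray, np.ndarray, str]:
    return normalize_input(vol), onehot_encode(lmap).astype(np.float32), vol.subject_id


def train(
    model: UNet3D,
    train_set: list[tuple[DixonVolume, LabelMap]],
    val_set: list[tuple[DixonVolume, LabelMap]],
    config: UNetConfig | None = None,
    train_is_augmented_from: set[str] | None = None,
) -> tuple[UNet3D, TrainingHistory]:
    """Train with BCE + Adam and early stopping on the validation loss.

    Training and validation must be disjoint by subject id (hard leakage
    guard). When the training set contains augmented copies, pass the set
    of original source ids via ``train_is_augmented_from`` so the guard
    checks provenance rather than the (possibly renamed) sample ids.
    """
    config = config or model.config
    train_ids = train_is_augmented_from or {v.subject_id for v, _ in train_set}
    val_ids = {v.subject_id for v, _ in val_set}
    leaked = sorted(train_ids & val_ids)
    if leaked:
        raise LeakageError(f"subjects in both training and validation: {leaked}")

    samples = [_as_sample(v, m) for v, m in train_set]
    val_samples = [_as_sample(v, m) for v, m in val_set]
    optimiser = Adam(model.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history = TrainingHistory()
    best_loss, best_weights, since_best = np.inf, model.get_weights(), 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(samples))
        ep_loss = 0.0
        for i in order:
            x, t, _ = samples[i]
            logits = model.forward(x, train=True)
            loss, dlogits = bce_with_logits(logits, t)
            model.backward(dlogits)
            optimiser.step()
            ep_loss += loss
        history.train_loss.append(ep_loss / len(samples))

        v_loss = 0.0
        for x, t, _ in val_samples:
            logits = model.forward(x, train=False)
            loss, _ = bce_with_logits(logits, t)
            v_loss += loss
        v_loss /= max(1, len(val_samples))
        history.val_loss.append(v_loss)

        if v_loss < best_loss:
            best_loss, best_weights, since_best = v_loss, model.get_weights(), 0
        else:
            since_best += 1
            if since_best >= config.patience:
                history.stopped_early = True
                break

    model.set_weights(best_weights)
    history.best_epoch = int(np.argmin(history.val_loss))
    return model, history


def predict(model: UNet3D, volume: DixonVolume, geometry: Geometry | None = None) -> LabelMap:
    """Segment one volume: per-voxel argmax over the sigmoid channels.

    Channel 0 is background and ``np.argmax`` returns the first maximal
    channel, so exact ties resolve toward background.
    """
    if geometry is not None and not volume.geometry.matches(geometry):
        raise GeometryMismatchError(
            "input geometry does not match the model's training geometry; "
            "homogenise the volume to the training grid first"
        )
    logits = model.forward(normalize_input(volume), train=False)
    codes = np.asarray([0] + sorted(MUSCLE_CODES), dtype=np.int16)
    labels = codes[np.argmax(logits, axis=0)]
    return LabelMap(labels, volume.geometry)


# ---------------------------------------------------------------------------
# scikit-learn style estimator


class UNetSegmenter(BaseEstimator):
    """3D U-Net muscle segmenter with a scikit-learn estimator surface.

    Parameters mirror :class:`UNetConfig`. ``fit(X, y)`` takes a list of
    :class:`DixonVolume` and a list of :class:`LabelMap`; ``predict(X)``
    maps volumes to label maps. Fitted attributes: ``model_``,
    ``history_``, ``n_params_``, ``geometry_``.
    """

    def __init__(
        self,
        levels: int = 3,
        base_filters: int = 8,
        growth: float = 2.0,
        kernel_size: int = 3,
        convs_per_block: int = 1,
        learning_rate: float = 1e-2,
        max_epochs: int = 30,
        patience: int = 5,
        seed: int = 0,
        validation_fraction: float = 0.25,
    ):
        self.levels = levels
        self.base_filters = base_filters
        self.growth = growth
        self.kernel_size = kernel_size
        self.convs_per_block = convs_per_block
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed
        self.validation_fraction = validation_fraction

    def _config(self) -> UNetConfig:
        return UNetConfig(
            levels=self.levels,
            base_filters=self.base_filters,
            growth=self.growth,
            kernel_size=self.kernel_size,
            convs_per_block=self.convs_per_block,
            learning_rate=self.learning_rate,
            max_epochs=self.max_epochs,
            patience=self.patience,
            seed=self.seed,
        )

    def fit(self, X, y, validation_data=None):
        X, y = list(X), list(y)
        if len(X) != len(y) or not X:
            raise ValueError("X and y must be equal-length, non-empty lists")
        config = self._config()
        if validation_data is None:
            rng = np.random.default_rng(self.seed)
            n_val = max(1, int(round(self.validation_fraction * len(X))))
            if n_val >= len(X):
                raise ValueError("not enough subjects to hold out a validation split")
            idx = rng.permutation(len(X))
            val_idx, tr_idx = idx[:n_val], idx[n_val:]
            train_pairs = [(X[i], y[i]) for i in tr_idx]
            val_pairs = [(X[i], y[i]) for i in val_idx]
        else:
            train_pairs = list(zip(X, y))
            val_pairs = [(v, m) for v, m in zip(*validation_data)]
        model, _ = build_model(config)
        self.model_, self.history_ = train(model, train_pairs, val_pairs, config)
        self.n_params_ = model.n_params
        self.geometry_ = X[0].geometry
        return self

    def predict(self, X):
        if not hasattr(self, "model_"):
            raise RuntimeError("fit the segmenter before predicting")
        single = isinstance(X, DixonVolume)
        vols = [X] if single else list(X)
        preds = [predict(self.model_, v, self.geometry_) for v in vols]
        return preds[0] if single else preds


# ---------------------------------------------------------------------------
# Monte-Carlo cross-validation


def mc_cross_validate(
    dataset: list[tuple[DixonVolume, LabelMap]],
    n_folds: int = 5,
    n_val: int = 8,
    seed: int = 0,
    config: UNetConfig | None = None,
    augment: str = "none",
):
    """Fixed-split Monte-Carlo cross-validation of the U-Net.

    Random train/validation splits are drawn ``n_folds`` times (resampled
    until every subject appears in at least one validation set); each
    fold trains a fresh model, optionally augmenting *only* its training
    subset (``augment``: 'none' | 'linear' | 'full'), and its validation
    predictions are pooled — n_folds x n_val predictions in total.
    """
    from .eval_stats import mc_cv_plan  # local import to avoid a cycle
    from .augment import apply_linear, full_plan, linear_plan, synthesize_deformed

    if augment not in ("none", "linear", "full"):
        raise ValueError("augment must be 'none', 'linear' or 'full'")
    config = config or UNetConfig.desk()
    by_id = {v.subject_id: (v, m) for v, m in dataset}
    plan = mc_cv_plan(n_subjects=len(dataset), n_folds=n_folds, n_val=n_val, seed=seed)
    ids = sorted(by_id)

    models, pooled = [], []
    for fold_i, (train_idx, val_idx) in enumerate(plan.folds):
        train_ids = [ids[i] for i in train_idx]
        val_ids = [ids[i] for i in val_idx]
        train_pairs = [by_id[i] for i in train_ids]
        val_pairs = [by_id[i] for i in val_ids]
        if augment != "none":
            aplan = linear_plan(train_ids) if augment == "linear" else full_plan(train_ids)
            aplan.assert_no_leakage(val_ids)
            aug_pairs = []
            for rec in aplan.records:
                vol, lmap = by_id[rec.source]
                if rec.kind == "linear":
                    aug_pairs.append(apply_linear(vol, lmap, rec.flip, rec.angle_deg))
                else:
                    fixed_vol, _ = by_id[rec.partner]
                    aug_pairs.append(synthesize_deformed((vol, lmap), fixed_vol))
            train_pairs = train_pairs + [(v, m) for v, m in aug_pairs]
        fold_config = replace(config, seed=config.seed + fold_i)
        model, _ = build_model(fold_config)
        model, history = train(
            model, train_pairs, val_pairs, fold_config, train_is_augmented_from=set(train_ids)
        )
        models.append((model, history))
        for vol, lmap in val_pairs:
            pooled.append(
                {"fold": fold_i, "subject": vol.subject_id, "pred": predict(model, vol), "truth": lmap}
            )
    return models, pooled
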