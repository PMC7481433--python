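"""Slice-level grade classifier (the "generator net").

Pipeline: a raw 2D slice is center-cropped to a 200x200 window around the
image center (the gland sits centrally in pelvic axial acquisitions),
bilinearly rescaled to 331x331, replicated to three channels and
standardized so each channel has mean 0.5 and variance 0.5.  A frozen
convolutional backbone turns the observation into a 4,320-dimensional
feature vector; a trainable softmax head on top of those features yields
the 5-category grade-group probabilities (or 6 categories when non-tumor
slices are modelled as an extra class 0).

Only the head is trained — SGD with momentum 0.9, learning rate 0.01 with
a 0.97 exponential decay per epoch, batch size 64, early stopping when
validation accuracy has not improved for five consecutive epochs.  The
default backbone is a five-stage convolutional pyramid whose filters are
fixed at (seeded) random initialisation: freezing every filter and training
only the final fully connected layer mirrors transfer-learning setups where
all but the last layers are frozen, and keeps training tractable on one
CPU.  Any callable mapping a (3, 331, 331) observation to a fixed-length
feature vector can be dropped in instead (``feature_dim`` is configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize

from .nn import MLP, SGDMomentum, softmax
from .phantom import VolumeStack

__all__ = [
    "SliceObservation", "SliceReadout", "TrainConfig",
    "FrozenConvBackbone", "SliceClassifier",
    "preprocess_slice", "augment", "cross_entropy_loss", "train_classifier",
]

CROP_SIZE = 200
INPUT_SIZE = 331
TARGET_MEAN = 0.5
TARGET_VAR = 0.5


@dataclass
class SliceObservation:
    """Preprocessed 3-channel 331x331 slice ready for the backbone."""

    pixels: np.ndarray              # (3, 331, 331)
    source_index: int = -1
    patient_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.shape != (3, INPUT_SIZE, INPUT_SIZE):
            raise ValueError(
                f"observation must be (3, {INPUT_SIZE}, {INPUT_SIZE}), "
                f"got {self.pixels.shape}")


@dataclass
class SliceReadout:
    """Classifier output for one slice: features, class probabilities and
    the argmax grade (ties broken toward the lower grade)."""

    features: np.ndarray
    probs: np.ndarray
    predicted_grade: int

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if (self.probs < 0).any() or abs(self.probs.sum() - 1.0) > 1e-6:
            raise ValueError("probs must be nonnegative and sum to 1")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 64
    lr: float = 3e-3
    lr_decay: float = 0.97          # multiplicative, per epoch
    momentum: float = 0.9
    early_stop_patience: int = 5
    max_epochs: int = 30
    n_classes: int = 5              # 6 adds "no tumor" as class 0
    feature_dim: int = 4320
    loss_epsilon: float = 1e-12
    augment_copies: int = 0         # extra augmented views per train slice
    seed: int = 0

    def __post_init__(self):
        if self.n_classes not in (5, 6):
            raise ValueError("n_classes must be 5 or 6")
        for name in ("batch_size", "lr", "lr_decay", "momentum",
                     "early_stop_patience", "max_epochs", "feature_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ------------------------------------------------------------ preprocessing

def preprocess_slice(raw_slice: np.ndarray, source_index: int = -1,
                     patient_id: str = "") -> SliceObservation:
    """Center crop 200x200, bilinear resize to 331x331, replicate to three
    channels, standardize each channel to mean 0.5 / variance 0.5.

    The crop anchor is the geometric center of the slice; for slices barely
    larger than the window the crop is clamped inside the image.  Slices
    smaller than 200x200 are rejected rather than silently padded.
    """
    raw = np.asarray(raw_slice, dtype=np.float64)
    if raw.ndim != 2:
        raise ValueError(f"expected a 2D slice, got shape {raw.shape}")
    h, w = raw.shape
    if h < CROP_SIZE or w < CROP_SIZE:
        raise ValueError(
            f"slice {h}x{w} smaller than the {CROP_SIZE}x{CROP_SIZE} "
            "crop window")
    crop = center_crop(raw)
    scaled = resize(crop, (INPUT_SIZE, INPUT_SIZE), order=1,
                    anti_aliasing=False, preserve_range=True)
    channel = standardize_channel(scaled)
    return SliceObservation(pixels=np.stack([channel] * 3),
                            source_index=source_index,
                            patient_id=patient_id)


def center_crop(raw: np.ndarray, size: int = CROP_SIZE) -> np.ndarray:
    """Crop a ``size`` x ``size`` window anchored at the geometric center,
    clamped inside the image for slices barely larger than the window."""
    h, w = raw.shape
    y0 = int(np.clip(round(h / 2 - size / 2), 0, h - size))
    x0 = int(np.clip(round(w / 2 - size / 2), 0, w - size))
    return raw[y0:y0 + size, x0:x0 + size]


def standardize_channel(x: np.ndarray, target_mean: float = TARGET_MEAN,
                        target_var: float = TARGET_VAR) -> np.ndarray:
    """Affine per-image standardization x' = (x - m)/s * sqrt(v*) + m*.

    Constant images (s < 1e-8) map to the target mean everywhere.
    """
    m, s = x.mean(), x.std()
    if s < 1e-8:
        return np.full_like(x, target_mean)
    return (x - m) / s * np.sqrt(target_var) + target_mean


# ------------------------------------------------------------- augmentation

@dataclass(frozen=True)
class AugmentConfig:
    enabled: bool = True
    max_rotation_deg: float = 15.0
    mirror_prob: float = 0.5
    max_translation_px: float = 10.0
    scale_range: tuple[float, float] = (0.9, 1.1)


def mirror(obs: SliceObservation, axis: int = 1) -> SliceObservation:
    """Flip along image rows (axis=0) or columns (axis=1); an involution."""
    return SliceObservation(pixels=np.flip(obs.pixels, axis=axis + 1).copy(),
                            source_index=obs.source_index,
                            patient_id=obs.patient_id)


def rotate(obs: SliceObservation, angle_deg: float) -> SliceObservation:
    if angle_deg == 0.0:
        return obs
    px = np.stack([ndimage.rotate(c, angle_deg, reshape=False, order=1,
                                  mode="nearest") for c in obs.pixels])
    return SliceObservation(pixels=px, source_index=obs.source_index,
                            patient_id=obs.patient_id)


def affine(obs: SliceObservation, scale: float = 1.0,
           shift: tuple[float, float] = (0.0, 0.0)) -> SliceObservation:
    if scale == 1.0 and shift == (0.0, 0.0):
        return obs
    center = (INPUT_SIZE - 1) / 2.0
    matrix = np.eye(2) / scale
    offset = center - matrix @ (np.array([center, center]) - np.asarray(shift))
    px = np.stack([ndimage.affine_transform(c, matrix, offset=offset,
                                            order=1, mode="nearest")
                   for c in obs.pixels])
    return SliceObservation(pixels=px, source_index=obs.source_index,
                            patient_id=obs.patient_id)


def augment(obs: SliceObservation, rng: np.random.Generator,
            cfg: AugmentConfig = AugmentConfig()) -> SliceObservation:
    """Random rotation, mirroring and small affine jitter (training only).

    Draws are taken from ``rng`` in a fixed order, so a seeded generator
    replays the same transform sequence.  Returns ``obs`` unchanged when
    augmentation is disabled.  Labels are untouched by construction.
    """
    if not cfg.enabled:
        return obs
    angle = rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg)
    do_mirror = rng.random() < cfg.mirror_prob
    shift = tuple(rng.uniform(-cfg.max_translation_px,
                              cfg.max_translation_px, size=2))
    scale = rng.uniform(*cfg.scale_range)
    out = rotate(obs, angle)
    if do_mirror:
        out = mirror(out)
    return affine(out, scale=scale, shift=shift)


# ------------------------------------------------------------------- losses

def cross_entropy_loss(probs: np.ndarray, labels: np.ndarray,
                       eps: float = 1e-12) -> float:
    """Mean negative log probability of the true class.

    ``labels`` are 0-based class indices into the columns of ``probs``.
    Zero probability at the true class is clamped at ``eps`` (and noted),
    so the loss stays finite.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    labels = np.atleast_1d(np.asarray(labels, dtype=np.intp))
    if len(labels) == 0:
        raise ValueError("empty batch")
    if labels.min() < 0 or labels.max() >= probs.shape[1]:
        raise ValueError("label outside class range")
    p_true = probs[np.arange(len(labels)), labels]
    if (p_true < eps).any():
        warnings.warn("zero probability at true class clamped",
                      stacklevel=2)
        p_true = np.clip(p_true, eps, None)
    return float(-np.log(p_true).mean())


# ----------------------------------------------------------------- backbone

class FrozenConvBackbone:
    """Five-stage convolutional feature pyramid with frozen filters.

    Stages 1-4 are strided valid convolutions with ReLU (3->8->16->30->30
    channels); stage 5 is an adaptive average pool onto a 12x12 grid,
    giving 30*12*12 = 4,320 features.  Filters are drawn once from a seeded
    He-scaled normal and never updated.
    """

    def __init__(self, seed: int = 0, final_channels: int = 30,
                 pool_grid: int = 12):
        rng = np.random.default_rng(seed)
        self.seed = seed
        self.final_channels = final_channels
        self.pool_grid = pool_grid

        def filt(f, c, k):
            w = rng.standard_normal((f, c, k, k)).astype(np.float32)
            return w / np.sqrt(c * k * k)

        self._stages = [
            (filt(8, 3, 5), 3),
            (filt(16, 8, 3), 2),
            (filt(final_channels, 16, 3), 2),
            (filt(final_channels, final_channels, 3), 2),
        ]

    @property
    def feature_dim(self) -> int:
        return self.final_channels * self.pool_grid ** 2

    @staticmethod
    def _conv(x: np.ndarray, w: np.ndarray, stride: int) -> np.ndarray:
        f, c, k, _ = w.shape
        _, h, wd = x.shape
        oh = (h - k) // stride + 1
        ow = (wd - k) // stride + 1
        s = x.strides
        patches = np.lib.stride_tricks.as_strided(
            x, (c, oh, ow, k, k),
            (s[0], s[1] * stride, s[2] * stride, s[1], s[2]))
        cols = patches.transpose(1, 2, 0, 3, 4).reshape(oh * ow, c * k * k)
        out = cols @ w.reshape(f, -1).T
        return np.maximum(out, 0.0).T.reshape(f, oh, ow)

    def __call__(self, obs: SliceObservation) -> np.ndarray:
        x = obs.pixels.astype(np.float32)
        for w, stride in self._stages:
            x = self._conv(x, w, stride)
        f, h, wd = x.shape
        g = self.pool_grid
        ys = np.linspace(0, h, g + 1).astype(int)
        xs = np.linspace(0, wd, g + 1).astype(int)
        pooled = np.empty((f, g, g), dtype=np.float64)
        for i in range(g):
            for j in range(g):
                pooled[:, i, j] = x[:, ys[i]:ys[i + 1],
                                    xs[j]:xs[j + 1]].mean(axis=(1, 2))
        return pooled.ravel()


# --------------------------------------------------------------- classifier

def _early_stop_epoch(val_accs: list[float], patience: int) -> bool:
    """True when the last ``patience`` epochs all failed to beat the best
    validation accuracy seen before them."""
    if len(val_accs) <= patience:
        return False
    best_before = max(val_accs[:-patience])
    return all(a <= best_before for a in val_accs[-patience:])


class SliceClassifier:
    """Frozen backbone + trainable softmax head.

    Features are centered by the training-set per-coordinate mean and
    divided by one global scale before the linear head; the constants are
    stored with the model so inference is self-contained.
    """

    def __init__(self, backbone=None, cfg: TrainConfig = TrainConfig()):
        self.backbone = backbone or FrozenConvBackbone(seed=cfg.seed)
        if self.backbone.feature_dim != cfg.feature_dim:
            raise ValueError(
                f"backbone feature_dim {self.backbone.feature_dim} != "
                f"configured {cfg.feature_dim}")
        self.cfg = cfg
        self.head = MLP([cfg.feature_dim, cfg.n_classes], init="zeros")
        self._mu = np.zeros(cfg.feature_dim)
        self._sd = np.ones(cfg.feature_dim)
        self.history: pd.DataFrame | None = None

    # -- features

    def features(self, obs: SliceObservation) -> np.ndarray:
        return self.backbone(obs)

    def features_for_stack(self, stack: VolumeStack) -> np.ndarray:
        """Backbone features for every slice of a stack, (n, feature_dim)."""
        return np.stack([
            self.features(preprocess_slice(s, source_index=i,
                                           patient_id=stack.patient_id))
            for i, s in enumerate(stack.slices)])

    # -- training on precomputed features

    def fit_features(self, x_train: np.ndarray, y_train: np.ndarray,
                     x_val: np.ndarray, y_val: np.ndarray) -> pd.DataFrame:
        """Train the softmax head; returns the per-epoch history.

        ``y`` holds 0-based class indices (grade−1 in 5-class mode; 0 =
        non-tumor and grade in 6-class mode).  Early stopping monitors
        validation accuracy with the configured patience and restores the
        best epoch's weights.
        """
        cfg = self.cfg
        if len(x_val) == 0:
            raise ValueError("empty validation set: early stopping undefined")
        rng = np.random.default_rng(cfg.seed)
        # Center each feature, then divide by one global scale.  Per-feature
        # whitening is deliberately avoided: many ReLU conv features are
        # silent on this data (sd ~ 0) and rescaling them to unit variance
        # amplifies pure noise.
        self._mu = x_train.mean(axis=0)
        self._sd = np.asarray(max(float((x_train - self._mu).std()), 1e-8))
        xt = (x_train - self._mu) / self._sd
        xv = (x_val - self._mu) / self._sd

        opt = SGDMomentum(self.head, lr=cfg.lr, momentum=cfg.momentum)
        best = (-np.inf, None)
        records, val_accs = [], []
        for epoch in range(cfg.max_epochs):
            opt.lr = cfg.lr * cfg.lr_decay ** epoch
            order = rng.permutation(len(y_train))
            losses = []
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                logits, acts = self.head.forward(xt[idx],
                                                 return_activations=True)
                p = softmax(logits)
                losses.append(cross_entropy_loss(p, y_train[idx],
                                                 cfg.loss_epsilon))
                grad = p.copy()
                grad[np.arange(len(idx)), y_train[idx]] -= 1.0
                grad /= len(idx)
                opt.step(*self.head.backward(acts, grad))
            train_acc = float((softmax(self.head.forward(xt)).argmax(1)
                               == y_train).mean())
            val_acc = float((softmax(self.head.forward(xv)).argmax(1)
                             == y_val).mean())
            val_accs.append(val_acc)
            records.append({"epoch": epoch, "lr": opt.lr,
                            "train_loss": float(np.mean(losses)),
                            "train_acc": train_acc, "val_acc": val_acc})
            if val_acc > best[0]:
                best = (val_acc, [w.copy() for w in self.head.weights]
                        + [b.copy() for b in self.head.biases])
            if _early_stop_epoch(val_accs, cfg.early_stop_patience):
                break
        if best[1] is not None:
            n = self.head.n_layers
            self.head.weights = best[1][:n]
            self.head.biases = best[1][n:]
        self.history = pd.DataFrame(records)
        return self.history

    # -- inference

    def predict_features(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities for rows of precomputed backbone features."""
        xs = (np.atleast_2d(x) - self._mu) / self._sd
        return softmax(self.head.forward(xs))

    def predict_slice(self, obs: SliceObservation) -> SliceReadout:
        """Deterministic readout for one observation.

        ``predicted_grade`` is the argmax class (1..5); in 6-class mode
        class 0 means "no tumor" and is reported as grade 0.  ``np.argmax``
        returns the first maximum, which is the lower grade on ties.
        """
        feats = self.features(obs)
        probs = self.predict_features(feats)[0]
        offset = 0 if self.cfg.n_classes == 6 else 1
        return SliceReadout(features=feats, probs=probs,
                            predicted_grade=int(probs.argmax()) + offset)

    # -- persistence

    def state_dict(self) -> dict:
        return {
            "head": self.head.state_dict(),
            "mu": self._mu, "sd": self._sd,
            "backbone_seed": self.backbone.seed,
            "n_classes": self.cfg.n_classes,
            "feature_dim": self.cfg.feature_dim,
        }

    @classmethod
    def from_state_dict(cls, state: dict,
                        cfg: TrainConfig | None = None) -> "SliceClassifier":
        cfg = cfg or TrainConfig(n_classes=int(state["n_classes"]),
                                 feature_dim=int(state["feature_dim"]))
        clf = cls(backbone=FrozenConvBackbone(seed=int(state["backbone_seed"])),
                  cfg=cfg)
        clf.head = MLP.from_state_dict(
            {k: np.asarray(v) for k, v in state["head"].items()}
            if not isinstance(state["head"], dict) else state["head"])
        clf._mu = np.asarray(state["mu"], dtype=np.float64)
        clf._sd = np.asarray(state["sd"], dtype=np.float64)
        return clf


def tumor_slice_dataset(stacks: list[VolumeStack], classifier: SliceClassifier,
                        include_nontumor: bool = False,
                        augment_copies: int = 0,
                        rng: np.random.Generator | None = None):
    """Backbone features and labels for a cohort.

    5-class mode uses tumor slices only, labelled with the patient-level
    grade (0-based).  6-class mode adds non-tumor slices as class 0 and
    shifts grades to 1..5.  ``augment_copies`` > 0 adds that many randomly
    augmented views of each included slice (training sets only); labels are
    unchanged by augmentation.
    """
    if augment_copies and rng is None:
        raise ValueError("augmentation requires an rng")
    xs, ys = [], []
    for stack in stacks:
        for i in range(stack.n_slices):
            if stack.tumor_flags[i]:
                label = stack.gg_rp if include_nontumor else stack.gg_rp - 1
            elif include_nontumor:
                label = 0
            else:
                continue
            obs = preprocess_slice(stack.slices[i], source_index=i,
                                   patient_id=stack.patient_id)
            views = [obs] + [augment(obs, rng)
                             for _ in range(augment_copies)]
            for v in views:
                xs.append(classifier.features(v))
                ys.append(label)
    return np.stack(xs), np.asarray(ys, dtype=np.intp)


def train_classifier(train_stacks: list[VolumeStack],
                     val_stacks: list[VolumeStack],
                     cfg: TrainConfig = TrainConfig(),
                     backbone=None) -> tuple[SliceClassifier, pd.DataFrame]:
    """End-to-end convenience: features -> head training -> (model, history)."""
    if not val_stacks:
        raise ValueError("empty validation set: early stopping undefined")
    clf = SliceClassifier(backbone=backbone, cfg=cfg)
    six = cfg.n_classes == 6
    aug_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 17]))
    x_tr, y_tr = tumor_slice_dataset(train_stacks, clf, include_nontumor=six,
                                     augment_copies=cfg.augment_copies,
                                     rng=aug_rng)
    x_va, y_va = tumor_slice_dataset(val_stacks, clf, include_nontumor=six)
    history = clf.fit_features(x_tr, y_tr, x_va, y_va)
    return clf, history
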