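"""A compact numpy CNN engine and the plaque-classifier training loop.

The classifier is a repeated motif of 3×3 convolution (padding 1), batch
normalization, ReLU and 2×2 max-pooling (stride 2).  The filter schedule
starts at 16 and grows by 16 per block up to 96 (six blocks), after which a
single affine layer maps the flattened 4×4×96 = 1536 features of a 256×256
input to three class scores (cored, diffuse, CAA).  Scores are raw logits;
the sigmoid is applied at evaluation time only.

Training: Adam (lr 0.001, weight decay 0.03), multi-label soft-margin loss,
60 epochs, best checkpoint selected by validation AUPRC on the cored class
(earliest epoch on ties).  Augmentation during training: random horizontal
and vertical flips, rotation by 180° with probability 0.5, mild color
jitter and a mild random affine transform; at evaluation only zero-mean /
unit-variance normalization is applied.

Everything runs in float32 on CPU; with a fixed seed, training is
bit-reproducible.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .data_model import CLASSES, LabelTable, logger, substream
from .labeling import class_balance

# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Conv3x3:
    """3×3 convolution, stride 1, padding 1 (im2col implementation)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        # He initialization
        fan_in = in_ch * 9
        self.w = (rng.standard_normal((fan_in, out_ch)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.in_ch, self.out_ch = in_ch, out_ch
        self._cols = None
        self._shape = None

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
        # (b, c, h, w, 3, 3) -> (b*h*w, c*9)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * 9)
        out = cols @ self.w + self.b
        self._cols, self._shape = cols, (b, c, h, w)
        return np.ascontiguousarray(out.reshape(b, h, w, self.out_ch).transpose(0, 3, 1, 2))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        gflat = grad.transpose(0, 2, 3, 1).reshape(b * h * w, self.out_ch)
        self.gw[...] = self._cols.T @ gflat
        self.gb[...] = gflat.sum(axis=0)
        dcols = (gflat @ self.w.T).reshape(b, h, w, c, 3, 3)
        dxp = np.zeros((b, c, h + 2, w + 2), dtype=np.float32)
        for i in range(3):
            for j in range(3):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, 1:-1, 1:-1]


class BatchNorm:
    """Per-channel batch normalization over (batch, H, W)."""

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(ch, dtype=np.float32)
        self.beta = np.zeros(ch, dtype=np.float32)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = x - mean.astype(np.float32)[None, :, None, None]
        xhat *= inv[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        out = xhat * self.gamma[None, :, None, None]
        out += self.beta[None, :, None, None]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, train, shape = self._cache
        self.ggamma[...] = (grad * xhat).sum(axis=(0, 2, 3))
        self.gbeta[...] = grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma[None, :, None, None]
        if not train:
            return g * inv[None, :, None, None]
        n = shape[0] * shape[2] * shape[3]
        return (
            inv[None, :, None, None]
            / n
            * (
                n * g
                - g.sum(axis=(0, 2, 3))[None, :, None, None]
                - xhat * (g * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
            )
        ).astype(np.float32)


class ReLU:
    def __init__(self):
        self._mask = None
        self.out = None  # retained for class-activation weighting

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        out = x * self._mask
        self.out = out
        return out

    def backward(self, grad: np.ndarray, guided: bool = False) -> np.ndarray:
        g = grad * self._mask
        if guided:
            # guided backpropagation: also gate on positive upstream gradient
            g = g * (grad > 0)
        return g


class MaxPool2x2:
    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        # four 2×2-phase views; first-maximum semantics via sequential masks
        slices = [
            x[:, :, 0::2, 0::2], x[:, :, 0::2, 1::2],
            x[:, :, 1::2, 0::2], x[:, :, 1::2, 1::2],
        ]
        out = np.maximum(np.maximum(slices[0], slices[1]),
                         np.maximum(slices[2], slices[3]))
        masks = []
        taken = np.zeros(out.shape, dtype=bool)
        for s in slices:
            m = (s == out) & ~taken
            taken |= m
            masks.append(m)
        self._cache = (masks, x.shape)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        masks, shape = self._cache
        dx = np.zeros(shape, dtype=np.float32)
        views = [
            dx[:, :, 0::2, 0::2], dx[:, :, 0::2, 1::2],
            dx[:, :, 1::2, 0::2], dx[:, :, 1::2, 1::2],
        ]
        for v, m in zip(views, masks):
            v += grad * m
        return dx


class Flatten:
    def __init__(self):
        self._shape = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((n_in, n_out)) * np.sqrt(1.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gw[...] = self._x.T @ grad
        self.gb[...] = grad.sum(axis=0)
        return grad @ self.w.T


# ---------------------------------------------------------------------------
# architecture
# ---------------------------------------------------------------------------

FULL_FILTER_SCHEDULE = (16, 32, 48, 64, 80, 96)
TINY_FILTER_SCHEDULE = (16, 32)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Conv-BN-ReLU-pool motif schedule plus the affine head."""

    filter_schedule: tuple = FULL_FILTER_SCHEDULE
    input_size: int = 256
    in_channels: int = 3
    n_classes: int = 3

    def __post_init__(self):
        if self.input_size % (2 ** len(self.filter_schedule)) != 0:
            raise ValueError(
                f"input size {self.input_size} not divisible by "
                f"2^{len(self.filter_schedule)}"
            )

    @property
    def head_input(self) -> int:
        side = self.input_size // (2 ** len(self.filter_schedule))
        return side * side * self.filter_schedule[-1]

    @classmethod
    def tiny(cls, input_size: int = 64) -> "ArchitectureSpec":
        """Reduced 2-block variant (filters 16, 32) for CPU-scale runs."""
        return cls(filter_schedule=TINY_FILTER_SCHEDULE, input_size=input_size)


class NumpyCNN:
    """Sequential conv-BN-ReLU-pool network with an affine head."""

    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator):
        self.spec = spec
        self.layers: list = []
        in_ch = spec.in_channels
        for out_ch in spec.filter_schedule:
            self.layers += [
                Conv3x3(in_ch, out_ch, rng),
                BatchNorm(out_ch),
                ReLU(),
                MaxPool2x2(),
            ]
            in_ch = out_ch
        self.layers += [Flatten(), Linear(spec.head_input, spec.n_classes, rng)]
        # index of the last ReLU: target layer for class-activation maps
        self.last_relu_index = len(self.layers) - 4

    # -- parameter plumbing ------------------------------------------------

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    @property
    def num_params(self) -> int:
        return sum(p.size for p, _ in self.params())

    def state_dict(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for (p, _), s in zip(self.params(), state):
            p[...] = s

    def bn_state(self) -> list[np.ndarray]:
        return [
            a.copy()
            for layer in self.layers
            if isinstance(layer, BatchNorm)
            for a in (layer.running_mean, layer.running_var)
        ]

    def load_bn_state(self, state: list[np.ndarray]) -> None:
        it = iter(state)
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = next(it)
                layer.running_var[...] = next(it)

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Map (B, C, H, W) float32 input to (B, n_classes) raw scores."""
        if x.shape[1:] != (self.spec.in_channels, self.spec.input_size, self.spec.input_size):
            raise ValueError(
                f"expected input (B, {self.spec.in_channels}, "
                f"{self.spec.input_size}, {self.spec.input_size}), got {x.shape}"
            )
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(
        self, grad: np.ndarray, guided: bool = False, capture_layer: int | None = None
    ) -> tuple[np.ndarray, np.ndarray | None]:
        """Backpropagate; returns (input gradient, gradient entering
        ``capture_layer``'s output if requested)."""
        captured = None
        for idx in range(len(self.layers) - 1, -1, -1):
            if capture_layer is not None and idx == capture_layer:
                captured = grad.copy()
            layer = self.layers[idx]
            if isinstance(layer, ReLU):
                grad = layer.backward(grad, guided=guided)
            else:
                grad = layer.backward(grad)
        return grad, captured


def build_cnn(spec: ArchitectureSpec, seed: int = 0) -> NumpyCNN:
    """Instantiate the classifier for a given architecture spec."""
    return NumpyCNN(spec, substream(seed, f"cnn-init-{spec.filter_schedule}-{spec.input_size}"))


def expected_param_count(spec: ArchitectureSpec) -> int:
    """Closed-form parameter count (layerwise arithmetic oracle)."""
    total = 0
    in_ch = spec.in_channels
    for out_ch in spec.filter_schedule:
        total += 9 * in_ch * out_ch + out_ch  # conv w + b
        total += 2 * out_ch  # bn gamma + beta
        in_ch = out_ch
    total += spec.head_input * spec.n_classes + spec.n_classes
    return total


# ---------------------------------------------------------------------------
# loss and optimizer
# ---------------------------------------------------------------------------


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def multilabel_soft_margin_loss(
    logits: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy with logits; returns (loss, dloss/dlogits)."""
    z = logits.astype(np.float64)
    loss = np.mean(np.logaddexp(0.0, z) - targets * z)
    grad = (sigmoid(z) - targets) / z.size
    return float(loss), grad.astype(np.float32)


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params, lr: float = 1e-3, weight_decay: float = 0.03,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            grad = g + self.wd * p
            m += (1 - self.b1) * (grad - m)
            v += (1 - self.b2) * (grad * grad - v)
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


# ---------------------------------------------------------------------------
# augmentation and normalization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AugmentSpec:
    """Training-time augmentation magnitudes (mild defaults)."""

    flip_prob: float = 0.5
    rot180_prob: float = 0.5
    jitter: float = 0.1  # brightness/contrast/saturation
    affine_degrees: float = 10.0
    affine_translate: float = 0.05
    affine_scale: tuple = (0.95, 1.05)

    @classmethod
    def identity(cls) -> "AugmentSpec":
        return cls(flip_prob=0.0, rot180_prob=0.0, jitter=0.0,
                   affine_degrees=0.0, affine_translate=0.0, affine_scale=(1.0, 1.0))


def augment(image: np.ndarray, rng: np.random.Generator,
            spec: AugmentSpec = AugmentSpec()) -> np.ndarray:
    """Randomly transform one (H, W, 3) float image for training.

    Horizontal/vertical flips, 180° rotation with probability 0.5, color
    jitter, then a mild random affine (rotation, translation, scale).
    Deterministic under a fixed generator state.
    """
    x = image.astype(np.float32)
    if rng.random() < spec.flip_prob:
        x = x[:, ::-1]
    if rng.random() < spec.flip_prob:
        x = x[::-1, :]
    if rng.random() < spec.rot180_prob:
        x = x[::-1, ::-1]
    if spec.jitter > 0:
        b, c, s = rng.uniform(1 - spec.jitter, 1 + spec.jitter, size=3)
        x = x * b
        x = (x - x.mean()) * c + x.mean()
        gray = x.mean(axis=2, keepdims=True)
        x = gray + (x - gray) * s
    if spec.affine_degrees > 0 or spec.affine_translate > 0 or spec.affine_scale != (1.0, 1.0):
        h, w = x.shape[:2]
        angle = np.deg2rad(rng.uniform(-spec.affine_degrees, spec.affine_degrees))
        scale = rng.uniform(*spec.affine_scale)
        tx = rng.uniform(-spec.affine_translate, spec.affine_translate) * w
        ty = rng.uniform(-spec.affine_translate, spec.affine_translate) * h
        ca, sa = np.cos(angle) / scale, np.sin(angle) / scale
        mat = np.array([[ca, -sa], [sa, ca]], dtype=np.float64)
        center = np.array([(h - 1) / 2, (w - 1) / 2])
        offset = center - mat @ (center + np.array([ty, tx]))
        x = np.stack(
            [
                ndimage.affine_transform(x[..., ch], mat, offset=offset, order=1,
                                         mode="nearest")
                for ch in range(x.shape[2])
            ],
            axis=2,
        )
    return np.ascontiguousarray(x)


def channel_stats(images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean/std over a (N, H, W, 3) uint8 stack."""
    flat = images.reshape(-1, 3).astype(np.float64)
    std = flat.std(axis=0)
    return flat.mean(axis=0), np.where(std > 1e-8, std, 1.0)


def normalize_batch(images: np.ndarray, stats: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """(N, H, W, 3) -> normalized (N, 3, H, W) float32."""
    mean, std = stats
    x = (images.astype(np.float32) - mean.astype(np.float32)) / std.astype(np.float32)
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainingRun:
    """Hyperparameters and provenance of one fold's training run."""

    fold_index: int = 0
    annotation_source: str = ""
    epochs: int = 60
    learning_rate: float = 1e-3
    weight_decay: float = 0.03
    batch_size: int = 32
    seed: int = 0
    balance: bool = True
    augment_spec: AugmentSpec = field(default_factory=AugmentSpec)


@dataclass
class ModelBundle:
    """A trained CNN plus everything needed to reproduce its predictions."""

    model: NumpyCNN
    run: TrainingRun
    norm_stats: tuple
    best_epoch: int = 0
    history: list = field(default_factory=list)  # per-epoch dicts

    @property
    def annotation_source(self) -> str:
        return self.run.annotation_source


def save_bundle(bundle: ModelBundle, stem: str | "os.PathLike") -> None:
    """Serialize a bundle as <stem>.npz (weights) + <stem>.json (manifest)."""
    import json
    from pathlib import Path

    stem = Path(stem)
    arrays = {f"p{i}": p for i, (p, _) in enumerate(bundle.model.params())}
    arrays.update({f"bn{i}": a for i, a in enumerate(bundle.model.bn_state())})
    arrays["norm_mean"], arrays["norm_std"] = bundle.norm_stats
    np.savez(stem.with_suffix(".npz"), **arrays)
    manifest = {
        "filter_schedule": list(bundle.model.spec.filter_schedule),
        "input_size": bundle.model.spec.input_size,
        "annotation_source": bundle.run.annotation_source,
        "fold_index": bundle.run.fold_index,
        "epochs": bundle.run.epochs,
        "learning_rate": bundle.run.learning_rate,
        "weight_decay": bundle.run.weight_decay,
        "seed": bundle.run.seed,
        "best_epoch": bundle.best_epoch,
        "history": bundle.history,
        "num_params": bundle.model.num_params,
    }
    stem.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_bundle(stem: str | "os.PathLike") -> ModelBundle:
    """Load a bundle serialized by :func:`save_bundle`."""
    import json
    from pathlib import Path

    stem = Path(stem)
    manifest = json.loads(stem.with_suffix(".json").read_text())
    spec = ArchitectureSpec(
        filter_schedule=tuple(manifest["filter_schedule"]),
        input_size=manifest["input_size"],
    )
    model = build_cnn(spec, seed=manifest["seed"])
    with np.load(stem.with_suffix(".npz")) as data:
        model.load_state([data[f"p{i}"] for i in range(len(model.params()))])
        n_bn = sum(2 for layer in model.layers if isinstance(layer, BatchNorm))
        model.load_bn_state([data[f"bn{i}"] for i in range(n_bn)])
        stats = (data["norm_mean"], data["norm_std"])
    run = TrainingRun(
        fold_index=manifest["fold_index"],
        annotation_source=manifest["annotation_source"],
        epochs=manifest["epochs"],
        learning_rate=manifest["learning_rate"],
        weight_decay=manifest["weight_decay"],
        seed=manifest["seed"],
    )
    return ModelBundle(model=model, run=run, norm_stats=stats,
                       best_epoch=manifest["best_epoch"], history=manifest["history"])


def make_folds(
    image_wsis: dict[str, str], fold_count: int, rng: np.random.Generator
) -> dict[str, int]:
    """Assign images to cross-validation folds at the slide level.

    All crops from the same source slide land in the same fold, so no fold's
    validation images share a slide with its training images.  Slides are
    dealt to folds greedily by descending crop count to balance fold sizes.
    """
    counts: dict[str, int] = {}
    for wsi in image_wsis.values():
        counts[wsi] = counts.get(wsi, 0) + 1
    order = sorted(counts, key=lambda k: (-counts[k], k))
    fold_sizes = [0] * fold_count
    wsi_fold = {}
    for wsi in order:
        fold = int(np.argmin(fold_sizes))
        # break count ties randomly but reproducibly
        tied = [i for i, s in enumerate(fold_sizes) if s == fold_sizes[fold]]
        fold = int(rng.choice(tied))
        wsi_fold[wsi] = fold
        fold_sizes[fold] += counts[wsi]
    return {img: wsi_fold[wsi] for img, wsi in image_wsis.items()}


def train_test_split_by_wsi(
    image_wsis: dict[str, str], test_fraction: float, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    """Split images into train/hold-out by slide, targeting a test fraction."""
    wsis = sorted(set(image_wsis.values()))
    rng.shuffle(wsis)
    n_total = len(image_wsis)
    test_wsis, n_test = set(), 0
    for wsi in wsis:
        if n_test >= test_fraction * n_total:
            break
        test_wsis.add(wsi)
        n_test += sum(1 for w in image_wsis.values() if w == wsi)
    train = [i for i, w in image_wsis.items() if w not in test_wsis]
    test = [i for i, w in image_wsis.items() if w in test_wsis]
    return train, test


def _forward_scores(model: NumpyCNN, x: np.ndarray, batch: int = 64) -> np.ndarray:
    out = [model.forward(x[i : i + batch]) for i in range(0, len(x), batch)]
    return np.concatenate(out, axis=0)


def predict(bundle: ModelBundle, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Sigmoid class scores in [0, 1]^3 for a (N, H, W, 3) uint8 stack."""
    x = normalize_batch(images, bundle.norm_stats)
    return sigmoid(_forward_scores(bundle.model, x, batch_size))


def train_model(
    train_images: np.ndarray,
    train_ids: list[str],
    val_images: np.ndarray,
    val_ids: list[str],
    labels: LabelTable,
    run: TrainingRun,
    arch: ArchitectureSpec | None = None,
) -> ModelBundle:
    """Train one CNN on one fold's data.

    Class balancing (minority-class replication) is recomputed on the
    training portion; normalization statistics come from the training split
    only.  The returned bundle holds the weights of the epoch with the best
    validation cored AUPRC (earliest on ties) and the full metric history.
    """
    from .evaluation import auprc, UndefinedMetricError

    if len(train_ids) == 0:
        raise ValueError("empty training fold")
    if arch is None:
        arch = ArchitectureSpec(input_size=train_images.shape[1])
    model = build_cnn(arch, seed=run.seed)
    opt = Adam(model.params(), lr=run.learning_rate, weight_decay=run.weight_decay)
    rng = substream(run.seed, f"train-{run.annotation_source}-fold{run.fold_index}")

    stats = channel_stats(train_images)
    index_of = {img: i for i, img in enumerate(train_ids)}
    if run.balance:
        balanced_ids, r1, r2 = class_balance(train_ids, labels)
        logger.info(
            "fold %d (%s): balanced %d -> %d images (r1=%d, r2=%d)",
            run.fold_index, run.annotation_source, len(train_ids), len(balanced_ids), r1, r2,
        )
    else:
        balanced_ids = list(train_ids)
    epoch_indices = np.array([index_of[i] for i in balanced_ids])
    y_train = labels.aligned_to(balanced_ids).matrix().astype(np.float32)
    y_val = labels.aligned_to(val_ids).matrix() if len(val_ids) else None
    x_val = normalize_batch(val_images, stats) if len(val_ids) else None

    mean, std = (a.astype(np.float32) for a in stats)
    best_state, best_bn, best_metric, best_epoch = None, None, -np.inf, -1
    history = []
    for epoch in range(run.epochs):
        order = rng.permutation(len(epoch_indices))
        losses = []
        for start in range(0, len(order), run.batch_size):
            sel = order[start : start + run.batch_size]
            batch = np.stack(
                [
                    (augment(train_images[epoch_indices[k]], rng, run.augment_spec) - mean) / std
                    for k in sel
                ]
            ).transpose(0, 3, 1, 2)
            logits = model.forward(np.ascontiguousarray(batch), train=True)
            loss, dlogits = multilabel_soft_margin_loss(logits, y_train[sel])
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        record = {"epoch": epoch, "loss": float(np.mean(losses))}
        if x_val is not None:
            val_scores = sigmoid(_forward_scores(model, x_val))
            try:
                cored_auprc = auprc(y_val[:, 0], val_scores[:, 0])
            except UndefinedMetricError:
                cored_auprc = 0.0
            record["val_cored_auprc"] = cored_auprc
            if cored_auprc > best_metric:  # strict: earliest epoch wins ties
                best_metric, best_epoch = cored_auprc, epoch
                best_state, best_bn = model.state_dict(), model.bn_state()
        history.append(record)
        logger.debug("epoch %d: %s", epoch, record)
    if best_state is not None:
        model.load_state(best_state)
        model.load_bn_state(best_bn)
    else:
        best_epoch = run.epochs - 1
    return ModelBundle(model=model, run=run, norm_stats=stats,
                       best_epoch=best_epoch, history=history)
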