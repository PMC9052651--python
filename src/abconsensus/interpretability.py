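"""Guided Grad-CAM saliency maps and map-comparison analytics.

Saliency combines guided backpropagation (ReLU gradients gated on both
positive activation and positive upstream gradient) with class-activation
weighting from the last convolutional block: the class score's gradient at
the final ReLU feature maps is spatially averaged into per-channel weights,
the weighted ReLU'd sum is upsampled to input resolution, and the guided
gradient is multiplied by it.  Maps are min-max rescaled to 0–255 before any
thresholding.

Comparison analytics operate on binarized maps: an SSIM sweep across
thresholds, a three-way subtraction map (signal only in A / only in B /
match), and subset fractions |A∩B|/|A| in both directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity

from .cnn import ModelBundle, normalize_batch
from .data_model import CLASSES

DEFAULT_THRESHOLDS = tuple(range(0, 257, 8))


@dataclass
class SaliencyMap:
    """Per-pixel attribution for one (image, class) pair, 8-bit rescaled."""

    values: np.ndarray  # uint8, same spatial shape as the input image
    model_source: str
    image_id: str
    cls: str


@dataclass
class BinaryMap:
    """A thresholded saliency map; values in {0, 255}."""

    values: np.ndarray
    threshold: int

    @property
    def on(self) -> np.ndarray:
        return self.values == 255


def rescale_to_uint8(values: np.ndarray) -> np.ndarray:
    """Min-max rescale to 0–255 (constant maps go to 0)."""
    lo, hi = float(values.min()), float(values.max())
    if hi - lo < 1e-12:
        return np.zeros(values.shape, dtype=np.uint8)
    return np.round((values - lo) / (hi - lo) * 255.0).astype(np.uint8)


def guided_gradcam(
    bundle: ModelBundle,
    image: np.ndarray,
    cls: str,
    image_id: str = "",
) -> SaliencyMap:
    """Guided Grad-CAM attribution for one image and one class.

    Deterministic given weights and input; any trained or untrained weights
    yield a map (garbage in, garbage map out).
    """
    if cls not in CLASSES:
        raise ValueError(f"unknown class {cls!r}")
    model = bundle.model
    x = normalize_batch(image[None], bundle.norm_stats)
    model.forward(x, train=False)

    k = CLASSES.index(cls)
    dout = np.zeros((1, len(CLASSES)), dtype=np.float32)
    dout[0, k] = 1.0
    dinput, dfeat = model.backward(
        dout, guided=True, capture_layer=model.last_relu_index
    )
    # class-activation weighting from the last conv block's ReLU output
    feats = model.layers[model.last_relu_index].out[0]  # (C, h, w)
    weights = dfeat[0].mean(axis=(1, 2))  # GAP of the gradients
    cam = np.maximum((weights[:, None, None] * feats).sum(axis=0), 0.0)
    zoom = image.shape[0] / cam.shape[0]
    cam_up = ndimage.zoom(cam, zoom, order=1)
    guided = np.abs(dinput[0]).sum(axis=0)  # (H, W) magnitude over channels
    return SaliencyMap(
        values=rescale_to_uint8(guided * cam_up),
        model_source=bundle.annotation_source,
        image_id=image_id,
        cls=cls,
    )


def binarize_map(smap: SaliencyMap | np.ndarray, t: int) -> BinaryMap:
    """Pixel >= t becomes 255, else 0 (t may be 0..256)."""
    values = smap.values if isinstance(smap, SaliencyMap) else np.asarray(smap)
    return BinaryMap(values=np.where(values >= t, 255, 0).astype(np.uint8), threshold=t)


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")


def ssim_curve(
    map_a: SaliencyMap | np.ndarray,
    map_b: SaliencyMap | np.ndarray,
    thresholds=DEFAULT_THRESHOLDS,
) -> list[float]:
    """SSIM between the two maps binarized at each threshold.

    Standard SSIM with a 7×7 window and data range 255; two identical
    constant maps (e.g. both all-OFF at t = 256) score 1.0.
    """
    va = map_a.values if isinstance(map_a, SaliencyMap) else np.asarray(map_a)
    vb = map_b.values if isinstance(map_b, SaliencyMap) else np.asarray(map_b)
    _check_same_shape(va, vb)
    out = []
    for t in thresholds:
        ba = binarize_map(va, t).values.astype(np.float64)
        bb = binarize_map(vb, t).values.astype(np.float64)
        if np.array_equal(ba, bb):
            out.append(1.0)
            continue
        out.append(
            float(structural_similarity(ba, bb, win_size=7, data_range=255))
        )
    return out


def subtraction_classes(novice: BinaryMap, consensus: BinaryMap) -> dict:
    """Three-way per-pixel classification of two binarized maps.

    Pixels are ``novice_only`` (ON in novice, OFF in consensus),
    ``consensus_only`` (the reverse) or ``match``; the three fractions
    partition the image and sum exactly to 1.
    """
    _check_same_shape(novice.values, consensus.values)
    a, b = novice.on, consensus.on
    n = a.size
    novice_only = int((a & ~b).sum())
    consensus_only = int((~a & b).sum())
    match = n - novice_only - consensus_only
    classes = np.zeros(a.shape, dtype=np.uint8)  # 0 = match
    classes[a & ~b] = 1
    classes[~a & b] = 2
    return {
        "classes": classes,
        "novice_only": novice_only / n,
        "consensus_only": consensus_only / n,
        "match": match / n,
    }


def subset_fractions(novice: BinaryMap, consensus: BinaryMap) -> tuple[float, float]:
    """(consensus_in_novice, novice_in_consensus) containment fractions.

    Each fraction is |A∩B| / |A| with A the named map's ON set; an empty ON
    set yields 1.0 (vacuous containment).
    """
    _check_same_shape(novice.values, consensus.values)
    a, b = novice.on, consensus.on
    inter = int((a & b).sum())
    consensus_in_novice = inter / int(b.sum()) if b.any() else 1.0
    novice_in_consensus = inter / int(a.sum()) if a.any() else 1.0
    return consensus_in_novice, novice_in_consensus
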