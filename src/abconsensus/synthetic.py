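"""Synthetic stain-like tiles, plaque morphologies and annotator cohorts.

Every pipeline stage is testable without the deposited slides: this module
renders brown-chromogen-like deposits on a neutral near-white background and
simulates multi-annotator label sets with controlled error rates.

Morphologies follow the three amyloid-beta phenotypes:

* ``cored`` — a compact high-density disk with a darker central core,
* ``diffuse`` — a scattered low-density cloud of overlapping blobs,
* ``caa`` — an annulus (ring around a clear vessel lumen).

Deposit colors are sampled inside the active stain's HSV detection range, so
the detector is guaranteed to be exercised, while the background is neutral
gray (saturation 0) and therefore always out of range.  Class prevalences
default to the phase-one candidate distribution (~12% cored, ~88% diffuse,
~2% CAA).

What this generator does NOT emulate: real chromogen chemistry, tissue
texture, out-of-focus blur, or annotator disagreement driven by genuinely
ambiguous morphology (simulated annotators err independently per image).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import color as skcolor

from .data_model import CLASSES, BoundingBox, LabelTable, logger, substream
from .labeling import float_label_table
from .preprocess import (
    HsvRange,
    PlaqueCandidate,
    Tile,
    center_crop,
    crop_window,
    detect_candidates,
)

DEFAULT_PREVALENCE = {"cored": 0.12, "diffuse": 0.88, "caa": 0.02}


@dataclass(frozen=True)
class MorphologySpec:
    """Geometry ranges (pixels) for one rendered deposit."""

    classes: tuple  # subset of CLASSES present in this deposit
    radius: float
    center: tuple  # (x, y) in tile frame


def _hsv_color(rng: np.random.Generator, v_range: tuple, s_range=(60, 200),
               h_range=(5, 35)) -> np.ndarray:
    """Sample an RGB color from inside the 4G8/6E10 HSV detection range.

    H is on the 0–179 half-degree scale; margins keep the color in-range
    after 8-bit quantization.
    """
    h = rng.integers(*h_range) / 180.0
    s = rng.integers(*s_range) / 255.0
    v = rng.integers(*v_range) / 255.0
    rgb = skcolor.hsv2rgb(np.array([[[h, s, v]]]))[0, 0]
    return np.round(rgb * 255.0).astype(np.uint8)


def _disk(shape: tuple, cx: float, cy: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


def _paint(canvas: np.ndarray, mask: np.ndarray, color: np.ndarray) -> None:
    canvas[mask] = color


def _render_deposit(
    canvas: np.ndarray, spec: MorphologySpec, rng: np.random.Generator
) -> dict[str, BoundingBox]:
    """Draw one (possibly multi-class composite) deposit; return per-class
    tight truth boxes.

    Multi-class composites are drawn concentric and touching so the deposit
    stays a single connected component for the detector.
    """
    cx, cy = spec.center
    r = spec.radius
    shape = canvas.shape[:2]
    boxes: dict[str, BoundingBox] = {}
    masks: dict[str, np.ndarray] = {}
    classes = set(spec.classes)

    if "caa" in classes:
        inner = 0.5 * r if "cored" in classes else 0.55 * r
        ring = _disk(shape, cx, cy, r) & ~_disk(shape, cx, cy, inner)
        _paint(canvas, ring, _hsv_color(rng, (120, 200)))
        masks["caa"] = ring
    if "cored" in classes:
        rr = 0.5 * r if "caa" in classes else r
        disk = _disk(shape, cx, cy, rr)
        _paint(canvas, disk, _hsv_color(rng, (120, 200)))
        core = _disk(shape, cx, cy, 0.45 * rr)
        _paint(canvas, core, _hsv_color(rng, (80, 120)))
        masks["cored"] = disk
    if "diffuse" in classes:
        anchor = 0.55 * r if ("cored" in classes or "caa" in classes) else 0.0
        cloud = np.zeros(shape, dtype=bool)
        color = _hsv_color(rng, (160, 210), s_range=(40, 120))
        n_blobs = int(rng.integers(6, 10))
        cloud |= _disk(shape, cx + anchor, cy, 0.5 * r)
        for _ in range(n_blobs):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, 0.55 * r)
            bx, by = cx + anchor + rad * np.cos(ang), cy + rad * np.sin(ang)
            cloud |= _disk(shape, bx, by, rng.uniform(0.35, 0.5) * r)
        # carve speckle holes for the scattered low-density look
        holes = rng.random(shape) < 0.15
        cloud &= ~holes
        existing = np.zeros(shape, dtype=bool)
        for m in masks.values():
            existing |= m
        _paint(canvas, cloud & ~existing, color)
        masks["diffuse"] = cloud

    for cls, mask in masks.items():
        ys, xs = np.nonzero(mask)
        boxes[cls] = BoundingBox(
            int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1,
            class_marks=frozenset({cls}),
        )
    return boxes


def render_tile(
    placements: list[MorphologySpec],
    seed: int,
    tile_size: int = 1536,
    stain: str = "4G8",
    wsi_id: str = "wsi0",
    tile_origin: tuple = (0, 0),
    min_separation_factor: float = 2.2,
) -> tuple[Tile, LabelTable, list[BoundingBox]]:
    """Render one tile; returns (tile, tile-level labels, truth boxes).

    Deterministic for a given seed.  Placements whose disks would collide
    (center distance below ``min_separation_factor`` × max radius) raise an
    error — the generator keeps deposits resolvable into distinct crops.
    """
    for i, a in enumerate(placements):
        ax, ay = a.center
        if not (a.radius <= ax < tile_size - a.radius and a.radius <= ay < tile_size - a.radius):
            raise ValueError(f"placement {i} outside tile bounds")
        for b in placements[i + 1 :]:
            d = np.hypot(ax - b.center[0], ay - b.center[1])
            if d < min_separation_factor * max(a.radius, b.radius):
                raise ValueError("placement density cap exceeded (deposits collide)")
    rng = substream(seed, f"render-{wsi_id}-{tile_origin}")
    gray = rng.integers(246, 253, size=(tile_size, tile_size)).astype(np.uint8)
    canvas = np.stack([gray] * 3, axis=2)  # neutral: saturation 0, out of range
    boxes: list[BoundingBox] = []
    present = set()
    for spec in placements:
        per_class = _render_deposit(canvas, spec, rng)
        boxes.extend(per_class.values())
        present.update(per_class.keys())
    tile = Tile(pixels=canvas, tile_origin=tile_origin, stain=stain,
                wsi_id=wsi_id, size=tile_size)
    row = {cls: int(cls in present) for cls in CLASSES}
    labels = LabelTable(
        pd.DataFrame([row], index=pd.Index([tile.tile_id], name="image_id")),
        source="truth",
    )
    return tile, labels, boxes


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """A generated crop cohort with truth labels and geometry metadata."""

    images: np.ndarray  # (N, crop, crop, 3) uint8
    image_ids: list
    truth: LabelTable
    image_wsis: dict  # image_id -> synthetic slide id
    records: list = field(default_factory=list)  # per-crop geometry dicts

    def __len__(self) -> int:
        return len(self.image_ids)


def generate_cohort(
    n_crops: int,
    prevalence: dict | None = None,
    seed: int = 0,
    crop_size: int = 64,
    stain: str = "4G8",
    crops_per_wsi: int = 80,
    min_area: int = 50,
) -> Cohort:
    """Generate crops through the real preprocess path (tile → detect → crop).

    Each crop receives exactly one composite deposit; class assignment hits
    the prevalence targets within ±1 image (cored and diffuse partition the
    cohort at 12%/88%; CAA is overlaid on a random 2%).  Truth labels come
    from the float-label machinery applied to the rendered truth boxes and
    the realized crop windows.
    """
    prevalence = dict(prevalence or DEFAULT_PREVALENCE)
    rng = substream(seed, "cohort")
    n_cored = int(round(prevalence["cored"] * n_crops))
    n_diffuse = int(round(prevalence["diffuse"] * n_crops))
    if n_cored + n_diffuse != n_crops:  # guard against rounding slack
        n_diffuse = n_crops - n_cored
    n_caa = int(round(prevalence["caa"] * n_crops))
    class_sets = [{"cored"} for _ in range(n_cored)] + [
        {"diffuse"} for _ in range(n_diffuse)
    ]
    rng.shuffle(class_sets)
    for i in rng.choice(n_crops, size=n_caa, replace=False):
        class_sets[i] = class_sets[i] | {"caa"}

    # 2×2 deposits per tile, cells wide enough that crop windows never
    # reach a neighboring deposit
    cell = int(crop_size * 1.5)
    tile_size = 2 * cell
    grid = [(cell // 2, cell // 2), (cell + cell // 2, cell // 2),
            (cell // 2, cell + cell // 2), (cell + cell // 2, cell + cell // 2)]
    r_lo, r_hi = 0.17 * crop_size, 0.24 * crop_size

    images, image_ids, records = [], [], []
    windows, boxes_by_image, image_wsis = {}, {}, {}
    hsv = HsvRange.for_stain(stain)
    k = 0
    tile_index = 0
    while k < n_crops:
        wsi_id = f"syn{tile_index * 4 // crops_per_wsi:03d}"
        placements = []
        for gx, gy in grid:
            if k + len(placements) >= n_crops:
                break
            jx, jy = rng.uniform(-3, 3, size=2)
            placements.append(
                MorphologySpec(
                    classes=tuple(sorted(class_sets[k + len(placements)])),
                    radius=float(rng.uniform(r_lo, r_hi)),
                    center=(gx + jx, gy + jy),
                )
            )
        tile, _, truth_boxes = render_tile(
            placements, seed=seed + tile_index, tile_size=tile_size, stain=stain,
            wsi_id=wsi_id, tile_origin=(0, 0),
        )
        candidates = detect_candidates(tile, hsv, min_area=min_area)
        matched = _match_candidates(candidates, placements)
        if len(matched) != len(placements):
            raise RuntimeError(
                f"tile {tile_index}: detected {len(matched)} of "
                f"{len(placements)} placements — adjust morphology parameters"
            )
        for cand, placement in matched:
            image_id = f"crop{k:06d}"
            crop = center_crop(tile, cand, crop_size)
            x0, x1, y0, y1 = crop_window(cand.centroid, tile_size, crop_size)
            window = BoundingBox(x0, y0, x1, y1)
            near = [
                b for b in truth_boxes if b.intersection_area(window) > 0
            ]
            images.append(crop)
            image_ids.append(image_id)
            windows[image_id] = window
            boxes_by_image[image_id] = near
            image_wsis[image_id] = wsi_id
            records.append(
                {
                    "image_id": image_id,
                    "tile_id": tile.tile_id,
                    "wsi_id": wsi_id,
                    "window": window,
                    "boxes": near,
                    "centroid": cand.centroid,
                }
            )
            k += 1
        tile_index += 1

    truth = float_label_table(windows, boxes_by_image, source="truth")
    truth = truth.aligned_to(image_ids)
    realized = {cls: int(truth.labels(cls).sum()) for cls in CLASSES}
    logger.info("cohort of %d crops; positives %s", n_crops, realized)
    return Cohort(
        images=np.stack(images),
        image_ids=image_ids,
        truth=truth,
        image_wsis=image_wsis,
        records=records,
    )


def _match_candidates(
    candidates: list[PlaqueCandidate], placements: list[MorphologySpec]
) -> list[tuple[PlaqueCandidate, MorphologySpec]]:
    """Greedy nearest-center matching of detections to placements."""
    matched = []
    used = set()
    for placement in placements:
        px, py = placement.center
        best, best_d = None, np.inf
        for i, cand in enumerate(candidates):
            if i in used:
                continue
            d = np.hypot(cand.centroid[0] - px, cand.centroid[1] - py)
            if d < best_d:
                best, best_d = i, d
        if best is not None and best_d <= 2.5 * placement.radius:
            used.add(best)
            matched.append((candidates[best], placement))
    return matched


# ---------------------------------------------------------------------------
# simulated annotators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotatorProfile:
    """Per-class sensitivity/specificity of one simulated annotator."""

    sensitivity: dict
    specificity: dict
    seed: int = 0
    annotator_id: str = "sim"

    @classmethod
    def uniform(cls, sens: float, spec: float, seed: int = 0,
                annotator_id: str = "sim") -> "AnnotatorProfile":
        return cls(
            sensitivity={c: sens for c in CLASSES},
            specificity={c: spec for c in CLASSES},
            seed=seed,
            annotator_id=annotator_id,
        )


def simulate_annotator(truth: LabelTable, profile: AnnotatorProfile) -> LabelTable:
    """Corrupt truth labels with independent per-class, per-image errors.

    Each truth-positive is missed with probability 1−sensitivity and each
    truth-negative is falsely marked with probability 1−specificity.
    """
    rng = substream(profile.seed, f"annotator-{profile.annotator_id}")
    data = {}
    for cls in CLASSES:
        y = truth.labels(cls)
        u = rng.random(len(y))
        keep_pos = u < profile.sensitivity[cls]
        keep_neg = u < profile.specificity[cls]
        data[cls] = np.where(y == 1, keep_pos.astype(int), (~keep_neg).astype(int))
    df = pd.DataFrame(data, index=pd.Index(truth.image_ids(), name="image_id"))
    return LabelTable(df, source=profile.annotator_id)


def simulate_cohort_annotations(
    truth: LabelTable,
    n_annotators: int = 5,
    sens: float = 0.9,
    spec: float = 0.9,
    seed: int = 0,
    prefix: str = "NP",
) -> list[LabelTable]:
    """Convenience: n independent annotators with identical error rates."""
    return [
        simulate_annotator(
            truth,
            AnnotatorProfile.uniform(sens, spec, seed=seed * 1000 + i,
                                     annotator_id=f"{prefix}{i + 1}"),
        )
        for i in range(n_annotators)
    ]
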