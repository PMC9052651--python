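"""Label construction: float representations, consensus-of-n, agreement.

An annotator's bounding-box marks are converted into a per-image,
per-class *floating-point representation*: the sum, over boxes positively
marked for the class, of the fraction of each box's area lying inside the
image window.  The value is nonnegative and may exceed 1.0; the image is
binary-positive for the class iff the value is strictly greater than 0.99.

Consensus-of-n aggregates the five expert binary tables: positive iff at
least n experts marked the image positive for that class (n=1 is the union,
n=|experts| the intersection).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import (
    CLASSES,
    FLOAT_THRESHOLD,
    BoundingBox,
    LabelTable,
    check_aligned,
    logger,
)


@dataclass(frozen=True)
class ConsensusSpec:
    """Vote threshold n over an ordered member-annotator list."""

    n: int
    member_annotators: tuple

    def __post_init__(self):
        if not (1 <= self.n <= len(self.member_annotators)):
            raise ValueError(
                f"n={self.n} outside 1..{len(self.member_annotators)}"
            )


def compute_float_label(
    image_window: BoundingBox,
    positive_boxes: list[BoundingBox],
    cls: str,
) -> float:
    """Sum of contained-area fractions of boxes positively marked for ``cls``.

    Each box marked positive for the class contributes
    ``area(box ∩ window) / area(box)``; boxes not marked for the class
    contribute nothing.  Additive over disjoint box sets and order-invariant.
    """
    total = 0.0
    for box in positive_boxes:
        if box.area <= 0:
            raise ValueError("zero-area bounding box")
        if cls in box.class_marks:
            total += box.intersection_area(image_window) / box.area
    return total


def binarize_float_label(value: float, threshold: float = FLOAT_THRESHOLD) -> int:
    """Binary label from a float representation: strictly greater than 0.99."""
    if value < 0:
        raise ValueError("float representation must be nonnegative")
    return int(value > threshold)


def float_label_table(
    windows: dict[str, BoundingBox],
    boxes_by_image: dict[str, list[BoundingBox]],
    source: str = "",
    threshold: float = FLOAT_THRESHOLD,
) -> LabelTable:
    """Build a LabelTable (floats + binaries) from windows and marked boxes."""
    rows = {}
    for image_id, window in windows.items():
        boxes = boxes_by_image.get(image_id, [])
        row = {}
        for cls in CLASSES:
            v = compute_float_label(window, boxes, cls)
            row[f"float_{cls}"] = v
            row[cls] = int(v > threshold)
        rows[image_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index").rename_axis("image_id")
    return LabelTable(df, source=source)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------


def consensus_of_n(label_tables: list[LabelTable], n: int) -> LabelTable:
    """Consensus-of-n label table over aligned member tables.

    Per image and class: positive iff at least ``n`` member tables are
    positive.  Monotone in n; n=1 is the set union, n=len(tables) the
    intersection.
    """
    if not (1 <= n <= len(label_tables)):
        raise ValueError(f"n={n} outside 1..{len(label_tables)}")
    image_ids = check_aligned(label_tables)
    votes = np.sum(
        [t.aligned_to(image_ids).matrix() for t in label_tables], axis=0
    )
    df = pd.DataFrame(
        (votes >= n).astype(int), index=pd.Index(image_ids, name="image_id"),
        columns=list(CLASSES),
    )
    return LabelTable(df, source=f"consensus-of-{n}")


def exact_agreement_histogram(
    label_tables: list[LabelTable], cls: str
) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of the exact number of positive votes per image.

    Returns ``(counts, fractions)`` where ``counts[e]`` is the number of
    images receiving exactly ``e`` positive votes for the class
    (e = 0..len(tables); counts partition all images) and ``fractions`` are
    the same counts normalised over images with at least one positive vote.
    """
    image_ids = check_aligned(label_tables)
    votes = np.sum(
        [t.aligned_to(image_ids).labels(cls) for t in label_tables], axis=0
    )
    k = len(label_tables)
    counts = np.bincount(votes, minlength=k + 1)
    n_any = counts[1:].sum()
    fractions = np.zeros(k + 1)
    if n_any > 0:
        fractions[1:] = counts[1:] / n_any
    return counts, fractions


def agreement_summary(label_tables: list[LabelTable]) -> pd.DataFrame:
    """Per-class exact-agreement fractions (rows: e = 1..n_annotators)."""
    rows = {}
    for cls in CLASSES:
        _, fractions = exact_agreement_histogram(label_tables, cls)
        rows[cls] = fractions[1:]
    return pd.DataFrame(rows, index=range(1, len(label_tables) + 1))


# ---------------------------------------------------------------------------
# class balancing
# ---------------------------------------------------------------------------


def balancing_ratios(table: LabelTable) -> tuple[int, int]:
    """Replication counts r1 (diffuse:cored) and r2 (diffuse:CAA).

    Nearest-integer rounding with a floor of 1; a zero minority count yields
    ratio 1 (no replication) with a warning.
    """
    d = int(table.labels("diffuse").sum())
    c = int(table.labels("cored").sum())
    a = int(table.labels("caa").sum())
    if d == 0:
        raise ValueError("no diffuse positives; balancing undefined")

    def ratio(minority: int, name: str) -> int:
        if minority == 0:
            logger.warning("no %s positives; skipping that balancing ratio", name)
            return 1
        return max(1, round(d / minority))

    return ratio(c, "cored"), ratio(a, "caa")


def class_balance(
    image_ids: list[str], table: LabelTable
) -> tuple[list[str], int, int]:
    """Oversample minority-class images by replication.

    Images positive for cored (and not CAA) appear r1 times, CAA-positive
    (not cored) r2 times, positive for both max(r1, r2) times, all others
    once.  Returns the replicated id list (grouped per image) plus (r1, r2).
    The distinct image set is preserved; only multiplicities change.
    """
    sub = table.aligned_to(image_ids)
    r1, r2 = balancing_ratios(sub)
    cored = sub.labels("cored")
    caa = sub.labels("caa")
    out = []
    for i, image_id in enumerate(image_ids):
        if cored[i] and caa[i]:
            reps = max(r1, r2)
        elif cored[i]:
            reps = r1
        elif caa[i]:
            reps = r2
        else:
            reps = 1
        out.extend([image_id] * reps)
    return out, r1, r2
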