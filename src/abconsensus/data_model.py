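"""Annotation data model, file formats, configuration and logging.

The package revolves around three tabular objects:

* :class:`RawAnnotation` — one annotator's marks for one image, exactly as
  recorded at annotation time (any combination of the three amyloid-beta
  classes plus the auxiliary "negative", "flag" and "not sure" marks, and the
  query bounding box that was shown).
* :class:`AnnotationSet` — all raw annotations of a single annotator over a
  fixed image list.
* :class:`LabelTable` — per-image, per-class binary labels, optionally backed
  by the floating-point representations they were binarized from.

Annotation tables are plain CSV (UTF-8, header required, booleans as 0/1);
coordinates are 0-based, half-open, ``(x=column, y=row)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("abconsensus")

CLASSES = ("cored", "diffuse", "caa")
AUX_MARKS = ("negative", "flag", "notsure")
STAINS = ("4G8", "6E10", "NAB228")

#: canonical CSV schema for annotation tables
ANNOTATION_COLUMNS = (
    "image_id",
    "annotator_id",
    "cored",
    "diffuse",
    "caa",
    "negative",
    "flag",
    "notsure",
    "x0",
    "y0",
    "x1",
    "y1",
)


def configure_logging(level: str = "INFO") -> None:
    """Initialise the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(getattr(logging, level.upper()))


class SchemaError(ValueError):
    """A required column is missing or malformed."""


class DuplicateKeyError(ValueError):
    """The same (annotator, image) key appears more than once."""


class AlignmentError(ValueError):
    """Label tables do not share an identical image set."""


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, 0-based, half-open, in the tile coordinate frame."""

    x0: int
    y0: int
    x1: int
    y1: int
    class_marks: frozenset = frozenset()

    def __post_init__(self):
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"degenerate box {(self.x0, self.y0, self.x1, self.y1)}")
        object.__setattr__(self, "class_marks", frozenset(self.class_marks))

    @property
    def area(self) -> int:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    def intersection_area(self, other: "BoundingBox") -> int:
        w = min(self.x1, other.x1) - max(self.x0, other.x0)
        h = min(self.y1, other.y1) - max(self.y0, other.y0)
        return max(w, 0) * max(h, 0)


# ---------------------------------------------------------------------------
# raw annotations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RawAnnotation:
    """One annotator's marks for one image.

    All marks are independently settable (the task is multi-label); the
    auxiliary marks never influence derived labels.
    """

    image_id: str
    annotator_id: str
    cored_mark: bool = False
    diffuse_mark: bool = False
    caa_mark: bool = False
    negative_mark: bool = False
    flag_mark: bool = False
    notsure_mark: bool = False
    box: BoundingBox | None = None
    extra: Mapping[str, object] = field(default_factory=dict)


def resolve_marks(raw: RawAnnotation) -> tuple[int, int, int]:
    """Resolve raw marks into the (cored, diffuse, caa) binary triple.

    A class is positive iff its mark is set.  "negative", "flag" and
    "not sure" are audit marks only: an image marked both negative and e.g.
    cored resolves to cored-positive, and the auxiliary marks never create a
    positive on their own.
    """
    return (int(raw.cored_mark), int(raw.diffuse_mark), int(raw.caa_mark))


@dataclass
class AnnotationSet:
    """All raw annotations of one annotator over a fixed image list."""

    annotator_id: str
    annotations: dict = field(default_factory=dict)  # image_id -> RawAnnotation

    def __len__(self) -> int:
        return len(self.annotations)

    def __iter__(self):
        return iter(self.annotations.values())

    def add(self, raw: RawAnnotation) -> None:
        if raw.image_id in self.annotations:
            raise DuplicateKeyError(
                f"duplicate image_id {raw.image_id!r} for annotator "
                f"{self.annotator_id!r}"
            )
        self.annotations[raw.image_id] = raw

    def image_ids(self) -> list[str]:
        return list(self.annotations.keys())

    def to_label_table(self) -> "LabelTable":
        """Resolve every raw annotation into a binary label row."""
        rows = {}
        for raw in self:
            rows[raw.image_id] = resolve_marks(raw)
        df = pd.DataFrame.from_dict(
            rows, orient="index", columns=list(CLASSES)
        ).rename_axis("image_id")
        return LabelTable(df, source=self.annotator_id)


# ---------------------------------------------------------------------------
# label tables
# ---------------------------------------------------------------------------


FLOAT_THRESHOLD = 0.99  # binary = float representation strictly greater


@dataclass
class LabelTable:
    """Per-image binary labels for the three amyloid-beta classes.

    ``frame`` is indexed by image_id with integer columns ``cored``,
    ``diffuse``, ``caa`` and optional ``float_<class>`` columns holding the
    nonnegative floating-point representations the binaries derive from
    (binary = float > 0.99 whenever both are present).
    """

    frame: pd.DataFrame
    source: str = ""

    def __post_init__(self):
        missing = [c for c in CLASSES if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"label table missing columns {missing}")
        self.frame = self.frame.copy()
        for c in CLASSES:
            self.frame[c] = self.frame[c].astype(int)
            fc = f"float_{c}"
            if fc in self.frame.columns:
                vals = self.frame[fc].astype(float)
                if (vals < 0).any():
                    raise ValueError(f"negative float labels in column {fc}")
                expected = (vals > FLOAT_THRESHOLD).astype(int)
                if not (expected == self.frame[c]).all():
                    raise ValueError(
                        f"binary column {c!r} inconsistent with {fc!r} "
                        f"under the >{FLOAT_THRESHOLD} rule"
                    )

    def __len__(self) -> int:
        return len(self.frame)

    def image_ids(self) -> list[str]:
        return list(self.frame.index)

    def labels(self, cls: str) -> np.ndarray:
        return self.frame[cls].to_numpy()

    def matrix(self) -> np.ndarray:
        """(n_images, 3) binary array in canonical class order."""
        return self.frame[list(CLASSES)].to_numpy()

    def positives(self, cls: str) -> set:
        return set(self.frame.index[self.frame[cls] == 1])

    def aligned_to(self, image_ids: Sequence[str]) -> "LabelTable":
        return LabelTable(self.frame.loc[list(image_ids)], source=self.source)


def check_aligned(tables: Sequence[LabelTable]) -> list[str]:
    """Return the shared image list; raise AlignmentError on any mismatch."""
    ids0 = set(tables[0].image_ids())
    for t in tables[1:]:
        ids = set(t.image_ids())
        if ids != ids0:
            diff = sorted(ids0.symmetric_difference(ids))
            raise AlignmentError(
                f"label tables disagree on image sets; symmetric difference "
                f"(first 10): {diff[:10]} ({len(diff)} total)"
            )
    return tables[0].image_ids()


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def read_annotation_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> AnnotationSet:
    """Read one annotator's raw annotation CSV.

    ``column_map`` optionally maps foreign column names onto the canonical
    schema (for externally deposited tables whose headers differ); unknown
    columns are preserved as opaque per-row metadata.
    """
    df = pd.read_csv(path, dtype={"image_id": str, "annotator_id": str})
    if column_map:
        df = df.rename(columns=dict(column_map))
    required = [c for c in ANNOTATION_COLUMNS if c not in ("x0", "y0", "x1", "y1")]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"annotation table {path} missing column {col!r}")
    has_box = all(c in df.columns for c in ("x0", "y0", "x1", "y1"))
    extra_cols = [c for c in df.columns if c not in ANNOTATION_COLUMNS]

    annotators = df["annotator_id"].unique()
    if len(annotators) != 1:
        raise SchemaError(
            f"annotation table {path} mixes annotators {list(annotators)}"
        )
    aset = AnnotationSet(annotator_id=str(annotators[0]))
    for row in df.itertuples(index=False):
        row = row._asdict()
        box = None
        if has_box:
            marks = frozenset(c for c in CLASSES if int(row[c]))
            box = BoundingBox(
                int(row["x0"]), int(row["y0"]), int(row["x1"]), int(row["y1"]),
                class_marks=marks,
            )
        aset.add(
            RawAnnotation(
                image_id=str(row["image_id"]),
                annotator_id=str(row["annotator_id"]),
                cored_mark=bool(int(row["cored"])),
                diffuse_mark=bool(int(row["diffuse"])),
                caa_mark=bool(int(row["caa"])),
                negative_mark=bool(int(row["negative"])),
                flag_mark=bool(int(row["flag"])),
                notsure_mark=bool(int(row["notsure"])),
                box=box,
                extra={c: row[c] for c in extra_cols},
            )
        )
    logger.info("read %d annotations for %s from %s", len(aset), aset.annotator_id, path)
    return aset


def write_annotation_table(aset: AnnotationSet, path: str | Path) -> None:
    """Write an AnnotationSet in the canonical CSV dialect (round-trip safe)."""
    rows = []
    for raw in aset:
        row = {
            "image_id": raw.image_id,
            "annotator_id": raw.annotator_id,
            "cored": int(raw.cored_mark),
            "diffuse": int(raw.diffuse_mark),
            "caa": int(raw.caa_mark),
            "negative": int(raw.negative_mark),
            "flag": int(raw.flag_mark),
            "notsure": int(raw.notsure_mark),
        }
        if raw.box is not None:
            row.update(x0=raw.box.x0, y0=raw.box.y0, x1=raw.box.x1, y1=raw.box.y1)
        rows.append(row)
    cols = [c for c in ANNOTATION_COLUMNS if rows and c in rows[0]]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_label_table(path: str | Path, source: str = "") -> LabelTable:
    df = pd.read_csv(path, dtype={"image_id": str}).set_index("image_id")
    src = source
    if "source" in df.columns:
        uniq = df["source"].unique()
        src = str(uniq[0]) if len(uniq) == 1 else source
        df = df.drop(columns=["source"])
    return LabelTable(df, source=src)


def write_label_table(table: LabelTable, path: str | Path) -> None:
    df = table.frame.copy()
    df["source"] = table.source
    df.rename_axis("image_id").to_csv(path)


# ---------------------------------------------------------------------------
# run configuration and reproducible random streams
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Top-level run configuration.

    Defaults follow the study protocol: four cross-validation folds, 60
    epochs, Adam with learning rate 0.001 and weight decay 0.03.
    """

    stain: str = "4G8"
    seed: int = 0
    fold_count: int = 4
    epochs: int = 60
    learning_rate: float = 1e-3
    weight_decay: float = 0.03
    consensus_n: int = 2
    annotator_count: int = 5
    min_blob_area: int = 100
    float_threshold: float = FLOAT_THRESHOLD
    normalize_before_detect: bool = True
    log_level: str = "INFO"
    out_dir: str = "out"

    def __post_init__(self):
        if self.stain not in STAINS:
            raise ValueError(f"unknown stain {self.stain!r}; expected one of {STAINS}")
        if not (1 <= self.consensus_n <= self.annotator_count):
            raise ValueError(
                f"consensus_n={self.consensus_n} outside 1..{self.annotator_count}"
            )
        if self.fold_count < 2:
            raise ValueError("fold_count must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)

    def with_(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    def rng(self, stage: str) -> np.random.Generator:
        return substream(self.seed, stage)


def substream(seed: int, stage: str) -> np.random.Generator:
    """Named, independent random substream derived from the run seed.

    Every source of randomness in the package draws from one of these, so a
    pipeline is bit-reproducible given (seed, stage-name) and stages do not
    perturb each other's streams.
    """
    import zlib

    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(key,))))
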