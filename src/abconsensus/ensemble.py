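"""Sparse-affine ensembles over frozen constituent CNNs.

An ensemble links M trained CNNs with a learnable sparse affine layer: the
constituents are frozen (no gradient reaches them) and the only trainable
parameters weight each constituent's final class outputs.  The layer is
block-diagonal per class — class c of the ensemble depends only on the
constituents' class-c scores — giving M weights plus one bias per class
(3·(M+1) parameters).  Constituent scores enter post-sigmoid.

The module also builds random-labeler annotation sets (class-prevalence-
matched label permutations) used to probe ensemble robustness to noisy
constituents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import CLASSES, LabelTable, check_aligned, logger, substream
from .cnn import Adam, ModelBundle, multilabel_soft_margin_loss, predict, sigmoid


@dataclass
class EnsembleSpec:
    """Frozen constituents plus the trainable per-class affine weights."""

    constituents: list  # ModelBundle instances or opaque handles
    w: np.ndarray  # (M, 3)
    b: np.ndarray  # (3,)
    trained_on: str = ""

    @property
    def n_constituents(self) -> int:
        return self.w.shape[0]

    @classmethod
    def init(cls, constituents: list, trained_on: str = "") -> "EnsembleSpec":
        """Uniform 1/M weights and zero bias: starts at simple vote averaging."""
        m = len(constituents)
        return cls(
            constituents=list(constituents),
            w=np.full((m, len(CLASSES)), 1.0 / m, dtype=np.float64),
            b=np.zeros(len(CLASSES), dtype=np.float64),
            trained_on=trained_on,
        )


def combine(spec: EnsembleSpec, constituent_scores: np.ndarray) -> np.ndarray:
    """Squashed affine combination of constituent class scores.

    ``constituent_scores`` is (M, 3) for one image or (N, M, 3) for a batch;
    output[c] = sigmoid(b[c] + sum_m w[m, c] * score[m, c]).
    """
    s = np.asarray(constituent_scores, dtype=float)
    single = s.ndim == 2
    if single:
        s = s[None]
    if s.shape[1] != spec.n_constituents or s.shape[2] != len(CLASSES):
        raise ValueError(
            f"expected (N, {spec.n_constituents}, {len(CLASSES)}) scores, got {s.shape}"
        )
    z = np.einsum("nmc,mc->nc", s, spec.w) + spec.b
    out = sigmoid(z)
    return out[0] if single else out


def constituent_score_matrix(
    constituents: list[ModelBundle], images: np.ndarray
) -> np.ndarray:
    """(N, M, 3) post-sigmoid scores of every constituent on an image stack."""
    return np.stack([predict(c, images) for c in constituents], axis=1)


class _AffineParams:
    """Adapter exposing (param, grad) pairs to the shared Adam optimizer."""

    def __init__(self, spec: EnsembleSpec):
        self.w = spec.w
        self.b = spec.b
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def pairs(self):
        return [(self.w, self.gw), (self.b, self.gb)]


def train_ensemble(
    spec: EnsembleSpec,
    constituent_scores: np.ndarray,
    image_ids: list[str],
    labels: LabelTable,
    epochs: int = 60,
    learning_rate: float = 1e-3,
    weight_decay: float = 0.03,
    batch_size: int = 32,
    seed: int = 0,
) -> EnsembleSpec:
    """Fit the affine weights against a label table; constituents untouched.

    Training mirrors the single-CNN recipe (Adam, lr 0.001, weight decay
    0.03, multi-label soft-margin loss, 60 epochs) but the only parameters
    updated are the 3·(M+1) affine weights, so the fit is convex in them.
    """
    scores = np.asarray(constituent_scores, dtype=np.float64)
    y = labels.aligned_to(image_ids).matrix().astype(np.float64)
    out = EnsembleSpec(
        constituents=spec.constituents,
        w=spec.w.copy(),
        b=spec.b.copy(),
        trained_on=labels.source,
    )
    params = _AffineParams(out)
    opt = Adam(params.pairs(), lr=learning_rate, weight_decay=weight_decay)
    rng = substream(seed, f"ensemble-{labels.source}")
    history = []
    for epoch in range(epochs):
        order = rng.permutation(len(scores))
        losses = []
        for start in range(0, len(order), batch_size):
            sel = order[start : start + batch_size]
            s = scores[sel]
            z = np.einsum("nmc,mc->nc", s, params.w) + params.b
            loss, dz = multilabel_soft_margin_loss(z, y[sel])
            params.gw[...] = np.einsum("nmc,nc->mc", s, dz.astype(np.float64))
            params.gb[...] = dz.sum(axis=0)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    out.loss_history = history
    return out


# ---------------------------------------------------------------------------
# random labelers
# ---------------------------------------------------------------------------


@dataclass
class RandomLabelSet:
    """A prevalence-matched random permutation of labels."""

    table: LabelTable
    permutation_seed: int


def make_random_label_set(
    expert_tables: list[LabelTable], seed: int, name: str = "random"
) -> RandomLabelSet:
    """Random annotation set keeping the experts' average class ratios.

    Per class, the positive count is the rounded mean of the expert positive
    counts; the positions are a seeded permutation, so two seeds give
    different assignments with identical counts.  Expected agreement with
    any expert is chance level (kappa ≈ 0).
    """
    image_ids = check_aligned(expert_tables)
    rng = substream(seed, f"random-labels-{name}")
    n = len(image_ids)
    data = {}
    for k, cls in enumerate(CLASSES):
        target = int(round(np.mean([t.aligned_to(image_ids).labels(cls).sum()
                                    for t in expert_tables])))
        col = np.zeros(n, dtype=int)
        col[:target] = 1
        rng.shuffle(col)
        data[cls] = col
    df = pd.DataFrame(data, index=pd.Index(image_ids, name="image_id"))
    return RandomLabelSet(table=LabelTable(df, source=name), permutation_seed=seed)


def inject_random_constituents(
    spec: EnsembleSpec,
    k: int,
    seed: int,
    expert_tables: list[LabelTable],
    train_constituent,
) -> EnsembleSpec:
    """Append k CNNs trained on independent random label sets.

    ``train_constituent(random_label_table, index)`` must return a frozen
    constituent (e.g. a trained ModelBundle).  The returned spec has
    reinitialised affine weights and must be trained normally afterwards.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    new_constituents = list(spec.constituents)
    for i in range(k):
        rls = make_random_label_set(expert_tables, seed + i, name=f"random-{i}")
        new_constituents.append(train_constituent(rls.table, i))
    return EnsembleSpec.init(new_constituents, trained_on=spec.trained_on)


# ---------------------------------------------------------------------------
# robustness experiment
# ---------------------------------------------------------------------------


def random_labeler_robustness(
    seed: int = 0,
    n_crops: int = 2000,
    n_annotators: int = 5,
    sensitivity: float = 0.9,
    specificity: float = 0.9,
    cnn_epochs: int = 5,
    ensemble_epochs: int = 60,
    crop_size: int = 64,
    batch_size: int = 64,
) -> dict:
    """Measure ensemble robustness to one random-labeler constituent.

    On a synthetic multi-annotator cohort, five expert CNNs and one
    random-labeler CNN are trained; for each of the ten annotation sources
    (five experts, five consensus strategies) an ensemble with and without
    the random constituent is trained, and both are evaluated on all ten
    hold-out benchmarks.  Returns the mean absolute per-benchmark AUPRC
    difference plus the per-comparison detail.

    The constituent CNNs use the reduced 2-block architecture and a short
    epoch budget so the experiment fits a desk-scale CPU run; the ensembles
    themselves train for the full 60 epochs.
    """
    from .cnn import ArchitectureSpec, TrainingRun, train_model, train_test_split_by_wsi
    from .evaluation import UndefinedMetricError, auprc
    from .labeling import consensus_of_n
    from .synthetic import AnnotatorProfile, generate_cohort, simulate_annotator

    cohort = generate_cohort(
        n_crops=n_crops, seed=seed, crop_size=crop_size
    )
    images, image_ids, truth = cohort.images, cohort.image_ids, cohort.truth
    expert_tables = [
        simulate_annotator(
            truth,
            AnnotatorProfile.uniform(sensitivity, specificity, seed=seed * 1000 + i,
                                     annotator_id=f"NP{i + 1}"),
        )
        for i in range(n_annotators)
    ]
    consensus_tables = [consensus_of_n(expert_tables, n) for n in
                        range(1, n_annotators + 1)]
    benchmarks = expert_tables + consensus_tables

    rng = substream(seed, "robustness-split")
    train_ids, test_ids = train_test_split_by_wsi(cohort.image_wsis, 0.33, rng)
    idx = {im: i for i, im in enumerate(image_ids)}
    # carve a validation quarter out of the training slides for checkpointing
    val_rng = substream(seed, "robustness-val")
    train_wsis = sorted({cohort.image_wsis[i] for i in train_ids})
    val_rng.shuffle(train_wsis)
    val_wsis = set(train_wsis[: max(1, len(train_wsis) // 4)])
    fit_ids = [i for i in train_ids if cohort.image_wsis[i] not in val_wsis]
    val_ids = [i for i in train_ids if cohort.image_wsis[i] in val_wsis]

    def img_stack(ids):
        return images[[idx[i] for i in ids]]

    arch = ArchitectureSpec.tiny(input_size=crop_size)

    def train_cnn(table: LabelTable, tag: str) -> ModelBundle:
        run = TrainingRun(
            fold_index=0, annotation_source=table.source, epochs=cnn_epochs,
            batch_size=batch_size, seed=seed,
        )
        logger.info("training constituent CNN on %s", table.source)
        return train_model(
            img_stack(fit_ids), fit_ids, img_stack(val_ids), val_ids, table, run,
            arch=arch,
        )

    expert_cnns = [train_cnn(t, t.source) for t in expert_tables]
    random_set = make_random_label_set(expert_tables, seed, name="random-0")
    random_cnn = train_cnn(random_set.table, "random-0")

    all_bundles = expert_cnns + [random_cnn]
    train_scores_all = constituent_score_matrix(all_bundles, img_stack(train_ids))
    test_scores_all = constituent_score_matrix(all_bundles, img_stack(test_ids))

    diffs, detail = [], []
    for source_table in benchmarks:  # ten annotation sources
        variants = {}
        for label, m in (("normal", n_annotators), ("with_random", n_annotators + 1)):
            spec = EnsembleSpec.init(all_bundles[:m], trained_on=source_table.source)
            fitted = train_ensemble(
                spec, train_scores_all[:, :m], train_ids, source_table,
                epochs=ensemble_epochs, seed=seed,
            )
            variants[label] = combine(fitted, test_scores_all[:, :m])
        for bench in benchmarks:
            y = bench.aligned_to(test_ids).matrix()
            for k, cls in enumerate(CLASSES):
                try:
                    a = auprc(y[:, k], variants["normal"][:, k])
                    b = auprc(y[:, k], variants["with_random"][:, k])
                except UndefinedMetricError:
                    continue
                diffs.append(abs(a - b))
                detail.append(
                    {"ensemble": source_table.source, "benchmark": bench.source,
                     "class": cls, "auprc_normal": a, "auprc_with_random": b}
                )
    return {
        "mean_abs_auprc_diff": float(np.mean(diffs)),
        "n_comparisons": len(diffs),
        "n_train": len(train_ids),
        "n_test": len(test_ids),
        "detail": detail,
    }
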