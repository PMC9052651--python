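"""Metrics and benchmark-scheme evaluation.

AUPRC is average precision in the step-wise sense: the mean, over positive
examples, of the precision at each positive's rank when examples are sorted
by descending score (ties broken by stable input order).  Its random
baseline equals class prevalence.  AUROC equals the Mann–Whitney U statistic
normalised by P·N.  Cohen's kappa is chance-corrected agreement with
marginal-product expected agreement.

The four benchmark schemes compare models trained on consensus labels with
models trained on individual-expert labels:

* ``self`` — each model against its own training annotation source,
* ``consensus`` — every model against all five consensus-of-n tables,
* ``individual`` — every model against all five expert tables,
* ``all`` — both of the above.

A two-sample one-sided Z-test asks whether mean consensus-side performance
exceeds mean expert-side performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import erf, sqrt

import numpy as np
import pandas as pd

from .data_model import CLASSES, LabelTable


class UndefinedMetricError(ValueError):
    """Raised when a ranking metric is requested for single-class labels."""


def _check_binary_pair(labels, scores):
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise ValueError("labels and scores must be equal-length 1-D")
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise UndefinedMetricError("labels contain a single class")
    return labels.astype(int), scores


def auprc(labels, scores) -> float:
    """Average precision over a descending-score ranking.

    Tied scores form one threshold group: every example in the group is
    scored with the precision at the group's end, so constant scores yield
    exactly the class prevalence (the metric's random baseline).
    """
    labels, scores = _check_binary_pair(labels, scores)
    order = np.argsort(-scores, kind="stable")
    ranked = labels[order]
    s = scores[order]
    cum_pos = np.cumsum(ranked)
    # last index of each tied-score group
    change = np.nonzero(np.diff(s))[0]
    group_end = np.append(change, len(s) - 1)
    group_id = np.concatenate([[0], np.cumsum(np.diff(s) != 0)])
    ends = group_end[group_id]
    precision_at = cum_pos[ends] / (ends + 1)
    return float(precision_at[ranked == 1].mean())


def auroc(labels, scores) -> float:
    """Probability a random positive outscores a random negative
    (Mann–Whitney U / (P·N); ties count half)."""
    labels, scores = _check_binary_pair(labels, scores)
    from scipy.stats import rankdata

    ranks = rankdata(scores)  # midranks handle ties
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def cohens_kappa(a, b) -> float:
    """Cohen's kappa for two binary raters.

    Guard: two constant and identical raters are defined as kappa = 1.0
    (perfect, if vacuous, agreement).
    """
    a = np.asarray(a).astype(int)
    b = np.asarray(b).astype(int)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("raters must be equal-length 1-D, length >= 2")
    po = float(np.mean(a == b))
    pa, pb = a.mean(), b.mean()
    pe = pa * pb + (1 - pa) * (1 - pb)
    if 1 - pe < 1e-12:
        return 1.0 if po == 1.0 else 0.0
    return float((po - pe) / (1 - pe))


def kappa_matrix(tables: list[LabelTable], cls: str) -> pd.DataFrame:
    """Pairwise Cohen's kappa between annotator label tables for one class."""
    from .data_model import check_aligned

    ids = check_aligned(tables)
    names = [t.source for t in tables]
    mat = pd.DataFrame(np.eye(len(tables)), index=names, columns=names)
    for i in range(len(tables)):
        for j in range(i + 1, len(tables)):
            k = cohens_kappa(
                tables[i].aligned_to(ids).labels(cls),
                tables[j].aligned_to(ids).labels(cls),
            )
            mat.iloc[i, j] = mat.iloc[j, i] = k
    return mat


def kappa_summary(tables: list[LabelTable]) -> dict[str, tuple[float, float]]:
    """Per-class mean ± sd of the pairwise kappas (upper triangle)."""
    out = {}
    for cls in CLASSES:
        mat = kappa_matrix(tables, cls).to_numpy()
        iu = np.triu_indices(len(tables), k=1)
        vals = mat[iu]
        out[cls] = (float(vals.mean()), float(vals.std()))
    return out


def z_test_one_sided(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample one-sided Z-test: H1 is mean(a) > mean(b).

    Uses sample standard deviations (n−1).  Degenerate zero-variance
    samples: p = 0 if mean(a) > mean(b), 0.5 if equal, else 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need size >= 2")
    se = sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
    if se < 1e-300:
        diff = a.mean() - b.mean()
        return (np.inf if diff > 0 else (-np.inf if diff < 0 else 0.0),
                0.0 if diff > 0 else (1.0 if diff < 0 else 0.5))
    z = (a.mean() - b.mean()) / se
    p = 0.5 * (1.0 - erf(z / sqrt(2.0)))
    return float(z), float(p)


def intra_rater_accuracy(replicate_sets: list[dict[str, list[int]]]) -> dict[str, float]:
    """Mean per-class consistency over 4-replicate label sets.

    Each set holds, per class, the four labels an annotator gave to the same
    image (one phase-one plus three phase-two presentations); per-set
    consistency is the modal-label fraction (count of the most common label
    over 4).  The reported value is the mean over sets.
    """
    if not replicate_sets:
        raise ValueError("no replicate sets")
    sums = {cls: 0.0 for cls in CLASSES}
    for rset in replicate_sets:
        for cls in CLASSES:
            labels = rset[cls]
            if len(labels) != 4:
                raise ValueError(f"replicate set for {cls!r} has size {len(labels)}, expected 4")
            n_pos = int(np.sum(labels))
            sums[cls] += max(n_pos, 4 - n_pos) / 4.0
    return {cls: sums[cls] / len(replicate_sets) for cls in CLASSES}


# ---------------------------------------------------------------------------
# benchmark schemes
# ---------------------------------------------------------------------------

SCHEMES = ("self", "consensus", "individual", "all")
#: per-scheme sample size for 5 experts, 5 consensus strategies, 4 folds
SCHEME_SAMPLE_SIZES = {"self": 20, "consensus": 100, "individual": 100, "all": 200}


@dataclass
class MetricReport:
    """Per-class ranking metrics of one model under one benchmark."""

    model_source: str
    benchmark_source: str
    fold_index: int
    auprc: dict = field(default_factory=dict)
    auroc: dict = field(default_factory=dict)
    prevalence: dict = field(default_factory=dict)


def score_report(
    scores: np.ndarray,
    benchmark: LabelTable,
    image_ids: list[str],
    model_source: str = "",
    fold_index: int = 0,
) -> MetricReport:
    """Metrics of one score matrix (n_images, 3) against one benchmark."""
    y = benchmark.aligned_to(image_ids).matrix()
    report = MetricReport(model_source, benchmark.source, fold_index)
    for k, cls in enumerate(CLASSES):
        report.prevalence[cls] = float(y[:, k].mean())
        try:
            report.auprc[cls] = auprc(y[:, k], scores[:, k])
            report.auroc[cls] = auroc(y[:, k], scores[:, k])
        except UndefinedMetricError:
            report.auprc[cls] = np.nan
            report.auroc[cls] = np.nan
    return report


def _is_consensus(source: str) -> bool:
    return source.startswith("consensus-of-")


def evaluate_scheme(
    model_scores: dict[tuple[str, int], np.ndarray],
    scheme: str,
    image_ids: list[str],
    benchmark_tables: list[LabelTable],
    cls: str = "cored",
) -> tuple[list[float], list[float]]:
    """Collect per-(model, benchmark, fold) AUPRC samples for a scheme.

    ``model_scores`` maps (annotation_source, fold) to hold-out score
    matrices.  Returns (consensus_sample, expert_sample) — the AUPRC values
    feeding the consensus-superiority Z-test.  Under ``self`` each model is
    paired only with the benchmark of its own annotation source.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    benchmarks = {t.source: t for t in benchmark_tables}
    consensus_sample, expert_sample = [], []
    for (source, fold), scores in sorted(model_scores.items()):
        if scheme == "self":
            if source not in benchmarks:
                raise ValueError(f"self scheme: no benchmark for model source {source!r}")
            targets = [benchmarks[source]]
        elif scheme == "consensus":
            targets = [t for t in benchmark_tables if _is_consensus(t.source)]
        elif scheme == "individual":
            targets = [t for t in benchmark_tables if not _is_consensus(t.source)]
        else:
            targets = list(benchmark_tables)
        for bench in targets:
            y = bench.aligned_to(image_ids).labels(cls)
            try:
                value = auprc(y, scores[:, CLASSES.index(cls)])
            except UndefinedMetricError:
                continue
            (consensus_sample if _is_consensus(source) else expert_sample).append(value)
    return consensus_sample, expert_sample


def superiority_test(
    consensus_sample: list[float], expert_sample: list[float]
) -> dict[str, float]:
    """Consensus-minus-expert mean AUPRC differential with one-sided p."""
    z, p = z_test_one_sided(consensus_sample, expert_sample)
    return {
        "consensus_mean": float(np.mean(consensus_sample)),
        "expert_mean": float(np.mean(expert_sample)),
        "difference": float(np.mean(consensus_sample) - np.mean(expert_sample)),
        "z": z,
        "p": p,
        "n_consensus": len(consensus_sample),
        "n_expert": len(expert_sample),
    }


def stratified_reports(
    scores: np.ndarray,
    benchmark: LabelTable,
    image_ids: list[str],
    groups: dict[str, str],
    model_source: str = "",
) -> dict[str, MetricReport]:
    """Per-group (e.g. per-stain) metric reports plus the pooled report.

    Pooled prevalence equals the group-size-weighted mean of group
    prevalences, so stratified accounting recombines consistently.
    """
    out = {"pooled": score_report(scores, benchmark, image_ids, model_source)}
    ids = np.array(image_ids)
    glabels = np.array([groups[i] for i in image_ids])
    for g in sorted(set(glabels)):
        sel = glabels == g
        out[g] = score_report(scores[sel], benchmark, list(ids[sel]), model_source)
    return out
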