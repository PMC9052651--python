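"""Ranking metrics, kappa, Z-test, benchmark schemes."""

import itertools

import numpy as np
import pandas as pd
import pytest

import abconsensus as ab
from abconsensus.data_model import CLASSES


def _ap_oracle(labels, scores):
    """Counting oracle: each positive scored with the precision at its own
    score threshold (no sorting; pure pair counting)."""
    precisions = []
    for i, y in enumerate(labels):
        if y == 1:
            at_or_above = [j for j in range(len(scores)) if scores[j] >= scores[i]]
            tp = sum(labels[j] for j in at_or_above)
            precisions.append(tp / len(at_or_above))
    return sum(precisions) / len(precisions)


def _auroc_oracle(labels, scores):
    """Pair-counting oracle: P(score+ > score-) with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum((p > n_) + 0.5 * (p == n_) for p in pos for n_ in neg)
    return wins / (len(pos) * len(neg))


class TestAuprc:
    def test_hand_enumerated_example(self):
        assert ab.auprc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.6]) == pytest.approx(
            (1.0 + 2 / 3) / 2
        )

    def test_perfect_separation(self):
        assert ab.auprc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_constant_scores_give_prevalence(self):
        labels = [1, 0, 0, 0, 1, 0, 0, 0, 0, 0]
        assert ab.auprc(labels, [0.5] * 10) == pytest.approx(0.2)

    def test_single_class_is_error(self):
        with pytest.raises(ab.UndefinedMetricError):
            ab.auprc([1, 1], [0.1, 0.2])

    def test_matches_oracle_on_all_configurations_up_to_8(self):
        """Every label pattern of length ≤ 8, tie-free and tied scores."""
        rng = np.random.default_rng(0)
        for n in range(2, 9):
            scores_pool = [
                list(rng.permutation(n) / n),  # tie-free
                list((rng.integers(0, 3, n)) / 3.0),  # heavy ties
            ]
            for labels in itertools.product([0, 1], repeat=n):
                if sum(labels) in (0, n):
                    continue
                for scores in scores_pool:
                    assert ab.auprc(labels, scores) == pytest.approx(
                        _ap_oracle(labels, scores)
                    )
                    assert ab.auroc(labels, scores) == pytest.approx(
                        _auroc_oracle(labels, scores)
                    )

    def test_agrees_with_sklearn_when_tie_free(self):
        from sklearn.metrics import average_precision_score, roc_auc_score

        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 40)
        labels[0], labels[1] = 0, 1
        scores = rng.permutation(40) / 40.0
        assert ab.auprc(labels, scores) == pytest.approx(
            average_precision_score(labels, scores))
        assert ab.auroc(labels, scores) == pytest.approx(
            roc_auc_score(labels, scores))


class TestAuroc:
    def test_reversed_ranking_is_zero(self):
        assert ab.auroc([1, 0], [0.3, 0.7]) == 0.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(2)
        labels = np.repeat([0, 1], 5000)
        scores = rng.random(10000)
        assert ab.auroc(labels, scores) == pytest.approx(0.5, abs=0.02)


class TestKappa:
    def test_identical_raters(self):
        assert ab.cohens_kappa([1, 0, 1, 0], [1, 0, 1, 0]) == 1.0

    def test_direct_formula_examples(self):
        assert ab.cohens_kappa([1, 1, 0, 0], [1, 0, 0, 0]) == pytest.approx(0.5)
        assert ab.cohens_kappa([1, 1, 0, 0], [0, 0, 0, 0]) == pytest.approx(0.0)

    def test_symmetry_and_complement(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 2, 30)
        b = rng.integers(0, 2, 30)
        assert ab.cohens_kappa(a, b) == pytest.approx(ab.cohens_kappa(b, a))
        balanced = np.repeat([0, 1], 10)
        assert ab.cohens_kappa(balanced, 1 - balanced) == pytest.approx(-1.0)

    def test_constant_identical_raters_guard(self):
        assert ab.cohens_kappa([1, 1, 1], [1, 1, 1]) == 1.0

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(4)
        a = rng.integers(0, 2, 100)
        b = np.where(rng.random(100) < 0.3, 1 - a, a)
        assert ab.cohens_kappa(a, b) == pytest.approx(cohen_kappa_score(a, b))

    def test_kappa_summary_mean_sd(self, expert_tables):
        summary = ab.kappa_summary(expert_tables)
        for cls, (mean, sd) in summary.items():
            assert -1 <= mean <= 1 and sd >= 0
        mat = ab.kappa_matrix(expert_tables, "diffuse")
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T)
        assert np.allclose(np.diag(mat.to_numpy()), 1.0)


class TestZTest:
    def test_identical_samples(self):
        z, p = ab.z_test_one_sided([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert z == 0.0 and p == 0.5

    def test_extreme_separation(self):
        a = np.array([10.0, 10.1, 10.2, 10.3])
        b = a - 10 * a.std(ddof=1)
        _, p = ab.z_test_one_sided(a, b)
        assert p < 1e-6

    def test_worked_example(self):
        z, p = ab.z_test_one_sided([0.7, 0.8, 0.9], [0.4, 0.5, 0.6])
        assert z == pytest.approx(3.674, abs=1e-3)
        assert p == pytest.approx(1.2e-4, rel=0.05)

    def test_worked_example_against_scipy(self):
        from scipy import stats

        a, b = [0.7, 0.8, 0.9], [0.4, 0.5, 0.6]
        z, p = ab.z_test_one_sided(a, b)
        se = np.sqrt(np.var(a, ddof=1) / 3 + np.var(b, ddof=1) / 3)
        z_ref = (np.mean(a) - np.mean(b)) / se
        assert z == pytest.approx(z_ref)
        assert p == pytest.approx(stats.norm.sf(z_ref))


class TestIntraRater:
    def test_modal_fraction_cases(self):
        sets = [
            {c: [1, 1, 1, 1] for c in CLASSES},
            {c: [1, 1, 1, 0] for c in CLASSES},
            {c: [1, 1, 0, 0] for c in CLASSES},
        ]
        acc = ab.intra_rater_accuracy(sets[:1])
        assert all(v == 1.0 for v in acc.values())
        assert ab.intra_rater_accuracy(sets[1:2])["cored"] == 0.75
        assert ab.intra_rater_accuracy(sets[2:3])["cored"] == 0.5
        assert ab.intra_rater_accuracy(sets)["cored"] == pytest.approx((1 + 0.75 + 0.5) / 3)

    def test_wrong_set_size_rejected(self):
        with pytest.raises(ValueError):
            ab.intra_rater_accuracy([{c: [1, 0, 1] for c in CLASSES}])


def _fake_model_scores(rng, sources, n_folds, n_images):
    return {
        (src, fold): rng.random((n_images, 3))
        for src in sources
        for fold in range(n_folds)
    }


class TestSchemes:
    @pytest.fixture()
    def setup(self):
        rng = np.random.default_rng(5)
        n = 40
        image_ids = [f"i{k}" for k in range(n)]
        experts = []
        for k in range(5):
            m = rng.integers(0, 2, (n, 3))
            m[0] = [1, 1, 1]
            m[1] = [0, 0, 0]
            experts.append(ab.LabelTable(
                pd.DataFrame(m, columns=list(CLASSES),
                             index=pd.Index(image_ids, name="image_id")),
                source=f"NP{k + 1}"))
        consensus = [ab.consensus_of_n(experts, n_) for n_ in range(1, 6)]
        sources = [t.source for t in experts + consensus]
        scores = _fake_model_scores(rng, sources, 4, n)
        return image_ids, experts + consensus, scores

    @pytest.mark.parametrize("scheme", ab.SCHEME_SAMPLE_SIZES)
    def test_sample_sizes_match_protocol(self, setup, scheme):
        image_ids, benchmarks, scores = setup
        cons, expert = ab.evaluate_scheme(scores, scheme, image_ids, benchmarks,
                                          cls="diffuse")
        assert len(cons) == len(expert) == ab.SCHEME_SAMPLE_SIZES[scheme]

    def test_identical_model_identical_benchmark_identical_value(self, setup):
        image_ids, benchmarks, scores = setup
        y = benchmarks[0].labels("cored")
        s = scores[("NP1", 0)][:, 0]
        assert ab.auprc(y, s) == ab.auprc(y, s.copy())

    def test_superiority_report_fields(self, setup):
        image_ids, benchmarks, scores = setup
        cons, expert = ab.evaluate_scheme(scores, "all", image_ids, benchmarks)
        rep = ab.superiority_test(cons, expert)
        assert rep["n_consensus"] == 200 and rep["n_expert"] == 200
        assert 0 <= rep["p"] <= 1

    def test_stratified_prevalence_recombines(self, setup):
        image_ids, benchmarks, scores = setup
        groups = {i: ("4G8" if k < 20 else "NAB228") for k, i in enumerate(image_ids)}
        reports = ab.stratified_reports(scores[("NP1", 0)], benchmarks[0],
                                        image_ids, groups)
        pooled = reports["pooled"].prevalence["cored"]
        weighted = 0.5 * reports["4G8"].prevalence["cored"] + \
            0.5 * reports["NAB228"].prevalence["cored"]
        assert pooled == pytest.approx(weighted)
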