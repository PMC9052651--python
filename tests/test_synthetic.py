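"""Synthetic tile rendering, cohort generation, simulated annotators."""

import numpy as np
import pandas as pd
import pytest

import abconsensus as ab
from abconsensus.data_model import CLASSES
from abconsensus.preprocess import HsvRange
from abconsensus.synthetic import MorphologySpec


class TestRenderTile:
    def test_same_seed_is_byte_identical(self):
        spec = [MorphologySpec(("cored",), 12.0, (64, 64))]
        t1, _, _ = ab.render_tile(spec, seed=9, tile_size=128)
        t2, _, _ = ab.render_tile(spec, seed=9, tile_size=128)
        assert (t1.pixels == t2.pixels).all()

    def test_empty_spec_yields_no_candidates(self):
        tile, labels, boxes = ab.render_tile([], seed=0, tile_size=128)
        assert boxes == []
        assert ab.detect_candidates(tile, min_area=20) == []
        assert labels.matrix().sum() == 0

    def test_single_cored_placement_detected_near_center(self):
        spec = [MorphologySpec(("cored",), 13.0, (70, 50))]
        tile, labels, boxes = ab.render_tile(spec, seed=1, tile_size=128)
        cands = ab.detect_candidates(tile, min_area=40)
        assert len(cands) >= 1
        d = min(np.hypot(c.centroid[0] - 70, c.centroid[1] - 50) for c in cands)
        assert d < 5
        assert labels.matrix()[0, 0] == 1

    def test_deposit_pixels_fall_inside_detection_range(self):
        for classes in (("cored",), ("diffuse",), ("caa",)):
            spec = [MorphologySpec(classes, 14.0, (64, 64))]
            tile, _, boxes = ab.render_tile(spec, seed=2, tile_size=128)
            mask = HsvRange.for_stain("4G8").mask(tile.pixels)
            for box in boxes:
                region = mask[box.y0 : box.y1, box.x0 : box.x1]
                assert region.mean() > 0.5  # bulk of the deposit is in-range

    def test_morphologies_differ_by_radial_density(self):
        """Cored is center-heavy, CAA center-empty, diffuse in between."""
        def center_density(classes):
            spec = [MorphologySpec(classes, 14.0, (64, 64))]
            tile, _, _ = ab.render_tile(spec, seed=3, tile_size=128)
            mask = HsvRange.for_stain("4G8").mask(tile.pixels)
            yy, xx = np.ogrid[:128, :128]
            inner = (xx - 64) ** 2 + (yy - 64) ** 2 <= 5 ** 2
            return mask[inner].mean()

        assert center_density(("cored",)) > 0.9
        assert center_density(("caa",)) < 0.1

    def test_colliding_placements_rejected(self):
        spec = [MorphologySpec(("cored",), 12.0, (60, 60)),
                MorphologySpec(("diffuse",), 12.0, (66, 66))]
        with pytest.raises(ValueError, match="density"):
            ab.render_tile(spec, seed=0, tile_size=128)


class TestCohort:
    def test_prevalence_counts_within_one(self, small_cohort):
        counts = {cls: int(small_cohort.truth.labels(cls).sum())
                  for cls in CLASSES}
        assert abs(counts["cored"] - 36) <= 1
        assert abs(counts["diffuse"] - 264) <= 1
        assert abs(counts["caa"] - 6) <= 1
        assert len(small_cohort) == 300

    def test_two_seeds_same_prevalence_different_pixels(self):
        a = ab.generate_cohort(60, seed=1)
        b = ab.generate_cohort(60, seed=2)
        for cls in CLASSES:
            assert a.truth.labels(cls).sum() == b.truth.labels(cls).sum()
        assert not (a.images == b.images).all()

    def test_truth_round_trips_through_csv(self, small_cohort, tmp_path):
        ab.write_label_table(small_cohort.truth, tmp_path / "t.csv")
        back = ab.read_label_table(tmp_path / "t.csv")
        assert (back.matrix() == small_cohort.truth.matrix()).all()
        assert back.image_ids() == small_cohort.truth.image_ids()

    def test_geometry_records_cover_cohort(self, small_cohort):
        assert len(small_cohort.records) == len(small_cohort)
        rec = small_cohort.records[0]
        assert {"image_id", "tile_id", "window", "boxes"} <= set(rec)


class TestSimulatedAnnotators:
    def test_perfect_annotator_reproduces_truth(self, small_cohort):
        profile = ab.AnnotatorProfile.uniform(1.0, 1.0, seed=0)
        out = ab.simulate_annotator(small_cohort.truth, profile)
        assert (out.matrix() == small_cohort.truth.matrix()).all()

    def test_sensitivity_binomial_bounds(self):
        n = 1000
        df = pd.DataFrame({"cored": 1, "diffuse": 0, "caa": 0},
                          index=pd.Index([f"i{k}" for k in range(n)],
                                         name="image_id"))
        truth = ab.LabelTable(df, source="truth")
        out = ab.simulate_annotator(
            truth, ab.AnnotatorProfile.uniform(0.8, 1.0, seed=1))
        observed = out.labels("cored").sum()
        assert abs(observed - 800) <= 38  # 3 sigma of Binomial(1000, 0.8)

    def test_coin_flip_annotator_has_chance_agreement(self):
        rng = np.random.default_rng(2)
        n = 10000
        df = pd.DataFrame({"cored": rng.integers(0, 2, n), "diffuse": 0, "caa": 0},
                          index=pd.Index([f"i{k}" for k in range(n)],
                                         name="image_id"))
        truth = ab.LabelTable(df, source="truth")
        out = ab.simulate_annotator(
            truth, ab.AnnotatorProfile.uniform(0.5, 0.5, seed=3))
        kappa = ab.cohens_kappa(truth.labels("cored"), out.labels("cored"))
        assert abs(kappa) < 0.05


def _balanced_accuracy(pred, truth):
    pred, truth = np.asarray(pred), np.asarray(truth)
    sens = pred[truth == 1].mean()
    spec = 1 - pred[truth == 0].mean()
    return (sens + spec) / 2


class TestConsensusRecovery:
    def _truth(self, n=5000, prev=0.12, seed=4):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({"cored": (rng.random(n) < prev).astype(int),
                           "diffuse": 1, "caa": 0},
                          index=pd.Index([f"i{k}" for k in range(n)],
                                         name="image_id"))
        return ab.LabelTable(df, source="truth")

    def test_consensus_of_two_beats_mean_individual(self):
        """Five 0.9/0.9 annotators on a 12%-prevalence class: the
        consensus-of-two table is closer to truth (balanced accuracy) than
        the average individual — the noise-cancellation the consensus
        strategy is built on."""
        truth = self._truth()
        tables = ab.simulate_cohort_annotations(truth, 5, 0.9, 0.9, seed=5)
        y = truth.labels("cored")
        individual = np.mean([
            _balanced_accuracy(t.labels("cored"), y) for t in tables
        ])
        c2 = ab.consensus_of_n(tables, 2)
        assert _balanced_accuracy(c2.labels("cored"), y) > individual
        # closed-form check: Binomial(5, .9) >= 2 vs Binomial(5, .1) >= 2
        from scipy.stats import binom
        sens_c2 = 1 - binom.cdf(1, 5, 0.9)
        spec_c2 = binom.cdf(1, 5, 0.1)
        assert (sens_c2 + spec_c2) / 2 > 0.9

    def test_monotone_degradation_with_sensitivity(self):
        truth = self._truth()
        high = ab.consensus_of_n(
            ab.simulate_cohort_annotations(truth, 5, 0.9, 0.9, seed=6), 2)
        low = ab.consensus_of_n(
            ab.simulate_cohort_annotations(truth, 5, 0.6, 0.9, seed=6), 2)
        for n in range(1, 6):
            hi = ab.consensus_of_n(
                ab.simulate_cohort_annotations(truth, 5, 0.9, 0.9, seed=6), n)
            lo = ab.consensus_of_n(
                ab.simulate_cohort_annotations(truth, 5, 0.6, 0.9, seed=6), n)
            assert lo.labels("cored").sum() < hi.labels("cored").sum()
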