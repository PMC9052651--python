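"""Phase-two set construction, neighbor expansion, prospective benchmarks."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

import abconsensus as ab
from abconsensus.data_model import CLASSES
from abconsensus.phase_two import protocol_demo_inputs


def _table(counts, n=5000, source="NP1", seed=0):
    """Label table with the requested disjoint per-class positive counts."""
    rng = np.random.default_rng(seed)
    ids = [f"i{k}" for k in range(n)]
    order = rng.permutation(ids)
    df = pd.DataFrame(0, index=pd.Index(ids, name="image_id"), columns=list(CLASSES))
    start = 0
    for cls in CLASSES:
        c = counts.get(cls, 0)
        df.loc[order[start : start + c], cls] = 1
        start += c
    return ab.LabelTable(df, source=source)


class TestSelfRepeat:
    def test_selection_order_and_triplication(self):
        table = _table({"caa": 50, "cored": 400, "diffuse": 3000})
        items = ab.build_self_repeat(table, seed=0)
        assert len(items) == 1800
        counts = Counter(img for img, _ in items)
        assert len(counts) == 600
        assert all(v == 3 for v in counts.values())
        chosen = set(counts)
        assert table.positives("caa") <= chosen  # every CAA positive included
        assert len(chosen & table.positives("cored")) == 350
        assert len(chosen & table.positives("diffuse")) == 200

    def test_shortfall_falls_back_to_diffuse(self):
        table = _table({"caa": 0, "cored": 100, "diffuse": 3000})
        items = ab.build_self_repeat(table, seed=1)
        counts = Counter(img for img, _ in items)
        assert len(counts) == 600
        assert len(set(counts) & table.positives("cored")) == 100
        assert len(set(counts) & table.positives("diffuse")) == 500

    def test_output_is_three_times_unique_even_when_scarce(self):
        table = _table({"caa": 5, "cored": 10, "diffuse": 20}, n=100)
        items = ab.build_self_repeat(table, seed=2)
        assert len(items) == 3 * len({img for img, _ in items}) == 3 * 35

    def test_rotations_are_quarter_turns(self):
        table = _table({"caa": 10, "cored": 400, "diffuse": 3000})
        items = ab.build_self_repeat(table, seed=3)
        assert {rot for _, rot in items} <= {0, 1, 2, 3}


class TestConsensusRepeat:
    def test_no_cross_class_overlap_gives_750(self):
        experts = [_table({"cored": 300, "diffuse": 300, "caa": 300},
                          source=f"NP{k}") for k in range(5)]
        items = ab.build_consensus_repeat(experts, seed=0)
        assert len(items) == 2250
        assert len({img for img, _ in items}) == 750

    def test_engineered_five_image_overlap_gives_745(self):
        demo = protocol_demo_inputs(seed=1)
        items = ab.build_consensus_repeat(demo["expert_tables"], seed=1)
        assert len({img for img, _ in items}) == 745
        assert len(items) == 2235

    def test_scarce_class_takes_all(self):
        experts = [_table({"cored": 40, "diffuse": 300, "caa": 0},
                          source=f"NP{k}") for k in range(5)]
        items = ab.build_consensus_repeat(experts, seed=2)
        assert len({img for img, _ in items}) == 40 + 250


class TestNeighborExpand:
    def _records(self):
        shared_box = ab.BoundingBox(40, 40, 56, 56)
        return {
            "a": {"tile_id": "t0", "window": ab.BoundingBox(0, 0, 64, 64),
                  "boxes": [shared_box]},
            "b": {"tile_id": "t0", "window": ab.BoundingBox(32, 32, 96, 96),
                  "boxes": [shared_box]},
            "c": {"tile_id": "t1", "window": ab.BoundingBox(0, 0, 64, 64),
                  "boxes": [ab.BoundingBox(10, 10, 26, 26)]},
            # box only 10% inside d's window -> below the 20% bar
            "d": {"tile_id": "t0", "window": ab.BoundingBox(54, 0, 118, 64),
                  "boxes": []},
        }

    def test_shared_plaque_makes_neighbors(self):
        assert ab.neighbor_expand(["a"], self._records()) == ["b"]

    def test_different_tiles_never_neighbors(self):
        assert "c" not in ab.neighbor_expand(["a"], self._records())

    def test_low_overlap_excluded(self):
        recs = self._records()
        # box (40,40,56,56): d's window starts at x=54 -> 2/16 of width inside
        assert "d" not in ab.neighbor_expand(["a"], recs)

    def test_missing_geometry_is_error(self):
        with pytest.raises(ValueError):
            ab.neighbor_expand(["zzz"], self._records())


class TestEnrichment:
    def test_cored_sampling_contract(self):
        rng = np.random.default_rng(0)
        n = 2000
        pool = [f"q{k}" for k in range(n)]
        scores = np.zeros((n, 3))
        scores[:900, 0] = rng.uniform(0.905, 1.0, 900)  # 900 qualifiers
        scores[:, 2] = rng.permutation(n) / n
        rule = ab.EnrichmentRule(self_final_size=3000)
        out = ab.build_enrichment(scores, pool, rule, seed=0, variant="self")
        qualifiers = set(pool[:900])
        sampled_cored = [i for i in out if i in qualifiers]
        # seed set had exactly 800 sampled qualifiers (some may also be CAA picks)
        assert len(set(out)) == len(out)  # no duplicates
        assert len(out) <= 3000

    def test_final_size_reached_with_ample_pool(self):
        demo = protocol_demo_inputs(seed=5)
        out = ab.build_enrichment(demo["pool_scores_self"], demo["pool_ids"],
                                  ab.EnrichmentRule(), seed=5, variant="self",
                                  records=demo["records"])
        assert len(out) == 3000
        out2 = ab.build_enrichment(demo["pool_scores_consensus"], demo["pool_ids"],
                                   ab.EnrichmentRule(), seed=5, variant="consensus",
                                   records=demo["records"])
        assert len(out2) == 3476

    def test_no_neighbors_adds_nothing(self):
        n = 100
        pool = [f"q{k}" for k in range(n)]
        scores = np.zeros((n, 3))
        scores[:, 2] = np.arange(n) / n
        records = {p: {"tile_id": f"t{k}", "window": ab.BoundingBox(0, 0, 64, 64),
                       "boxes": []} for k, p in enumerate(pool)}
        rule = ab.EnrichmentRule(cored_sample=10, caa_top=10)
        out = ab.build_enrichment(scores, pool, rule, seed=1, variant="self",
                                  records=records)
        assert len(out) == 10  # only the CAA top-10; no cored qualifiers, no neighbors


class TestAssignOverlap:
    def test_deterministic_per_image(self):
        assert ab.assign_overlap("img7", 3) == ab.assign_overlap("img7", 3)

    def test_fair_split(self):
        sides = [ab.assign_overlap(f"i{k}", 1) for k in range(10000)]
        frac = sides.count("self") / 10000
        assert frac == pytest.approx(0.5, abs=0.015)


class TestProtocolAssembly:
    def test_pool_must_be_disjoint_from_phase_one(self):
        demo = protocol_demo_inputs(seed=2)
        bad_pool = demo["pool_ids"][:-1] + [demo["annotations"].image_ids()[0]]
        with pytest.raises(ValueError, match="overlaps"):
            ab.build_phase_two_sets(
                demo["annotations"], demo["expert_tables"],
                demo["pool_scores_self"], demo["pool_scores_consensus"],
                bad_pool, demo["records"], seed=2,
            )

    def test_per_annotator_total(self):
        demo = protocol_demo_inputs(seed=4)
        sets = ab.build_phase_two_sets(
            demo["annotations"], demo["expert_tables"],
            demo["pool_scores_self"], demo["pool_scores_consensus"],
            demo["pool_ids"], demo["records"], seed=4,
        )
        assert (len(sets.self_repeat), len(sets.consensus_repeat),
                len(sets.self_enrichment), len(sets.consensus_enrichment)) == \
            (1800, 2235, 3000, 3476)
        assert sets.total == 10511
        # repeats come from phase-one, enrichment from the unseen pool
        phase_one = set(demo["annotations"].image_ids())
        assert {i for i, _ in sets.self_repeat} <= phase_one
        assert set(sets.self_enrichment).isdisjoint(phase_one)


class TestProspective:
    def test_consensus_model_wins_when_consensus_equals_truth(self):
        """Noise-cancellation: a model mimicking the (truth-equal) consensus
        outscores expert-mimicking models under the consensus benchmark."""
        rng = np.random.default_rng(6)
        n = 800
        ids = [f"i{k}" for k in range(n)]
        truth = np.zeros((n, 3), int)
        truth[:, 0] = rng.random(n) < 0.2
        truth[:, 1] = rng.random(n) < 0.7
        truth[:, 2] = rng.random(n) < 0.1
        def flip(y, p):
            f = rng.random(y.shape) < p
            return np.where(f, 1 - y, y)
        experts = []
        for k in range(5):
            df = pd.DataFrame(flip(truth, 0.12), columns=list(CLASSES),
                              index=pd.Index(ids, name="image_id"))
            experts.append(ab.LabelTable(df, source=f"NP{k + 1}"))
        scores = {}
        for t in experts:  # each individual model mimics its noisy expert
            scores[t.source] = np.clip(
                t.matrix() * 0.8 + 0.1 + rng.normal(0, 0.05, (n, 3)), 0, 1)
        scores["consensus-of-2"] = np.clip(
            truth * 0.8 + 0.1 + rng.normal(0, 0.05, (n, 3)), 0, 1)
        res = ab.prospective_evaluate(scores, experts, ids)
        cons = res["consensus_model"]["consensus_benchmark"]
        indiv_mean = np.mean([
            res["individual_models"][t.source]["consensus_benchmark"]["cored"]["auprc"]
            for t in experts
        ])
        assert cons["cored"]["auprc"] >= indiv_mean

    def test_replicate_sets_and_intra_rater(self):
        table = _table({"cored": 3, "diffuse": 3}, n=10)
        repeats = [(i, 0) for i in table.image_ids()[:4] for _ in range(3)]
        labels = {
            i: [dict(zip(CLASSES, table.frame.loc[i, list(CLASSES)]))] * 3
            for i in table.image_ids()[:4]
        }
        sets = ab.collect_replicate_sets(table, repeats, labels)
        acc = ab.intra_rater_accuracy(sets)
        assert all(v == 1.0 for v in acc.values())  # perfectly consistent rater
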