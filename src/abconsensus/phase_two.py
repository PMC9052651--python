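"""Prospective-validation protocol: repeat sets, enrichment, benchmarking.

Phase two presents each annotator with 10,511 images in four categories,
in a category order fixed and identical across annotators:

* ``self_repeat`` — 600 unique phase-one images chosen per annotator
  (all CAA positives, then random cored positives to 400, then random
  diffuse positives to 600), triplicated with random 90°-increment
  rotations and shuffled → 1800;
* ``consensus_repeat`` — 250 random consensus-of-two positives per class,
  deduplicated (745 unique in the study protocol), triplicated and
  shuffled → 2235, identical for all annotators;
* ``self_enrichment`` — 3000 unseen images enriched by the annotator's own
  model (800 random images with cored score > 0.90, the top 800 by CAA
  confidence, plus ≥20%-overlap neighbors);
* ``consensus_enrichment`` — 3476 unseen images enriched by the
  consensus-of-two model (750 random predicted-positives per minority
  class plus neighbors).

Enrichment draws only from the hold-out pool never annotated in phase one;
repeats draw only from phase-one images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import CLASSES, BoundingBox, LabelTable, logger, substream
from .labeling import consensus_of_n


@dataclass(frozen=True)
class EnrichmentRule:
    """Thresholds and sizes of the model-driven enrichment step."""

    cored_threshold: float = 0.90
    cored_sample: int = 800
    caa_top: int = 800
    consensus_per_class: int = 750
    positive_threshold: float = 0.5  # "predicted positive" for the consensus variant
    neighbor_overlap: float = 0.20
    self_final_size: int = 3000
    consensus_final_size: int = 3476


@dataclass
class PhaseTwoSets:
    """The four per-annotator image lists, in the fixed category order."""

    self_repeat: list
    consensus_repeat: list
    self_enrichment: list
    consensus_enrichment: list

    @property
    def total(self) -> int:
        return (len(self.self_repeat) + len(self.consensus_repeat)
                + len(self.self_enrichment) + len(self.consensus_enrichment))


def _triplicate_with_rotations(
    image_ids: list, rng: np.random.Generator
) -> list[tuple]:
    """Three copies of every image, each with a random quarter-turn rotation,
    shuffled."""
    items = [(img, int(rng.integers(0, 4))) for img in image_ids for _ in range(3)]
    rng.shuffle(items)
    return items


def build_self_repeat(annotations: LabelTable, seed: int) -> list[tuple]:
    """Per-annotator repeat set: CAA → cored (to 400) → diffuse (to 600).

    Selection is duplicate-free; shortfalls take whatever is available with
    a warning.  The 600 unique images are triplicated with random
    90°-increment rotations and shuffled, so the output is always three
    times the unique count (1800 under the study protocol).
    """
    rng = substream(seed, f"self-repeat-{annotations.source}")
    caa = sorted(annotations.positives("caa"))
    chosen = list(caa)
    chosen_set = set(chosen)

    cored_pool = sorted(annotations.positives("cored") - chosen_set)
    n_cored = max(0, 400 - len(chosen))
    if len(cored_pool) < n_cored:
        logger.warning(
            "self-repeat (%s): only %d cored positives available for %d slots",
            annotations.source, len(cored_pool), n_cored,
        )
        n_cored = len(cored_pool)
    picked = list(rng.choice(cored_pool, size=n_cored, replace=False)) if n_cored else []
    chosen += picked
    chosen_set.update(picked)

    diffuse_pool = sorted(annotations.positives("diffuse") - chosen_set)
    n_diffuse = max(0, 600 - len(chosen))
    if len(diffuse_pool) < n_diffuse:
        logger.warning(
            "self-repeat (%s): only %d diffuse positives available for %d slots",
            annotations.source, len(diffuse_pool), n_diffuse,
        )
        n_diffuse = len(diffuse_pool)
    chosen += list(rng.choice(diffuse_pool, size=n_diffuse, replace=False)) if n_diffuse else []
    return _triplicate_with_rotations(chosen, rng)


def build_consensus_repeat(expert_tables: list[LabelTable], seed: int) -> list[tuple]:
    """Shared repeat set: 250 consensus-of-two positives per class, deduped,
    triplicated and shuffled (745 unique → 2235 under the study protocol)."""
    rng = substream(seed, "consensus-repeat")
    c2 = consensus_of_n(expert_tables, 2)
    selected: list = []
    seen = set()
    for cls in CLASSES:
        pool = sorted(c2.positives(cls))
        take = min(250, len(pool))
        if take < 250:
            logger.warning(
                "consensus-repeat: only %d consensus-of-two %s positives", len(pool), cls
            )
        for img in rng.choice(pool, size=take, replace=False):
            if img not in seen:  # dedupe across classes
                seen.add(img)
                selected.append(img)
    return _triplicate_with_rotations(selected, rng)


# ---------------------------------------------------------------------------
# neighbors and enrichment
# ---------------------------------------------------------------------------


def _box_fraction_in(box: BoundingBox, window: BoundingBox) -> float:
    return box.intersection_area(window) / box.area


def neighbor_expand(
    selected: list,
    records: dict,
    overlap_min: float = 0.20,
) -> list:
    """Pool images sharing a plaque box with any selected image.

    ``records`` maps image_id → dict with keys ``tile_id``, ``window``
    (BoundingBox of the crop) and ``boxes`` (plaque BoundingBoxes in tile
    coordinates).  A pool image is a neighbor iff some plaque box has at
    least ``overlap_min`` of its area inside BOTH the selected image's crop
    window and the pool image's crop window.  Images from different tiles
    are never neighbors.
    """
    for img in selected:
        if img not in records:
            raise ValueError(f"missing geometry metadata for {img!r}")
    by_tile: dict = {}
    for img, rec in records.items():
        if not {"tile_id", "window", "boxes"} <= set(rec):
            raise ValueError(f"incomplete geometry metadata for {img!r}")
        by_tile.setdefault(rec["tile_id"], []).append(img)
    selected_set = set(selected)
    neighbors: list = []
    neighbor_set: set = set()
    for img in sorted(selected_set):
        rec = records[img]
        for other in by_tile.get(rec["tile_id"], []):
            if other in selected_set or other in neighbor_set:
                continue
            orec = records[other]
            for box in {id(b): b for b in rec["boxes"] + orec["boxes"]}.values():
                if (
                    _box_fraction_in(box, rec["window"]) >= overlap_min
                    and _box_fraction_in(box, orec["window"]) >= overlap_min
                ):
                    neighbors.append(other)
                    neighbor_set.add(other)
                    break
    return neighbors


def build_enrichment(
    scores: np.ndarray,
    pool_ids: list,
    rule: EnrichmentRule,
    seed: int,
    variant: str = "self",
    records: dict | None = None,
) -> list:
    """Model-driven enrichment of the unseen hold-out pool.

    ``scores`` are the enrichment model's sigmoid class scores over
    ``pool_ids`` (the fold-three model in the full pipeline; any
    scorer's output works).  Self variant: a random ``cored_sample`` of the
    images with cored score above ``cored_threshold`` plus the ``caa_top``
    highest-CAA-confidence images, neighbor-expanded, shuffled and truncated
    to ``self_final_size``.  Consensus variant: ``consensus_per_class``
    random predicted-positives per minority class, topped up with random
    neighbors to ``consensus_final_size``.
    """
    rng = substream(seed, f"enrichment-{variant}")
    scores = np.asarray(scores, dtype=float)
    pool = np.asarray(pool_ids)
    cored_scores = scores[:, CLASSES.index("cored")]
    caa_scores = scores[:, CLASSES.index("caa")]

    if variant == "self":
        qualifiers = pool[cored_scores > rule.cored_threshold]
        take = min(rule.cored_sample, len(qualifiers))
        if take < rule.cored_sample:
            logger.warning("self-enrichment: only %d cored qualifiers above %.2f",
                           len(qualifiers), rule.cored_threshold)
        cored_sel = list(rng.choice(qualifiers, size=take, replace=False)) if take else []
        order = np.argsort(-caa_scores, kind="stable")
        caa_sel = list(pool[order[: rule.caa_top]])
        seed_set = list(dict.fromkeys(cored_sel + caa_sel))
        expanded = seed_set + (neighbor_expand(seed_set, records, rule.neighbor_overlap)
                               if records else [])
        rng.shuffle(expanded)
        return expanded[: rule.self_final_size]

    if variant == "consensus":
        seed_set: list = []
        seen = set()
        for cls in ("cored", "caa"):
            col = scores[:, CLASSES.index(cls)]
            positives = pool[col > rule.positive_threshold]
            positives = np.array([p for p in positives if p not in seen])
            take = min(rule.consensus_per_class, len(positives))
            if take < rule.consensus_per_class:
                logger.warning("consensus-enrichment: only %d predicted %s positives",
                               len(positives), cls)
            picked = list(rng.choice(positives, size=take, replace=False)) if take else []
            seen.update(picked)
            seed_set += picked
        neighbors = (neighbor_expand(seed_set, records, rule.neighbor_overlap)
                     if records else [])
        rng.shuffle(neighbors)
        need = rule.consensus_final_size - len(seed_set)
        out = seed_set + neighbors[:max(0, need)]
        if len(out) < rule.consensus_final_size:
            logger.warning("consensus-enrichment: %d of %d images available",
                           len(out), rule.consensus_final_size)
        rng.shuffle(out)
        return out

    raise ValueError(f"unknown enrichment variant {variant!r}")


def assign_overlap(image_id: str, seed: int) -> str:
    """Fair coin assignment of a doubly-qualifying image to self/consensus.

    Per-image seeded stream: the assignment depends only on (seed,
    image_id), never on evaluation order.
    """
    rng = substream(seed, f"overlap-{image_id}")
    return "self" if rng.random() < 0.5 else "consensus"


def build_phase_two_sets(
    annotations: LabelTable,
    expert_tables: list[LabelTable],
    pool_scores_self: np.ndarray,
    pool_scores_consensus: np.ndarray,
    pool_ids: list,
    records: dict | None,
    seed: int,
    rule: EnrichmentRule = EnrichmentRule(),
) -> PhaseTwoSets:
    """Assemble the four per-annotator categories (fixed order)."""
    phase_one_ids = set(annotations.image_ids())
    overlap = set(pool_ids) & phase_one_ids
    if overlap:
        raise ValueError(
            f"enrichment pool overlaps phase-one images ({len(overlap)} shared)"
        )
    return PhaseTwoSets(
        self_repeat=build_self_repeat(annotations, seed),
        consensus_repeat=build_consensus_repeat(expert_tables, seed),
        self_enrichment=build_enrichment(
            pool_scores_self, pool_ids, rule, seed, "self", records
        ),
        consensus_enrichment=build_enrichment(
            pool_scores_consensus, pool_ids, rule, seed, "consensus", records
        ),
    )


def protocol_demo_inputs(seed: int = 0) -> dict:
    """Synthetic fixture sized to the printed phase-two protocol.

    Builds one annotator's phase-one label table (50 CAA, 400 cored and
    3000 diffuse positives over 6000 images), five expert tables whose
    consensus-of-two positives are exactly 250 per class with five images
    shared between the cored and CAA pools (so deduplication yields 745
    unique repeats), and a 12,000-image unseen pool with synthetic model
    scores and 4-crops-per-tile neighbor geometry.  Feeding these into
    :func:`build_phase_two_sets` demonstrates the protocol arithmetic:
    1800 + 2235 + 3000 + 3476 = 10,511 images per annotator.
    """
    import pandas as pd

    rng = substream(seed, "protocol-demo")
    n_phase_one = 6000
    ids = [f"p{k:05d}" for k in range(n_phase_one)]

    def table(positives: dict, source: str) -> LabelTable:
        df = pd.DataFrame(0, index=pd.Index(ids, name="image_id"),
                          columns=list(CLASSES))
        for cls, members in positives.items():
            df.loc[list(members), cls] = 1
        return LabelTable(df, source=source)

    order = list(rng.permutation(ids))
    annotator = table(
        {"caa": order[:50], "cored": order[50:450], "diffuse": order[450:3450]},
        source="NP1",
    )
    cored_pool = order[3450:3700]                     # 250
    caa_pool = cored_pool[:5] + order[3700:3945]      # 5 shared + 245
    diffuse_pool = order[3945:4195]                   # 250
    experts = [
        table({"cored": cored_pool, "caa": caa_pool, "diffuse": diffuse_pool},
              source=f"NP{k + 1}")
        for k in range(5)
    ]

    n_pool = 12000
    pool_ids = [f"q{k:05d}" for k in range(n_pool)]
    records = {}
    offsets = ((0, 0), (32, 0), (0, 32), (32, 32))
    for k, img in enumerate(pool_ids):
        tile = k // 4
        ox, oy = offsets[k % 4]
        records[img] = {
            "tile_id": f"pt{tile}",
            "window": BoundingBox(ox, oy, ox + 64, oy + 64),
            # central plaque shared by all four windows of the tile
            "boxes": [BoundingBox(40, 40, 56, 56)],
        }

    # self-model scores: ~1000 confident cored predictions, continuous CAA
    scores_self = np.zeros((n_pool, len(CLASSES)))
    hot = rng.choice(n_pool, size=1000, replace=False)
    scores_self[:, 0] = rng.uniform(0.0, 0.9, n_pool)
    scores_self[hot, 0] = rng.uniform(0.905, 1.0, 1000)
    scores_self[:, 1] = rng.uniform(0.0, 1.0, n_pool)
    scores_self[:, 2] = rng.permutation(n_pool) / n_pool

    # consensus-model scores: disjoint confident cored/CAA positive sets
    scores_cons = np.full((n_pool, len(CLASSES)), 0.1)
    perm = rng.permutation(n_pool)
    scores_cons[perm[:800], 0] = rng.uniform(0.55, 1.0, 800)
    scores_cons[perm[800:1600], 2] = rng.uniform(0.55, 1.0, 800)
    scores_cons[:, 1] = rng.uniform(0.0, 1.0, n_pool)

    return {
        "annotations": annotator,
        "expert_tables": experts,
        "pool_scores_self": scores_self,
        "pool_scores_consensus": scores_cons,
        "pool_ids": pool_ids,
        "records": records,
    }


# ---------------------------------------------------------------------------
# prospective benchmarking
# ---------------------------------------------------------------------------


def prospective_evaluate(
    model_scores: dict,
    expert_tables: list[LabelTable],
    image_ids: list,
) -> dict:
    """Evaluate phase-two predictions under individual and consensus-of-two
    benchmarks.

    ``model_scores`` maps a model source (expert annotator id or
    "consensus-of-2") to its (N, 3) sigmoid scores over ``image_ids``.
    Individual-expert models are paired with their own annotator under the
    individual benchmark and averaged over the five experts; the consensus
    model on the consensus benchmark is a single value with no variation by
    definition.  Missing annotators drop their benchmark with a warning.
    """
    from .evaluation import UndefinedMetricError, auprc, auroc

    experts = {t.source: t for t in expert_tables}
    c2 = consensus_of_n(expert_tables, 2)

    def metrics(scores, table):
        y = table.aligned_to(image_ids).matrix()
        out = {}
        for k, cls in enumerate(CLASSES):
            try:
                out[cls] = {"auprc": auprc(y[:, k], scores[:, k]),
                            "auroc": auroc(y[:, k], scores[:, k])}
            except UndefinedMetricError:
                out[cls] = {"auprc": np.nan, "auroc": np.nan}
        return out

    results: dict = {"individual_models": {}, "consensus_model": {}}
    indiv = {src: s for src, s in model_scores.items() if src in experts}
    for src, scores in indiv.items():
        results["individual_models"][src] = {
            "individual_benchmark": metrics(scores, experts[src]),
            "consensus_benchmark": metrics(scores, c2),
        }
    missing = [src for src in model_scores if src not in experts and src != "consensus-of-2"]
    for src in missing:
        logger.warning("no phase-two annotations for %s; dropping benchmark", src)
    if "consensus-of-2" in model_scores:
        scores = model_scores["consensus-of-2"]
        results["consensus_model"] = {
            "individual_benchmark": {
                src: metrics(scores, table) for src, table in experts.items()
            },
            "consensus_benchmark": metrics(scores, c2),  # single value, no variance
        }
    return results


def collect_replicate_sets(
    phase_one: LabelTable,
    phase_two_repeats: list[tuple],
    phase_two_labels: dict,
) -> list[dict]:
    """Assemble 4-label replicate sets (1 phase-one + 3 phase-two) per image.

    ``phase_two_repeats`` is a triplicated repeat list (image_id, rotation);
    ``phase_two_labels`` maps image_id → list of three {class: 0/1} dicts in
    presentation order.
    """
    per_image: dict = {}
    for img, _ in phase_two_repeats:
        per_image[img] = per_image.get(img, 0) + 1
    out = []
    for img, count in per_image.items():
        if count != 3 or img not in phase_two_labels or len(phase_two_labels[img]) != 3:
            raise ValueError(f"replicate set for {img!r} does not have 3 phase-two labels")
        row = phase_one.frame.loc[img]
        rset = {}
        for cls in CLASSES:
            rset[cls] = [int(row[cls])] + [int(d[cls]) for d in phase_two_labels[img]]
        out.append(rset)
    return out
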