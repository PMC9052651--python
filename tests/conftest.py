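"""Shared fixtures: one small synthetic cohort and one overfit tiny model."""

import numpy as np
import pytest

import abconsensus as ab
from abconsensus.cnn import ArchitectureSpec, TrainingRun, train_model


@pytest.fixture(scope="session")
def small_cohort():
    """300 tiny crops at the default 12/88/2 prevalence."""
    return ab.generate_cohort(300, seed=7)


@pytest.fixture(scope="session")
def expert_tables(small_cohort):
    """Five simulated experts at sensitivity = specificity = 0.9."""
    return ab.simulate_cohort_annotations(small_cohort.truth, 5, 0.9, 0.9, seed=7)


@pytest.fixture(scope="session")
def overfit_bundle():
    """A tiny CNN memorizing a 16-crop cohort with all classes present.

    Used for checkpointing, separability and saliency tests; validation is
    the training set itself, so the best checkpoint is the best memorizer.
    """
    cohort = ab.generate_cohort(
        16, prevalence={"cored": 0.25, "diffuse": 0.75, "caa": 0.25}, seed=11
    )
    run = TrainingRun(annotation_source="truth", epochs=60, batch_size=8, seed=3,
                      augment_spec=ab.AugmentSpec.identity())
    bundle = train_model(
        cohort.images, cohort.image_ids, cohort.images[:0], [],
        cohort.truth, run, arch=ArchitectureSpec.tiny(64),
    )
    return bundle, cohort
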