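"""Shared fixtures.

The expensive benchmark fixtures (rendered feature tables, the control screen)
are session-scoped and shared between the unit suite and the acceptance
criteria so each is computed once per run.
"""

from __future__ import annotations

import pandas as pd
import pytest

from morphoscreen.boosting import TrainingSet, train_gentle_boost
from morphoscreen.features import measure_objects
from morphoscreen.fixtures import (
    delamination_training_from_well,
    labeled_feature_frame,
)
from morphoscreen.phantoms import (
    DoseGroup,
    SceneConfig,
    generate_well,
    rng_for,
)
from morphoscreen.segmentation import assign_microwells, segment_montage

BENCHMARK_SEED = 42


@pytest.fixture(scope="session")
def scene() -> SceneConfig:
    return SceneConfig()


@pytest.fixture(scope="session")
def phenotype_benchmark(scene):
    """30 exemplars/class training table and a 500-object held-out table,
    rendered at the default class separation and SNR."""
    train = labeled_feature_frame(30, scene, rng_for(BENCHMARK_SEED, "train"))
    test = labeled_feature_frame(100, scene, rng_for(BENCHMARK_SEED, "test"))
    return train, test


@pytest.fixture(scope="session")
def phenotype_model(phenotype_benchmark):
    train, _ = phenotype_benchmark
    return train_gentle_boost(TrainingSet.from_dataframe(train), n_rounds=50)


@pytest.fixture(scope="session")
def delamination_model(scene):
    """Binary delaminated/attached model trained on 30 exemplars per class
    curated from a rendered training well (same measurement path as the
    screen)."""
    train = delamination_training_from_well(
        scene, rng_for(BENCHMARK_SEED, "btrain"), n_per_class=30)
    return train_gentle_boost(TrainingSet.from_dataframe(train), n_rounds=50)


@pytest.fixture(scope="session")
def control_screen(scene):
    """Three replicate control wells of 165 structures at the published
    control composition (72% XEn/EpiC) and delaminated fraction (16%),
    segmented and measured end to end.

    Exact-count composition isolates pipeline error from sampling noise.
    Returns (features_df with well_id, truth_df).
    """
    dg = DoseGroup(dose=0.0, delaminated_fraction=0.16, mixture_mode="exact")
    feats_all, truth_all = [], []
    for rep in range(1, 4):
        wid = f"control_r{rep}"
        montage, truth = generate_well(dg, scene, rng_for(BENCHMARK_SEED, wid),
                                       well_id=wid)
        seg = assign_microwells(
            segment_montage(montage, pixel_size=scene.pixel_size), scene)
        feats, _ = measure_objects(seg, montage, scene.pixel_size,
                                   compartments=False)
        feats.insert(0, "well_id", wid)
        feats_all.append(feats)
        truth_all.append(truth)
    return (pd.concat(feats_all, ignore_index=True),
            pd.concat(truth_all, ignore_index=True))
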