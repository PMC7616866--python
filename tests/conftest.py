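"""Shared fixtures.

The two expensive session fixtures — a trainable mid-size cohort and a full
desk-scale derivation run — are built once and shared by every test that
needs a trained network, so the suite stays within a small CPU budget.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from ecgpheno.pipeline import PipelineConfig, run_derivation, stage_seed
from ecgpheno.preprocess import ECGPreprocessor
from ecgpheno.synthetic import (CohortConfig, STRONG_GROUP_MORPHOLOGY,
                                simulate_cohort)


@pytest.fixture(scope="session")
def train_cohort():
    """Mid-size cohort plus preprocessed tensors for training tests."""
    cohort = simulate_cohort(CohortConfig(n=1200, seed=3))
    X = ECGPreprocessor().transform(cohort.records)
    y = cohort.labels.drop(columns="subject_id").to_numpy()
    return cohort, X, y


@pytest.fixture(scope="session")
def derivation(tmp_path_factory):
    """Desk-scale derivation run under strong group-morphology contrasts.

    Returns the pipeline config, its manifest, the output directory, the
    regenerated cohort (bit-identical to the one the run used) and the
    preprocessed signal tensor.
    """
    out = tmp_path_factory.mktemp("derivation")
    cfg = PipelineConfig(
        cohort=CohortConfig(n=3000,
                            group_morphology=dict(STRONG_GROUP_MORPHOLOGY)),
        out_dir=str(out), seed=1)
    manifest = run_derivation(cfg)
    cohort = simulate_cohort(dataclasses.replace(
        cfg.cohort, seed=stage_seed(cfg.seed, "simulate")))
    X = ECGPreprocessor().transform(cohort.records)
    return {"config": cfg, "manifest": manifest, "out": out,
            "cohort": cohort, "X": X,
            "E": np.load(out / "embeddings.npy")}
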