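"""Shared fixtures: synthetic cohorts and the cross-validated training runs.

The weakly supervised cross-validation (5 folds, 40 patients, 30 patches
of 64 x 64 each, 10 epochs per fold) is expensive, so it runs once per
session and is shared by the end-to-end and risk-map tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import wsisurv as w
from wsisurv.tiling import enumerate_rois, extract_patch, sample_rois, tissue_mask
from wsisurv.training import PatientPatches


def build_patch_datasets(beta_true: float, cohort_seed: int, n_patients: int = 40,
                         n_patches: int = 30, size: int = 64):
    """Synthetic cohort -> per-patient patch datasets plus ground truth."""
    params = w.SynthParams(n_patients=n_patients, slide_size=256, beta_true=beta_true,
                           censor_rate=0.3, seed=cohort_seed)
    slides, cohort, truth = w.generate_cohort(params)
    ds = {}
    for i, p in enumerate(cohort.patients):
        slide = slides[p.slide_ids[0]]
        mask = tissue_mask(slide.image.mean(axis=2))
        coords = enumerate_rois(mask, size=size, stride=size // 2)
        chosen = sample_rois(coords, n_patches, seed=100 + i)
        patches = np.stack([extract_patch(slide.image, x, y, size) for x, y in chosen])
        ds[p.patient_id] = PatientPatches(patches, p.time_months, p.event)
    return ds, cohort, slides, truth


def run_cross_validation(ds: dict, cohort, train_seed: int = 0, epochs: int = 10):
    """Train one model per fold; pool each fold's test-patient median risks."""
    plan = w.make_split_plan(cohort, k=5, seed=0)
    pooled, models = {}, []
    for fold in plan.folds:
        model = w.init_weights(w.RiskModel(input_size=64), seed=train_seed)
        model, history = w.train(
            model,
            {p: ds[p] for p in fold.train_ids},
            w.TrainConfig(epochs=epochs, batch_size=16, seed=train_seed),
            val_dataset={p: ds[p] for p in fold.val_ids},
        )
        models.append((model, history))
        for pid in fold.test_ids:
            x = w.normalize(ds[pid].patches).transpose(0, 3, 1, 2)
            pooled[pid] = float(np.median(model.forward(x)))
    pids = sorted(pooled)
    c = w.concordance_index(
        np.array([pooled[p] for p in pids]),
        np.array([ds[p].time_months for p in pids]),
        np.array([ds[p].event for p in pids]),
    )
    return c, pooled, models


@pytest.fixture(scope="session")
def signal_cv():
    """Cross-validated weakly supervised run on a prognostic cohort (beta=1.5)."""
    ds, cohort, slides, truth = build_patch_datasets(beta_true=1.5, cohort_seed=0)
    c, pooled, models = run_cross_validation(ds, cohort, train_seed=0)
    return {"c_index": c, "pooled": pooled, "models": models,
            "dataset": ds, "cohort": cohort, "slides": slides, "truth": truth}


@pytest.fixture(scope="session")
def null_cv():
    """Same protocol on a no-signal cohort (beta=0): the negative control."""
    ds, cohort, _, _ = build_patch_datasets(beta_true=0.0, cohort_seed=1)
    c, pooled, _ = run_cross_validation(ds, cohort, train_seed=0)
    return {"c_index": c, "pooled": pooled}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
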