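"""Shared fixtures.

The expensive end-to-end bundle (full-size corpora and tuned tree models for
all three dosage forms) is built once per session and shared by the
acceptance tests; unit tests use small canvases throughout.
"""

from __future__ import annotations

import numpy as np
import pytest

from printqc.metrics import evaluate
from printqc.models import ModelSpec, train
from printqc.preprocess import PreprocessConfig, build_features
from printqc.render import (
    FormGeometry,
    OODSpec,
    RenderSpec,
    generate_ood_set,
    generate_pseudo_real_set,
    generate_training_set,
)
from printqc.stress import ood_kinds_for

FORMS = ("capsule", "tablet", "film")
E2E_SIZE = 125  # image size for the end-to-end experiment, grayscale


@pytest.fixture(scope="session")
def small_tablet_geom():
    return FormGeometry.default("tablet", canvas_px=256)


@pytest.fixture(scope="session")
def small_good_spec(small_tablet_geom):
    return RenderSpec(geometry=small_tablet_geom, quality="good", defect="none", seed=7)


@pytest.fixture(scope="session")
def e2e_bundle():
    """Full-scale experiment: per form, 200 virtual train / 200 pseudo-real
    test images, tuned DT and RF at size 125 grayscale, their test reports,
    and feature matrices for 200 OOD images of each of the four kinds.

    Raw OOD pixel corpora are converted to feature matrices immediately and
    only one pseudo-real corpus is retained in memory; the bundle otherwise
    grows past the session's memory comfort zone.
    """
    cfg = PreprocessConfig(target_size_px=E2E_SIZE, color_space="gray")
    bundle = {}
    for form in FORMS:
        train_set = generate_training_set(form, 100, 100, seed=1)
        test_set = generate_pseudo_real_set(form, 200, seed=2)
        train_fm = build_features(train_set, cfg)
        test_fm = build_features(test_set, cfg)
        models = {
            tech: train(ModelSpec(technique=tech, seed=0), train_fm)
            for tech in ("DT", "RF")
        }
        reports = {tech: evaluate(model, test_fm) for tech, model in models.items()}
        ood_fms = {}
        for ki, kind in enumerate(ood_kinds_for(form)):
            ood_set = generate_ood_set(
                OODSpec(kind=kind, n=200, canvas_px=512, seed=100 + ki)
            )
            ood_fms[kind] = build_features(ood_set, cfg)
        bundle[form] = {
            "train_set": train_set,
            "test_set": test_set if form == "tablet" else None,
            "train_fm": train_fm,
            "test_fm": test_fm,
            "models": models,
            "reports": reports,
            "ood_fms": ood_fms,
            "config": cfg,
        }
    return bundle


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
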