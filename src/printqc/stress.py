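"""Robustness program: scalability, confidence profiling and OOD testing.

Three stress tests probe a trained quality-control model beyond its plain
test accuracy:

* *scalability* — the test set is expanded 16-fold by crop/orientation
  augmentation (the training set is only grayscale-transformed, never
  augmented) and the tree-based learners are re-evaluated at every image
  size;
* *confidence* — the most-confident statistic is histogrammed over
  [0.5, 1.0] in 0.05-wide bins and paired with the Brier score;
* *out-of-distribution* — tuned and untuned models are fed images that
  depict no dosage form (background, noise, a generic shape and the shape
  that most resembles the form's own geometry) and scored by the fraction
  they classify 'bad'.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from printqc.metrics import MetricsReport, ProbPredictions, brier, most_confident, evaluate
from printqc.models import ExceededLimits, FittedModel, ModelSpec, TrainBudget, train
from printqc.preprocess import (
    DEFAULT_CROP_FRACTIONS,
    PreprocessConfig,
    augment_test_set,
    build_features,
    to_grayscale,
)
from printqc.render import Dataset, OODSpec, generate_ood_set

#: the OOD shape that most resembles each form's own silhouette
MATCHED_SHAPE = {"capsule": "oblong", "tablet": "circle", "film": "diamond"}

CONFIDENCE_BIN_WIDTH = 0.05


def ood_kinds_for(form: str) -> tuple[str, str, str, str]:
    """The four OOD kinds evaluated per form: background, noise, a generic
    shape (triangle) and the geometry-matched shape."""
    return ("background", "noise", "triangle", MATCHED_SHAPE[form])


@dataclass(frozen=True)
class StressConfig:
    techniques: tuple[str, ...] = ("DT", "RF")
    sizes: tuple[int, ...] = (25, 50, 125, 256, 512)
    crop_fractions: tuple[float, ...] = DEFAULT_CROP_FRACTIONS
    n_ood_per_kind: int = 200
    ood_canvas_px: int = 512
    seed: int = 0
    budget: TrainBudget | None = None

    def __post_init__(self) -> None:
        if not self.techniques:
            raise ValueError("at least one technique is required")
        if len(self.crop_fractions) != 4:
            raise ValueError("exactly 4 crop fractions are required")


@dataclass
class ConfidenceReport:
    """Histogram of most-confident values plus the Brier score."""

    bin_edges: np.ndarray  # 11 edges spanning [0.5, 1.0]
    counts: np.ndarray  # 10 bin counts
    brier: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count": self.counts,
            }
        )


def confidence_report(p: ProbPredictions) -> ConfidenceReport:
    """Histogram the most-confident statistic over [0.5, 1.0], bins of 0.05."""
    values = most_confident(p)
    edges = np.round(np.arange(0.5, 1.0 + CONFIDENCE_BIN_WIDTH / 2, CONFIDENCE_BIN_WIDTH), 10)
    counts, _ = np.histogram(values, bins=edges)
    # np.histogram's last bin is closed on the right, so 1.0 lands in it
    return ConfidenceReport(bin_edges=edges, counts=counts, brier=brier(p))


def run_scalability(
    config: StressConfig,
    train_set: Dataset,
    test_set: Dataset,
) -> dict[tuple[str, int], MetricsReport | ExceededLimits]:
    """Train on grayscale virtual images, evaluate on the 16x-augmented test.

    The training set is only grayscale-transformed (it stays at its original
    count); the test set grows 16-fold via 4 crops x 4 orientations. One
    MetricsReport per (technique, size).
    """
    if len(test_set) < 2 or len(set(test_set.labels())) < 2:
        raise ValueError("test set needs >= 2 images covering both classes")
    gray_test = Dataset(
        items=[to_grayscale(im) for im in test_set],
        metadata=dict(test_set.metadata),
    )
    augmented = augment_test_set(gray_test, config.crop_fractions)
    results: dict[tuple[str, int], MetricsReport | ExceededLimits] = {}
    for size in config.sizes:
        cfg = PreprocessConfig(target_size_px=size, color_space="gray")
        train_fm = build_features(train_set, cfg)
        test_fm = build_features(augmented, cfg)
        for tech in config.techniques:
            spec = ModelSpec(technique=tech, seed=config.seed, tuned=True)
            fitted = train(spec, train_fm, budget=config.budget)
            if isinstance(fitted, ExceededLimits):
                results[(tech, size)] = fitted
            else:
                results[(tech, size)] = evaluate(fitted, test_fm)
    return results


def ood_accuracy(model: FittedModel, ood_set: Dataset, config: PreprocessConfig) -> float:
    """Fraction of OOD images the model classifies 'bad'.

    OOD images flow through the identical preprocessing path as any test
    image; a dimension mismatch here is a bug, not a catchable condition.
    """
    fm = build_features(ood_set, config)
    labels = model.predict_label(fm)
    return float(np.mean(labels == "bad"))


def run_ood(
    config: StressConfig,
    models_per_form: dict[str, dict[tuple[str, bool, int], FittedModel]],
) -> pd.DataFrame:
    """Evaluate every supplied (technique, tuned, size) model on the four
    OOD kinds for its form.

    ``models_per_form`` maps form -> {(technique, tuned, size): model}. The
    result is a tidy frame with one row per (form, technique, tuned, kind,
    size) and the fraction classified 'bad' as ``ood_accuracy``.
    """
    rows = []
    for form, models in models_per_form.items():
        for kind_idx, kind in enumerate(ood_kinds_for(form)):
            ood = generate_ood_set(
                OODSpec(
                    kind=kind,
                    n=config.n_ood_per_kind,
                    canvas_px=config.ood_canvas_px,
                    seed=config.seed * 1000 + kind_idx,
                )
            )
            for (tech, tuned, size), model in models.items():
                if model is None:
                    raise ValueError(f"missing model variant ({tech}, tuned={tuned}, {size})")
                cfg = PreprocessConfig(target_size_px=size, color_space="gray")
                rows.append(
                    {
                        "form": form,
                        "technique": tech,
                        "tuned": tuned,
                        "kind": kind,
                        "size": size,
                        "n": config.n_ood_per_kind,
                        "ood_accuracy": ood_accuracy(model, ood, cfg),
                    }
                )
    return pd.DataFrame(rows)
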