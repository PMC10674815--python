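"""End-to-end experiment orchestration.

The main experiment trains every configured technique on the virtual corpus
of each dosage form and evaluates it on the pseudo-real corpus, for every
image size and color space — one MetricsReport per (form, size, color_space,
technique) cell. Cells whose fit exhausts its resource budget are recorded
as "exceeded limits" rather than aborting the sweep; other failures are
isolated per cell and the run continues.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from printqc import __version__
from printqc.metrics import evaluate
from printqc.models import ExceededLimits, ModelSpec, TrainBudget, train
from printqc.preprocess import PreprocessConfig, build_features
from printqc.render import generate_pseudo_real_set, generate_training_set

log = logging.getLogger("printqc")

DEFAULT_SIZES = (25, 50, 125, 256, 512)
DEFAULT_TECHNIQUES = ("LR", "DT", "RF", "GB", "MLP", "SVM", "kNN")


@dataclass(frozen=True)
class ExperimentConfig:
    forms: tuple[str, ...] = ("capsule", "tablet", "film")
    sizes: tuple[int, ...] = DEFAULT_SIZES
    color_spaces: tuple[str, ...] = ("rgb", "gray")
    techniques: tuple[str, ...] = DEFAULT_TECHNIQUES
    n_train_good: int = 100
    n_train_bad: int = 100
    n_test: int = 200
    train_canvas_px: int = 512
    test_canvas_px: int = 1024
    seed: int = 0
    wall_time_s_per_fit: float | None = None
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if not (self.forms and self.sizes and self.techniques):
            raise ValueError("forms, sizes and techniques must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("forms", "sizes", "color_spaces", "techniques"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def provenance(self) -> dict:
        return {
            "version": __version__,
            "seed": self.seed,
            "forms": list(self.forms),
            "sizes": list(self.sizes),
            "color_spaces": list(self.color_spaces),
            "techniques": list(self.techniques),
            "counts": {
                "train_good": self.n_train_good,
                "train_bad": self.n_train_bad,
                "test": self.n_test,
            },
        }


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Run the full (form x size x color-space x technique) sweep.

    Returns a tidy frame with one row per cell: metrics, best params, or the
    'exceeded limits' / error status for cells that did not produce one.
    """
    budget = (
        TrainBudget(wall_time_s=config.wall_time_s_per_fit)
        if config.wall_time_s_per_fit
        else None
    )
    rows = []
    for form in config.forms:
        log.info("generating corpora for %s (seed=%d)", form, config.seed)
        train_set = generate_training_set(
            form, config.n_train_good, config.n_train_bad, config.seed, config.train_canvas_px
        )
        test_set = generate_pseudo_real_set(
            form, config.n_test, config.seed + 1, config.test_canvas_px
        )
        for size in config.sizes:
            for space in config.color_spaces:
                cfg = PreprocessConfig(target_size_px=size, color_space=space)
                train_fm = build_features(train_set, cfg)
                test_fm = build_features(test_set, cfg)
                for tech in config.techniques:
                    row = {"form": form, "size": size, "color_space": space, "technique": tech}
                    try:
                        fitted = train(
                            ModelSpec(technique=tech, seed=config.seed), train_fm, budget=budget
                        )
                        if isinstance(fitted, ExceededLimits):
                            row.update(status="exceeded_limits", detail=fitted.reason)
                        else:
                            report = evaluate(fitted, test_fm)
                            row.update(
                                status="ok",
                                best_params=json.dumps(fitted.best_params, default=str),
                                **{
                                    k: v
                                    for k, v in report.to_dict().items()
                                    if k != "counts"
                                },
                            )
                    except Exception as exc:  # cell isolation: sweep continues
                        log.warning("cell %s failed: %s", row, exc)
                        row.update(status="error", detail=str(exc))
                    rows.append(row)
                    log.info("cell done: %s", {k: row.get(k) for k in ("form", "size", "color_space", "technique", "status", "accuracy")})
    return pd.DataFrame(rows)


def best_cells(results: pd.DataFrame) -> pd.DataFrame:
    """The best (highest-accuracy) cell per form."""
    ok = results[results["status"] == "ok"].copy()
    if ok.empty:
        return ok
    idx = ok.groupby("form")["accuracy"].idxmax()
    return ok.loc[idx].reset_index(drop=True)


def write_results(results: pd.DataFrame, config: ExperimentConfig, out_dir: str | Path) -> Path:
    """Persist the sweep: cells CSV, best-cell summary, provenance JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.to_csv(out / "cells.csv", index=False)
    best_cells(results).to_csv(out / "summary_best_cells.csv", index=False)
    (out / "provenance.json").write_text(json.dumps(config.provenance(), indent=2))
    return out
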