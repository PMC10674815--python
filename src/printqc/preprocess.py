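"""Image standardization and test-set augmentation.

Standardization mirrors the classical machine-vision front end: square
resize (aspect ratio deliberately not preserved), grayscale conversion with
standard-definition luma weights, and row-major flattening into a feature
matrix whose width is S*S (gray) or 3*S*S (RGB).

Augmentation expands a test set 16-fold: four centered crop fractions
crossed with four orientations (identity, horizontal flip, vertical flip,
180-degree rotation). The transforms are label-preserving, so class balance
is conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
from PIL import Image

from printqc.render import Dataset, LabeledImage

GRAY_WEIGHTS = (0.299, 0.587, 0.114)
ORIENTATIONS = ("identity", "hflip", "vflip", "rot180")
DEFAULT_CROP_FRACTIONS = (0.9, 0.8, 0.7, 0.6)


@dataclass(frozen=True)
class PreprocessConfig:
    """How images are standardized before entering a model."""

    target_size_px: int = 125
    color_space: str = "gray"  # rgb | gray
    intensity_scale: str = "unit_0_1"  # raw_0_255 | unit_0_1

    def __post_init__(self) -> None:
        if self.target_size_px < 8:
            raise ValueError("target_size_px must be >= 8")
        if self.color_space not in ("rgb", "gray"):
            raise ValueError("color_space must be 'rgb' or 'gray'")
        if self.intensity_scale not in ("raw_0_255", "unit_0_1"):
            raise ValueError("intensity_scale must be 'raw_0_255' or 'unit_0_1'")

    @property
    def n_features(self) -> int:
        s2 = self.target_size_px**2
        return s2 if self.color_space == "gray" else 3 * s2


@dataclass
class FeatureMatrix:
    """n_images x d design matrix plus labels and per-row provenance."""

    values: np.ndarray
    labels: np.ndarray
    row_provenance: list[str]
    config: PreprocessConfig

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels length must match number of rows")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# pixel-level operations


def to_grayscale_array(pixels: np.ndarray) -> np.ndarray:
    """Luma conversion with round-half-up; idempotent on gray input."""
    px = np.asarray(pixels)
    if px.ndim == 2:
        return px.copy()
    w = np.array(GRAY_WEIGHTS)
    luma = px.astype(np.float64) @ w
    return np.floor(luma + 0.5).astype(np.uint8)


def to_grayscale(image: LabeledImage) -> LabeledImage:
    """Convert an image to single-channel grayscale, preserving labels."""
    if image.is_gray:
        return image
    return LabeledImage(
        pixels=to_grayscale_array(image.pixels),
        label=image.label,
        defect=image.defect,
        source=image.source,
        spec_digest=image.spec_digest,
    )


def resize_array(pixels: np.ndarray, size_px: int) -> np.ndarray:
    """Square resize to size_px x size_px (bilinear; Pillow's filter does
    area-weighted averaging when downscaling). Aspect ratio is NOT preserved:
    rectangular forms are distorted on purpose, matching a plain square
    resize front end."""
    if size_px < 1:
        raise ValueError("size must be positive")
    px = np.asarray(pixels)
    if px.shape[0] == size_px and px.shape[1] == size_px:
        return px.copy()
    mode = "L" if px.ndim == 2 else "RGB"
    img = Image.fromarray(px, mode=mode)
    out = img.resize((size_px, size_px), resample=Image.Resampling.BILINEAR)
    return np.asarray(out)


def resize(image: LabeledImage, size_px: int) -> LabeledImage:
    """Resize an image to a square raster of side ``size_px``."""
    return LabeledImage(
        pixels=resize_array(image.pixels, size_px),
        label=image.label,
        defect=image.defect,
        source=image.source,
        spec_digest=image.spec_digest,
    )


def crop_center(image: LabeledImage, fraction: float) -> LabeledImage:
    """Centered crop keeping floor(fraction*H) x floor(fraction*W) pixels."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"crop fraction must lie in (0, 1], got {fraction}")
    px = image.pixels
    h, w = px.shape[0], px.shape[1]
    if fraction == 1.0:
        return dc_replace(image, pixels=px.copy())
    h2, w2 = int(np.floor(fraction * h)), int(np.floor(fraction * w))
    if h2 < 1 or w2 < 1:
        raise ValueError("crop fraction leaves no pixels")
    top, left = (h - h2) // 2, (w - w2) // 2
    return dc_replace(image, pixels=px[top : top + h2, left : left + w2].copy())


def orient_array(pixels: np.ndarray, which: str) -> np.ndarray:
    if which == "identity":
        return pixels.copy()
    if which == "hflip":
        return pixels[:, ::-1].copy()
    if which == "vflip":
        return pixels[::-1, :].copy()
    if which == "rot180":
        return pixels[::-1, ::-1].copy()
    raise ValueError(f"unknown orientation {which!r}; expected one of {ORIENTATIONS}")


def orient(image: LabeledImage, which: str) -> LabeledImage:
    """Apply an exact pixel permutation: flip or 180-degree rotation."""
    return dc_replace(image, pixels=orient_array(image.pixels, which))


# ---------------------------------------------------------------------------
# dataset-level operations


def augment_test_set(dataset: Dataset, fractions=DEFAULT_CROP_FRACTIONS) -> Dataset:
    """Expand a grayscale test set 16x: 4 centered crops x 4 orientations.

    Each output records its provenance (source digest, crop fraction,
    orientation). Outputs differ in raster size across crop fractions; they
    are brought to a common size by the downstream resize.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 4 or len(set(fractions)) != 4:
        raise ValueError("exactly 4 distinct crop fractions are required")
    items: list[LabeledImage] = []
    for idx, image in enumerate(dataset):
        if not image.is_gray:
            raise ValueError(
                f"augment_test_set expects grayscale images; item {idx} has "
                f"shape {image.shape}"
            )
        for f in fractions:
            cropped = crop_center(image, f)
            for which in ORIENTATIONS:
                out = orient(cropped, which)
                out.source = "augmented"
                out.spec_digest = f"{image.spec_digest}|crop={f}|orient={which}"
                items.append(out)
    meta = dict(dataset.metadata)
    meta.update({"augmented": True, "crop_fractions": fractions})
    return Dataset(items=items, metadata=meta)


def preprocess_dataset(dataset: Dataset, config: PreprocessConfig) -> Dataset:
    """Apply the configured color-space conversion and square resize."""
    items = []
    for image in dataset:
        out = to_grayscale(image) if config.color_space == "gray" else image
        if config.color_space == "rgb" and out.is_gray:
            raise ValueError("cannot lift grayscale images back to rgb")
        items.append(resize(out, config.target_size_px))
    return Dataset(items=items, metadata=dict(dataset.metadata))


def flatten(dataset: Dataset, config: PreprocessConfig) -> FeatureMatrix:
    """Row-major flattening of an already-standardized dataset.

    d = S*S for grayscale or 3*S*S for RGB; intensities scaled per config.
    Mixed shapes are an error naming the offending rows.
    """
    s = config.target_size_px
    want = (s, s) if config.color_space == "gray" else (s, s, 3)
    bad_rows = [i for i, im in enumerate(dataset) if im.shape != want]
    if bad_rows:
        raise ValueError(
            f"rows {bad_rows[:10]} have shapes inconsistent with config "
            f"{want} (showing up to 10 of {len(bad_rows)})"
        )
    rows = np.stack([im.pixels.reshape(-1) for im in dataset]).astype(np.float64)
    if config.intensity_scale == "unit_0_1":
        rows /= 255.0
    return FeatureMatrix(
        values=rows,
        labels=dataset.labels(),
        row_provenance=[im.spec_digest for im in dataset],
        config=config,
    )


def unflatten(row: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Inverse of one flatten row back to its raster (uint8)."""
    s = config.target_size_px
    shape = (s, s) if config.color_space == "gray" else (s, s, 3)
    values = np.asarray(row, dtype=np.float64)
    if config.intensity_scale == "unit_0_1":
        values = values * 255.0
    return np.rint(values).astype(np.uint8).reshape(shape)


def build_features(dataset: Dataset, config: PreprocessConfig) -> FeatureMatrix:
    """Standardize then flatten in one call."""
    return flatten(preprocess_dataset(dataset, config), config)


def save_features(fm: FeatureMatrix, path) -> None:
    """Persist a feature matrix as a compressed array store plus a CSV
    manifest of per-row provenance and labels."""
    import pandas as pd
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path,
        values=fm.values,
        size=fm.config.target_size_px,
        color_space=fm.config.color_space,
        intensity_scale=fm.config.intensity_scale,
    )
    manifest = path.with_suffix(".manifest.csv")
    pd.DataFrame({"provenance": fm.row_provenance, "label": fm.labels}).to_csv(
        manifest, index=False
    )


def load_features(path) -> FeatureMatrix:
    """Load a feature matrix saved by save_features."""
    import pandas as pd
    from pathlib import Path

    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz") if path.suffix else Path(str(path) + ".npz")
    store = np.load(path, allow_pickle=False)
    manifest = pd.read_csv(
        path.with_suffix("").with_suffix(".manifest.csv"), keep_default_na=False
    )
    config = PreprocessConfig(
        target_size_px=int(store["size"]),
        color_space=str(store["color_space"]),
        intensity_scale=str(store["intensity_scale"]),
    )
    return FeatureMatrix(
        values=store["values"],
        labels=manifest["label"].to_numpy(),
        row_provenance=manifest["provenance"].astype(str).tolist(),
        config=config,
    )
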