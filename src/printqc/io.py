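"""PNG + CSV-manifest persistence for generated datasets."""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from printqc.render import Dataset, LabeledImage

MANIFEST_NAME = "manifest.csv"


def encode_png(image: LabeledImage) -> bytes:
    mode = "L" if image.is_gray else "RGB"
    buf = _io.BytesIO()
    Image.fromarray(image.pixels, mode=mode).save(buf, format="PNG")
    return buf.getvalue()


def save_dataset(dataset: Dataset, out_dir: str | Path, force: bool = False) -> Path:
    """Write one PNG per image plus a manifest CSV; returns the manifest path.

    File names follow {form}_{label}_{defect}_{index}.png. Refuses to write
    into an existing non-empty directory unless ``force``.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    form = dataset.metadata.get("form", dataset.metadata.get("kind", "image"))
    seed = dataset.metadata.get("seed", "")
    rows = []
    for i, image in enumerate(dataset):
        name = f"{form}_{image.label}_{image.defect}_{i:04d}.png"
        (out / name).write_bytes(encode_png(image))
        rows.append(
            {
                "filename": name,
                "form": form,
                "label": image.label,
                "defect": image.defect,
                "source": image.source,
                "seed": seed,
            }
        )
    manifest = out / MANIFEST_NAME
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(in_dir: str | Path) -> Dataset:
    """Load a directory written by save_dataset (or any dir with a manifest)."""
    in_dir = Path(in_dir)
    manifest = in_dir / MANIFEST_NAME
    if not manifest.exists():
        raise FileNotFoundError(f"no {MANIFEST_NAME} in {in_dir}")
    frame = pd.read_csv(manifest, keep_default_na=False)
    items = []
    for rec in frame.to_dict("records"):
        px = np.asarray(Image.open(in_dir / rec["filename"]))
        items.append(
            LabeledImage(
                pixels=px,
                label=rec["label"],
                defect=rec["defect"] or "none",
                source=rec.get("source", "user") or "user",
                spec_digest=rec["filename"],
            )
        )
    meta = {"form": frame["form"].iloc[0] if len(frame) else None}
    if "seed" in frame.columns and len(frame):
        meta["seed"] = frame["seed"].iloc[0]
    return Dataset(items=items, metadata=meta)


def load_image(path: str | Path) -> LabeledImage:
    """Load one user PNG/JPEG for prediction; label is unknown ('bad' placeholder
    is never used for scoring user images)."""
    px = np.asarray(Image.open(path).convert("RGB"))
    return LabeledImage(pixels=px, label="bad", defect="none", source="user", spec_digest=str(path))
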