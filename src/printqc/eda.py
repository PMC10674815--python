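"""Exploratory data analysis of generated image corpora.

Summarizes what a practitioner inspects before modeling: class balance,
defect-subtype composition, PNG-encoded byte sizes (the virtual/photograph
file-size gap shows up here) and per-channel intensity histograms (the
color-gamut gap between the wide virtual palette and the near-grayscale
test images).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from printqc.io import encode_png
from printqc.render import Dataset


@dataclass
class EDASummary:
    n_images: int
    class_counts: dict
    class_ratio_good: float
    defect_counts: dict
    byte_size_mean: float
    byte_size_sd: float
    channel_histograms: dict = field(repr=False, default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_images": self.n_images,
            "class_counts": self.class_counts,
            "class_ratio_good": self.class_ratio_good,
            "defect_counts": self.defect_counts,
            "byte_size_mean": self.byte_size_mean,
            "byte_size_sd": self.byte_size_sd,
            "channel_histograms": {k: v.tolist() for k, v in self.channel_histograms.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def summarize(dataset: Dataset) -> EDASummary:
    """Compute the EDA summary of an in-memory dataset."""
    if len(dataset) == 0:
        raise ValueError("cannot summarize an empty dataset")
    sizes = np.array([len(encode_png(im)) for im in dataset], dtype=np.float64)
    hists = {}
    channels = {"r": [], "g": [], "b": [], "gray": []}
    for im in dataset:
        if im.is_gray:
            channels["gray"].append(im.pixels)
        else:
            channels["r"].append(im.pixels[:, :, 0])
            channels["g"].append(im.pixels[:, :, 1])
            channels["b"].append(im.pixels[:, :, 2])
    for name, planes in channels.items():
        if planes:
            values = np.concatenate([p.reshape(-1) for p in planes])
            hists[name], _ = np.histogram(values, bins=256, range=(0, 256))
    counts = dataset.class_counts()
    return EDASummary(
        n_images=len(dataset),
        class_counts=counts,
        class_ratio_good=counts.get("good", 0) / len(dataset),
        defect_counts=dataset.defect_counts(),
        byte_size_mean=float(sizes.mean()),
        byte_size_sd=float(sizes.std(ddof=1)) if len(sizes) > 1 else 0.0,
        channel_histograms=hists,
    )


def plot_channel_histograms(summary: EDASummary, path: str | Path) -> Path:
    """Render the per-channel intensity histograms to a PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    colors = {"r": "tab:red", "g": "tab:green", "b": "tab:blue", "gray": "tab:gray"}
    for name, counts in summary.channel_histograms.items():
        ax.plot(np.arange(256), counts, color=colors.get(name, "k"), label=name)
    ax.set_xlabel("intensity")
    ax.set_ylabel("pixel count")
    ax.set_title("Color distribution")
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
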