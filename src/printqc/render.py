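"""Procedural rasterizer for synthetic dosage-form images.

This module generates the three image corpora the pipeline runs on:

* the *virtual* training corpus — brightly and variedly colored top-down
  renders of capsules, tablets and films, defect-free ("good") or carrying
  one of three SLA failure modes ("bad": cracked, over-cured, under-cured);
* the *pseudo-real* test corpus — a deliberately domain-shifted stand-in for
  smartphone photographs of physical prints: near-grayscale palette, larger
  canvas, sensor noise and in-plane pose jitter;
* the *out-of-distribution* distractor corpus — backgrounds, pixel noise and
  geometric shapes that depict no dosage form at all and should always be
  classified "bad".

Every generator is a pure function of its spec and seed: rendering the same
spec twice yields byte-identical pixel arrays.

Defect appearance is a declared convention of this package. SLA prints fail
by fracture (rendered as dark jagged polylines spanning the body), by excess
photopolymerization (silhouette dilated with a darkened, blurred rim) and by
incomplete cure (silhouette eroded with missing boundary chunks and a
translucent body).
"""

from __future__ import annotations

import colorsys
import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image, ImageDraw
from scipy import ndimage

FORMS = ("capsule", "tablet", "film")
DEFECTS = ("cracked", "over_cured", "under_cured")
OOD_KINDS = ("background", "noise", "triangle", "oblong", "circle", "diamond")

#: physical top-down extents in millimetres (length, width)
FORM_DIMENSIONS_MM = {
    "capsule": (18.0, 8.0),
    "tablet": (10.0, 10.0),
    "film": (30.0, 10.0),
}

#: fraction of the canvas the longest dimension occupies by default
_DEFAULT_FILL = 0.70

#: per-image pixel standard deviation bound for 'background' OOD images
BACKGROUND_PIXEL_SD_BOUND = 1.0

GENERATOR_VERSION = "printqc-0.1.0"


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class FormGeometry:
    """Top-down geometry of one dosage form on a square canvas."""

    form: str
    length_mm: float
    width_mm: float
    px_per_mm: float
    canvas_px: int

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}; expected one of {FORMS}")
        if self.length_mm <= 0 or self.width_mm <= 0 or self.px_per_mm <= 0:
            raise ValueError("geometry dimensions must be positive")
        if self.canvas_px < 8:
            raise ValueError("canvas_px must be >= 8")
        # silhouette must fit with >= 5% margin on every side
        max_extent_px = max(self.length_mm, self.width_mm) * self.px_per_mm
        if max_extent_px > 0.9 * self.canvas_px:
            raise ValueError(
                f"silhouette ({max_extent_px:.0f} px) exceeds 90% of the "
                f"{self.canvas_px} px canvas; shrink px_per_mm"
            )

    @property
    def diameter_mm(self) -> float:
        """Alias for circular forms (tablet)."""
        return self.length_mm

    @classmethod
    def default(cls, form: str, canvas_px: int = 512) -> "FormGeometry":
        length, width = FORM_DIMENSIONS_MM[form]
        return cls(
            form=form,
            length_mm=length,
            width_mm=width,
            px_per_mm=_DEFAULT_FILL * canvas_px / length,
            canvas_px=canvas_px,
        )


@dataclass(frozen=True)
class RenderSpec:
    """Full parametric description of one synthetic dosage-form image."""

    geometry: FormGeometry
    quality: str  # good | bad
    defect: str  # none | cracked | over_cured | under_cured
    base_color: tuple[int, int, int] = (210, 170, 60)
    layer_spacing_px: float = 8.0
    layer_amplitude: float = 30.0
    background_shade: int = 30
    noise_sd: float = 2.0
    surface_mottle_sd: float = 0.0
    seed: int = 0
    rotation_deg: float = 0.0
    offset_px: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.quality not in ("good", "bad"):
            raise ValueError(f"quality must be 'good' or 'bad', got {self.quality!r}")
        if self.quality == "good" and self.defect != "none":
            raise ValueError("quality='good' requires defect='none'")
        if self.quality == "bad" and self.defect not in DEFECTS:
            raise ValueError(
                f"quality='bad' requires defect in {DEFECTS}, got {self.defect!r}"
            )
        if not all(0 <= c <= 255 for c in self.base_color):
            raise ValueError("base_color channels must lie in 0-255")
        if not 0 <= self.background_shade <= 255:
            raise ValueError("background_shade must lie in 0-255")
        if self.layer_spacing_px <= 0 or self.layer_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("texture/noise parameters out of range")

    def digest(self) -> str:
        h = hashlib.sha256(repr(self).encode()).hexdigest()[:16]
        return f"render:{h}"


@dataclass
class LabeledImage:
    """Pixel raster plus class label, defect subtype and provenance."""

    pixels: np.ndarray  # H x W x 3 (RGB) or H x W (gray), uint8
    label: str  # good | bad
    defect: str  # none | cracked | over_cured | under_cured
    source: str  # virtual | pseudo_real | ood | augmented | user
    spec_digest: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3) or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("pixels must be a HxW or HxWx3 raster")
        if px.ndim == 3 and px.shape[2] != 3:
            raise ValueError("color rasters must have exactly 3 channels")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    @property
    def is_gray(self) -> bool:
        return self.pixels.ndim == 2


@dataclass
class Dataset:
    """Ordered collection of labeled images with generation metadata."""

    items: list[LabeledImage]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i: int) -> LabeledImage:
        return self.items[i]

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {"good": 0, "bad": 0}
        for item in self.items:
            counts[item.label] = counts.get(item.label, 0) + 1
        return counts

    def defect_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for item in self.items:
            if item.label == "bad":
                counts[item.defect] = counts.get(item.defect, 0) + 1
        return counts

    def labels(self) -> np.ndarray:
        return np.array([item.label for item in self.items])


@dataclass(frozen=True)
class OODSpec:
    """Specification of one out-of-distribution distractor batch."""

    kind: str
    n: int
    canvas_px: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in OOD_KINDS:
            raise ValueError(f"unknown OOD kind {self.kind!r}; expected one of {OOD_KINDS}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.canvas_px < 8:
            raise ValueError("canvas_px must be >= 8")


# ---------------------------------------------------------------------------
# silhouette geometry


def _centered_coords_mm(
    geom: FormGeometry, rotation_deg: float, offset_px: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Millimetre coordinates of each pixel center in the form's frame."""
    n = geom.canvas_px
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    x = (xx - c - offset_px[0]) / geom.px_per_mm
    y = (yy - c - offset_px[1]) / geom.px_per_mm
    if rotation_deg:
        t = np.deg2rad(rotation_deg)
        x, y = x * np.cos(t) + y * np.sin(t), -x * np.sin(t) + y * np.cos(t)
    return x, y


def _inside(form: str, x: np.ndarray, y: np.ndarray, length: float, width: float):
    """Boolean inside-test for the top-down silhouette, coordinates in mm."""
    if form == "tablet":
        r = length / 2.0
        return x * x + y * y <= r * r
    if form == "capsule":
        # stadium: rectangle of length L-W capped by two semicircles of radius W/2
        r = width / 2.0
        half = max(length / 2.0 - r, 0.0)
        dx = np.maximum(np.abs(x) - half, 0.0)
        return dx * dx + y * y <= r * r
    if form == "film":
        # rounded rectangle with a small corner radius
        cr = min(1.0, width / 4.0)
        dx = np.maximum(np.abs(x) - (length / 2.0 - cr), 0.0)
        dy = np.maximum(np.abs(y) - (width / 2.0 - cr), 0.0)
        return dx * dx + dy * dy <= cr * cr
    raise ValueError(f"unknown form {form!r}")


def silhouette_mask(
    geom: FormGeometry,
    scale: float = 1.0,
    rotation_deg: float = 0.0,
    offset_px: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Boolean foreground mask for the silhouette at an optional scale factor."""
    x, y = _centered_coords_mm(geom, rotation_deg, offset_px)
    return _inside(geom.form, x, y, geom.length_mm * scale, geom.width_mm * scale)


def _boundary_point_px(
    geom: FormGeometry,
    theta: float,
    scale: float,
    rotation_deg: float,
    offset_px: tuple[float, float],
) -> tuple[float, float]:
    """Pixel coordinates (x, y) of the silhouette boundary along direction theta.

    Bisection on the inside-test in the form's own frame, then mapped back to
    canvas pixels.
    """
    length = geom.length_mm * scale
    width = geom.width_mm * scale
    lo, hi = 0.0, float(np.hypot(length, width))
    dx, dy = np.cos(theta), np.sin(theta)
    for _ in range(48):
        mid = 0.5 * (lo + hi)
        if _inside(geom.form, np.array(mid * dx), np.array(mid * dy), length, width):
            lo = mid
        else:
            hi = mid
    r = lo
    x_mm, y_mm = r * dx, r * dy
    if rotation_deg:
        t = np.deg2rad(rotation_deg)
        x_mm, y_mm = x_mm * np.cos(t) - y_mm * np.sin(t), x_mm * np.sin(t) + y_mm * np.cos(t)
    c = (geom.canvas_px - 1) / 2.0
    return (c + offset_px[0] + x_mm * geom.px_per_mm, c + offset_px[1] + y_mm * geom.px_per_mm)


def _min_dim_px(geom: FormGeometry) -> float:
    return min(geom.length_mm, geom.width_mm) * geom.px_per_mm


# ---------------------------------------------------------------------------
# defect layers


def _crack_mask(
    geom: FormGeometry,
    rng: np.random.Generator,
    rotation_deg: float,
    offset_px: tuple[float, float],
) -> np.ndarray:
    """Dark jagged polylines spanning the body, endpoints on the boundary."""
    n = geom.canvas_px
    canvas = Image.new("L", (n, n), 0)
    draw = ImageDraw.Draw(canvas)
    n_cracks = 3
    width_px = max(2, int(round(rng.uniform(0.022, 0.03) * _min_dim_px(geom))))
    for k in range(n_cracks):
        theta = rng.uniform(0, 2 * np.pi)
        # the first fracture is a full transverse break through the body
        # center; the others wander
        theta2 = theta + np.pi + (0.0 if k == 0 else rng.uniform(-0.35, 0.35))
        p0 = _boundary_point_px(geom, theta, 1.0, rotation_deg, offset_px)
        p1 = _boundary_point_px(geom, theta2, 1.0, rotation_deg, offset_px)
        k = 8
        ts = np.linspace(0.0, 1.0, k + 1)
        xs = p0[0] + ts * (p1[0] - p0[0])
        ys = p0[1] + ts * (p1[1] - p0[1])
        jitter = rng.normal(0.0, 0.05 * _min_dim_px(geom), size=k + 1)
        jitter[0] = jitter[-1] = 0.0  # endpoints stay on the boundary
        # jitter perpendicular to the chord
        chord = np.array([p1[0] - p0[0], p1[1] - p0[1]])
        norm = np.hypot(*chord) or 1.0
        perp = np.array([-chord[1], chord[0]]) / norm
        pts = list(zip(xs + jitter * perp[0], ys + jitter * perp[1]))
        draw.line(pts, fill=255, width=width_px, joint="curve")
    return np.asarray(canvas) > 0


def _chunk_holes(
    geom: FormGeometry,
    rng: np.random.Generator,
    scale: float,
    rotation_deg: float,
    offset_px: tuple[float, float],
) -> np.ndarray:
    """Discs centered on the (eroded) boundary, to punch out missing chunks."""
    n = geom.canvas_px
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    holes = np.zeros((n, n), dtype=bool)
    for _ in range(int(rng.integers(1, 4))):
        theta = rng.uniform(0, 2 * np.pi)
        cx, cy = _boundary_point_px(geom, theta, scale, rotation_deg, offset_px)
        radius = rng.uniform(0.08, 0.16) * _min_dim_px(geom)
        holes |= (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    return holes


# ---------------------------------------------------------------------------
# rendering


def _lighting_field(n: int) -> np.ndarray:
    """Radial vignette plus a gentle top-left luminance gradient."""
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    c = (n - 1) / 2.0
    r2 = ((xx - c) ** 2 + (yy - c) ** 2) / (2 * c * c)
    vignette = 1.0 - 0.22 * r2
    gradient = 1.0 + 0.08 * (1.0 - (xx + yy) / (2 * (n - 1)))
    return vignette * gradient


def render_form_layers(spec: RenderSpec) -> tuple[LabeledImage, dict[str, np.ndarray]]:
    """Render one image and also return its internal masks.

    The mask dictionary carries the boolean ``foreground`` (final silhouette,
    defects applied) and, for cracked specs, the ``crack`` polyline mask; it
    exists so downstream checks can measure geometry without re-deriving it
    from pixels.
    """
    geom = spec.geometry
    n = geom.canvas_px
    rng = np.random.default_rng(np.uint64(spec.seed % (2**63)))

    base_mask = silhouette_mask(geom, 1.0, spec.rotation_deg, spec.offset_px)
    masks: dict[str, np.ndarray] = {}

    # foreground color field: base color shaded by horizontal layer lines,
    # imitating the layer-by-layer texture of vat photopolymerization
    yy = np.mgrid[0:n, 0:n][0].astype(np.float64)
    # fixed phase: the virtual scene (camera, lighting, print position) is
    # held constant across the generation loop, so the layer lines land on
    # the same rows in every render
    tex = 0.5 * (1.0 + np.sin(2 * np.pi * yy / spec.layer_spacing_px))
    # layer-line contrast is strongest where the surface faces the camera
    # squarely and washes out toward the silhouette edge, where the curved
    # surface is viewed obliquely
    xx_t = np.mgrid[0:n, 0:n][1].astype(np.float64)
    c = (n - 1) / 2.0
    r2_tex = ((xx_t - c) ** 2 + (yy - c) ** 2) / (2 * c * c)
    shading = spec.layer_amplitude * tex * np.exp(-r2_tex / 0.08)
    color = np.array(spec.base_color, dtype=np.float64)
    fg = np.clip(color[None, None, :] - shading[:, :, None], 0, 255)

    alpha = base_mask.astype(np.float64)
    body_mask = base_mask

    if spec.defect == "cracked":
        crack = _crack_mask(geom, rng, spec.rotation_deg, spec.offset_px) & base_mask
        fg = np.where(crack[:, :, None], fg * 0.18, fg)
        masks["crack"] = crack
    elif spec.defect == "over_cured":
        grow = 1.0 + rng.uniform(0.0, 0.12)
        dilated = silhouette_mask(geom, grow, spec.rotation_deg, spec.offset_px)
        rim = dilated & ~base_mask
        # excess polymerization melts the layer lines: the body keeps only a
        # faint, blurred remnant of the stripe texture
        melted = ndimage.gaussian_filter(shading, 3.0) * rng.uniform(0.12, 0.25)
        fg = np.clip(color[None, None, :] - melted[:, :, None], 0, 255)
        fg = np.where(rim[:, :, None], color[None, None, :] * 0.45 - melted[:, :, None], fg)
        fg = np.clip(fg, 0, 255)
        alpha = ndimage.gaussian_filter(dilated.astype(np.float64), 2.0)
        body_mask = dilated
        masks["rim"] = rim
    elif spec.defect == "under_cured":
        shrink = 1.0 - rng.uniform(0.0, 0.10)
        eroded = silhouette_mask(geom, shrink, spec.rotation_deg, spec.offset_px)
        holes = _chunk_holes(geom, rng, shrink, spec.rotation_deg, spec.offset_px)
        body_mask = eroded & ~holes
        translucency = rng.uniform(0.35, 0.62)
        # incomplete cure dims the ridge tops of the layer lines — uncured
        # resin reflects less light — while the shadowed valleys stay dark
        # regardless; the effect is worst where the print is thickest, i.e.
        # the body center
        alpha_center = 1.0 - (1.0 - translucency) * np.exp(-r2_tex / 0.10)
        ridge_weight = (1.0 - tex) * np.exp(-r2_tex / 0.08)
        dim = 1.0 - (1.0 - alpha_center) * ridge_weight
        fg = fg * dim[:, :, None]
        alpha = body_mask.astype(np.float64)
        masks["holes"] = holes

    if spec.defect != "over_cured":
        # 1 px anti-alias; over-cured already carries a wide blurred rim
        alpha = ndimage.gaussian_filter(alpha, 0.8)
    alpha = np.clip(alpha, 0.0, 1.0)

    bg = np.full((n, n, 3), float(spec.background_shade))
    img = bg * (1.0 - alpha[:, :, None]) + fg * alpha[:, :, None]
    img *= _lighting_field(n)[:, :, None]

    if spec.surface_mottle_sd > 0:
        # spatially correlated luminance mottle on the body: cured resin is
        # not optically uniform, and unlike pixel noise this texture survives
        # heavy downsampling; the amplitude grows toward the canvas edge,
        # where the oblique view of the curved surface scatters more light
        field = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=(n, n)), n / 48.0)
        sd = field.std()
        if sd > 0:
            yy2, xx2 = np.mgrid[0:n, 0:n].astype(np.float64)
            c = (n - 1) / 2.0
            r2 = ((xx2 - c) ** 2 + (yy2 - c) ** 2) / (2 * c * c)
            radial_gain = 0.5 + 2.5 * r2
            img += (field * (spec.surface_mottle_sd / sd) * radial_gain * alpha)[:, :, None]

    if spec.noise_sd > 0:
        # luminance noise: one field shared by all channels, so the chroma
        # spread of near-gray renders is preserved
        img += rng.normal(0.0, spec.noise_sd, size=(n, n))[:, :, None]

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    masks["foreground"] = body_mask
    image = LabeledImage(
        pixels=pixels,
        label=spec.quality,
        defect=spec.defect,
        source="virtual",
        spec_digest=spec.digest(),
    )
    return image, masks


def render_form(spec: RenderSpec) -> LabeledImage:
    """Render one dosage-form image from its full parametric spec."""
    image, _ = render_form_layers(spec)
    return image


# ---------------------------------------------------------------------------
# corpus generators


def _defect_schedule(n_bad: int) -> list[str]:
    """Split n_bad across the three subtypes; remainder goes to 'cracked'."""
    base, rem = divmod(n_bad, 3)
    counts = {"cracked": base + rem, "over_cured": base, "under_cured": base}
    schedule: list[str] = []
    for defect in DEFECTS:
        schedule.extend([defect] * counts[defect])
    return schedule


_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])
_LUMA_CYCLE = (210.0, 195.0, 180.0, 165.0)


def _sweep_color(i: int, n: int, rng: np.random.Generator) -> tuple[int, int, int]:
    """Systematic hue sweep at controlled luma with seeded jitter.

    Hue rotates uniformly across the loop while the grayscale luma cycles
    through a fixed bright-to-mid band, so the palette is wide in RGB (the
    virtual corpus looks colorful) yet the body stays clearly brighter than
    the background after grayscale conversion. Saturation is reduced (toward
    pastel) only when a hue is intrinsically too dark to reach the target
    luma at full value.
    """
    hue = (i / max(n, 1)) % 1.0
    target = float(np.clip(_LUMA_CYCLE[i % 4] + rng.normal(0.0, 5.0), 160.0, 220.0))
    pure = np.array(colorsys.hsv_to_rgb(hue, 1.0, 1.0))
    luma_pure = float(_LUMA_WEIGHTS @ pure) * 255.0
    if luma_pure >= target:
        rgb = np.array(colorsys.hsv_to_rgb(hue, 1.0, target / luma_pure))
    else:
        sat = (255.0 - target) / max(255.0 - luma_pure, 1e-9)
        rgb = np.array(colorsys.hsv_to_rgb(hue, float(np.clip(sat, 0.0, 1.0)), 1.0))
    r, g, b = np.clip(np.rint(rgb * 255.0), 0, 255)
    return (int(r), int(g), int(b))


def generate_training_set(
    form: str,
    n_good: int = 100,
    n_bad: int = 100,
    seed: int = 0,
    canvas_px: int = 512,
) -> Dataset:
    """Generate the virtual training corpus for one dosage form.

    Exactly ``n_good`` defect-free and ``n_bad`` defective renders; the bad
    half is split as evenly as possible across the three defect subtypes with
    any remainder assigned to 'cracked' (100 bad -> 34/33/33). Base colors
    are swept systematically across the loop.
    """
    if n_good < 1:
        raise ValueError("n_good must be >= 1")
    if n_bad < 3:
        raise ValueError("n_bad must be >= 3 to cover all defect subtypes")
    geom = FormGeometry.default(form, canvas_px)
    rng = np.random.default_rng(seed)
    items: list[LabeledImage] = []
    schedule = [("good", "none")] * n_good + [("bad", d) for d in _defect_schedule(n_bad)]
    for i, (quality, defect) in enumerate(schedule):
        color = _sweep_color(i, n_good, rng)
        # ±3% print-size tolerance: even well-formed prints vary slightly in
        # scale, so over/under-cure cannot be read off one boundary pixel
        size_jitter = rng.uniform(0.97, 1.03)
        spec = RenderSpec(
            geometry=replace(geom, px_per_mm=geom.px_per_mm * size_jitter),
            quality=quality,
            defect=defect,
            base_color=color,
            layer_spacing_px=max(3.0, canvas_px / 32.0),
            layer_amplitude=95.0,
            background_shade=int(rng.integers(10, 40)),
            noise_sd=2.0,
            surface_mottle_sd=4.0,
            seed=int(seed) + i,
        )
        items.append(render_form(spec))
    return Dataset(
        items=items,
        metadata={"form": form, "seed": int(seed), "role": "train", "generator": GENERATOR_VERSION},
    )


def generate_pseudo_real_set(
    form: str,
    n: int = 200,
    seed: int = 0,
    canvas_px: int = 1024,
) -> Dataset:
    """Generate the domain-shifted test corpus emulating photographs.

    50:50 good/bad with the bad half split in thirds; near-grayscale palette
    (channel spread <= 15 before noise), a canvas at least twice the training
    default, luminance sensor noise and random in-plane pose jitter.
    """
    if n % 2 != 0:
        raise ValueError("n must be even (50:50 class balance)")
    if n < 6:
        raise ValueError("n must be >= 6 to cover all defect subtypes")
    geom = FormGeometry.default(form, canvas_px)
    rng = np.random.default_rng(seed)
    n_good = n // 2
    schedule = [("good", "none")] * n_good + [("bad", d) for d in _defect_schedule(n - n_good)]
    items: list[LabeledImage] = []
    noise_sd = 4.0
    for i, (quality, defect) in enumerate(schedule):
        value = rng.uniform(160, 215)
        tint = rng.uniform(-5, 5, size=3)  # max spread 10 < 15
        color = tuple(int(round(c)) for c in np.clip(value + tint, 0, 255))
        size_jitter = rng.uniform(0.97, 1.03)
        spec = RenderSpec(
            geometry=replace(geom, px_per_mm=geom.px_per_mm * size_jitter),
            quality=quality,
            defect=defect,
            base_color=color,
            layer_spacing_px=max(3.0, canvas_px / 32.0),
            layer_amplitude=90.0,
            background_shade=int(rng.integers(8, 45)),
            noise_sd=noise_sd,
            surface_mottle_sd=4.0,
            seed=int(seed) + i,
            rotation_deg=float(rng.uniform(-2.0, 2.0)),
            offset_px=(
                float(rng.uniform(-0.01, 0.01) * canvas_px),
                float(rng.uniform(-0.01, 0.01) * canvas_px),
            ),
        )
        image = render_form(spec)
        image.source = "pseudo_real"
        items.append(image)
    return Dataset(
        items=items,
        metadata={"form": form, "seed": int(seed), "role": "test", "generator": GENERATOR_VERSION},
    )


# --- OOD distractors -------------------------------------------------------


def _ood_shape_pixels(
    kind: str, canvas_px: int, rng: np.random.Generator
) -> np.ndarray:
    """One filled shape (triangle/oblong/circle/diamond) in random pose."""
    n = canvas_px
    bg = int(rng.integers(5, 45))
    color = tuple(int(c) for c in rng.integers(40, 240, size=3))
    cx = n / 2 + rng.uniform(-0.06, 0.06) * n
    cy = n / 2 + rng.uniform(-0.06, 0.06) * n
    size = rng.uniform(0.26, 0.42) * n  # circumradius; always fully on canvas
    angle = rng.uniform(0, 2 * np.pi)

    img = Image.new("RGB", (n, n), (bg, bg, bg))
    draw = ImageDraw.Draw(img)

    def rot(px: float, py: float) -> tuple[float, float]:
        return (
            cx + px * np.cos(angle) - py * np.sin(angle),
            cy + px * np.sin(angle) + py * np.cos(angle),
        )

    if kind == "triangle":
        pts = [rot(size * np.cos(a), size * np.sin(a)) for a in (0, 2 * np.pi / 3, 4 * np.pi / 3)]
        draw.polygon(pts, fill=color)
    elif kind == "diamond":
        w = size * rng.uniform(0.5, 0.9)
        pts = [rot(size, 0), rot(0, w), rot(-size, 0), rot(0, -w)]
        draw.polygon(pts, fill=color)
    elif kind == "circle":
        draw.ellipse([cx - size, cy - size, cx + size, cy + size], fill=color)
    elif kind == "oblong":
        # stadium shape: rectangle with semicircular caps, approximated as a
        # dense polygon so it can be drawn in any orientation
        half = size
        r = size * rng.uniform(0.35, 0.55)
        pts = []
        for a in np.linspace(-np.pi / 2, np.pi / 2, 24):
            pts.append(rot(half - r + r * np.cos(a), r * np.sin(a)))
        for a in np.linspace(np.pi / 2, 3 * np.pi / 2, 24):
            pts.append(rot(-(half - r) + r * np.cos(a), r * np.sin(a)))
        draw.polygon(pts, fill=color)
    else:
        raise ValueError(f"not a shape kind: {kind!r}")
    return np.asarray(img)


def generate_ood_set(spec: OODSpec) -> Dataset:
    """Generate out-of-distribution distractor images, all labeled 'bad'.

    Kinds: 'background' (uniform dark canvas, shade jittered across images),
    'noise' (i.i.d. uniform pixels), and filled geometric shapes in random
    pose ('triangle', 'oblong', 'circle', 'diamond').
    """
    rng = np.random.default_rng(spec.seed)
    n_px = spec.canvas_px
    items: list[LabeledImage] = []
    for i in range(spec.n):
        if spec.kind == "background":
            shade = int(rng.integers(5, 45))
            pixels = np.full((n_px, n_px, 3), shade, dtype=np.uint8)
        elif spec.kind == "noise":
            pixels = rng.integers(0, 256, size=(n_px, n_px, 3), dtype=np.uint8)
        else:
            pixels = _ood_shape_pixels(spec.kind, n_px, rng)
        items.append(
            LabeledImage(
                pixels=pixels,
                label="bad",
                defect="none",
                source="ood",
                spec_digest=f"ood:{spec.kind}:{spec.seed}:{i}",
            )
        )
    return Dataset(
        items=items,
        metadata={
            "kind": spec.kind,
            "seed": int(spec.seed),
            "role": "ood",
            "generator": GENERATOR_VERSION,
        },
    )
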