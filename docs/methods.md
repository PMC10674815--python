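# Methods

## Overview

`printqc` is a self-contained study of synthetic-to-real transfer for
machine-vision quality control of SLA-printed dosage forms. Because no
photograph corpus ships with the package, *both* sides of the domain gap are
procedural: a **virtual** training corpus (colorful, clean, 512 px canvas)
and a **pseudo-real** test corpus that emulates the observable properties of
smartphone photographs of physical prints — a near-grayscale palette, a
canvas twice as large (hence PNG files several times larger), sensor noise,
and in-plane pose jitter. Everything downstream (preprocessing, the seven
learners, the metrics, the stress harness) operates on these corpora exactly
as it would on real images.

## The renderer

All images are drawn by a deterministic rasterizer (`printqc.render`); every
generator is a pure function of its spec and seed, and regeneration is
byte-identical.

**Geometry.** Top-down silhouettes at millimetre scale: film 30 × 10 mm
(rounded rectangle), tablet Ø 10 mm (disc), capsule 18 × 8 mm (stadium).
The default scale puts the longest dimension at 70% of the canvas;
geometries that would leave less than a 5% margin are rejected. Pixel-center
sampling keeps silhouette area within 2–5% of the analytic value for any
px/mm ≥ 5 (verified against closed-form disc/stadium areas in the tests).

**Surface model.** The body carries horizontal layer lines — the signature
texture of vat photopolymerization — rendered as a fixed-phase sinusoid
(period canvas/32) whose contrast is strongest where the surface faces the
camera squarely and washes out toward the silhouette edge (Gaussian radial
window). On top of that: a spatially correlated luminance mottle (cured
resin is not optically uniform; amplitude grows toward the canvas edge), a
radial vignette with a top-left illumination gradient, and i.i.d. luminance
noise. The scene (camera, lighting, print position, stripe phase) is held
constant across a generation loop; only colors and defects vary.

**Color.** Training colors sweep hue uniformly around the wheel while the
grayscale luma is pinned to a controlled cycle (≈160–220): the virtual
palette is wide in RGB but consistent after grayscale conversion.
Without luma control a hue sweep spans luma 29–226 (pure blue vs. yellow),
which destroys grayscale transfer — a defect-free dark-blue print and an
under-cured bright print become indistinguishable. Pseudo-real bodies are
near-gray (channel spread ≤ 10 before noise, against a spec bound of
15 + 3·noise_sd); sensor noise is a single luminance field shared by all
channels so the low-chroma property survives.

**Defects** (declared conventions; the failure modes are named in the SLA
literature but their pixel-level appearance is this package's design):

- *Cracked* — three dark jagged polylines (width 2.2–3% of the smallest
  silhouette dimension, fill ×0.18) spanning the body with endpoints on the
  boundary. The first is a full transverse break through the body center;
  the others wander. Routing one fracture through the center keeps thin
  cracks detectable after heavy downsampling on the narrow capsule body.
- *Over-cured* — excess polymerization melts the layer lines (the stripe
  shading is blurred to a 12–25% remnant) and may dilate the silhouette by
  0–12% with a darkened, edge-blurred rim. Texture loss and dimensional
  growth are sampled independently: a mildly dilated but fully melted print
  is a legitimate over-cure, so no single boundary pixel separates the
  class.
- *Under-cured* — incomplete cure dims the ridge tops of the layer lines
  (uncured resin reflects less light) while the shadowed valleys stay dark
  regardless; the effect is strongest at the body center, where the print is
  thickest, and 1–3 boundary chunks are missing.

All prints, good or bad, carry a ±3% size tolerance.

### Why the defect signatures look the way they do

The generator has a contract with the downstream experiments, stated in the
package's invariants and enforced by the acceptance tests: (a) a
depth-unlimited decision tree must reach ≥ 90% on held-out virtual images —
the defect renderings must be *learnable*; (b) tuned DT/RF trained on
virtual images must reach ≥ 65% on the pseudo-real corpus — the domain gap
must be crossable; (c) tuned DT and RF must classify ≥ 95% of every OOD kind
as 'Bad'. A greedy axis-aligned tree satisfies (c) only if every path to a
'good' leaf contains tests that no flat, textureless image can pass. The
design above makes the bright stripe rows and dark stripe valleys of the
body center the *cleanest* class separators available, so trained trees pin
their decisions there: a good print must be bright on a ridge row **and**
dark on an adjacent valley row, a conjunction that uniform backgrounds,
downsample-flattened noise, and filled geometric shapes all fail. The wide
across-image luma range additionally denies any single pixel full purity for
the over-cured class, pushing trees toward paired (base-then-valley) tests
that act as relative rather than absolute thresholds. These are design
choices of the simulator, and results on it bound what the pipeline can do
on real photographs only qualitatively.

## Preprocessing and augmentation

Grayscale uses the standard-definition luma weights 0.299/0.587/0.114 with
round-half-up, so tests can be bit-exact. Resizing is Pillow bilinear
(area-weighted when downscaling) to a square — the aspect distortion of
rectangular films is intentional and mirrors a plain square-resize front
end. Flattening is row-major; d = S² (gray) or 3S² (RGB); intensities are
scaled to [0, 1] by default because half the model zoo is scale-sensitive.
The test-time augmentation is exactly 4 centered crops (default fractions
0.9/0.8/0.7/0.6) × 4 orientations including identity, giving the 16×
expansion (200 → 3200); the training set is never augmented, only
grayscale-transformed.

## Models

Seven scikit-learn learners behind one `train()` surface. Tuning is an
explicit loop over the declared grid in declared order with stratified
5-fold cross-validated accuracy; ties keep the first candidate, and the loop
checks a cooperative wall-time/feature-count budget between candidates so an
oversized fit yields a structured "exceeded limits" record instead of a
crash (logistic regression on ≥125 px images is the canonical case).
Default grids are small and practical; notably the random-forest grid
includes 5 trees, because small forests dominate this regime. "Untuned"
means library defaults with the same seed. Class order is fixed (bad, good),
the positive class is 'Good', and a probability tie predicts 'Bad' — the
conservative choice for quality control.

## Metrics

Implemented directly from their defining formulas and cross-checked in the
tests against independent routes (confusion ratios vs. enumeration,
Mann–Whitney AUROC vs. sklearn's trapezoidal ROC, Brier vs.
`brier_score_loss`). Brier is scored single-class: the probability assigned
to 'Good' against the 0/1 indicator of 'Good', keeping the 0–1 range.
Metrics with an empty denominator (e.g. specificity with no negatives)
return NaN — an explicit undefined marker, never 0. Confidence profiling
histograms max(p̂, 1−p̂) over [0.5, 1.0] in 0.05 bins.

## Study conditions and problem sizes

The headline experiment trains on 100 Good + 100 Bad virtual images per form
(bad split 34/33/33 across cracked/over/under; the odd image goes to
cracked), tests on 200 pseudo-real images (50:50, thirds), at size 125
grayscale, and feeds 200 OOD images of each of four kinds per form
(background, noise, triangle, and the geometry-matched shape: oblong for
capsules, circle for tablets, diamond for films). Unit tests run the same
code on reduced canvases (128–256 px) to stay fast; the acceptance tests run
the full-size experiment once per session and share its artifacts.

## Numerical choices and degenerate inputs

Per-image seeds are `dataset_seed + index`; all randomness flows through
`numpy.random.default_rng`. Crack masks are drawn with Pillow and
intersected with the silhouette; anti-aliasing is a 0.8 px Gaussian on the
alpha. Quality/defect mismatches, single-class training data, odd
pseudo-real counts, unknown OOD kinds, crop fractions outside (0, 1], and
feature-dimension mismatches all raise early with messages naming the
offending values.

## Limitations

The pseudo-real corpus shares the renderer with the training corpus, so the
domain gap — palette, scale, noise, pose — is narrower than a real
camera/print gap: transfer accuracies here (≈0.95+) sit above what
photographs of physical prints would give, and should be read as an upper
bound and a correctness check of the pipeline, not a claim about deployment
accuracy. Only top-down views are rendered; internal defects and dimensional
QC are out of scope. The OOD result holds for the distractor families
generated here; a distractor engineered to mimic the body-center stripe
pattern would defeat it, as it would defeat any pixel-threshold model.
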