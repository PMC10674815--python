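# printqc

Machine-vision quality control for 3D-printed dosage forms, trained entirely
on synthetic images.

Stereolithography (SLA) printing of capsules, tablets and orodispersible
films needs a non-destructive quality check, but collecting and annotating
photographs of real prints is slow and expensive. `printqc` takes the
synthetic-data route: it procedurally renders top-down images of the three
dosage forms — defect-free ("Good") or carrying one of three SLA failure
modes ("Bad": cracked, over-cured, under-cured) — trains classical
scikit-learn classifiers on those virtual images, and evaluates them on a
deliberately domain-shifted, photograph-like test corpus plus
out-of-distribution (OOD) distractors.

The package is aimed at researchers studying synthetic-to-real transfer for
pharmaceutical machine vision, and at anyone who wants a fully reproducible,
self-contained benchmark of classical learners on an image QC task.

## What it computes

For a binary classifier with 'Good' as the positive class:

- **Accuracy** = (TP + TN) / (TP + FP + TN + FN)
- **Sensitivity** = TP / (TP + FN), **Specificity** = TN / (TN + FP)
- **AUROC**: rank-based (Mann–Whitney) probability that a random positive
  outranks a random negative, ties credited ½ — equal to trapezoidal
  integration of the ROC curve; 0.5 is a worthless test, 1.0 a perfect one
- **Brier score** = (1/N) Σ (p̂(Good) − 1[Good])², lower is better
  calibrated; a constant-0.5 predictor scores exactly 0.25
- **Most-confident statistic** = max(p̂, 1−p̂) per instance, in [0.5, 1]

Seven learners are supported (LR, DT, RF, GB, MLP, SVM, kNN), each with
stratified 5-fold grid search; the stress harness covers a 16× test-set
augmentation (4 center crops × {identity, h-flip, v-flip, 180° rotation}),
confidence histograms, and OOD testing with tuned vs. untuned trees.

## Worked example

```python
from printqc import (
    ModelSpec, PreprocessConfig, build_features, evaluate,
    generate_training_set, generate_pseudo_real_set, train,
)

cfg = PreprocessConfig(target_size_px=125, color_space="gray")
train_set = generate_training_set("tablet", n_good=100, n_bad=100, seed=1)
test_set = generate_pseudo_real_set("tablet", n=200, seed=2)

model = train(ModelSpec(technique="DT", seed=0), build_features(train_set, cfg))
report = evaluate(model, build_features(test_set, cfg))
print(f"accuracy    {report.accuracy:.3f}")
print(f"sensitivity {report.sensitivity:.3f}")
print(f"specificity {report.specificity:.3f}")
print(f"auroc       {report.auroc:.3f}")
print(f"brier       {report.brier:.3f}")
```

prints

```
accuracy    0.985
sensitivity 1.000
specificity 0.970
auroc       0.985
brier       0.015
```

— a hyperparameter-tuned decision tree trained on 200 virtual tablet
renders classifies 98.5% of the 200 photograph-like test images correctly,
with balanced sensitivity/specificity and a well-calibrated Brier score.
(The synthetic domain gap is milder than a real camera's; see
`docs/methods.md` for what this does and does not show.)

The same pipeline is available from the shell:

```bash
printqc generate --form tablet --role train --seed 1 --out data/train
printqc eda data/train
printqc run --form tablet --size 50 --technique DT --out results/
printqc stress --form tablet --size 125 --out results/stress
printqc predict --form tablet my_print.png
```

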