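# ordvit

Ordinal severity grading of lesion images with a progression-aware vision
transformer, a dual categorical + continuous risk output, and Score-CAM
attribution — built for researchers studying graded malignancy-risk
assessment in endoscopic imaging, and exercised end to end on synthetic
ordinal-severity data so every component is testable on one CPU.

## The model

Images are graded along the ordinal axis Benign (0) → Low-Risk (1) →
High-Risk (2) → Malignant (3). A pre-norm ViT encoder turns the frame into
patch tokens plus a [CLS] descriptor; a Sequential Feature Learner (SFL)
replicates the [CLS] vector across four stage positions, adds learned stage
embeddings e₀..e₃, mixes the stages with self-attention, and mean-pools the
per-stage FFN outputs. Two heads read the pooled vector:

- a 4-class softmax classifier, trained with class-weighted cross-entropy;
- a sigmoid risk head emitting a score in [0, 1], trained with MSE against
  the ordinal anchors y/3, so the continuous score should rise monotonically
  from Benign to Malignant.

The total loss is `w_y·CE + λ·(risk − y/3)²`. Attribution uses Score-CAM:
final-block token channels become spatial maps that mask the input; the
change in the re-forwarded class score (vs an all-zero baseline) weights
each map, and the rectified weighted sum is the heatmap. A heatmap is
*concordant* with a lesion mask when at least τ of its high-activation
region lies inside the mask.

Everything — the transformer, the SFL, AdamW training with early stopping,
and the Score-CAM re-forwarding loop — runs on a small numpy reverse-mode
autodiff engine (`ordvit.autograd`), verified against finite differences
and a nested-loop attention oracle in the test suite.

## Worked example

```bash
python examples/01_generate_dataset.py
python examples/02_train_and_evaluate.py
python examples/03_score_cam.py       # uses the checkpoint from example 02
python examples/04_ablation.py
```

Example 02 trains the tiny preset (64-px input, 8-px patches, dim 64, 2
blocks) from scratch on 400 synthetic images for up to 30 epochs and prints:

```
test accuracy      1.000
weighted P/R/F1    1.000 / 1.000 / 1.000
per-class AUC      [1.0, 1.0, 1.0, 1.0]
micro AUC          1.000
risk means 0..3    [0.022, 0.207, 0.629, 0.923] monotone=True
adjacent errors    0.00 (no errors: True)
```

Read: the four ordinal classes of the easy synthetic set are fully
separated, and the continuous risk score increases strictly with class —
the progression-aware design working as intended. Example 03 then runs
Score-CAM on a malignant test frame with that checkpoint and prints an
overlap of 0.56 with the ground-truth lesion mask (concordant at τ = 0.5).

A thin CLI wraps the same functions for shell use:

```bash
ordvit generate --out data --n-per-class 50 --seed 0
ordvit split --manifest data/manifest.csv --fractions 0.8,0.1,0.1 --seed 0
ordvit train --config run.yaml --seed 0 --variant full --out ckpt.npz
ordvit evaluate --checkpoint ckpt.npz --data-dir data --split test
ordvit explain --checkpoint ckpt.npz --data-dir data --split test --out maps
ordvit ablate --config run.yaml --seeds 0,1,2
```

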