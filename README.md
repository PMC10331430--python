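# lungpaste

One-class anomaly detection for chest radiographs via **lung-confined
cut-paste augmentation**, exercised end-to-end on synthetic radiograph
phantoms. The pipeline:

1. **Phantom generation** (`lungpaste.phantom`) — synthetic chest-radiograph
   phantoms (dark lung ellipses, bright mediastinum, rib arcs, vignette,
   noise) with analytic ground-truth lung masks, plus abnormal variants with
   injected bright lung opacities.
2. **Lung-field segmentation** (`lungpaste.segmentation`) — annotation-free:
   CLAHE, Otsu binarization (dark foreground), disc opening, border
   clearing, disc dilation, and minimum-component-area filtering
   (8-connectivity throughout).
3. **Augmentation** (`lungpaste.augment`) — a patch is cropped and pasted at
   a random location; an oval/rectangle opacity shape (interior value
   v ~ U[0.59, 1], Gaussian edge blur of radius r ~ U[0, 15] px) is drawn
   over the pasted position, multiplied with the lung mask, and used as the
   blend weight `out = normal * (1 - mask) + pasted * mask`. Ablation modes:
   `no_segmentation` (lung mask replaced by ones) and `no_blur` (hard
   shape).
4. **Pretext training** (`lungpaste.model`, `lungpaste.train`) — a residual
   CNN backbone plus a 3-layer projection head classifies original (0) vs
   augmented (1) images, trained with SGD (lr 0.03, momentum 0.9, weight
   decay 3e-5, batch 64, cycle cosine annealing), checkpointed by validation
   AUC. Implemented in pure NumPy (manual backprop) so it runs anywhere;
   a `tiny` preset (64x64) trains in under a minute on one CPU, and a
   `resnet18` preset mirrors the 18-layer reference recipe at 256x256.
5. **Scoring and evaluation** (`lungpaste.scoring`, `lungpaste.metrics`) —
   anomaly score = -log of a unit-bandwidth Gaussian KDE of the query
   embedding against the normal-training embedding bank, min-max
   normalized; threshold chosen to maximize F1 on a labeled validation set;
   ROC/AUC, accuracy, F1 reporting; ensemble averaging of score sets.

## CLI

All stages are exposed under a single `lungpaste` entry point:

```bash
lungpaste synth --n-normal 50 --n-abnormal 10 --out data/ --seed 1 --size 256
lungpaste segment --in data/images --out masks/
lungpaste augment --in data/images --masks masks/ --out aug/ --mode full --seed 2
lungpaste train --train data/images --masks masks/ --val val/images \
    --val-labels val/labels.csv --preset tiny --out model.npz
lungpaste score --ckpt model.npz --train-bank data/images --in test/images --out scores.csv
lungpaste threshold --scores scores.csv --labels labels.csv --out decision.json
lungpaste evaluate --scores scores.csv --labels labels.csv --threshold 0.5 --out report.json
lungpaste run --config config.yaml --out results/    # full pipeline, one seed
```

`run` consumes a YAML mirroring `lungpaste.pipeline.PipelineConfig` and
writes `config.yaml`, `scores.csv`, `training_log.csv`, `report.json`, a
model checkpoint, and augmented preview PNGs — byte-identical across
invocations with the same config and seed.

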