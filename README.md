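# earcount

Counting wheat ears in field imagery by density-map-augmented instance
segmentation.

Estimating wheat yield starts with counting ears per unit area, and
field images make that hard: ears overlap, occlude each other, and share
color and texture with the surrounding canopy. `earcount` addresses the
dense-counting problem with a one-stage prototype/coefficient
segmentation network (YOLACT-style) extended in two ways:

1. **GeM-pooled attention.** Each backbone stage feeding the feature
   pyramid passes through a CBAM attention block in which every pooling
   operator is a generalized-mean (GeM) pool,
   `GeM_p(x) = ((1/(H·W)) Σ x_{i,j}^p)^{1/p}`, with learnable exponents
   initialized at p = 11 (channel branch) and p = 19 (spatial branch).
   p = 1 is average pooling; large p approaches max pooling.
2. **A density branch.** Ground truth for each image is a Gaussian
   density map, `D(a,b) = Σ_i (1/(2πσ²)) exp(−((a−a_i)² + (b−b_i)²)/(2σ²))`,
   whose total mass equals the ear count; a small head per FPN level
   regresses it under an MSE loss, and at inference the predicted
   density modulates detection confidence.

The training objective is the weighted sum
`L = 1·L_cla + 1.5·(L_obj + L_box) + 6.125·L_seg + w_d·L_density`.
Counting quality is reported as RMSE, Bias = mean(y − ŷ), and R²;
segmentation quality as mask mAP / mAP50 / mAP75 (101-point COCO
interpolation).

The package is aimed at plant-phenotyping researchers who want a fully
inspectable, CPU-runnable implementation of this method: every component
— annotation I/O (labelme/COCO polygons), density-map generation,
the network and its losses, the evaluation metrics, and a synthetic
field-scene generator for end-to-end testing — is plain numpy/scipy
Python, including a small built-in reverse-mode autodiff engine.

## Worked example

Train the desk-scale (`tiny`) model on 32 synthetic 128×128 field scenes
and count ears on 16 held-out scenes:

```python
from earcount.benchmark import run_smoke_benchmark

result = run_smoke_benchmark(seed=0)
print(f"loss {result.initial_loss:.2f} -> {result.final_loss:.2f}")
print(f"count threshold {result.count_threshold:.2f}")
m = result.test_metrics
print(f"held-out counting: RMSE {m.rmse:.2f}  Bias {m.bias:.2f}  R2 {m.r2:.3f}")
```

Output (200 SGD iterations, momentum 0.9, about 3 minutes on one CPU):

```
loss 10.24 -> 0.85
count threshold 0.10
held-out counting: RMSE 0.90  Bias 0.44  R2 0.912
```

Reading: the composite loss fell by ~92%; the detection-score threshold
0.10 was calibrated on the training scenes; on held-out scenes the
predicted counts are off by 0.9 ears RMS with a slight under-count
(Bias = mean(y − ŷ) > 0), explaining 91% of the count variance across
scenes with 5–15 ears. Results at this desk scale vary noticeably with
the seed.

The same pipeline is scriptable from the shell:

```bash
earcount synth --n 25 --size 128 --seed 0 --out-dir data/
earcount split --coco data/coco.json --seed 0 --out split.json
earcount train --config cfg.yaml --coco data/coco.json --image-dir data/ --out run/model.npz
earcount count --checkpoint run/model.npz --coco data/coco.json --image-dir data/ --out counts.csv
earcount evaluate --gt data/coco.json --pred results.json --out report.json
```

## Layout

- `src/earcount/annotations.py` — labelme/COCO polygon I/O, centroids,
  tiling, 8:1:1 splits
- `src/earcount/density.py` — Gaussian density maps, rescaling, MSE
- `src/earcount/attention.py` — GeM pooling and the GeM-CBAM block
- `src/earcount/model.py`, `losses.py`, `train.py`, `inference.py` —
  the network, composite loss, SGD training, prediction/NMS/counting
- `src/earcount/evaluation.py` — RMSE/Bias/R², mask IoU, AP/mAP,
  density-level stratification
- `src/earcount/synth.py` — seeded synthetic field scenes with exact
  polygon ground truth
- `src/earcount/nn/` — the numpy autodiff core and layers
- `docs/methods.md` — model details, parameter choices, limitations
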