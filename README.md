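# glottalmidline

Synthetic vocal-fold oscillations with a known glottal midline, and
the algorithms that try to find it.

## The problem

The vocal folds oscillate left/right-symmetrically in healthy
phonation. High-speed videoendoscopy quantifies this: the glottal area
(the opening between the folds) is segmented frame by frame, and a
**glottal midline** — the symmetry axis connecting the posterior point
*P* and the anterior point *A* — splits the area into the left and
right fold contributions, from which clinically relevant left/right
symmetry measures are derived. Evaluating midline detectors on
clinical data is circular: the "truth" is itself an annotation. This
package instead builds the midline benchmark on simulation, where the
axis is known by construction, and is aimed at researchers developing
or validating glottis-analysis pipelines.

It provides:

* a **six-mass lumped-element model** (three laterally moving masses
  per fold between fixed posterior/anterior anchors, coupled by
  anchor/coupling/tension springs, collision forces and a
  flow-modulated driving pressure) that produces symmetric and
  asymmetric self-sustained oscillations in the 100–220 Hz range and
  renders them into realistic binary segmentation-mask sequences
  (Chaikin-smoothed outlines, boundary-pixel dropout noise p = 0.5,
  examination motion as rigid rotation U[−30°, 30°] plus slow
  translation), with the ground-truth midline carried through every
  transform;
* **six classical midline detectors** — top/bottom-most points (TB),
  transposed linear regression (LR), orthogonal distance regression
  (ODR), PCA, image moments, and ellipse fitting — all operating on
  weighted images and returning *P*/*A* as the first/last intersection
  of their line with the segmented shape;
* **temporal-context aggregation**: glottal area waveform (GAW)
  computation, oscillation-maximum detection, and pixel-wise summation
  of the 2r+1 frames around each maximum, which weights pixels near
  the oscillation center and stabilises the symmetric estimators;
* the **evaluation harness**: point-wise MAPE
  (relative Euclidean distance |pred − gt|/|gt|) and the left/right
  split mIoU, `mIoU = ½[IoU(GT_l, P_l) + IoU(GT_r, P_r)]`;
* smoke-scale **neural reference models** (MidlineNet, a ConvLSTM
  variant, and the multi-task encoder–decoder GlottisNet) on a small
  numpy autodiff core.

## Worked example

```python
import numpy as np
from glottalmidline import (sample_config, simulate, render_sequence,
                            compute_gaw, detect_maxima, sum_frames,
                            DETECTORS, Midline, mape_point, miou_midline)

cfg = sample_config(rng_seed=42)          # random Q factors, both sides
traj = simulate(cfg)                      # RK4, 150 ms, first 85 ms dropped
seq = render_sequence(traj, cfg, rng_seed=42)
gaw = compute_gaw(seq)
peaks = detect_maxima(gaw)
peaks = peaks[(peaks >= 10) & (peaks < len(seq) - 10)]

peak = int(peaks[3])
image = sum_frames(seq, peak, half_range=10)      # 21-frame context
P, A = seq.gt_midline[peak]
gt = Midline(P=tuple(P), A=tuple(A))
for name, detect in DETECTORS.items():
    ml = detect(image)
    print(f"{name:8s} MAPE(A) = {mape_point(ml.A, A, euclidean=True):.3f}  "
          f"mIoU = {miou_midline(seq.masks[peak], gt, ml):.3f}")
```

prints (this sequence is moderately asymmetric, with a posterior gap
of 14 % of the fold length and a fundamental frequency near 148 Hz):

```
tb       MAPE(A) = 0.041  mIoU = 0.998
lr       MAPE(A) = 0.038  mIoU = 0.895
odr      MAPE(A) = 0.038  mIoU = 0.895
pca      MAPE(A) = 0.038  mIoU = 0.895
moments  MAPE(A) = 0.038  mIoU = 0.895
ellipse  MAPE(A) = 0.038  mIoU = 0.903
```

All six detectors place the anterior point within ~4 % relative
distance of the truth; the area split (mIoU) is where they differ —
here the TB heuristic splits this asymmetric glottis best, while the
principal-axis family (LR/ODR/PCA/moments/ellipse) is pulled slightly
toward the stronger fold even with temporal context.

There is also a CLI for batch work:

```bash
glottal-midline generate -n 50 --seed 0 -o data/        # masks + manifest
glottal-midline bench -n 250 --seed 0 -o results/       # full benchmark
glottal-midline toy -o results/                          # rotated-ellipse suite
glottal-midline report --records results/records.csv -o results/
```

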