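# dermoseg

Automatic border detection for pigmented skin lesions in dermoscopy images.

Delineating the lesion border is the first step of computer-aided melanoma
assessment: asymmetry, border irregularity and abrupt cutoff are all computed
from it, and human delineations suffer from inter- and intra-observer
variability. `dermoseg` implements two independent segmentation frameworks
plus the evaluation machinery to compare them against a reference border —
and a synthetic phantom generator so the whole system can be exercised and
tested without patient images.

## The two methods

**Exact-solution active contour (ACM).** The image is sharpened with a 3×3
high-boost mask parameterized by integers (A, B, C),

```
        -B      -C      -B
        -C   A+4B+4C    -C          (entry sum = A)
        -B      -C      -B
```

built from A·f − B·(diagonal directional derivatives) − C·∇²f with two-node
differences. With the default (A, B, C) = (6, 0, 1) flat regions saturate
white while strong edges survive as narrow intensity valleys — the
background becomes homogeneous and most artifacts vanish. A closed contour
then evolves by the exact first-harmonic solution of the geometric heat flow
r_t = r_ss on the parameter circle,

```
r(s, t) = c + e^{−t} (a₀ cos s, b₀ sin s),
```

an ellipse inscribed in the image that shrinks exponentially toward its
center. Each of the N = ⌈perimeter⌉ contour points freezes permanently once
the (bilinearly sampled) filtered intensity at its next position departs
from the background reference by more than τ (default 30 gray levels); the
frozen points trace the lesion border.

**Boundary-driven density-based clustering (BD-DBSCAN).** The image is
converted to HSL lightness ((min+max)/2 of the RGB channels), binarized with
the iterative intermeans (Ridler–Calvard) threshold
T ← ⌊(μ₁ + μ₂)/2⌋, and the dark (lesion) pixels are clustered with a
density algorithm using radius R = 5 and minimum population MP = 60.
Unlike classic DBSCAN, which fires one region query per cluster member, the
boundary-driven variant maintains an explicit polygonal cluster boundary
(outer polygon plus holes — the donut case) as the union of the convex
hulls of accepted queries, and skips the query of any member whose closed
R-ball provably lies inside the covered region. The pruning is lossless —
the partition equals classic DBSCAN's — and skips the large majority of
queries on compact lesions. The largest cluster becomes the lesion mask.

**Evaluation.** Masks are scored with the XOR border error
`Area(auto ⊕ manual)/Area(manual) = (FP+FN)/(TP+FN)`, plus precision,
recall and accuracy.

## Worked example

```python
import dermoseg as d
from dermoseg import acm

# synthetic dermoscopy image: dark irregular lesion on light skin,
# Gaussian noise (sigma 10), 5 hairs, 5 bubbles, plus exact ground truth
img, gt = d.make_phantom(d.preset_spec("noisy", seed=7))

contour, acm_mask = acm.run_acm(img)
print(d.evaluate_masks(acm_mask, gt))

gray = d.to_lightness_gray(img)
thr = d.intermeans_threshold(d.compute_histogram(gray))
binary = d.binarize(gray, thr)
ps = d.PointSet.from_mask(binary)
labeling = d.run_bd_dbscan(ps)
bd_mask = d.labeling_to_mask(labeling, ps, nc=600, nr=400)
print(d.evaluate_masks(bd_mask, gt))
```

prints (abridged):

```
ACM:        border_error=0.0175  precision=0.985  recall=0.998
intermeans threshold T=110 (mu1=40.9, mu2=179.6)
BD-DBSCAN:  47703 points, 1 cluster, 7843 queries   # 84% of queries pruned
BD-DBSCAN:  border_error=0.0091  precision=1.000  recall=0.991
```

Both methods recover the lesion to within ~1–2% border error on this
phantom. The characteristic difference is visible in the precision/recall
split: BD-DBSCAN trims the lesion slightly (precision 1.0, recall 0.99),
while the contour hugs it from outside (recall ~1.0, precision slightly
lower).

The clustering core is also available as a scikit-learn estimator:

```python
from dermoseg import BoundaryDrivenDBSCAN
labels = BoundaryDrivenDBSCAN(radius=5, min_points=60).fit_predict(ps.points)
```

## Command line

```
dermoseg phantom --preset noisy --seed 7 --out img.png --gt gt.png
dermoseg segment acm img.png -o mask_acm.png
dermoseg segment bddbscan img.png -o mask_bd.png --radius 5 --minpts 60
dermoseg evaluate --auto mask_bd.png --manual gt.png --json report.json
dermoseg batch DIR --method bddbscan --csv table.csv
```

`batch` evaluates every `*_img.png` / `*_gt.png` pair in a directory and
writes a per-image table with min/max/mean/stdev summary rows, so a user
with their own dermoscopy images and reference borders can reproduce a
like-for-like method comparison.

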