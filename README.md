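# kinetrack

Motion-feature extraction, colour-histogram tracking and eigen-subspace
injury classification for activity video — the image-analysis core of a
student physical-health monitoring workflow, packaged as a reusable library
with a CLI.

It is aimed at researchers who need the classical building blocks of such a
system as tested, composable operations rather than an opaque deployed
application: per-pixel Gaussian-mixture background subtraction, image-moment
shape features, CAMSHIFT tracking with a colour-marker fallback, an
eigen-subspace ("eigenfaces"-style) nearest-neighbour classifier for injury
patterns, and graph-convolutional management of per-detection features.
Because real classroom/sports footage of this kind is not publicly
available, the package ships a seeded synthetic-scene generator with full
ground truth (masks, trajectories, marker centroids, class labels) that all
recovery tests run against.

## The models

**Grayscale and moments.** Frames are converted with
`Gray = 0.299 R + 0.587 G + 0.114 B`, smoothed by a separable low-pass
kernel, and shapes are summarized by central moments
`E_pq = Σ (x−x̄)^p (y−ȳ)^q D(x,y)` and their scale-normalized form
`η_pq = E_pq / E_00^γ`, `γ = (p+q)/2 + 1` for `p+q ∈ {2,3,4}`.

**Background.** Each pixel's gray history is a K-component Gaussian mixture
maintained with the classic online recursion (match at 2.5 σ, learning rate
α, replace-weakest on no match, weights renormalized to Σ_k w = 1 every
step). Foreground is the thresholded difference against the reconstructed
background, cleaned by one 3×3 morphological opening.

**Tracking.** The target is a kernel-weighted colour histogram
`p_u = I_h Σ_i k(‖(y−x_i)/h‖²) δ(b(x_i)−u)` over hue bins with an
Epanechnikov profile; back-projection replaces each pixel by `p_{b(x)}` and
the window climbs it by mean shift, adapting its size to the weight
distribution's second moments (CAMSHIFT). If the windowed density collapses,
the tracker re-seeds on the nearest saturated-red marker worn by the target.

**Injury analysis.** Damage regions are localized by a greedy active
contour minimizing `E = a·E_in + β·E_es` (stretching/bending vs. gradient
attraction); damage images are classified by projecting onto the leading
eigenvectors of the training covariance — kept until 60 % of the eigenvalue
mass — and taking the Euclidean nearest neighbour in coefficient space.

**Feature management.** Detections become nodes of a temporal/spatial
graph; features propagate through
`h^l = σ(D^{-1/2}(A+I)D^{-1/2} h^{l-1} W^{l-1})`, the first-order form of
spectral filtering `U g(Λ) Uᵀ x` on the normalized Laplacian.

## Worked example

```python
import numpy as np
from kinetrack import synthetic, tracker

cfg = synthetic.default_scene_config(seed=0)      # 64x64, 40 frames, 1 blob
seq, gt = synthetic.make_scene(cfg)
trk = tracker.track(seq, tracker.SearchWindow(tuple(gt.trajectories[0, 0]),
                                              cfg.blobs[0].axes))
err = trk.centers() - gt.trajectories[0]
print("track RMSE (px):", round(float(np.sqrt((err**2).sum(axis=1).mean())), 3))
print("reinit events:", trk.reinit_events)
```

prints

```
track RMSE (px): 0.289
reinit events: []
```

— the window stays within a third of a pixel of the true blob centre and the
red-marker fallback never needs to fire on the clean default scene. Running
the background model with 30 blob-free warm-up frames on the same scene
yields a mean foreground IoU of 0.81 against the ground-truth masks, and the
eigen-subspace classifier keeps 4 of 30 training components at the default
0.60 retention and classifies all 15 held-out gallery images correctly
(accuracy 1.0).

The same steps are available from the shell:

```
kinetrack simulate --out scene --seed 0
kinetrack track --frames scene/frames --init 32,12,10,6 --out track.csv
kinetrack run --out full_run --seed 0        # the whole pipeline
```

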