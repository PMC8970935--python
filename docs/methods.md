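# Methods

This note records the models implemented in `kinetrack`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic test
conditions do and do not demonstrate.

## Synthetic scenes

The generator renders a static background (uniform gray 0.5 plus a fixed
per-pixel texture draw, σ = 0.05) and axis-aligned elliptical "person"
blobs moving at constant velocity, each optionally carrying a small
saturated-red disc marker at a fixed body offset. Per-frame i.i.d. Gaussian
noise (σ = 0.01) is added after rendering and clipped to [0, 1]; ground
truth (masks, blob trajectories, marker centroids) is computed from the
noise-free render. The default scene is 64×64 with 40 frames and one
blue-clad blob (semi-axes 10×6 px, gray level ≈ 0.33) drifting one pixel
per frame — small enough that every test and the full pipeline run in
seconds on one core, large enough that the blob, marker and background are
resolved at realistic contrast. Occlusion is by draw order; blob
trajectories are validated to stay at least one semi-axis inside the frame.

What the scenes do **not** emulate: articulated or deforming bodies, camera
motion, illumination changes, shadows, compression artifacts, or multiple
interacting targets of the same colour. Passing the recovery tests
demonstrates correctness of the algorithms under their model assumptions,
not field performance on real footage.

The damage gallery is a separate fixture: each class is a Gaussian bright
spot (amplitude = `class_separation`, default 0.5) at a class-specific
position along a vertical limb — evoking hip/knee/ankle injury sites — plus
pixel noise (σ = 0.1, i.e. separation is 5× the noise). With
`class_separation = 0` all classes collapse to one template, the
classifier's worst case.

## Image preprocessing and moments

Grayscale uses the ITU-601 luminance weights 0.299/0.587/0.114, which sum
to one, so gray values stay in [0, 1] and achromatic pixels are fixed
points. Smoothing is separable convolution with a normalized Haar-like tap
set [1, 2, 1]/4 (any odd, finite tap vector is accepted); boundaries are
reflect-padded, a choice with no data-dependent effect.

Central moments are computed about the mass centroid for all orders
`p + q ≤ max_order`; the weight grid may be a gray image or a binary mask —
both are legitimate mass distributions and the operations are agnostic.
Normalized moments `η_pq = E_pq / E_00^γ` with `γ = (p+q)/2 + 1` are
defined only for `p + q ∈ {2, 3, 4}`; other orders raise rather than
extrapolate. η is exactly invariant under continuous rescaling and
approximately (≈ 5 %) under ×2 integer upsampling of discrete masks, which
is what the property test asserts.

## Background model

Per-pixel scalar (gray) mixtures with K = 3 components; colour is not
modelled because the pipeline converts to gray before background
estimation. The online update is the standard recursion: a value matches a
component within 2.5 σ; the best match (largest w/σ) takes
`w ← (1−α)w + α`, `μ ← (1−α)μ + αx`, `σ² ← (1−α)σ² + α(x−μ)²` with
α = 0.05; unmatched weights decay; on no match the weakest component is
replaced by (x, σ² = 0.04, w = 0.05); weights renormalize to sum 1 every
step and variances are floored at 1e-4 (σ = 0.01, the frame-noise scale).
The mean/variance adaptation rate is α itself — the hard-assignment
responsibility of the matched component is 1.

The background image is the mean of each pixel's dominant (top-w/σ)
component; that component is by construction within any background fraction
T > 0 of cumulative weight, so the T parameter is retained in the state for
completeness but does not change the reconstruction. Foreground is
`|frame − background| > 0.1` followed by a single morphological opening
with the 3×3 cross (4-connected) structuring element — the cross, rather
than the full square, removes isolated speckle without eroding thin parts
of legitimately ragged blob masks.

Known limitation: when a dark background-texture pixel happens to sit near
the blob's gray level the difference test cannot separate them, so
individual frames can dip in IoU; the scene-level mean IoU is the
meaningful summary and is what the acceptance property asserts.

## Tracking

Colour binning uses the HSV hue channel, 16 bins, with pixels of saturation
< 0.1 routed to a dedicated achromatic bin so the gray background cannot
contaminate the colour bins. The target model is the kernel-weighted
histogram with Epanechnikov profile `k(r) = max(0, 1 − r)` evaluated at
squared normalized distance, bandwidth h = the window half-diagonal (every
window pixel contributes), normalized to sum to one.

Two refinements stabilize the stock algorithm, both defaults in
`TrackParams`:

- **Achromatic suppression.** The model built from the initial window
  inevitably contains achromatic mass from the window corners; back-projected
  over the whole frame it assigns that probability to every background
  pixel, biasing centroids. When the dominant model bin is chromatic, the
  achromatic bin is zeroed and the model renormalized.
- **Inflated measurement window.** Second moments measured inside a window
  that truncates the target systematically underestimate its extent and
  make the window shrink and drift. After mean-shift convergence, size and
  centre are re-measured on the window grown by 1.5×.

Window size is set by inverting the discrete uniform-window second moment:
`h' = (√(12·M₂/M₀ + 1) − 1)/2`, which makes a constant-weight window an
*exact* fixed point — a property a plain `c·√M₀` rule cannot have for any
constant c — while still growing and shrinking with the target. Mean-shift
centroid moves are accepted only if the windowed mass does not decrease, so
the ascent property holds by construction even on discrete pixel grids;
iteration stops at a centre shift below 0.5 px or 20 iterations.

Track confidence is the mean back-projection weight inside the window (the
zeroth-moment density), which is invariant to the adaptive window size.
When confidence drops below 0.3 of its initial value (or the window loses
all mass), red pixels (hue within ±15° of 0°, saturation ≥ 0.5, value
≥ 0.3) are labelled into 8-connected components and the window re-seeds on
the marker centroid nearest the last confident position, ties broken by
larger area; the frame index is recorded as a re-initialization event. The
0.3 trigger is a free design choice; it fires promptly on a teleported
target without false-triggering on the clean default scene.

## Damage localization and classification

The snake energy is `E = a·E_in + β·E_es` with
`E_in = Σ‖p_{t+1}−p_t‖² + Σ‖p_{t+1}−2p_t+p_{t−1}‖²` over the closed
polygon and `E_es = −Σ |∇Gray|` bilinearly sampled at the points; the image
enters the objective purely through its gradient-magnitude field.
Minimization is greedy coordinate descent — each point takes the best of
its 3×3 neighbourhood at spacing `step`, full passes until no move or
`max_iter` — so the energy trace is non-increasing by construction. The
external force only reaches as far as the image gradient does: hard binary
edges have a capture range of about one pixel, so localization from a few
pixels away expects a smoothed edge map (e.g. the output of the separable
low-pass filter, or a Gaussian-blurred intensity image); the convergence
test contracts a circle initialized 3 px outside a σ = 2-blurred disc and
lands within 0.4 px mean radial error using a = 0.01, β = 5. No acceptance
threshold gates the result; the contract is descent, not detection.

The subspace classifier flattens images, subtracts the mean, and
eigendecomposes the 1/(m−1) sample covariance — via the m×m Gram matrix
when the pixel dimension exceeds the sample count, mapping eigenvectors
back to pixel space and normalizing. Eigenpairs are sorted descending;
numerically zero eigenvalues are dropped (relative threshold 1e-10, plus a
data-scale test that returns an explicitly empty subspace, with a warning,
for identical training samples). Retention keeps the smallest k whose
cumulative eigenvalue mass reaches the retention fraction, default 0.60 —
read as mass coverage, not 60 % of the component count, since the point is
to preserve most of the gallery's variance. Projection centres on the mean
(`y = Uᵀ(x − u)`); without centring the first component degenerates to the
mean direction. Classification is Euclidean nearest neighbour in
coefficient space, ties to the lowest gallery index.

## Graph feature management

Detections (track, frame) are nodes; consecutive frames of a track are
linked, and detections of different tracks in the same frame are linked
when their window centres fall within `radius` (default 20 px). Propagation
uses `D^{-1/2}(A+I)D^{-1/2}` — self-loops are added before normalization so
isolated nodes have well-defined degree, and the operator's spectrum lies
in [−1, 1]. The spectral route `U g(Λ) Uᵀ x` on
`L = I − D^{-1/2}(A+I)D^{-1/2}` reproduces the propagation product exactly
at `g(λ) = 1 − λ`, which the tests assert as the spatial/spectral
equivalence. Layer weights are user-supplied or seeded-random; the default
activation is the identity so algebraic tests are exact, with ReLU
available. No training loop exists — the module manages and propagates
features deterministically; it does not fit anything.

## Pipeline

Processing is batch/offline. The default run simulates the stock scene,
warms the background model on 30 blob-free frames, writes per-frame masks,
moment features of the masks, a single-target track (initialized from the
ground-truth position, or from `init_window` for external footage), a
damage-classification report on the synthetic gallery, and GCN embeddings
of the track's detections. `validate_config` returns either the typed
config or the complete list of violations; all randomness flows from the
config seed, and two runs with identical configs produce byte-identical
CSV/JSON data outputs (the run report additionally contains wall-clock
timings and is excluded from that guarantee).

Problem sizes throughout (64×64 frames, 40-frame sequences, 16×16 gallery
images, ≤ 300-sample covariance checks) were chosen so the entire suite and
the acceptance script complete in seconds while every statistic they
compute is comfortably away from its pass/fail boundary.
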