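"""Per-pixel Gaussian-mixture background modelling and foreground masks.

Each pixel's gray-level history is modelled by a K-component mixture kept
up to date with the classic online recursion: a new value matches a
component if it lies within ``match_threshold`` standard deviations of its
mean; matched components gain weight and drift toward the value, unmatched
ones decay, and when nothing matches the weakest component is replaced by a
fresh wide component centred on the value.  Weights are renormalized to sum
to one at every pixel after every update.  The background image is read off
the dominant (highest weight/sigma) components; foreground is the
thresholded difference between a frame and that background, cleaned with a
single 3x3 morphological opening.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage


@dataclass
class GMMParams:
    """Mixture hyperparameters on the [0, 1] gray scale.

    ``learning_rate`` is the exponential forgetting factor alpha;
    ``match_threshold`` is in standard deviations; ``background_fraction``
    is the cumulative-weight share treated as background.
    """

    learning_rate: float = 0.05
    match_threshold: float = 2.5
    background_fraction: float = 0.7
    init_variance: float = 0.01
    replace_variance: float = 0.04
    replace_weight: float = 0.05
    variance_floor: float = 1e-4

    def validate(self) -> None:
        if not 0.0 < self.learning_rate < 1.0:
            raise ValueError("learning_rate: must be in (0, 1)")
        if self.match_threshold <= 0:
            raise ValueError("match_threshold: must be positive")
        if not 0.0 < self.background_fraction <= 1.0:
            raise ValueError("background_fraction: must be in (0, 1]")
        if self.variance_floor <= 0:
            raise ValueError("variance_floor: must be positive")


@dataclass
class PixelGMM:
    """Per-pixel mixture state: (H, W, K) weights, means and variances."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    params: GMMParams

    @property
    def K(self) -> int:
        return self.weights.shape[-1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.weights.shape[:2]


@dataclass
class ForegroundMask:
    mask: np.ndarray
    frame_index: int = -1


def init_gmm(first_frame: np.ndarray, K: int = 3,
             params: GMMParams | None = None) -> PixelGMM:
    """Initialize the mixture from the first frame.

    Component 0 takes the pixel value with weight 1; the remaining
    components start empty (weight 0, mean 0, variance at the floor).
    """
    if K < 1:
        raise ValueError("K: need at least one component")
    params = params or GMMParams()
    params.validate()
    frame = np.asarray(first_frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("first_frame: expected a 2-D gray frame")
    h, w = frame.shape
    weights = np.zeros((h, w, K))
    means = np.zeros((h, w, K))
    variances = np.full((h, w, K), params.variance_floor)
    weights[..., 0] = 1.0
    means[..., 0] = frame
    variances[..., 0] = params.init_variance
    return PixelGMM(weights=weights, means=means, variances=variances, params=params)


def update_gmm(model: PixelGMM, frame: np.ndarray) -> PixelGMM:
    """One online update step; modifies and returns ``model``.

    Per pixel: the best-matching component (largest weight/sigma among those
    within ``match_threshold`` sigma of the value) absorbs the observation at
    rate alpha, other weights decay by (1 - alpha); with no match the weakest
    component is replaced.  Weights are renormalized so they sum to 1.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != model.frame_shape:
        raise ValueError(f"frame: shape {frame.shape} does not match model "
                         f"{model.frame_shape}")
    p = model.params
    alpha = p.learning_rate
    w, mu, var = model.weights, model.means, model.variances
    x = frame[..., None]

    sigma = np.sqrt(var)
    match = np.abs(x - mu) <= p.match_threshold * sigma
    score = w / sigma
    any_match = match.any(axis=-1)
    # best matching component per pixel (undefined where no match; masked later)
    masked_score = np.where(match, score, -np.inf)
    best = np.argmax(masked_score, axis=-1)
    best_oh = np.eye(model.K, dtype=bool)[best]  # (H, W, K) one-hot

    # matched pixels: decay all weights, boost the winner, move it toward x
    upd = any_match[..., None]
    sel = upd & best_oh
    w_new = np.where(upd, (1 - alpha) * w, w)
    w_new = np.where(sel, w_new + alpha, w_new)
    mu_new = np.where(sel, (1 - alpha) * mu + alpha * x, mu)
    var_new = np.where(sel, (1 - alpha) * var + alpha * (x - mu_new) ** 2, var)

    # unmatched pixels: replace the weakest component with a fresh one
    weakest = np.argmin(score, axis=-1)
    weak_oh = np.eye(model.K, dtype=bool)[weakest]
    rep = (~any_match[..., None]) & weak_oh
    w_new = np.where(rep, p.replace_weight, w_new)
    mu_new = np.where(rep, x, mu_new)
    var_new = np.where(rep, p.replace_variance, var_new)

    var_new = np.maximum(var_new, p.variance_floor)
    w_new = w_new / w_new.sum(axis=-1, keepdims=True)

    model.weights, model.means, model.variances = w_new, mu_new, var_new
    return model


def background_image(model: PixelGMM) -> np.ndarray:
    """Reconstruct the background as the mean of each pixel's dominant component.

    Components are ranked by weight/sigma; the top-ranked component is by
    construction inside the top ``background_fraction`` of cumulative weight,
    and its mean is the background estimate.
    """
    score = model.weights / np.sqrt(model.variances)
    top = np.argmax(score, axis=-1)
    return np.take_along_axis(model.means, top[..., None], axis=-1)[..., 0]


def foreground_mask(model: PixelGMM, frame: np.ndarray,
                    diff_threshold: float = 0.1,
                    frame_index: int = -1) -> ForegroundMask:
    """Threshold |frame - background| and clean with one 3x3 opening."""
    frame = np.asarray(frame, dtype=float)
    if frame.shape != model.frame_shape:
        raise ValueError(f"frame: shape {frame.shape} does not match model "
                         f"{model.frame_shape}")
    raw = np.abs(frame - background_image(model)) > diff_threshold
    # 3x3 cross (4-connected) structuring element: kills speckle without
    # eating thin parts of legitimate blobs
    structure = ndimage.generate_binary_structure(2, 1)
    cleaned = ndimage.binary_opening(raw, structure=structure)
    return ForegroundMask(mask=cleaned, frame_index=frame_index)


def save_model(model: PixelGMM, path: str | Path) -> None:
    """Persist mixture state as an .npz archive (weights, means, variances, params)."""
    p = model.params
    np.savez(Path(path), weights=model.weights, means=model.means,
             variances=model.variances,
             params=np.array([p.learning_rate, p.match_threshold,
                              p.background_fraction, p.init_variance,
                              p.replace_variance, p.replace_weight,
                              p.variance_floor]))


def load_model(path: str | Path) -> PixelGMM:
    data = np.load(Path(path))
    vals = data["params"]
    params = GMMParams(*[float(v) for v in vals])
    return PixelGMM(weights=data["weights"], means=data["means"],
                    variances=data["variances"], params=params)
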