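"""Kernel-histogram target model and CAMSHIFT window tracking.

The target is described by a kernel-weighted colour histogram

    p_u = I_h * sum_i k(||(y - x_i)/h||^2) * delta(b(x_i) - u)

over hue bins ``u`` (plus one achromatic bin for low-saturation pixels),
with ``y`` the window centre, ``h`` the window half-diagonal, an
Epanechnikov profile ``k(r) = max(0, 1 - r)``, and ``I_h`` the factor that
makes the bins sum to one.  Back-projection replaces each pixel with the
model probability of its bin; the search window then climbs the
back-projection by mean shift (centroid moves) and adapts its size to the
second moments of the weights.  When the windowed probability density
collapses — the target was lost — the tracker falls back on the saturated
red marker worn by the target: red pixels are clustered into connected
components and the window is re-seeded on the nearest marker centroid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import measure
from skimage.color import rgb2hsv

from .frames import FrameSequence


@dataclass
class SearchWindow:
    """Axis-aligned window: float centre (row, col) and half-extents in px."""

    center: tuple[float, float]
    half_extent: tuple[float, float]

    def bounds(self, shape: tuple[int, int]) -> tuple[int, int, int, int]:
        """Inclusive integer (r0, r1, c0, c1) clipped to the frame."""
        cr, cc = self.center
        hr, hc = self.half_extent
        r0 = max(0, int(round(cr - hr)))
        r1 = min(shape[0] - 1, int(round(cr + hr)))
        c0 = max(0, int(round(cc - hc)))
        c1 = min(shape[1] - 1, int(round(cc + hc)))
        return r0, r1, c0, c1

    def is_empty(self, shape: tuple[int, int]) -> bool:
        r0, r1, c0, c1 = self.bounds(shape)
        return r0 > r1 or c0 > c1


@dataclass
class TargetModel:
    p_u: np.ndarray  # normalized histogram, length n_bins + 1 (achromatic last)
    n_bins: int
    bandwidth: float  # kernel bandwidth h (window half-diagonal)
    kernel: str = "epanechnikov"
    sat_threshold: float = 0.1

    @property
    def I_h(self) -> float:
        """Normalization factor actually applied (1 / unnormalized mass)."""
        return self._I_h

    _I_h: float = 1.0


@dataclass
class RedMarkerDetection:
    centroid: tuple[float, float]
    contour: np.ndarray  # ordered (row, col) boundary points
    area: int


@dataclass
class RedThresholds:
    """HSV gate for marker pixels: hue within +/-tol of 0/360 degrees."""

    hue_tol_deg: float = 15.0
    sat_min: float = 0.5
    val_min: float = 0.3


@dataclass
class TrackParams:
    n_bins: int = 16
    sat_threshold: float = 0.1
    kernel: str = "epanechnikov"
    max_iter: int = 20
    shift_tol: float = 0.5
    conf_ratio: float = 0.3
    min_marker_area: int = 4
    min_extent: float = 2.0
    adapt_size: bool = True
    # drop the achromatic bin from the working model when the target itself
    # is chromatic, so gray background in the window corners cannot pull the
    # centroid; ignored when the dominant model bin is the achromatic one
    suppress_achromatic: bool = True
    # measurement window inflation for size adaptation: second moments of a
    # window-truncated blob underestimate its extent, so size is measured on
    # a grown copy of the converged window
    grow_factor: float = 1.5
    red: RedThresholds = field(default_factory=RedThresholds)


@dataclass
class Track:
    windows: list[SearchWindow] = field(default_factory=list)
    confidences: list[float] = field(default_factory=list)
    reinit_events: list[int] = field(default_factory=list)

    def centers(self) -> np.ndarray:
        return np.array([w.center for w in self.windows])

    def to_csv(self, path: str | Path) -> None:
        rows = [{"frame": i, "row": w.center[0], "col": w.center[1],
                 "half_rows": w.half_extent[0], "half_cols": w.half_extent[1],
                 "confidence": self.confidences[i],
                 "reinit": int(i in self.reinit_events)}
                for i, w in enumerate(self.windows)]
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Track":
        df = pd.read_csv(path)
        track = cls()
        for _, r in df.iterrows():
            track.windows.append(SearchWindow((r["row"], r["col"]),
                                              (r["half_rows"], r["half_cols"])))
            track.confidences.append(float(r["confidence"]))
            if int(r["reinit"]):
                track.reinit_events.append(int(r["frame"]))
        return track


def bin_indices(frame: np.ndarray, n_bins: int = 16,
                sat_threshold: float = 0.1) -> np.ndarray:
    """Map each RGB pixel to a hue bin; low-saturation pixels go to bin n_bins."""
    hsv = rgb2hsv(np.clip(np.asarray(frame, dtype=float), 0.0, 1.0))
    bins = np.minimum((hsv[..., 0] * n_bins).astype(int), n_bins - 1)
    bins[hsv[..., 1] < sat_threshold] = n_bins
    return bins


def _kernel_profile(r2: np.ndarray, kernel: str) -> np.ndarray:
    if kernel == "epanechnikov":
        return np.maximum(0.0, 1.0 - r2)
    if kernel == "uniform":
        return (r2 < 1.0).astype(float)
    raise ValueError(f"kernel: unknown profile {kernel!r}")


def build_target_model(frame: np.ndarray, window: SearchWindow,
                       n_bins: int = 16, kernel: str = "epanechnikov",
                       sat_threshold: float = 0.1) -> TargetModel:
    """Kernel-weighted normalized colour histogram of the window contents."""
    frame = np.asarray(frame, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins: need at least 2 colour bins")
    shape = frame.shape[:2]
    if window.is_empty(shape):
        raise ValueError("window: empty after clipping to frame")
    r0, r1, c0, c1 = window.bounds(shape)
    h = math.hypot(*window.half_extent)
    rr, cc = np.mgrid[r0:r1 + 1, c0:c1 + 1]
    r2 = ((rr - window.center[0]) ** 2 + (cc - window.center[1]) ** 2) / h ** 2
    k = _kernel_profile(r2, kernel)
    bins = bin_indices(frame[r0:r1 + 1, c0:c1 + 1], n_bins, sat_threshold)
    hist = np.bincount(bins.ravel(), weights=k.ravel(), minlength=n_bins + 1)
    mass = hist.sum()
    if mass <= 0:
        raise ValueError("window: kernel mass is zero (degenerate window)")
    model = TargetModel(p_u=hist / mass, n_bins=n_bins, bandwidth=h,
                        kernel=kernel, sat_threshold=sat_threshold)
    model._I_h = 1.0 / mass
    return model


def backproject(frame: np.ndarray, model: TargetModel) -> np.ndarray:
    """Per-pixel weight image: each pixel gets p_u of its colour bin."""
    bins = bin_indices(frame, model.n_bins, model.sat_threshold)
    return model.p_u[bins]


def _window_moments(weights: np.ndarray, window: SearchWindow):
    r0, r1, c0, c1 = window.bounds(weights.shape)
    patch = weights[r0:r1 + 1, c0:c1 + 1]
    m00 = float(patch.sum())
    if m00 <= 0:
        return m00, None, None, None, None
    rr, cc = np.mgrid[r0:r1 + 1, c0:c1 + 1]
    r_bar = float((rr * patch).sum() / m00)
    c_bar = float((cc * patch).sum() / m00)
    mrr = float(((rr - r_bar) ** 2 * patch).sum())
    mcc = float(((cc - c_bar) ** 2 * patch).sum())
    return m00, r_bar, c_bar, mrr, mcc


def _extent_from_moment(m2: float, m00: float) -> float:
    # inverse of the discrete uniform-window second moment: a constant-weight
    # window of half-extent h has m2/m00 = h(h+1)/3, i.e. 12*m2/m00+1 = (2h+1)^2
    return (math.sqrt(12.0 * m2 / m00 + 1.0) - 1.0) / 2.0


def camshift_step(weights: np.ndarray, window: SearchWindow,
                  min_extent: float = 2.0,
                  adapt_size: bool = True) -> tuple[SearchWindow, bool]:
    """One CAMSHIFT step: re-centre on the windowed centroid, adapt size.

    Returns ``(new_window, lost)``; with zero windowed mass the window is
    returned unchanged and ``lost`` is True.  Size adaptation inverts the
    second moments of the weights so that a constant-weight window is a
    fixed point; extents are clamped to ``[min_extent, frame/2]``.
    """
    weights = np.asarray(weights, dtype=float)
    if window.is_empty(weights.shape):
        return window, True
    m00, r_bar, c_bar, mrr, mcc = _window_moments(weights, window)
    if m00 <= 0:
        return window, True
    hr, hc = window.half_extent
    if adapt_size:
        hr = _extent_from_moment(mrr, m00)
        hc = _extent_from_moment(mcc, m00)
        hr = min(max(hr, min_extent), weights.shape[0] / 2.0)
        hc = min(max(hc, min_extent), weights.shape[1] / 2.0)
    return SearchWindow(center=(r_bar, c_bar), half_extent=(hr, hc)), False


def mean_shift(weights: np.ndarray, window: SearchWindow,
               max_iter: int = 20, tol: float = 0.5):
    """Iterate centroid moves (fixed size) until convergence.

    A move that would decrease the windowed zeroth moment is rejected and
    iteration stops, so the mass sequence is non-decreasing by construction.
    Returns ``(window, lost, masses)`` with the per-iteration mass trace.
    """
    weights = np.asarray(weights, dtype=float)
    m00, r_bar, c_bar, _, _ = _window_moments(weights, window)
    if m00 <= 0:
        return window, True, [m00]
    masses = [m00]
    for _ in range(max_iter):
        cand = SearchWindow(center=(r_bar, c_bar), half_extent=window.half_extent)
        cand_m00 = _window_moments(weights, cand)[0]
        if cand_m00 < masses[-1] - 1e-12:
            break
        shift = math.hypot(cand.center[0] - window.center[0],
                           cand.center[1] - window.center[1])
        window = cand
        masses.append(cand_m00)
        m00, r_bar, c_bar, _, _ = _window_moments(weights, window)
        if shift < tol:
            break
    return window, False, masses


def detect_red_markers(frame: np.ndarray, thresholds: RedThresholds | None = None,
                       min_area: int = 4) -> list[RedMarkerDetection]:
    """Threshold red pixels, label 8-connected components, return markers.

    Detections of at least ``min_area`` pixels are returned sorted by area
    descending, each with its centroid and ordered boundary contour.
    """
    thresholds = thresholds or RedThresholds()
    hsv = rgb2hsv(np.clip(np.asarray(frame, dtype=float), 0.0, 1.0))
    hue_deg = hsv[..., 0] * 360.0
    red = ((hue_deg <= thresholds.hue_tol_deg)
           | (hue_deg >= 360.0 - thresholds.hue_tol_deg)) \
        & (hsv[..., 1] >= thresholds.sat_min) & (hsv[..., 2] >= thresholds.val_min)
    labels = measure.label(red, connectivity=2)
    out = []
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        comp = labels == region.label
        contours = measure.find_contours(comp.astype(float), 0.5)
        contour = max(contours, key=len) if contours else np.empty((0, 2))
        out.append(RedMarkerDetection(centroid=tuple(region.centroid),
                                      contour=contour, area=int(region.area)))
    out.sort(key=lambda d: -d.area)
    return out


def _confidence(weights: np.ndarray, window: SearchWindow) -> float:
    """Mean back-projection weight inside the window (mass density)."""
    r0, r1, c0, c1 = window.bounds(weights.shape)
    patch = weights[r0:r1 + 1, c0:c1 + 1]
    return float(patch.mean()) if patch.size else 0.0


def _locate(weights: np.ndarray, window: SearchWindow, params: TrackParams):
    window, lost, _ = mean_shift(weights, window, params.max_iter, params.shift_tol)
    if not lost and params.adapt_size:
        meas = SearchWindow(window.center,
                            (params.grow_factor * window.half_extent[0],
                             params.grow_factor * window.half_extent[1]))
        window, lost = camshift_step(weights, meas, params.min_extent, True)
    return window, lost


def track(frames: FrameSequence | list[np.ndarray], init_window: SearchWindow,
          params: TrackParams | None = None) -> Track:
    """Track a single target through the sequence with marker feedback.

    The colour model is built once on frame 0.  Per frame the window climbs
    the back-projection to convergence; if the windowed density drops below
    ``conf_ratio`` of its initial value (or the window loses all mass), the
    window is re-seeded on the red-marker centroid nearest the last
    confident position (ties broken by larger area) and the frame index is
    recorded as a re-initialization event.
    """
    frame_list = list(frames)
    if not frame_list:
        raise ValueError("frames: empty sequence")
    params = params or TrackParams()
    if init_window.is_empty(frame_list[0].shape[:2]):
        raise ValueError("init_window: empty after clipping to frame 0")
    model = build_target_model(frame_list[0], init_window, params.n_bins,
                               params.kernel, params.sat_threshold)
    if params.suppress_achromatic and int(np.argmax(model.p_u)) != model.n_bins:
        p = model.p_u.copy()
        p[model.n_bins] = 0.0
        model.p_u = p / p.sum()
    result = Track()
    window = init_window
    last_good = init_window.center
    init_conf = None
    for t, frame in enumerate(frame_list):
        bp = backproject(frame, model)
        window, lost = _locate(bp, window, params)
        conf = _confidence(bp, window)
        if init_conf is None:
            init_conf = conf
        if lost or conf < params.conf_ratio * init_conf:
            markers = detect_red_markers(frame, params.red, params.min_marker_area)
            if markers:
                markers.sort(key=lambda d: (
                    math.hypot(d.centroid[0] - last_good[0],
                               d.centroid[1] - last_good[1]), -d.area))
                window = SearchWindow(center=markers[0].centroid,
                                      half_extent=window.half_extent)
                window, lost = _locate(bp, window, params)
                conf = _confidence(bp, window)
                result.reinit_events.append(t)
        if conf >= params.conf_ratio * init_conf:
            last_good = window.center
        result.windows.append(window)
        result.confidences.append(conf)
    return result
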