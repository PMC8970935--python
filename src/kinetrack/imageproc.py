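"""Frame preprocessing and image-moment features.

Grayscale conversion uses the luminance weighting
``Gray = 0.299 R + 0.587 G + 0.114 B``; smoothing is a separable low-pass
filter (default a normalized [1, 2, 1]/4 tap set, the Haar-like scaling
filter); shape features are central moments about the mass centroid and
their scale-normalized form ``eta_pq = E_pq / E_00**gamma`` with
``gamma = (p+q)/2 + 1`` for orders ``p+q`` in {2, 3, 4}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

GRAY_WEIGHTS = (0.299, 0.587, 0.114)
NORMALIZED_ORDERS = (2, 3, 4)


@dataclass
class FilterKernel:
    """Separable 2-D smoothing kernel given by one tap vector.

    The 2-D kernel is the outer product of ``taps_1d`` with itself.
    """

    taps_1d: np.ndarray

    def __post_init__(self):
        self.taps_1d = np.asarray(self.taps_1d, dtype=float)
        if self.taps_1d.ndim != 1 or self.taps_1d.size < 1 or self.taps_1d.size % 2 == 0:
            raise ValueError("taps_1d: need an odd-length 1-D tap vector")
        if not np.all(np.isfinite(self.taps_1d)):
            raise ValueError("taps_1d: taps must be finite")

    @property
    def normalization(self) -> float:
        return float(self.taps_1d.sum())

    @classmethod
    def default(cls) -> "FilterKernel":
        return cls(np.array([1.0, 2.0, 1.0]) / 4.0)


@dataclass
class CentralMoments:
    mass: float  # E_00
    centroid: tuple[float, float]  # (row, col) mass centroid
    E_pq: dict[tuple[int, int], float] = field(default_factory=dict)


@dataclass
class NormalizedMoments:
    eta_pq: dict[tuple[int, int], float] = field(default_factory=dict)
    gamma_pq: dict[tuple[int, int], float] = field(default_factory=dict)


def to_gray(frame: np.ndarray) -> np.ndarray:
    """Convert an (H, W, 3) RGB frame in [0, 1] to grayscale.

    Per pixel ``Gray = 0.299 R + 0.587 G + 0.114 B``; the weights sum to 1,
    so the output stays in [0, 1] and equal-channel pixels map to themselves.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise ValueError(f"frame: expected 3 channels, got shape {frame.shape}")
    wr, wg, wb = GRAY_WEIGHTS
    return wr * frame[..., 0] + wg * frame[..., 1] + wb * frame[..., 2]


def filter_frame(frame: np.ndarray, kernel: FilterKernel | None = None) -> np.ndarray:
    """Smooth a gray frame with the separable kernel, reflect-padded.

    Equivalent to full 2-D convolution with the outer product
    ``taps ⊗ taps`` under symmetric boundary extension; same output shape.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0 or frame.ndim != 2:
        raise ValueError("frame: expected a nonempty 2-D gray frame")
    kernel = kernel or FilterKernel.default()
    out = ndimage.convolve1d(frame, kernel.taps_1d, axis=0, mode="reflect")
    return ndimage.convolve1d(out, kernel.taps_1d, axis=1, mode="reflect")


def central_moments(weights: np.ndarray, max_order: int = 4) -> CentralMoments:
    """Central moments ``E_pq = sum (r - r̄)^p (c - c̄)^q D(r, c)``.

    ``weights`` is any nonnegative weight grid — a gray image or a binary
    mask.  The centroid is the mass-weighted mean position; all orders with
    ``p + q <= max_order`` are stored.  Central moments of order >= 2 are
    invariant to integer translations of the pattern.
    """
    D = np.asarray(weights, dtype=float)
    if D.ndim != 2:
        raise ValueError("weights: expected a 2-D grid")
    if np.any(D < 0):
        raise ValueError("weights: must be nonnegative")
    mass = float(D.sum())
    if mass <= 0:
        raise ValueError("weights: zero total mass, moments undefined")
    rr, cc = np.mgrid[0:D.shape[0], 0:D.shape[1]]
    r_bar = float((rr * D).sum() / mass)
    c_bar = float((cc * D).sum() / mass)
    dr, dc = rr - r_bar, cc - c_bar
    moments: dict[tuple[int, int], float] = {}
    for p in range(max_order + 1):
        for q in range(max_order + 1 - p):
            moments[(p, q)] = float((dr ** p * dc ** q * D).sum())
    return CentralMoments(mass=mass, centroid=(r_bar, c_bar), E_pq=moments)


def gamma_exponent(p: int, q: int) -> float:
    """Normalization exponent gamma = (p+q)/2 + 1, defined for p+q in {2,3,4}."""
    if (p + q) not in NORMALIZED_ORDERS:
        raise ValueError(f"gamma is defined only for p+q in {NORMALIZED_ORDERS}, "
                         f"got p+q={p + q}")
    return (p + q) / 2.0 + 1.0


def normalized_moments(m: CentralMoments) -> NormalizedMoments:
    """Scale-normalized moments ``eta_pq = E_pq / E_00**gamma``.

    Computed for every stored pair with ``p + q`` in {2, 3, 4}; eta is
    approximately invariant to spatial rescaling of the pattern.
    """
    if m.mass <= 0:
        raise ValueError("moments: E_00 must be positive")
    out = NormalizedMoments()
    for (p, q), e in m.E_pq.items():
        if (p + q) not in NORMALIZED_ORDERS:
            continue
        g = gamma_exponent(p, q)
        out.gamma_pq[(p, q)] = g
        out.eta_pq[(p, q)] = e / m.mass ** g
    if not out.eta_pq:
        raise ValueError("moments: no stored pairs with p+q in {2, 3, 4}; "
                         "compute central_moments with max_order >= 2")
    return out


def moments_to_json(m: CentralMoments, nm: NormalizedMoments | None = None,
                    path: str | Path | None = None) -> dict:
    """Export moments keyed ``"p_q"``; optionally write the JSON to ``path``."""
    doc = {
        "mass": m.mass,
        "centroid": list(m.centroid),
        "E": {f"{p}_{q}": v for (p, q), v in sorted(m.E_pq.items())},
    }
    if nm is not None:
        doc["eta"] = {f"{p}_{q}": v for (p, q), v in sorted(nm.eta_pq.items())}
        doc["gamma"] = {f"{p}_{q}": v for (p, q), v in sorted(nm.gamma_pq.items())}
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(doc, indent=2))
    return doc
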