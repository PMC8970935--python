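"""Injury-region localization and eigen-subspace damage classification.

Localization uses a closed active contour ("snake") minimizing

    E(C) = a * E_in(C) + beta * E_es(C)

where the internal term penalizes stretching and bending,
``E_in = sum ||p_{t+1} - p_t||^2 + sum ||p_{t+1} - 2 p_t + p_{t-1}||^2``
(indices wrap), and the external term attracts the contour to edges of the
gray image, ``E_es = -sum |grad Gray|`` sampled at the contour points by
bilinear interpolation.  Minimization is greedy: each point in turn moves
to the lowest-energy position in its 3x3 neighbourhood, so the energy never
increases.

Classification is eigen-subspace nearest neighbour: training images are
flattened, the mean ``u = (1/m) sum x_i`` is subtracted, the sample
covariance is eigendecomposed (via the small Gram matrix when the pixel
dimension exceeds the sample count), eigenpairs are kept in decreasing
order until their cumulative eigenvalue mass reaches the retention fraction
(default 0.60), queries are projected as ``y = U^T (x - u)`` and labelled
by the Euclidean-nearest gallery coefficient vector.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

DEFAULT_RETENTION = 0.60


@dataclass
class ContourModel:
    """Closed contour: ordered (row, col) points plus energy weights a, beta."""

    points: np.ndarray
    a: float = 0.1
    beta: float = 1.0

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 4:
            raise ValueError("points: need >= 4 (row, col) points")
        if np.any(np.all(self.points[1:] == self.points[:-1], axis=1)):
            raise ValueError("points: duplicate consecutive points")


@dataclass
class EigenSubspace:
    mean: np.ndarray  # flattened mean image u
    eigenvalues: np.ndarray  # retained, descending
    eigenvectors: np.ndarray  # (d, k) orthonormal columns U
    retention: float
    image_shape: tuple[int, int]

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[1]


@dataclass
class Gallery:
    coefficients: np.ndarray  # (n, k) projected training vectors
    labels: np.ndarray

    def __post_init__(self):
        if len(self.coefficients) != len(self.labels):
            raise ValueError("gallery: one coefficient vector per label required")


def _gradient_magnitude(gray: np.ndarray) -> np.ndarray:
    gr, gc = np.gradient(np.asarray(gray, dtype=float))
    return np.hypot(gr, gc)


def _check_inside(points: np.ndarray, shape: tuple[int, int]) -> None:
    if (np.any(points[:, 0] < 0) or np.any(points[:, 0] > shape[0] - 1)
            or np.any(points[:, 1] < 0) or np.any(points[:, 1] > shape[1] - 1)):
        raise ValueError("contour: points outside the frame")


def _internal_energy(points: np.ndarray) -> float:
    d1 = np.roll(points, -1, axis=0) - points
    d2 = np.roll(points, -1, axis=0) - 2 * points + np.roll(points, 1, axis=0)
    return float((d1 ** 2).sum() + (d2 ** 2).sum())


def _external_energy(points: np.ndarray, grad_mag: np.ndarray) -> float:
    vals = ndimage.map_coordinates(grad_mag, points.T, order=1, mode="nearest")
    return float(-vals.sum())


def snake_energy(contour: ContourModel, gray: np.ndarray) -> float:
    """Total snake energy a*E_in + beta*E_es of a closed contour on a gray frame."""
    gray = np.asarray(gray, dtype=float)
    _check_inside(contour.points, gray.shape)
    if contour.a == 0.0 and contour.beta == 0.0:
        return 0.0
    e_in = _internal_energy(contour.points) if contour.a != 0.0 else 0.0
    e_es = _external_energy(contour.points, _gradient_magnitude(gray)) \
        if contour.beta != 0.0 else 0.0
    return contour.a * e_in + contour.beta * e_es


def localize_damage(gray: np.ndarray, init: ContourModel, max_iter: int = 100,
                    step: float = 1.0) -> ContourModel:
    """Greedy snake descent from ``init``; returns the relaxed contour.

    Each full pass moves every point to the lowest-energy position among
    its 3x3 neighbourhood at spacing ``step`` (candidates clamped inside the
    frame); passes repeat until no point moves or ``max_iter``.  The final
    energy never exceeds the initial energy.
    """
    gray = np.asarray(gray, dtype=float)
    _check_inside(init.points, gray.shape)
    grad_mag = _gradient_magnitude(gray)
    pts = init.points.copy()
    a, beta = init.a, init.beta

    def total(p):
        return a * _internal_energy(p) + beta * _external_energy(p, grad_mag)

    offsets = [(dr, dc) for dr in (-step, 0.0, step) for dc in (-step, 0.0, step)]
    energy = total(pts)
    for _ in range(max_iter):
        moved = False
        for i in range(len(pts)):
            best_e, best_pt = energy, pts[i].copy()
            orig = pts[i].copy()
            for dr, dc in offsets:
                if dr == 0.0 and dc == 0.0:
                    continue
                cand = (min(max(orig[0] + dr, 0.0), gray.shape[0] - 1.0),
                        min(max(orig[1] + dc, 0.0), gray.shape[1] - 1.0))
                pts[i] = cand
                e = total(pts)
                if e < best_e - 1e-12:
                    best_e, best_pt = e, np.array(cand)
            pts[i] = best_pt
            if best_e < energy - 1e-12:
                energy = best_e
                moved = True
        if not moved:
            break
    return ContourModel(points=pts, a=a, beta=beta)


def fit_subspace(samples: list[np.ndarray],
                 retention: float = DEFAULT_RETENTION) -> EigenSubspace:
    """Fit the eigen-subspace of a gallery of equally shaped gray images.

    Uses 1/(m-1) covariance normalization; eigenpairs sorted descending,
    zero eigenvalues dropped, and the smallest k kept whose cumulative
    eigenvalue mass reaches ``retention`` of the total.
    """
    if len(samples) < 2:
        raise ValueError("samples: need at least 2 training images")
    if not 0.0 < retention <= 1.0:
        raise ValueError("retention: must be in (0, 1]")
    shape = np.asarray(samples[0]).shape
    X = np.stack([np.asarray(s, dtype=float).ravel() for s in samples])
    if any(np.asarray(s).shape != shape for s in samples):
        raise ValueError("samples: all images must share one shape")
    m, d = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean
    if d > m:
        # Gram trick: eigenvectors of (Xc Xc^T)/(m-1) map into pixel space
        gram = Xc @ Xc.T / (m - 1)
        lam, V = np.linalg.eigh(gram)
        order = np.argsort(lam)[::-1]
        lam, V = lam[order], V[:, order]
        keep = lam > max(lam.max(), 0.0) * 1e-10 if lam.size else lam > 0
        lam, V = lam[keep], V[:, keep]
        U = Xc.T @ V
        if lam.size:
            U /= np.sqrt(lam * (m - 1))
    else:
        cov = Xc.T @ Xc / (m - 1)
        lam, U = np.linalg.eigh(cov)
        order = np.argsort(lam)[::-1]
        lam, U = lam[order], U[:, order]
        keep = lam > max(lam.max(), 0.0) * 1e-10 if lam.size else lam > 0
        lam, U = lam[keep], U[:, keep]
    # floating residue of mean subtraction can leave ~eps "variance" even for
    # identical samples; judge degeneracy on the scale of the data itself
    if lam.size and lam.sum() <= 1e-12 * max(1.0, float((mean ** 2).sum())):
        lam = np.empty(0)
        U = np.empty((d, 0))
    if lam.size == 0:
        warnings.warn("all training samples identical: empty eigen-subspace")
        return EigenSubspace(mean=mean, eigenvalues=np.empty(0),
                             eigenvectors=np.empty((d, 0)), retention=retention,
                             image_shape=tuple(shape))
    cum = np.cumsum(lam) / lam.sum()
    k = int(np.searchsorted(cum, retention - 1e-12) + 1)
    return EigenSubspace(mean=mean, eigenvalues=lam[:k], eigenvectors=U[:, :k],
                         retention=retention, image_shape=tuple(shape))


def project(sample: np.ndarray, subspace: EigenSubspace) -> np.ndarray:
    """Project a gray image onto the subspace: y = U^T (x - mean)."""
    x = np.asarray(sample, dtype=float)
    if x.shape != subspace.image_shape:
        raise ValueError(f"sample: shape {x.shape} does not match training shape "
                         f"{subspace.image_shape}")
    return subspace.eigenvectors.T @ (x.ravel() - subspace.mean)


def build_gallery(samples: list[np.ndarray], labels,
                  subspace: EigenSubspace) -> Gallery:
    coeffs = np.stack([project(s, subspace) for s in samples])
    return Gallery(coefficients=coeffs, labels=np.asarray(labels))


def classify_nn(query: np.ndarray, gallery: Gallery):
    """Nearest-neighbour label by Euclidean distance in coefficient space.

    Ties are broken by the lowest gallery index.  Returns (label, distance).
    """
    if len(gallery.coefficients) == 0:
        raise ValueError("gallery: empty")
    q = np.asarray(query, dtype=float)
    if q.shape != gallery.coefficients.shape[1:]:
        raise ValueError("query: dimension does not match gallery")
    dists = np.sqrt(((gallery.coefficients - q) ** 2).sum(axis=1))
    idx = int(np.argmin(dists))  # argmin returns the first minimum: low-index tie-break
    return gallery.labels[idx], float(dists[idx])


def save_subspace(subspace: EigenSubspace, path: str | Path) -> None:
    np.savez(Path(path), mean=subspace.mean, eigenvalues=subspace.eigenvalues,
             eigenvectors=subspace.eigenvectors,
             retention=np.array(subspace.retention),
             image_shape=np.array(subspace.image_shape))


def load_subspace(path: str | Path) -> EigenSubspace:
    d = np.load(Path(path))
    return EigenSubspace(mean=d["mean"], eigenvalues=d["eigenvalues"],
                         eigenvectors=d["eigenvectors"],
                         retention=float(d["retention"]),
                         image_shape=tuple(int(v) for v in d["image_shape"]))


def classification_report(queries: list[np.ndarray], subspace: EigenSubspace,
                          gallery: Gallery, path: str | Path | None = None) -> dict:
    """Classify each query; report label, distance and runner-up margin."""
    records = []
    for i, q in enumerate(queries):
        y = project(q, subspace)
        dists = np.sqrt(((gallery.coefficients - y) ** 2).sum(axis=1))
        order = np.argsort(dists, kind="stable")
        rec = {"query": i, "label": int(gallery.labels[order[0]]),
               "distance": float(dists[order[0]]),
               "runner_up_margin": float(dists[order[1]] - dists[order[0]])
               if len(dists) > 1 else float("inf")}
        records.append(rec)
    doc = {"n_components": subspace.n_components,
           "retention": subspace.retention, "results": records}
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(doc, indent=2))
    return doc
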