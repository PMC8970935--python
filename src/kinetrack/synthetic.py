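"""Seeded synthetic scenes with full ground truth.

The generator emulates the kind of footage the rest of the package is built
for — a static cluttered background with one or more moving, uniformly
coloured elliptical "person" blobs, each optionally carrying a small
saturated-red marker patch — and exports everything the real footage never
comes with: per-frame foreground masks, per-blob trajectories, marker
centroids and class labels.  Everything is deterministic given the seed.

Blobs are axis-aligned ellipses; occlusion is resolved by draw order (a
later blob overwrites an earlier one).  Noise is added after rendering and
clipped to [0, 1]; ground truth is computed from the noise-free render.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .frames import FrameSequence, save_frames, write_image

RED = (0.9, 0.05, 0.05)


@dataclass
class BlobSpec:
    """One moving elliptical target.

    ``start_center`` and ``velocity`` are in (row, col) pixels; ``axes`` are
    the (row, col) semi-axes of the ellipse; ``body_color`` is RGB in [0, 1].
    """

    start_center: tuple[float, float]
    velocity: tuple[float, float]
    axes: tuple[float, float]
    body_color: tuple[float, float, float]


@dataclass
class MarkerSpec:
    """A small saturated disc riding on a blob at a fixed offset."""

    blob_index: int
    offset: tuple[float, float]
    radius: float
    color: tuple[float, float, float] = RED


@dataclass
class SceneConfig:
    height: int = 64
    width: int = 64
    n_frames: int = 40
    background_value: float = 0.5
    texture_sigma: float = 0.05
    blobs: list[BlobSpec] = field(default_factory=list)
    markers: list[MarkerSpec] = field(default_factory=list)
    noise_sigma: float = 0.01
    seed: int = 0


@dataclass
class GroundTruth:
    """Noise-free per-frame annotations for a synthetic scene."""

    masks: list[np.ndarray]
    trajectories: np.ndarray  # (n_blobs, n_frames, 2) float (row, col)
    marker_centroids: np.ndarray  # (n_markers, n_frames, 2)
    labels: list[int] | None = None


def default_scene_config(seed: int = 0, n_frames: int = 40) -> SceneConfig:
    """The stock 64x64 scene: one blue-clad blob drifting right, one red marker."""
    return SceneConfig(
        n_frames=n_frames,
        blobs=[BlobSpec(start_center=(32.0, 12.0), velocity=(0.0, 1.0),
                        axes=(10.0, 6.0), body_color=(0.2, 0.3, 0.8))],
        markers=[MarkerSpec(blob_index=0, offset=(-4.0, 0.0), radius=2.0)],
        seed=seed,
    )


def validate_scene_config(config: SceneConfig) -> None:
    """Raise ``ValueError`` naming the offending field on an invalid config."""
    if config.height < 32 or config.width < 32:
        raise ValueError("height/width: frame must be at least 32x32")
    if config.n_frames < 2:
        raise ValueError("n_frames: need at least 2 frames")
    for name, val in (("background_value", config.background_value),):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name}: intensity {val} outside [0, 1]")
    for sig_name in ("texture_sigma", "noise_sigma"):
        if getattr(config, sig_name) < 0:
            raise ValueError(f"{sig_name}: must be nonnegative")
    for b, blob in enumerate(config.blobs):
        if min(blob.axes) <= 0:
            raise ValueError(f"blobs[{b}].axes: semi-axes must be positive")
        if any(not 0.0 <= c <= 1.0 for c in blob.body_color):
            raise ValueError(f"blobs[{b}].body_color: outside [0, 1]")
        for t in (0, config.n_frames - 1):
            r = blob.start_center[0] + t * blob.velocity[0]
            c = blob.start_center[1] + t * blob.velocity[1]
            if not (blob.axes[0] <= r <= config.height - 1 - blob.axes[0]
                    and blob.axes[1] <= c <= config.width - 1 - blob.axes[1]):
                raise ValueError(
                    f"blobs[{b}]: trajectory leaves the one-semi-axis interior "
                    f"margin at frame {t} (center ({r:.1f}, {c:.1f}))")
    for m, marker in enumerate(config.markers):
        if not 0 <= marker.blob_index < len(config.blobs):
            raise ValueError(f"markers[{m}].blob_index: no blob {marker.blob_index}")
        if marker.radius <= 0:
            raise ValueError(f"markers[{m}].radius: must be positive")


def _ellipse_mask(h: int, w: int, center: tuple[float, float],
                  axes: tuple[float, float]) -> np.ndarray:
    rr, cc = np.mgrid[0:h, 0:w]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def _disc_mask(h: int, w: int, center: tuple[float, float], radius: float) -> np.ndarray:
    return _ellipse_mask(h, w, center, (radius, radius))


def render_background(config: SceneConfig, n_frames: int,
                      seed: int | None = None) -> FrameSequence:
    """Render blob-free frames of the scene's background (with frame noise).

    Useful for warming up a background model before the targets appear; the
    static texture matches :func:`make_scene` for the same config.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    bg = _static_background(config, rng)
    noise_rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    frames = []
    for _ in range(n_frames):
        f = bg + noise_rng.normal(0.0, config.noise_sigma, bg.shape)
        frames.append(np.clip(f, 0.0, 1.0))
    return FrameSequence(frames=frames)


def _static_background(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    bg = np.full((config.height, config.width, 3), config.background_value)
    if config.texture_sigma > 0:
        # static clutter: same draw for every frame of the scene
        bg = bg + rng.normal(0.0, config.texture_sigma,
                             (config.height, config.width, 1))
    return np.clip(bg, 0.0, 1.0)


def make_scene(config: SceneConfig) -> tuple[FrameSequence, GroundTruth]:
    """Render the scene and its noise-free ground truth.

    Identical (config, seed) gives bit-identical output.  Ground-truth masks
    mark exactly the pixels whose noise-free colour differs from the
    background (blob bodies plus markers).
    """
    validate_scene_config(config)
    h, w, T = config.height, config.width, config.n_frames
    rng = np.random.default_rng(config.seed)
    bg = _static_background(config, rng)
    noise_rng = np.random.default_rng(config.seed + 1)

    n_blobs, n_markers = len(config.blobs), len(config.markers)
    traj = np.zeros((n_blobs, T, 2))
    marker_traj = np.zeros((n_markers, T, 2))
    frames, masks = [], []
    for t in range(T):
        clean = bg.copy()
        mask = np.zeros((h, w), dtype=bool)
        centers = []
        for b, blob in enumerate(config.blobs):
            center = (blob.start_center[0] + t * blob.velocity[0],
                      blob.start_center[1] + t * blob.velocity[1])
            centers.append(center)
            traj[b, t] = center
            em = _ellipse_mask(h, w, center, blob.axes)
            clean[em] = blob.body_color
            mask |= em
        for m, marker in enumerate(config.markers):
            bc = centers[marker.blob_index]
            mc = (bc[0] + marker.offset[0], bc[1] + marker.offset[1])
            marker_traj[m, t] = mc
            dm = _disc_mask(h, w, mc, marker.radius)
            clean[dm] = marker.color
            mask |= dm
        noisy = clean + noise_rng.normal(0.0, config.noise_sigma, clean.shape) \
            if config.noise_sigma > 0 else clean
        frames.append(np.clip(noisy, 0.0, 1.0))
        masks.append(mask)
    gt = GroundTruth(masks=masks, trajectories=traj, marker_centroids=marker_traj)
    return FrameSequence(frames=frames, ground_truth=gt), gt


def make_damage_gallery(n_classes: int, n_per_class: int,
                        image_shape: tuple[int, int] = (16, 16),
                        class_separation: float = 0.5,
                        noise_sigma: float = 0.1,
                        seed: int = 0) -> tuple[list[np.ndarray], np.ndarray]:
    """Labeled gallery of gray images for the injury classifier.

    Each class is a distinct template — a bright Gaussian bump at a
    class-specific joint position along a vertical "leg" (hip / knee / ankle
    and so on as ``n_classes`` grows) with amplitude ``class_separation`` —
    plus i.i.d. pixel noise of ``noise_sigma``.  ``class_separation=0``
    collapses all templates to the same image (the classifier's worst case);
    ``noise_sigma=0`` makes within-class samples bit-identical.
    """
    if n_classes < 2:
        raise ValueError("n_classes: need at least 2 classes")
    if n_per_class < 2:
        raise ValueError("n_per_class: need at least 2 samples per class")
    H, W = image_shape
    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[0:H, 0:W]
    sigma_blob = max(min(H, W) / 8.0, 1.0)
    samples, labels = [], []
    for k in range(n_classes):
        joint = ((k + 1) * H / (n_classes + 1.0), W / 2.0)
        template = class_separation * np.exp(
            -(((rr - joint[0]) ** 2 + (cc - joint[1]) ** 2) / (2 * sigma_blob ** 2)))
        for _ in range(n_per_class):
            img = template
            if noise_sigma > 0:
                img = img + rng.normal(0.0, noise_sigma, (H, W))
            samples.append(np.clip(img, 0.0, 1.0))
            labels.append(k)
    return samples, np.asarray(labels)


def make_graph_fixture(n_nodes: int, edge_prob: float, feature_dim: int,
                       seed: int = 0):
    """Erdős–Rényi detection-graph fixture with Gaussian node features."""
    from .graphnet import DetectionGraph

    if n_nodes < 1:
        raise ValueError("n_nodes: need at least 1 node")
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError("edge_prob: must be a probability")
    rng = np.random.default_rng(seed)
    upper = rng.random((n_nodes, n_nodes)) < edge_prob
    A = np.triu(upper, k=1)
    A = (A | A.T).astype(float)
    H = rng.standard_normal((n_nodes, feature_dim))
    meta = [(0, i) for i in range(n_nodes)]
    return DetectionGraph(adjacency=A, features=H, node_meta=meta)


def export_scene(seq: FrameSequence, gt: GroundTruth, out_dir: str | Path) -> dict:
    """Write frames, mask PNGs and a trajectory CSV; return the manifest."""
    out_dir = Path(out_dir)
    frame_paths = save_frames(seq, out_dir / "frames")
    mask_dir = out_dir / "masks"
    for i, mask in enumerate(gt.masks):
        write_image(mask_dir / f"mask_{i:04d}.png", mask.astype(float))
    traj_path = out_dir / "trajectories.csv"
    with open(traj_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "blob_id", "row", "col"])
        n_blobs, T, _ = gt.trajectories.shape
        for t in range(T):
            for b in range(n_blobs):
                writer.writerow([t, b, gt.trajectories[b, t, 0], gt.trajectories[b, t, 1]])
    return {"frames": [str(p) for p in frame_paths],
            "masks": [str(mask_dir / f"mask_{i:04d}.png") for i in range(len(gt.masks))],
            "trajectories": str(traj_path)}
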