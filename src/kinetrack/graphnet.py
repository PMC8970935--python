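"""Detection graphs and graph-convolutional feature propagation.

Tracked detections become nodes of an undirected graph — temporal edges
join consecutive frames of a track, spatial edges join detections of
different tracks that fall within a radius in the same frame.  Node
features are propagated with the renormalized graph convolution

    h^l = sigma( D^{-1/2} (A + I) D^{-1/2} h^{l-1} W^{l-1} )

(self-loops added so isolated nodes have a well-defined degree), which is
the first-order approximation of spectral filtering in the eigenbasis of
the symmetric normalized Laplacian, ``U g(Lambda) U^T x``.  No training
loop is provided: layer weights are user-supplied or seeded-random, and
the module's job is deterministic feature management, not fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class DetectionGraph:
    adjacency: np.ndarray  # (n, n) symmetric, zero diagonal
    features: np.ndarray  # (n, d) node features h^0
    node_meta: list[tuple[int, int]] = field(default_factory=list)  # (track, frame)

    def __post_init__(self):
        A = np.asarray(self.adjacency, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1] or A.shape[0] < 1:
            raise ValueError("adjacency: need a square matrix with n >= 1")
        if not np.allclose(A, A.T):
            raise ValueError("adjacency: must be symmetric")
        if np.any(A < 0):
            raise ValueError("adjacency: entries must be nonnegative")
        self.adjacency = A
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape[0] != A.shape[0]:
            raise ValueError("features: one row per node required")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class GCNLayerParams:
    W: np.ndarray
    activation: str = "identity"  # or "relu"

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        if not np.all(np.isfinite(self.W)):
            raise ValueError("W: entries must be finite")
        if self.activation not in ("identity", "relu"):
            raise ValueError(f"activation: unknown {self.activation!r}")


def build_detection_graph(tracks: list, features: list[np.ndarray],
                          radius: float) -> DetectionGraph:
    """One node per (track, frame) detection; temporal + within-radius edges.

    ``features[i]`` is the (T_i, d) feature matrix of track i, row t for the
    detection at frame t.  Edges: consecutive frames of the same track, and
    detections of different tracks in the same frame whose window centres
    lie within ``radius`` pixels.  The adjacency is binary and symmetric.
    """
    if not tracks:
        raise ValueError("tracks: need at least one track")
    feats = [np.atleast_2d(np.asarray(f, dtype=float)) for f in features]
    dims = {f.shape[1] for f in feats}
    if len(dims) != 1:
        raise ValueError("features: inconsistent feature dimension across tracks")
    node_meta, rows, centers = [], [], []
    for ti, (trk, F) in enumerate(zip(tracks, feats)):
        if len(trk.windows) != F.shape[0]:
            raise ValueError(f"features[{ti}]: one row per tracked frame required")
        for t, w in enumerate(trk.windows):
            node_meta.append((ti, t))
            rows.append(F[t])
            centers.append(w.center)
    n = len(node_meta)
    A = np.zeros((n, n))
    index = {meta: i for i, meta in enumerate(node_meta)}
    for (ti, t), i in index.items():
        j = index.get((ti, t + 1))
        if j is not None:
            A[i, j] = A[j, i] = 1.0
    for i in range(n):
        for j in range(i + 1, n):
            ti, t = node_meta[i]
            tj, s = node_meta[j]
            if ti != tj and t == s:
                d = math.hypot(centers[i][0] - centers[j][0],
                               centers[i][1] - centers[j][1])
                if d <= radius:
                    A[i, j] = A[j, i] = 1.0
    return DetectionGraph(adjacency=A, features=np.stack(rows), node_meta=node_meta)


def _check_symmetric(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency: need a square matrix")
    if not np.allclose(A, A.T):
        raise ValueError("adjacency: must be symmetric")
    return A


def normalized_adjacency(A: np.ndarray) -> np.ndarray:
    """Renormalized propagation matrix D^{-1/2} (A + I) D^{-1/2}.

    Self-loops are added before degree normalization; the result is
    symmetric with spectrum contained in [-1, 1].
    """
    A = _check_symmetric(A)
    if np.any(A < 0):
        raise ValueError("adjacency: entries must be nonnegative")
    A_hat = A + np.eye(A.shape[0])
    deg = A_hat.sum(axis=1)
    with np.errstate(divide="ignore"):
        d_inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
    return d_inv_sqrt[:, None] * A_hat * d_inv_sqrt[None, :]


def gcn_layer(H: np.ndarray, P: np.ndarray, params: GCNLayerParams) -> np.ndarray:
    """One propagation layer: sigma(P @ H @ W)."""
    H = np.asarray(H, dtype=float)
    P = np.asarray(P, dtype=float)
    if H.ndim != 2 or P.shape[1] != H.shape[0]:
        raise ValueError("dimensions: P columns must match H rows")
    if H.shape[1] != params.W.shape[0]:
        raise ValueError("dimensions: H columns must match W rows")
    Z = P @ H @ params.W
    if params.activation == "relu":
        return np.maximum(Z, 0.0)
    return Z


def spectral_filter(x: np.ndarray, A: np.ndarray, g) -> np.ndarray:
    """Filter a node signal in the Laplacian eigenbasis: U g(Lambda) U^T x.

    ``L = I - D^{-1/2}(A+I)D^{-1/2}`` is the symmetric normalized Laplacian
    of the self-loop-augmented graph; ``g`` maps an eigenvalue to a gain.
    The identity gain returns x exactly; ``g(l) = 1 - l`` reproduces the
    renormalized adjacency product.
    """
    A = _check_symmetric(A)
    x = np.asarray(x, dtype=float)
    if x.shape[0] != A.shape[0]:
        raise ValueError("x: length must equal the number of nodes")
    L = np.eye(A.shape[0]) - normalized_adjacency(A)
    lam, U = np.linalg.eigh(L)
    gains = np.array([float(g(v)) for v in lam])
    return U @ (gains * (U.T @ x))


def manage_features(graph: DetectionGraph, layers: list[GCNLayerParams]):
    """Propagate node features through the layer stack.

    Returns ``(H_final, pooled)`` where ``pooled`` maps each track id to the
    mean of its nodes' final embeddings.
    """
    if not layers:
        raise ValueError("layers: need at least one layer")
    P = normalized_adjacency(graph.adjacency)
    H = graph.features
    for layer in layers:
        H = gcn_layer(H, P, layer)
    pooled: dict[int, np.ndarray] = {}
    for tid in sorted({m[0] for m in graph.node_meta}):
        idx = [i for i, m in enumerate(graph.node_meta) if m[0] == tid]
        pooled[tid] = H[idx].mean(axis=0)
    return H, pooled


def random_layers(dims: list[int], seed: int = 0,
                  activation: str = "identity") -> list[GCNLayerParams]:
    """Seeded Gaussian layer weights for the given dimension chain."""
    rng = np.random.default_rng(seed)
    return [GCNLayerParams(W=rng.standard_normal((a, b)) / np.sqrt(a),
                           activation=activation)
            for a, b in zip(dims[:-1], dims[1:])]


def export_graph(graph: DetectionGraph, out_dir: str | Path) -> dict:
    """Write edge-list and feature CSVs; return the file manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    src, dst = np.nonzero(np.triu(graph.adjacency, k=1))
    edges_path = out_dir / "edges.csv"
    pd.DataFrame({"src": src, "dst": dst}).to_csv(edges_path, index=False)
    feat_path = out_dir / "features.csv"
    df = pd.DataFrame(graph.features,
                      columns=[f"f{i}" for i in range(graph.features.shape[1])])
    df.insert(0, "track", [m[0] for m in graph.node_meta])
    df.insert(1, "frame", [m[1] for m in graph.node_meta])
    df.to_csv(feat_path, index=False)
    return {"edges": str(edges_path), "features": str(feat_path)}


def export_embeddings(graph: DetectionGraph, H: np.ndarray,
                      path: str | Path) -> None:
    df = pd.DataFrame(H, columns=[f"e{i}" for i in range(H.shape[1])])
    df.insert(0, "track", [m[0] for m in graph.node_meta])
    df.insert(1, "frame", [m[1] for m in graph.node_meta])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
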