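"""Frame sequences and image file I/O.

All images in the package are ``float64`` arrays with intensities on a real
[0, 1] scale, coordinates ``(row, col)``, 0-based, origin at the top-left.
8-bit files are converted on read by dividing by 255 and on write by
multiplying by 255 and rounding.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

_FRAME_NAME = "frame_{:04d}.png"
_FRAME_RE = re.compile(r".*\.(png|tif|tiff)$", re.IGNORECASE)


def to_float(img: np.ndarray) -> np.ndarray:
    """Convert an integer image to float64 in [0, 1]; pass floats through."""
    img = np.asarray(img)
    if np.issubdtype(img.dtype, np.integer):
        return img.astype(np.float64) / 255.0
    return img.astype(np.float64)


def to_uint8(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(np.asarray(img) * 255.0), 0, 255).astype(np.uint8)


@dataclass
class FrameSequence:
    """An ordered sequence of RGB frames, optionally with ground truth.

    ``frames`` is a list of (H, W, 3) float arrays in [0, 1].  When the
    sequence was produced by the synthetic generator, ``ground_truth`` holds
    the matching :class:`kinetrack.synthetic.GroundTruth`.
    """

    frames: list[np.ndarray] = field(default_factory=list)
    ground_truth: object | None = None

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]

    def __iter__(self):
        return iter(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        h, w = self.frames[0].shape[:2]
        return h, w


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as float64 in [0, 1]."""
    return to_float(iio.imread(Path(path)))


def write_image(path: str | Path, img: np.ndarray) -> None:
    """Write a [0, 1] float image as an 8-bit PNG/TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, to_uint8(img))


def load_frames(directory: str | Path) -> FrameSequence:
    """Load all PNG/TIFF frames from a directory in lexicographic order."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"frame directory not found: {directory}")
    paths = sorted(p for p in directory.iterdir() if _FRAME_RE.match(p.name))
    if not paths:
        raise FileNotFoundError(f"no PNG/TIFF frames in {directory}")
    return FrameSequence(frames=[read_image(p) for p in paths])


def save_frames(seq: FrameSequence, directory: str | Path) -> list[Path]:
    """Write frames as zero-padded numbered PNGs (``frame_0000.png``, ...)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for i, frame in enumerate(seq):
        p = directory / _FRAME_NAME.format(i)
        write_image(p, frame)
        out.append(p)
    return out
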