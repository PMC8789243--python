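"""Datasets: synthetic digit-like stimuli and IDX (MNIST-dialect) files.

The synthetic generator renders ten fixed stroke-grid glyph templates onto an
arbitrary pixel grid and corrupts them with i.i.d. Gaussian pixel noise and a
random one-pixel jitter, giving a download-free, seeded stand-in for
hand-written digits with controllable difficulty.  External data arrives in
the IDX binary container used by MNIST distributions (big-endian dimensions,
magic 0x00000803 for images and 0x00000801 for labels), with a center-crop
step that extracts the 21x20 window feeding the 420 input units of the
reference architecture.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .exceptions import (
    ConfigurationError,
    IdxCountMismatchError,
    IdxMagicError,
    IdxTruncatedError,
)

__all__ = [
    "Dataset",
    "generate_synthetic_digits",
    "load_idx",
    "write_idx",
    "crop_center",
]

IMAGES_MAGIC = 0x00000803
LABELS_MAGIC = 0x00000801

# 7x5 stroke-grid glyphs for digits 0-9 ('1' = ink).  Shipped as code
# constants so generation needs no downloads and is versioned with the code.
_GLYPHS = [
    ("01110", "10001", "10011", "10101", "11001", "10001", "01110"),  # 0
    ("00100", "01100", "00100", "00100", "00100", "00100", "01110"),  # 1
    ("01110", "10001", "00001", "00010", "00100", "01000", "11111"),  # 2
    ("11111", "00010", "00100", "00010", "00001", "10001", "01110"),  # 3
    ("00010", "00110", "01010", "10010", "11111", "00010", "00010"),  # 4
    ("11111", "10000", "11110", "00001", "00001", "10001", "01110"),  # 5
    ("00110", "01000", "10000", "11110", "10001", "10001", "01110"),  # 6
    ("11111", "00001", "00010", "00100", "01000", "01000", "01000"),  # 7
    ("01110", "10001", "10001", "01110", "10001", "10001", "01110"),  # 8
    ("01110", "10001", "10001", "01111", "00001", "00010", "01100"),  # 9
]

N_TEMPLATES = len(_GLYPHS)


@dataclass
class Dataset:
    """Pixel stimuli with class labels.

    ``stimuli`` is an ``(n, rows*cols)`` float array in [0, 1], flattened
    row-major; ``labels`` holds class indices ``0..n_classes-1``.
    """

    stimuli: np.ndarray
    labels: np.ndarray
    image_shape: tuple[int, int]
    provenance: str = "synthetic"
    n_classes: Optional[int] = None

    def __post_init__(self) -> None:
        self.stimuli = np.asarray(self.stimuli, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.stimuli.ndim != 2 or self.stimuli.shape[0] != self.labels.shape[0]:
            raise ConfigurationError("stimuli and labels must have matching first dimension")
        r, c = self.image_shape
        if self.stimuli.shape[1] != r * c:
            raise ConfigurationError(
                f"stimulus length {self.stimuli.shape[1]} != {r}x{c}"
            )
        if self.stimuli.size and (self.stimuli.min() < 0 or self.stimuli.max() > 1):
            raise ConfigurationError("pixel values must lie in [0, 1]")
        if self.n_classes is None:
            self.n_classes = int(self.labels.max()) + 1 if self.labels.size else 0
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.n_classes):
            raise ConfigurationError("labels must lie in 0..n_classes-1")

    def __len__(self) -> int:
        return self.stimuli.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.stimuli.shape[1]

    def subset(self, indices) -> "Dataset":
        return replace(self, stimuli=self.stimuli[indices], labels=self.labels[indices])

    def images(self) -> np.ndarray:
        """Stimuli reshaped to ``(n, rows, cols)``."""
        return self.stimuli.reshape(len(self), *self.image_shape)


def render_template(digit: int, image_shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour rendering of a glyph onto the grid interior.

    A one-pixel blank border is kept around the glyph so jitter cannot push
    ink off the grid.
    """
    rows, cols = image_shape
    if rows < 5 or cols < 4:
        raise ConfigurationError(f"image shape {image_shape} too small for glyphs")
    if not 0 <= digit < N_TEMPLATES:
        raise ConfigurationError(f"no glyph template for class {digit}")
    glyph = np.array([[int(ch) for ch in row] for row in _GLYPHS[digit]], dtype=float)
    ir, ic = rows - 2, cols - 2
    rr = (np.arange(ir) * glyph.shape[0]) // ir
    cc = (np.arange(ic) * glyph.shape[1]) // ic
    img = np.zeros((rows, cols))
    img[1 : 1 + ir, 1 : 1 + ic] = glyph[np.ix_(rr, cc)]
    return img


def generate_synthetic_digits(
    n_per_class: int,
    n_classes: int = 10,
    image_shape: tuple[int, int] = (28, 28),
    noise_sd: float = 0.1,
    jitter: bool = True,
    seed: int = 0,
) -> Dataset:
    """Balanced, seeded synthetic digit dataset.

    Each stimulus is its class template plus i.i.d. Gaussian pixel noise and
    (optionally) a uniform shift of -1/0/+1 pixels along each axis, clipped
    back to [0, 1].  The returned order is a seeded shuffle of the balanced
    class blocks.
    """
    if not 1 <= n_classes <= N_TEMPLATES:
        raise ConfigurationError(f"n_classes must lie in 1..{N_TEMPLATES}")
    if n_per_class < 1:
        raise ConfigurationError("n_per_class must be >= 1")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    templates = [render_template(k, image_shape) for k in range(n_classes)]
    images, labels = [], []
    for k, tpl in enumerate(templates):
        for _ in range(n_per_class):
            img = tpl
            if jitter:
                dr, dc = rng.integers(-1, 2, size=2)
                img = np.roll(np.roll(img, dr, axis=0), dc, axis=1)
            if noise_sd > 0:
                img = img + rng.normal(0.0, noise_sd, size=img.shape)
            images.append(np.clip(img, 0.0, 1.0))
            labels.append(k)
    order = rng.permutation(len(images))
    stimuli = np.stack(images).reshape(len(images), -1)[order]
    return Dataset(
        stimuli=stimuli,
        labels=np.asarray(labels)[order],
        image_shape=image_shape,
        provenance="synthetic",
        n_classes=n_classes,
    )


def _read_header(data: bytes, magic: int, n_dims: int, path) -> tuple[tuple[int, ...], int]:
    header = 4 * (1 + n_dims)
    if len(data) < header:
        raise IdxTruncatedError(f"{path}: file shorter than its {header}-byte header")
    found = struct.unpack(">i", data[:4])[0]
    if found != magic:
        raise IdxMagicError(f"{path}: magic 0x{found:08x}, expected 0x{magic:08x}")
    dims = struct.unpack(f">{n_dims}i", data[4:header])
    return dims, header


def load_idx(images_path, labels_path) -> Dataset:
    """Read an IDX image/label pair, scaling pixels from 0..255 to [0, 1]."""
    images_path, labels_path = Path(images_path), Path(labels_path)
    img_data = images_path.read_bytes()
    (n, rows, cols), off = _read_header(img_data, IMAGES_MAGIC, 3, images_path)
    payload = n * rows * cols
    if len(img_data) < off + payload:
        raise IdxTruncatedError(
            f"{images_path}: expected {payload} pixel bytes, found {len(img_data) - off}"
        )
    pixels = np.frombuffer(img_data, dtype=np.uint8, count=payload, offset=off)

    lbl_data = labels_path.read_bytes()
    (n_lbl,), off_l = _read_header(lbl_data, LABELS_MAGIC, 1, labels_path)
    if len(lbl_data) < off_l + n_lbl:
        raise IdxTruncatedError(f"{labels_path}: label payload truncated")
    if n_lbl != n:
        raise IdxCountMismatchError(f"{n} images but {n_lbl} labels")
    labels = np.frombuffer(lbl_data, dtype=np.uint8, count=n_lbl, offset=off_l)

    return Dataset(
        stimuli=pixels.reshape(n, rows * cols).astype(float) / 255.0,
        labels=labels.astype(int),
        image_shape=(rows, cols),
        provenance="idx_file",
    )


def write_idx(dataset: Dataset, images_path, labels_path) -> None:
    """Write a dataset as an IDX image/label pair (pixels rounded to 0..255)."""
    n = len(dataset)
    rows, cols = dataset.image_shape
    pixels = np.rint(dataset.stimuli * 255.0).astype(np.uint8)
    with open(images_path, "wb") as fh:
        fh.write(struct.pack(">4i", IMAGES_MAGIC, n, rows, cols))
        fh.write(pixels.tobytes())
    with open(labels_path, "wb") as fh:
        fh.write(struct.pack(">2i", LABELS_MAGIC, n))
        fh.write(dataset.labels.astype(np.uint8).tobytes())


def crop_center(dataset: Dataset, target_shape: tuple[int, int] = (21, 20)) -> Dataset:
    """Extract a centered window from every image.

    For odd margins the extra row/column is dropped from the bottom/right
    (top-left offset is ``floor(margin / 2)``).  The reference protocol crops
    28x28 images to 21x20 = 420 pixels.
    """
    rows, cols = dataset.image_shape
    tr, tc = target_shape
    if tr > rows or tc > cols:
        raise ConfigurationError(f"crop {target_shape} larger than source {dataset.image_shape}")
    r0 = (rows - tr) // 2
    c0 = (cols - tc) // 2
    cropped = dataset.images()[:, r0 : r0 + tr, c0 : c0 + tc]
    return replace(
        dataset,
        stimuli=cropped.reshape(len(dataset), tr * tc),
        image_shape=(tr, tc),
    )
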