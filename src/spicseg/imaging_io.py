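"""Image stack, slice and mask I/O.

All geometry in this package uses a single convention: pixel coordinates
are ``(row, col)``, 0-based, with rows increasing downward.  When a formula
is written in ``(x, y)`` form, ``x`` maps to the column index and ``y`` to
the row index.  Gray values are stored as floats; :func:`read_stack`
rescales each stack to ``[0, 1]`` by min-max so that downstream gradient
magnitudes live on a fixed scale regardless of the source bit depth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import nibabel as nib
import numpy as np

__all__ = [
    "Image2D",
    "ImageStack",
    "Mask2D",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
]

_SLICE_EXTS = {".png", ".tif", ".tiff"}


@dataclass(frozen=True)
class Image2D:
    """A single 2-D grayscale image (float pixels)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"Image2D requires a 2-D array, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("Image2D pixels must be finite")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ImageStack:
    """An ordered stack of equally sized 2-D slices."""

    slices: tuple[Image2D, ...]

    def __post_init__(self) -> None:
        slices = tuple(self.slices)
        if len(slices) < 1:
            raise ValueError("ImageStack requires at least one slice")
        h, w = slices[0].height, slices[0].width
        for k, s in enumerate(slices):
            if (s.height, s.width) != (h, w):
                raise ValueError(
                    f"slice {k} has shape {(s.height, s.width)}, expected {(h, w)}"
                )
        object.__setattr__(self, "slices", slices)

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def height(self) -> int:
        return self.slices[0].height

    @property
    def width(self) -> int:
        return self.slices[0].width

    def as_array(self) -> np.ndarray:
        """Return a (n_slices, height, width) float array copy."""
        return np.stack([s.pixels for s in self.slices], axis=0)

    @classmethod
    def from_array(cls, volume: np.ndarray) -> "ImageStack":
        volume = np.asarray(volume, dtype=float)
        if volume.ndim != 3:
            raise ValueError(f"expected a 3-D array, got shape {volume.shape}")
        return cls(tuple(Image2D(volume[k]) for k in range(volume.shape[0])))


@dataclass(frozen=True)
class Mask2D:
    """A binary 2-D mask; values are exactly 0 or 1 (uint8)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"Mask2D requires a 2-D array, got shape {px.shape}")
        vals = np.unique(px)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"Mask2D values must be 0/1, got {vals}")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def area(self) -> int:
        return int(self.pixels.sum())


def _minmax_rescale(volume: np.ndarray) -> np.ndarray:
    lo, hi = float(volume.min()), float(volume.max())
    if hi > lo:
        return (volume - lo) / (hi - lo)
    return np.zeros_like(volume)


def _list_slice_files(directory: Path) -> list[Path]:
    files = sorted(
        p for p in directory.iterdir()
        if p.is_file() and p.suffix.lower() in _SLICE_EXTS
    )
    if not files:
        raise FileNotFoundError(f"no slice images (*.png, *.tif) found in {directory}")
    return files


def read_stack(path: str | os.PathLike, rescale: bool = True) -> ImageStack:
    """Read a slice stack from a directory of 2-D images or a NIfTI volume.

    Directories are read in lexicographic filename order.  NIfTI volumes
    are interpreted with the last axis as the slice axis.  With
    ``rescale=True`` (the default) intensities are min-max rescaled to
    ``[0, 1]`` per stack.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.is_dir():
        planes = []
        for f in _list_slice_files(path):
            pl = np.asarray(iio.imread(f), dtype=float)
            if pl.ndim == 3:  # collapse RGB(A) written by generic writers
                pl = pl[..., 0]
            planes.append(pl)
        shapes = {pl.shape for pl in planes}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent slice dimensions in {path}: {sorted(shapes)}")
        volume = np.stack(planes, axis=0)
    elif path.suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=float)
        if data.ndim != 3:
            raise ValueError(f"NIfTI volume must be 3-D, got shape {data.shape}")
        # stored (x, y, z) -> (slice, row, col)
        volume = np.transpose(data, (2, 1, 0))
    else:
        raise ValueError(f"unreadable stack format: {path}")
    if rescale:
        volume = _minmax_rescale(volume)
    return ImageStack.from_array(volume)


def write_stack(stack: ImageStack, path: str | os.PathLike, fmt: str = "png") -> None:
    """Write a stack as 16-bit slice images in a directory, or as NIfTI.

    16-bit output keeps the round trip through :func:`read_stack` (which
    min-max rescales) lossless to ~1.5e-5, and NIfTI output exactly
    lossless.
    """
    path = Path(path)
    if fmt == "nifti" or path.name.endswith((".nii", ".nii.gz")):
        volume = np.transpose(stack.as_array(), (2, 1, 0))
        nib.save(nib.Nifti1Image(volume, affine=np.eye(4)), str(path))
        return
    path.mkdir(parents=True, exist_ok=True)
    arr = stack.as_array()
    lo, hi = arr.min(), arr.max()
    scaled = np.zeros_like(arr) if hi <= lo else (arr - lo) / (hi - lo)
    as_u16 = np.round(scaled * 65535).astype(np.uint16)
    ndigits = max(4, len(str(stack.n_slices)))
    for k in range(stack.n_slices):
        iio.imwrite(path / f"slice_{k:0{ndigits}d}.{fmt}", as_u16[k])


def read_mask(path: str | os.PathLike) -> Mask2D:
    """Read a binary mask image; any value > 0 maps to 1."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return Mask2D((arr > 0).astype(np.uint8))


def write_mask(mask: Mask2D, path: str | os.PathLike) -> None:
    """Write a mask as an 8-bit image with values {0, 255}."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (mask.pixels * 255).astype(np.uint8))
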