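"""Raster I/O and mask bookkeeping.

Conventions used throughout the package:

* A grayscale frame (``GrayImage``) is a 2-D ``uint8`` array of intensities in
  ``[0, 255]``, indexed ``(row, col)`` with row 0 at the top and col 0 at the
  left.
* A binary vessel mask (``BinaryMask``) is a boolean array of the same shape
  where ``True`` marks VESSEL — the dark, low-intensity class in an
  angiograph — and ``False`` marks BACKGROUND.  On disk a mask stores vessel
  as 0 (black) and background as 255 (white), so masks render like the
  binarized figures clinicians are used to.

Inputs are nominally 512 x 512 angiography frames, but any size is accepted
here; divisibility constraints are enforced by the tiling stage.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "read_gray",
    "write_gray",
    "read_mask",
    "write_mask",
    "count_mask_pixels",
    "write_counts_csv",
]

#: luminance weights (ITU-R BT.601) used to collapse color rasters
_LUMA = np.array([0.299, 0.587, 0.114])


def read_gray(path: str | Path) -> np.ndarray:
    """Read a raster file as an 8-bit grayscale image.

    Multi-channel input is converted to luminance; an alpha channel, if
    present, is dropped.  16-bit (or other non-8-bit integer) input is
    linearly rescaled to [0, 255] with a logged warning.  Floating-point
    rasters are assumed to span [0, 1] (or [0, 255] if their maximum exceeds
    1) and are rescaled likewise.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    OSError / ValueError
        If the file cannot be decoded or decodes to an empty image.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    arr = np.asarray(iio.imread(path))
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path}")

    # dtype -> intensity scale of the decoded samples
    if arr.dtype == np.uint8:
        src_max = 255.0
    elif np.issubdtype(arr.dtype, np.integer):
        src_max = float(np.iinfo(arr.dtype).max)
        logger.warning("%s-bit raster %s rescaled to 8-bit",
                       np.iinfo(arr.dtype).bits, path)
    elif np.issubdtype(arr.dtype, np.floating):
        src_max = 1.0 if float(np.nanmax(arr)) <= 1.0 else 255.0
    else:
        raise ValueError(f"unsupported raster dtype {arr.dtype}: {path}")

    arr = arr.astype(np.float64)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[..., :3]
        if arr.shape[2] == 2:  # gray + alpha
            arr = arr[..., 0]
        else:
            arr = arr @ _LUMA
    elif arr.ndim != 2:
        raise ValueError(f"unsupported raster shape {arr.shape}: {path}")

    if src_max != 255.0:
        arr = arr * (255.0 / src_max)
    return np.clip(np.rint(arr), 0, 255).astype(np.uint8)


def write_gray(img: np.ndarray, path: str | Path) -> None:
    """Write a 2-D uint8 grayscale image to *path* (format from suffix)."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    iio.imwrite(Path(path), img.astype(np.uint8))


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary vessel mask: VESSEL -> 0 (black), BACKGROUND -> 255.

    ``read_gray`` of the written file reproduces the two-valued grid exactly,
    and ``read_mask`` round-trips the boolean array.
    """
    mask = np.asarray(mask, dtype=bool)
    out = np.where(mask, 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), out)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask raster; pixels below 128 are VESSEL (True)."""
    return read_gray(path) < 128


def count_mask_pixels(mask: np.ndarray) -> tuple[int, int]:
    """Return ``(vessel_count, background_count)`` for a binary mask.

    The two counts always sum to ``height * width`` — the black/white pixel
    accounting used to compare segmentation strategies.
    """
    mask = np.asarray(mask, dtype=bool)
    vessel = int(mask.sum())
    return vessel, mask.size - vessel


def write_counts_csv(
    records: Iterable[Sequence], path: str | Path
) -> None:
    """Write per-image pixel-count rows (image_id, vessel_pixels, background_pixels)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "vessel_pixels", "background_pixels"])
        for row in records:
            writer.writerow(list(row))
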