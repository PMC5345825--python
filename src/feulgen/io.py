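"""Reading and writing images, masks and tables.

TIFF goes through :mod:`tifffile` (including multi-page stacks and 32-bit
OD planes); PNG through :mod:`imageio`. Label masks are stored as 16-bit
images.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from feulgen.optics import ImagePlane
from feulgen.segmentation import LabelMask


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF or PNG image; multi-page TIFFs come back as a stack."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return np.asarray(iio.imread(path))


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write an image, scaling floats on the 0-255 scale to 8-bit for PNG."""
    path = Path(path)
    image = np.asarray(image)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
        return
    if np.issubdtype(image.dtype, np.floating):
        image = np.clip(np.round(image), 0, 255).astype(np.uint8)
    iio.imwrite(path, image)


def write_od_plane(path: str | Path, plane: ImagePlane) -> None:
    """Write an OD plane as 32-bit float TIFF."""
    tifffile.imwrite(Path(path), plane.pixels.astype(np.float32))


def read_od_plane(path: str | Path, pixel_size_um: float = 0.45) -> ImagePlane:
    return ImagePlane(tifffile.imread(Path(path)).astype(float), "optical_density", pixel_size_um)


def write_label_mask(path: str | Path, mask: LabelMask | np.ndarray) -> None:
    """Write a label mask as a 16-bit TIFF/PNG."""
    arr = mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)
    if arr.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels cannot be stored in 16 bits")
    write_image(Path(path), arr.astype(np.uint16))


def read_label_mask(path: str | Path) -> LabelMask:
    return LabelMask(read_image(path).astype(np.int32))
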