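"""Raw microscope frames to background-corrected optical-density planes.

The measurement chain is: average repeated exposures, keep the green channel
(the Feulgen--DNA dye complex absorbs most strongly in green), divide by a
blank-field image to obtain transmittance, and take ``-log10`` to obtain
per-pixel optical density (OD).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

log = logging.getLogger(__name__)

#: default micrometres per pixel
DEFAULT_PIXEL_SIZE_UM = 0.45

#: default OD ceiling; 8-bit intensities cannot resolve OD beyond ~3
DEFAULT_OD_MAX = 3.0


@dataclass
class ImagePlane:
    """A 2-D scalar grid carrying either intensity or optical density.

    Parameters
    ----------
    pixels : ndarray
        2-D float array.
    value_kind : {"intensity", "optical_density"}
        What the values mean.
    pixel_size_um : float
        Micrometres per pixel (isotropic).
    """

    pixels: np.ndarray
    value_kind: Literal["intensity", "optical_density"] = "intensity"
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"ImagePlane requires a 2-D array, got shape {self.pixels.shape}")
        if self.value_kind == "intensity" and np.any(self.pixels < 0):
            raise ValueError("intensity planes must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _as_array(plane: ImagePlane | np.ndarray) -> np.ndarray:
    return plane.pixels if isinstance(plane, ImagePlane) else np.asarray(plane, dtype=float)


def average_frames(frames: Sequence[ImagePlane | np.ndarray]) -> ImagePlane:
    """Pixel-wise arithmetic mean of repeated exposures of the same field.

    Averaging k frames of i.i.d. sensor noise reduces the residual noise
    standard deviation by a factor sqrt(k).
    """
    if len(frames) == 0:
        raise ValueError("average_frames requires at least one frame")
    arrays = [_as_array(f) for f in frames]
    shape = arrays[0].shape
    for i, a in enumerate(arrays[1:], start=1):
        if a.shape != shape:
            raise ValueError(f"frame {i} has shape {a.shape}, expected {shape}")
    pixel_size = next(
        (f.pixel_size_um for f in frames if isinstance(f, ImagePlane)), DEFAULT_PIXEL_SIZE_UM
    )
    mean = np.mean(np.stack(arrays, axis=0), axis=0)
    return ImagePlane(mean, "intensity", pixel_size)


def extract_green(rgb: np.ndarray, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> ImagePlane:
    """Return the green channel of an RGB image as an intensity plane.

    A single-channel input is passed through unchanged with a warning.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim == 2:
        warnings.warn("single-channel image: passing through unchanged", stacklevel=2)
        return ImagePlane(rgb, "intensity", pixel_size_um)
    if rgb.ndim != 3 or rgb.shape[-1] < 3:
        raise ValueError(f"expected an RGB image (H, W, 3), got shape {rgb.shape}")
    return ImagePlane(rgb[..., 1].copy(), "intensity", pixel_size_um)


def background_correct(
    sample: ImagePlane | np.ndarray,
    blank: ImagePlane | np.ndarray | float,
    od_max: float = DEFAULT_OD_MAX,
) -> ImagePlane:
    """Transmittance-ratio background correction.

    Divides the sample intensity by the blank-field (incident light)
    intensity, pixel by pixel, which cancels illumination gradients. The
    blank may be a full image or a scalar (mean intensity of a clear region
    of the slide). The result is clipped to ``(10**-od_max, 1]``.
    """
    s = _as_array(sample)
    if np.isscalar(blank):
        if blank <= 0:
            raise ValueError("scalar blank intensity must be positive")
        b = float(blank)
    else:
        b = _as_array(blank)
        if b.shape != s.shape:
            raise ValueError(f"blank shape {b.shape} does not match sample shape {s.shape}")
        if np.any(b <= 0):
            raise ValueError("blank-field image must be positive everywhere")
    eps = 10.0 ** (-od_max)
    t = np.clip(s / b, eps, 1.0)
    pixel_size = (
        sample.pixel_size_um if isinstance(sample, ImagePlane) else DEFAULT_PIXEL_SIZE_UM
    )
    return ImagePlane(t, "intensity", pixel_size)


def to_optical_density(
    transmittance: ImagePlane | np.ndarray, od_max: float = DEFAULT_OD_MAX
) -> ImagePlane:
    """Per-pixel optical density ``OD = -log10(T)``, clipped at ``od_max``.

    OD is monotone decreasing in transmittance and OD(1) = 0.
    """
    t = _as_array(transmittance)
    if np.any(t <= 0) or np.any(t > 1):
        raise ValueError("transmittance values must lie in (0, 1]")
    eps = 10.0 ** (-od_max)
    n_clipped = int(np.count_nonzero(t < eps))
    if n_clipped:
        log.info("clipping %d transmittance pixels below %.3g to od_max=%.2f", n_clipped, eps, od_max)
    od = -np.log10(np.maximum(t, eps))
    pixel_size = (
        transmittance.pixel_size_um
        if isinstance(transmittance, ImagePlane)
        else DEFAULT_PIXEL_SIZE_UM
    )
    return ImagePlane(od, "optical_density", pixel_size)


def od_from_raw(
    rgb: np.ndarray,
    blank_rgb: np.ndarray | float,
    od_max: float = DEFAULT_OD_MAX,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> tuple[ImagePlane, ImagePlane]:
    """Convenience chain: green channel -> transmittance -> OD.

    Returns ``(green_intensity, od_plane)``.
    """
    green = extract_green(rgb, pixel_size_um)
    if np.isscalar(blank_rgb):
        blank: ImagePlane | float = float(blank_rgb)
    else:
        blank_arr = np.asarray(blank_rgb)
        blank = extract_green(blank_arr, pixel_size_um) if blank_arr.ndim == 3 else ImagePlane(
            blank_arr, "intensity", pixel_size_um
        )
    t = background_correct(green, blank, od_max)
    return green, to_optical_density(t, od_max)
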