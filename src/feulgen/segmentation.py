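"""Nucleus segmentation: Otsu mask, edge cleaning, watershed, size filter,
label-preserving dilation.

The chain mirrors classic particle-analysis practice on stained sections:
global Otsu threshold of the green channel (nuclei are the dark class),
deletion of objects cut by the image border, distance-transform watershed to
separate touching nuclei, a pixel-count size filter, and morphological
dilation that never merges neighbouring labels.

Foreground components use 8-connectivity, background 4-connectivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from feulgen.optics import ImagePlane

log = logging.getLogger(__name__)

#: 3x3 structuring element: 8-connected foreground
STRUCT8 = np.ones((3, 3), dtype=bool)

DEFAULT_MIN_SIZE = 25
DEFAULT_MAX_SIZE = 300


@dataclass
class LabelMask:
    """Integer-labelled 2-D grid; 0 is background, k > 0 is nucleus k."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("LabelMask requires a 2-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("LabelMask requires an integer array")
        if np.any(self.labels < 0):
            raise ValueError("labels must be non-negative")

    @property
    def n_labels(self) -> int:
        return len(self.label_ids)

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


def _labels_of(mask: LabelMask | np.ndarray) -> np.ndarray:
    return mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)


def otsu_threshold(
    plane: ImagePlane | np.ndarray, n_bins: int = 256
) -> float:
    """Threshold maximising between-class variance on an ``n_bins`` histogram.

    Returns the bin edge (upper edge of the last "dark" bin) such that
    pixels strictly below it form the dark (nucleus) class. Among equally
    good thresholds the lowest is returned.
    """
    values = (plane.pixels if isinstance(plane, ImagePlane) else np.asarray(plane, float)).ravel()
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise ValueError("cannot threshold a constant image")
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))

    # the between-class criterion is invariant under affine transforms of
    # the grey values, so it can be evaluated on integer bin indices with
    # exact integer arithmetic: between(t) ~ (m0*w1 - m1*w0)^2 / (w0*w1),
    # compared as cross-multiplied big-int fractions so near-ties cannot
    # flip on floating round-off
    c = [int(v) for v in counts]
    total_w = sum(c)
    total_m = sum(i * v for i, v in enumerate(c))
    best, best_num, best_den = None, -1, 1
    w0 = m0 = 0
    for t in range(n_bins - 1):
        w0 += c[t]
        m0 += t * c[t]
        w1 = total_w - w0
        if w0 == 0 or w1 == 0:
            continue
        m1 = total_m - m0
        num = (m0 * w1 - m1 * w0) ** 2
        den = w0 * w1
        if num * best_den > best_num * den:  # strict: lowest maximiser wins
            best, best_num, best_den = t, num, den
    return float(edges[best + 1])


def binarize(
    plane: ImagePlane | np.ndarray,
    threshold: float | None = None,
    dark_foreground: bool = True,
    n_bins: int = 256,
) -> np.ndarray:
    """Binary nucleus mask from an intensity (or OD) plane.

    On intensity images nuclei absorb light, so the foreground is the dark
    class (``dark_foreground=True``). On OD planes pass
    ``dark_foreground=False`` to pick the bright class.
    """
    arr = plane.pixels if isinstance(plane, ImagePlane) else np.asarray(plane, float)
    if isinstance(plane, ImagePlane) and plane.value_kind == "optical_density":
        dark_foreground = False
    if threshold is None:
        threshold = otsu_threshold(arr, n_bins)
    return arr < threshold if dark_foreground else arr >= threshold


def remove_edge_objects(mask: LabelMask | np.ndarray) -> np.ndarray:
    """Delete every connected component that touches the image border.

    Accepts a binary or labelled mask; returns the same kind of array.
    """
    arr = _labels_of(mask)
    if arr.dtype == bool:
        labels, _ = ndi.label(arr, structure=STRUCT8)
    else:
        labels = arr
    border = np.zeros_like(labels, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    touching = np.unique(labels[border & (labels > 0)])
    out = arr.copy()
    out[np.isin(labels, touching)] = 0 if arr.dtype != bool else False
    return out


def watershed_split(
    mask: np.ndarray,
    min_seed_distance: int = 5,
    smoothing_sigma: float = 1.0,
) -> LabelMask:
    """Split touching nuclei by distance-transform watershed.

    Seeds are local maxima of the (smoothed) Euclidean distance transform
    separated by at least ``min_seed_distance`` pixels; watershed ridge
    lines become background, so the union of the output labels is a subset
    of the input mask and no pixel carries two labels.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return LabelMask(np.zeros(mask.shape, dtype=np.int32))
    distance = ndi.distance_transform_edt(mask)
    smoothed = ndi.gaussian_filter(distance, smoothing_sigma) if smoothing_sigma > 0 else distance
    # seed per component with a separation that grows with the component's
    # inscribed radius: a large single nucleus has a broad ridge whose
    # near-equal maxima must not each become a seed
    comps, n_comps = ndi.label(mask, structure=STRUCT8)
    markers = np.zeros(mask.shape, dtype=np.int32)
    for sl, comp_id in zip(ndi.find_objects(comps), range(1, n_comps + 1)):
        sub = comps[sl] == comp_id
        inscribed = float(np.max(np.where(sub, distance[sl], 0.0)))
        # extra smoothing for large components flattens the near-constant
        # ridge of a single elongated nucleus into one maximum while the
        # deep neck between genuinely touching nuclei survives
        sigma = max(smoothing_sigma, 0.25 * inscribed)
        sub_dist = np.where(sub, ndi.gaussian_filter(np.where(sub, distance[sl], 0.0), sigma), 0.0)
        sep = max(min_seed_distance, int(0.9 * inscribed))
        coords = peak_local_max(sub_dist, min_distance=sep, labels=sub, exclude_border=False)
        for y, x in coords:
            markers[sl[0].start + y, sl[1].start + x] = 1
    markers, _ = ndi.label(markers > 0, structure=STRUCT8)
    if markers.max() == 0:  # degenerate: no maxima found, keep components whole
        labels, _ = ndi.label(mask, structure=STRUCT8)
        return LabelMask(labels.astype(np.int32))
    labels = watershed(-smoothed, markers, mask=mask, watershed_line=True)
    return relabel_sequential(labels)


def relabel_sequential(labels: np.ndarray) -> LabelMask:
    """Renumber labels to 1..n in ascending order of the old ids."""
    labels = np.asarray(labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(int(labels.max()) + 1 if labels.size else 1, dtype=np.int32)
    lut[ids] = np.arange(1, len(ids) + 1, dtype=np.int32)
    return LabelMask(lut[labels])


def size_filter(
    labels: LabelMask | np.ndarray,
    min_px: int = DEFAULT_MIN_SIZE,
    max_px: float = DEFAULT_MAX_SIZE,
) -> LabelMask:
    """Keep only labels whose pixel count lies in ``[min_px, max_px]`` inclusive."""
    if min_px > max_px:
        raise ValueError(f"min_px {min_px} exceeds max_px {max_px}")
    arr = _labels_of(labels)
    if arr.dtype == bool:
        arr, _ = ndi.label(arr, structure=STRUCT8)
    out = arr.copy()
    ids, counts = np.unique(arr[arr > 0], return_counts=True)
    bad = ids[(counts < min_px) | (counts > max_px)]
    out[np.isin(out, bad)] = 0
    return relabel_sequential(out)


def dilate_no_merge(labels: LabelMask | np.ndarray, iterations: int = 1) -> LabelMask:
    """Grow each label by 8-connected shells without merging neighbours.

    In each iteration a background pixel adjacent to exactly one label takes
    that label; a pixel contested by two or more labels stays background.
    The number of distinct labels is invariant.
    """
    arr = _labels_of(labels).astype(np.int64).copy()
    sentinel = np.int64(2) ** 31  # far above any label id; int64.max overflows inside the filter
    for _ in range(iterations):
        hi = ndi.maximum_filter(arr, footprint=STRUCT8)
        lo = ndi.minimum_filter(np.where(arr == 0, sentinel, arr), footprint=STRUCT8)
        grow = (arr == 0) & (hi > 0) & (hi == lo)
        arr[grow] = hi[grow]
    return LabelMask(arr.astype(np.int32))


def apply_exclusion(
    labels: LabelMask | np.ndarray,
    exclusion: np.ndarray,
    max_overlap: float = 0.5,
) -> LabelMask:
    """Delete labels overlapping an exclusion mask by more than ``max_overlap``.

    Automated stand-in for manual removal of non-target nuclei: any label
    whose fraction of pixels inside the exclusion mask strictly exceeds the
    threshold is dropped.
    """
    arr = _labels_of(labels)
    excl = np.asarray(exclusion).astype(bool)
    if excl.shape != arr.shape:
        raise ValueError(f"exclusion shape {excl.shape} does not match labels {arr.shape}")
    out = arr.copy()
    ids, totals = np.unique(arr[arr > 0], return_counts=True)
    if len(ids) == 0:
        return LabelMask(out)
    inside = np.bincount(arr[excl & (arr > 0)], minlength=int(arr.max()) + 1)[ids]
    bad = ids[inside / totals > max_overlap]
    out[np.isin(out, bad)] = 0
    return LabelMask(out)


def segment_nuclei(
    plane: ImagePlane | np.ndarray,
    n_bins: int = 256,
    min_px: int = DEFAULT_MIN_SIZE,
    max_px: float = DEFAULT_MAX_SIZE,
    dilate_iterations: int = 0,
    use_watershed: bool = True,
    min_seed_distance: int = 5,
    exclusion: np.ndarray | None = None,
    dark_foreground: bool = True,
    fill_holes: bool = True,
) -> LabelMask:
    """Full segmentation chain from an intensity plane to a label mask.

    Bright chromatin clearings inside a nucleus can fall above the global
    threshold, so interior holes are filled by default before watershed.
    """
    mask = binarize(plane, dark_foreground=dark_foreground, n_bins=n_bins)
    if fill_holes:
        # close hairline constrictions left by bright chromatin bands,
        # then fill interior clearings
        mask = ndi.binary_closing(mask, structure=STRUCT8)
        mask = ndi.binary_fill_holes(mask)
    mask = remove_edge_objects(mask)
    if use_watershed:
        lm = watershed_split(mask, min_seed_distance=min_seed_distance)
    else:
        labels, _ = ndi.label(mask, structure=STRUCT8)
        lm = LabelMask(labels.astype(np.int32))
    lm = size_filter(lm, min_px=min_px, max_px=max_px)
    if dilate_iterations > 0:
        lm = dilate_no_merge(lm, dilate_iterations)
    if exclusion is not None:
        lm = apply_exclusion(lm, exclusion)
    log.debug("segment_nuclei: %d labels", lm.n_labels)
    return lm
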