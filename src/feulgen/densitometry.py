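"""Integrated optical density, DNA content and ploidy histograms.

The stain amount bound in a Feulgen preparation is stoichiometric with DNA,
so the summed optical density over a nucleus (IOD) is proportional to its
DNA content. A nucleus's C-value is the IOD scaled by a reference standard
(the mean IOD of normal haemocytes, taken as 1C); the ploidy ratio is the
raw IOD ratio, so the reference population sits at 1 by construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from feulgen.optics import ImagePlane
from feulgen.segmentation import LabelMask

log = logging.getLogger(__name__)

#: DNA mass of the 1C primary standard in picograms (normal mussel haemocytes)
DEFAULT_CP_PG = 0.96

#: minimum reference-population size before calibrate_reference warns
MIN_REFERENCE_N = 30

DEFAULT_BIN_WIDTH = 0.2
DEFAULT_PLOIDY_RANGE = (0.0, 50.0)
DEFAULT_SMOOTH_WINDOW = 7
DEFAULT_MIN_PROMINENCE = 0.05


@dataclass
class ReferenceStandard:
    """Calibration anchor: mean IOD of the reference population = ``cp_pg`` picograms."""

    iodp: float
    cp_pg: float = DEFAULT_CP_PG
    n_reference: int = 0

    def __post_init__(self) -> None:
        if not self.iodp > 0:
            raise ValueError("reference mean IOD must be positive")


@dataclass
class PloidyProfile:
    """Histogram of per-nucleus ploidy ratios with smoothed curve and peaks.

    ``peaks`` is a DataFrame with columns ``location`` (C-ratio),
    ``height`` and ``prominence``.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    smoothed: np.ndarray
    peaks: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["location", "height", "prominence"])
    )

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_centre": self.bin_centres, "count": self.counts, "smoothed": self.smoothed}
        )


def integrated_od(
    region_mask: np.ndarray, od_plane: ImagePlane | np.ndarray
) -> tuple[float, float]:
    """IOD (summed OD over the region) and GrAverage (mean OD).

    ``IOD = sum_i -log10(IF_i / IB_i)`` where the log-ratio plane has been
    prepared by the optics module.
    """
    mask = np.asarray(region_mask).astype(bool)
    od = od_plane.pixels if isinstance(od_plane, ImagePlane) else np.asarray(od_plane, float)
    if mask.shape != od.shape:
        raise ValueError(f"mask shape {mask.shape} does not match OD plane {od.shape}")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("cannot integrate over an empty region")
    total = float(od[mask].sum())
    return total, total / n


def integrate_labels(labels: LabelMask | np.ndarray, od_plane: ImagePlane | np.ndarray) -> pd.DataFrame:
    """IOD and GrAverage for every label; one row per label, ascending."""
    arr = labels.labels if isinstance(labels, LabelMask) else np.asarray(labels)
    od = od_plane.pixels if isinstance(od_plane, ImagePlane) else np.asarray(od_plane, float)
    if arr.shape != od.shape:
        raise ValueError("label mask and OD plane dimensions differ")
    ids = np.unique(arr[arr > 0])
    sums = np.array([float(od[arr == i].sum()) for i in ids])
    counts = np.array([int((arr == i).sum()) for i in ids])
    return pd.DataFrame(
        {"label": ids, "IOD": sums, "GrAverage": sums / counts, "pixel_count": counts}
    )


def calibrate_reference(
    reference: pd.DataFrame | np.ndarray,
    cp_pg: float = DEFAULT_CP_PG,
    min_n: int = MIN_REFERENCE_N,
) -> ReferenceStandard:
    """Reference standard from a table (with an ``IOD`` column) or IOD array."""
    iods = np.asarray(reference["IOD"] if isinstance(reference, pd.DataFrame) else reference, float)
    iods = iods[np.isfinite(iods)]
    if len(iods) == 0:
        raise ValueError("reference table is empty")
    if len(iods) < min_n:
        warnings.warn(
            f"reference population has only {len(iods)} nuclei (< {min_n}); "
            "the standard may be unstable",
            stacklevel=2,
        )
    iodp = float(iods.mean())
    if iodp <= 0:
        raise ValueError("reference mean IOD must be positive")
    return ReferenceStandard(iodp=iodp, cp_pg=cp_pg, n_reference=len(iods))


def ploidy(
    iod: float | np.ndarray, standard: ReferenceStandard
) -> tuple[float | np.ndarray, float | np.ndarray]:
    """DNA content and ploidy ratio of a sample IOD against the standard.

    ``Cs = IODs * Cp / IODp`` (picograms); the ploidy ratio is
    ``IODs / IODp`` so the reference population averages exactly 1.
    """
    ratio = np.asarray(iod, dtype=float) / standard.iodp
    cs = ratio * standard.cp_pg
    if np.isscalar(iod) or np.ndim(iod) == 0:
        return float(cs), float(ratio)
    return cs, ratio


def ploidy_histogram(
    ratios: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
    ploidy_range: tuple[float, float] = DEFAULT_PLOIDY_RANGE,
) -> PloidyProfile:
    """Histogram of ploidy ratios on a grid whose bin centres sit on
    multiples of ``bin_width`` (so integer ploidy values fall on centres)."""
    ratios = np.asarray(ratios, float)
    ratios = ratios[np.isfinite(ratios)]
    lo, hi = ploidy_range
    first = np.floor(lo / bin_width)
    last = np.ceil(hi / bin_width)
    edges = (np.arange(first, last + 1) - 0.5) * bin_width
    counts, _ = np.histogram(ratios, bins=edges)
    counts = counts.astype(float)
    return PloidyProfile(bin_edges=edges, counts=counts, smoothed=counts.copy())


def smooth_profile(counts: np.ndarray, window: int = DEFAULT_SMOOTH_WINDOW) -> np.ndarray:
    """Centred running average; near the edges the window shrinks
    symmetrically so no padding value is invented."""
    if window % 2 != 1 or window < 1:
        raise ValueError("smoothing window must be odd and >= 1")
    counts = np.asarray(counts, float)
    n = len(counts)
    if window == 1 or n == 0:
        return counts.copy()
    half = window // 2
    idx = np.arange(n)
    # symmetric shrinking: the half-width shrinks near the edges so the
    # window stays centred (an asymmetric truncated window would inflate
    # edge bins above interior plateaus)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    csum = np.concatenate([[0.0], np.cumsum(counts)])
    total = csum[idx + h + 1] - csum[idx - h]
    return total / (2 * h + 1)


def detect_peaks(
    profile: PloidyProfile,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    window: int = DEFAULT_SMOOTH_WINDOW,
    coarse_factor: int = 9,
) -> pd.DataFrame:
    """Local maxima of the smoothed histogram.

    A maximum is reported when its prominence reaches
    ``min_prominence x max(smoothed)``; the location is the bin centre of
    the maximum. A second pass on a ``coarse_factor``-times-wider running
    average catches shallow-but-broad components (e.g. a wide high-ploidy
    shoulder at ~15% mixture weight) whose mass is spread too thinly for
    the narrow window; coarse peaks closer than half the coarse window to an
    already-found peak are discarded as duplicates. Updates
    ``profile.smoothed``/``profile.peaks`` in place and returns the peak
    table sorted by location.
    """
    profile.smoothed = smooth_profile(profile.counts, window)
    centres = profile.bin_centres
    sm = profile.smoothed
    if len(sm) == 0 or sm.max() <= 0:
        profile.peaks = pd.DataFrame(columns=["location", "height", "prominence"])
        return profile.peaks

    bin_width = centres[1] - centres[0] if len(centres) > 1 else 1.0

    def refine(i: int, half: int) -> float:
        """Count-weighted centre of the bins around a peak index."""
        lo, hi = max(0, i - half), min(len(centres), i + half + 1)
        mass = profile.counts[lo:hi]
        if mass.sum() <= 0:
            return float(centres[i])
        return float(np.average(centres[lo:hi], weights=mass))

    # wlen bounds the prominence base so shallow wiggles riding on a broad
    # component are judged against their local surroundings, not the
    # global valley
    wlen = max(window * coarse_factor, 3)
    idx, props = find_peaks(sm, prominence=min_prominence * float(sm.max()), wlen=wlen)
    # suppress split maxima closer than one smoothing window, strongest wins
    locations: list[float] = []
    heights: list[float] = []
    prominences: list[float] = []
    min_sep = window * bin_width
    for k in np.argsort(-props["prominences"]):
        loc = refine(int(idx[k]), window // 2)
        if any(abs(loc - x) < min_sep for x in locations):
            continue
        locations.append(loc)
        heights.append(float(sm[idx[k]]))
        prominences.append(float(props["prominences"][k]))

    coarse_window = window * coarse_factor
    coarse_window += 1 - coarse_window % 2
    total = float(profile.counts.sum())
    if coarse_factor > 1 and len(sm) > coarse_window and total > 0:
        coarse = smooth_profile(profile.counts, coarse_window)
        cidx, cprops = find_peaks(coarse, prominence=0)
        merge_radius = 0.5 * coarse_window * bin_width
        # a broad component must still carry real mass: its smoothed height
        # times the coarse window approximates the nuclei it holds
        order = np.argsort(-cprops["prominences"])
        coarse_accepted: list[float] = []
        for k in order:
            i = int(cidx[k])
            loc = centres[i]
            if coarse[i] * coarse_window < min_prominence * total:
                continue
            if any(abs(loc - x) <= merge_radius for x in locations):
                continue
            # wiggles within one full coarse window of a stronger coarse
            # peak belong to the same broad component
            if any(abs(loc - x) <= 2 * merge_radius for x in coarse_accepted):
                continue
            coarse_accepted.append(loc)
            locations.append(refine(i, coarse_window // 2))
            heights.append(float(coarse[i]))
            prominences.append(float(cprops["prominences"][k]))

    profile.peaks = pd.DataFrame(
        {"location": locations, "height": heights, "prominence": prominences}
    ).sort_values("location", ignore_index=True)
    return profile.peaks


def profile_from_iods(
    iods: np.ndarray,
    standard: ReferenceStandard,
    bin_width: float = DEFAULT_BIN_WIDTH,
    ploidy_range: tuple[float, float] = DEFAULT_PLOIDY_RANGE,
    window: int = DEFAULT_SMOOTH_WINDOW,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> PloidyProfile:
    """Full chain: IODs -> ploidy ratios -> smoothed histogram with peaks."""
    _, ratios = ploidy(np.asarray(iods, float), standard)
    profile = ploidy_histogram(ratios, bin_width=bin_width, ploidy_range=ploidy_range)
    detect_peaks(profile, min_prominence=min_prominence, window=window)
    return profile
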