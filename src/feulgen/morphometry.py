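"""Per-nucleus shape descriptors from labelled masks.

Measures follow the particle-analysis convention in which the region outline
is the closed polygon through the centres of its boundary pixels (traced
with the Moore neighbourhood, 8-connected foreground). Area and perimeter
are polygon quantities, not raw pixel counts; the pixel count is kept as a
separate column because the segmentation size filter operates on it.

Descriptor set (21 columns, fixed order):

====================  =========  =============================================
IOD                   OD*px      summed optical density over the region
GrAverage             OD         IOD / pixel count
Perimeter             px         length of the boundary polygon
Area                  px^2       shoelace area of the boundary polygon
MinR, MaxR            px         min/max centroid-to-boundary distance
Feret                 px         largest boundary point pair distance
Breadth               px         extent perpendicular to the Feret axis
CHull                 px         convex-hull perimeter
MBCRadius             px         minimal bounding circle radius
AspRatio              --         Feret / Breadth
Circularity           --         4*pi*Area / Perimeter^2 (form factor)
Roundness             --         4*Area / (pi*Feret^2)
Compactness           --         sqrt((4/pi)*Area) / Feret
Solidity              --         Area / ConvexArea
Concavity             px^2       ConvexArea - Area
Convexity             --         CHull / Perimeter
Shape                 --         Perimeter^2 / Area
ModRatio              --         2*MinR / Feret
Sphericity            --         MinR / MaxR
Rectangularity        --         Area / (Feret * Breadth)
====================  =========  =============================================
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError

from feulgen.optics import ImagePlane
from feulgen.segmentation import LabelMask

log = logging.getLogger(__name__)

#: the 21 descriptor columns, in output order
DESCRIPTOR_COLUMNS = [
    "IOD", "GrAverage", "Perimeter", "Area", "MinR", "MaxR", "Feret",
    "Breadth", "CHull", "MBCRadius", "AspRatio", "Circularity", "Roundness",
    "Compactness", "Solidity", "Concavity", "Convexity", "Shape", "ModRatio",
    "Sphericity", "Rectangularity",
]

#: provenance columns appended after the descriptors
PROVENANCE_COLUMNS = ["label", "pixel_count", "image_id", "stage", "cell_type", "ploidy"]

# Moore neighbourhood in clockwise order (dy, dx), y pointing down
_CLOCKWISE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Trace the closed boundary of a connected region through pixel centres.

    Moore-neighbour tracing with 8-connected foreground. Returns an (n, 2)
    array of ``(x, y)`` pixel-centre coordinates, oriented so the shoelace
    sum over ``(x, y)`` is non-negative, without the closing vertex repeated.
    A single-pixel region yields a single point.
    """
    mask = np.asarray(mask).astype(bool)
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        raise ValueError("cannot trace an empty region")
    order = np.lexsort((xs, ys))  # topmost, then leftmost
    start = (int(ys[order[0]]), int(xs[order[0]]))
    if len(ys) == 1:
        return np.array([[start[1], start[0]]], dtype=float)

    h, w = mask.shape

    def is_fg(p: tuple[int, int]) -> bool:
        return 0 <= p[0] < h and 0 <= p[1] < w and mask[p]

    contour: list[tuple[int, int]] = []
    c = start
    b = (start[0], start[1] - 1)  # background by the raster-scan choice of start
    seen: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    while (c, b) not in seen:
        seen.add((c, b))
        contour.append(c)
        db = (b[0] - c[0], b[1] - c[1])
        idx = _CLOCKWISE.index(db)
        nxt = None
        for k in range(1, 9):
            off = _CLOCKWISE[(idx + k) % 8]
            cand = (c[0] + off[0], c[1] + off[1])
            if is_fg(cand):
                prev_off = _CLOCKWISE[(idx + k - 1) % 8]
                nxt = cand
                b = (c[0] + prev_off[0], c[1] + prev_off[1])
                break
        if nxt is None:  # isolated pixel under 8-connectivity
            break
        c = nxt
    poly = np.array([[x, y] for y, x in contour], dtype=float)
    if _signed_area(poly) < 0:
        poly = poly[::-1]
    return poly


def _signed_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _poly_length(poly: np.ndarray) -> float:
    d = np.diff(np.vstack([poly, poly[:1]]), axis=0)
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def base_measures(mask: np.ndarray) -> dict[str, float]:
    """Size measures of one connected region.

    Returns a dict with ``Perimeter``, ``Area``, ``MinR``, ``MaxR``,
    ``Feret``, ``Breadth``, ``CHull``, ``ConvexArea``, ``MBCRadius`` and
    ``pixel_count``. Regions whose boundary polygon has fewer than 3 unique
    vertices are degenerate: Area falls back to the pixel count, Perimeter
    to 0, and the remaining measures to NaN.
    """
    mask = np.asarray(mask).astype(bool)
    pixel_count = int(mask.sum())
    poly = trace_boundary(mask)
    points = np.unique(poly, axis=0)
    out: dict[str, float] = {"pixel_count": float(pixel_count)}
    if len(points) < 3 or abs(_signed_area(poly)) == 0.0:
        out.update(
            Perimeter=0.0, Area=float(pixel_count), MinR=np.nan, MaxR=np.nan,
            Feret=np.nan, Breadth=np.nan, CHull=np.nan, ConvexArea=np.nan,
            MBCRadius=np.nan,
        )
        return out

    ys, xs = np.nonzero(mask)
    centroid = np.array([xs.mean(), ys.mean()])

    out["Perimeter"] = _poly_length(poly)
    out["Area"] = abs(_signed_area(poly))

    # MinR: inscribed circle centred at the centre of mass touches the
    # boundary polygon, so use point-to-segment distance; the enclosing
    # circle (MaxR) always touches a vertex.
    out["MinR"] = _min_distance_to_polygon(centroid, poly)
    dists = np.hypot(points[:, 0] - centroid[0], points[:, 1] - centroid[1])
    out["MaxR"] = float(dists.max())

    try:
        hull = ConvexHull(points)
        hull_pts = points[hull.vertices]
        out["CHull"] = _poly_length(hull_pts)
        out["ConvexArea"] = abs(_signed_area(hull_pts))
    except QhullError:  # collinear boundary
        hull_pts = points
        out["CHull"] = np.nan
        out["ConvexArea"] = np.nan

    feret, pair = _max_feret(hull_pts)
    out["Feret"] = feret
    axis = pair[1] - pair[0]
    norm = np.hypot(*axis)
    if norm > 0:
        perp = np.array([-axis[1], axis[0]]) / norm
        proj = points @ perp
        out["Breadth"] = float(proj.max() - proj.min())
    else:
        out["Breadth"] = np.nan

    out["MBCRadius"] = float(shapely.minimum_bounding_radius(shapely.MultiPoint(points)))
    return out


def _min_distance_to_polygon(point: np.ndarray, poly: np.ndarray) -> float:
    """Distance from a point to a closed polyline (vertices and edges)."""
    a = poly
    b = np.roll(poly, -1, axis=0)
    ab = b - a
    ap = point[None, :] - a
    denom = np.einsum("ij,ij->i", ab, ab)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.clip(np.einsum("ij,ij->i", ap, ab) / denom, 0.0, 1.0)
    t = np.nan_to_num(t)
    closest = a + t[:, None] * ab
    return float(np.min(np.hypot(*(point[None, :] - closest).T)))


def _max_feret(pts: np.ndarray) -> tuple[float, np.ndarray]:
    """Largest pairwise distance among points (antipodal pair on the hull).

    Ties (several maximal chords, e.g. the two diagonals of a square) are
    broken by the lexicographically smallest pair of endpoints so the
    dependent Breadth measure is deterministic.
    """
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    dmax = float(np.max(d2))
    ii, jj = np.nonzero(d2 >= dmax - 1e-9)
    pairs = sorted(
        tuple(sorted((tuple(pts[i]), tuple(pts[j])))) for i, j in zip(ii, jj) if i < j
    )
    a, b = pairs[0]
    return float(math.sqrt(dmax)), np.array([a, b], dtype=float)


def derived_descriptors(base: dict[str, float]) -> dict[str, float]:
    """Ratio descriptors from the base size measures.

    Any descriptor with a zero or non-finite denominator is set to NaN.
    """
    p, a = base.get("Perimeter", np.nan), base.get("Area", np.nan)
    feret, breadth = base.get("Feret", np.nan), base.get("Breadth", np.nan)
    minr, maxr = base.get("MinR", np.nan), base.get("MaxR", np.nan)
    chull, carea = base.get("CHull", np.nan), base.get("ConvexArea", np.nan)

    def ratio(num: float, den: float) -> float:
        if not np.isfinite(den) or den == 0 or not np.isfinite(num):
            return np.nan
        return num / den

    return {
        "AspRatio": ratio(feret, breadth),
        "Circularity": ratio(4.0 * math.pi * a, p * p),
        "Roundness": ratio(4.0 * a, math.pi * feret * feret),
        "Compactness": ratio(math.sqrt(4.0 / math.pi * a) if a >= 0 else np.nan, feret),
        "Solidity": ratio(a, carea),
        "Concavity": carea - a if np.isfinite(carea) else np.nan,
        "Convexity": ratio(chull, p),
        "Shape": ratio(p * p, a),
        "ModRatio": ratio(2.0 * minr, feret),
        "Sphericity": ratio(minr, maxr),
        "Rectangularity": ratio(a, feret * breadth),
    }


def measure_region(mask: np.ndarray, od: np.ndarray | None = None) -> dict[str, float]:
    """All 21 descriptors of one region; OD columns NaN when no OD given."""
    rec = base_measures(mask)
    rec.update(derived_descriptors(rec))
    if od is not None:
        od = np.asarray(od, dtype=float)
        vals = od[mask.astype(bool)]
        rec["IOD"] = float(vals.sum())
        rec["GrAverage"] = float(vals.sum() / len(vals)) if len(vals) else np.nan
    else:
        rec["IOD"] = np.nan
        rec["GrAverage"] = np.nan
    return rec


def measure_all(
    labels: LabelMask | np.ndarray,
    od_plane: ImagePlane | np.ndarray | None = None,
    image_id: str = "",
    stage: str = "",
    cell_type: str = "unknown",
) -> pd.DataFrame:
    """Feature table with one row per label, ascending label order.

    ``od_plane`` must match the mask dimensions; when omitted the
    densitometric columns (IOD, GrAverage) are NaN.
    """
    arr = labels.labels if isinstance(labels, LabelMask) else np.asarray(labels)
    od = None
    if od_plane is not None:
        od = od_plane.pixels if isinstance(od_plane, ImagePlane) else np.asarray(od_plane, float)
        if od.shape != arr.shape:
            raise ValueError(f"OD plane shape {od.shape} does not match labels {arr.shape}")

    rows = []
    slices = ndi.find_objects(arr)
    for idx, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        sub = arr[sl] == idx
        rec = measure_region(sub, od[sl] if od is not None else None)
        rec.update(label=idx, image_id=image_id, stage=stage, cell_type=cell_type, ploidy=np.nan)
        rows.append(rec)
    cols = DESCRIPTOR_COLUMNS + PROVENANCE_COLUMNS
    if not rows:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows)
    df["pixel_count"] = df["pixel_count"].astype(int)
    return df[cols]
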