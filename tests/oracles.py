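"""Independent brute-force oracles used across the suite.

These deliberately avoid the library code paths they check: exhaustive
scans, flood fill, and O(n^2)/O(n^3) geometry.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def otsu_bruteforce(values: np.ndarray, n_bins: int = 256) -> float:
    """Exhaustive between-class-variance scan over every candidate split.

    The criterion is affine-invariant in the grey values, so it is scored
    on integer bin indices with exact (Fraction) arithmetic; for each split
    every partial sum is recomputed from scratch.
    """
    from fractions import Fraction

    values = np.asarray(values, float).ravel()
    counts, edges = np.histogram(values, bins=n_bins, range=(values.min(), values.max()))
    c = [int(v) for v in counts]
    best_t, best_var = None, Fraction(-1)
    for t in range(n_bins - 1):  # split after bin t
        w0 = sum(c[: t + 1])
        w1 = sum(c[t + 1:])
        if w0 == 0 or w1 == 0:
            continue
        m0 = sum(i * c[i] for i in range(t + 1))
        m1 = sum(i * c[i] for i in range(t + 1, n_bins))
        var = Fraction((m0 * w1 - m1 * w0) ** 2, w0 * w1)
        if var > best_var:  # strict: keeps the lowest maximiser
            best_var, best_t = var, t
    return float(edges[best_t + 1])


def flood_fill_count(mask: np.ndarray) -> int:
    """Number of 8-connected components by breadth-first flood fill."""
    mask = np.asarray(mask).astype(bool)
    seen = np.zeros_like(mask)
    count = 0
    h, w = mask.shape
    for sy, sx in zip(*np.nonzero(mask)):
        if seen[sy, sx]:
            continue
        count += 1
        queue = deque([(sy, sx)])
        seen[sy, sx] = True
        while queue:
            y, x = queue.popleft()
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                        seen[ny, nx] = True
                        queue.append((ny, nx))
    return count


def feret_bruteforce(points: np.ndarray) -> tuple[float, np.ndarray]:
    """Max pairwise distance over ALL boundary points, O(n^2).

    Tied maximal chords resolve to the lexicographically smallest endpoint
    pair (same convention as the library) so Breadth is comparable.
    """
    diff = points[:, None, :] - points[None, :, :]
    d2 = (diff**2).sum(axis=-1)
    dmax = float(np.max(d2))
    ii, jj = np.nonzero(d2 >= dmax - 1e-9)
    pairs = sorted(
        tuple(sorted((tuple(points[i]), tuple(points[j]))))
        for i, j in zip(ii, jj)
        if i < j
    )
    a, b = pairs[0]
    return float(np.sqrt(dmax)), np.array([a, b], dtype=float)


def breadth_bruteforce(points: np.ndarray) -> float:
    """Extent perpendicular to the brute-force Feret chord."""
    _, (a, b) = feret_bruteforce(points)
    axis = b - a
    perp = np.array([-axis[1], axis[0]]) / np.hypot(*axis)
    proj = points @ perp
    return float(proj.max() - proj.min())


def mbc_bruteforce(points: np.ndarray, tol: float = 1e-9) -> float:
    """Minimal enclosing circle radius by trying all pairs and triples.

    Exhaustive O(n^3) enumeration (vectorised for speed, not pruned): the
    optimal circle is determined by two diametral points or by three points
    on its rim, so testing every candidate and keeping the smallest circle
    that covers all points is exact.
    """
    points = np.asarray(points, float)
    n = len(points)
    ii, jj = np.triu_indices(n, k=1)
    centres = 0.5 * (points[ii] + points[jj])
    radii = 0.5 * np.sqrt(((points[ii] - points[jj]) ** 2).sum(axis=1))

    ti, tj, tk = _triple_indices(n)
    a, b, c = points[ti], points[tj], points[tk]
    d = 2.0 * (a[:, 0] * (b[:, 1] - c[:, 1]) + b[:, 0] * (c[:, 1] - a[:, 1])
               + c[:, 0] * (a[:, 1] - b[:, 1]))
    ok = np.abs(d) > 1e-12
    a2 = (a**2).sum(axis=1)
    b2 = (b**2).sum(axis=1)
    c2 = (c**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ux = (a2 * (b[:, 1] - c[:, 1]) + b2 * (c[:, 1] - a[:, 1]) + c2 * (a[:, 1] - b[:, 1])) / d
        uy = (a2 * (c[:, 0] - b[:, 0]) + b2 * (a[:, 0] - c[:, 0]) + c2 * (b[:, 0] - a[:, 0])) / d
    tri_centres = np.stack([ux[ok], uy[ok]], axis=1)
    tri_radii = np.sqrt(((a[ok] - tri_centres) ** 2).sum(axis=1))

    centres = np.vstack([centres, tri_centres])
    radii = np.concatenate([radii, tri_radii])
    order = np.argsort(radii)
    for idx in order:
        dist = np.sqrt(((points - centres[idx]) ** 2).sum(axis=1))
        if np.all(dist <= radii[idx] + tol):
            return float(radii[idx])
    raise AssertionError("no covering candidate circle found")


def _triple_indices(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    i, j, k = np.meshgrid(np.arange(n), np.arange(n), np.arange(n), indexing="ij")
    sel = (i < j) & (j < k)
    return i[sel], j[sel], k[sel]


def shoelace(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))
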