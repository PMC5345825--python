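"""Synthetic Feulgen-stained scenes and feature tables with known ground truth.

The generator produces brightfield-like RGB images of dark stained nuclei on
a bright background. The stain model is stoichiometric: each nucleus carries
a per-pixel optical-density field whose sum equals ``od_per_C x dna_content``
exactly, and the transmitted intensity follows Beer--Lambert,
``IF = IB * 10**(-OD)``, with the green channel carrying the full stain
absorption. Stage presets draw DNA contents from ploidy mixtures that mirror
the disease progression of haemic neoplasia in mussels: a normal component
at 1n plus aneuploid components whose centres depend on severity, rendered
with the corresponding morphotypes (A: ovoid, pleomorphic, vesicular;
B: round, larger, dense chromatin; very-high-ploidy material as
multinucleate clusters of overlapping lobes).

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from feulgen.segmentation import LabelMask

STAGES = ("normal", "light", "moderate", "heavy")
GROUPS = ("normal", "neoplastic", "A", "B")

#: default ploidy mixtures per disease stage:
#: (centre in C-units, weight, CV, morphotype) — weights are conventions,
#: not measured proportions, and can be overridden.
STAGE_MIXTURES: dict[str, list[tuple[float, float, float, str]]] = {
    "normal": [(1.0, 1.0, 0.08, "normal")],
    "light": [
        (1.0, 0.50, 0.08, "normal"),
        (6.2, 0.35, 0.08, "A"),
        (10.7, 0.15, 0.08, "A"),
    ],
    "moderate": [
        (1.0, 0.40, 0.08, "normal"),
        (7.0, 0.60, 0.08, "AB"),
    ],
    "heavy": [
        (1.0, 0.30, 0.08, "normal"),
        (7.8, 0.55, 0.08, "B"),
        (31.0, 0.15, 0.18, "multi"),
    ],
}

#: nucleus geometry per morphotype: 1C-equivalent radius (px), radius SD,
#: aspect-ratio spread, boundary irregularity, chromatin texture, and the
#: exponent with which radius grows with DNA content. A-type (vesicular)
#: nuclei dilute their stain over an area roughly proportional to DNA, so
#: their mean OD stays near the normal level; B-type chromatin is denser
#: (area grows sub-linearly), matching the published mean-OD ratios.
_MORPHOLOGY = {
    "normal": dict(radius=6.1, radius_sd=0.35, aspect_spread=0.12, irregularity=0.05,
                   texture=0.20, dna_exponent=0.50),
    "A": dict(radius=4.3, radius_sd=0.40, aspect_spread=0.45, irregularity=0.16,
              texture=0.15, dna_exponent=0.55),
    "B": dict(radius=6.0, radius_sd=0.40, aspect_spread=0.05, irregularity=0.05,
              texture=0.35, dna_exponent=0.40),
}


@dataclass
class NucleusSpec:
    """Parameters of one rendered nucleus (or multinucleate cluster)."""

    centre: tuple[float, float]  # (x, y), 0-based pixel coordinates
    morphotype: str
    base_radius: float
    aspect_ratio: float
    orientation: float
    boundary_irregularity: float
    dna_content: float
    chromatin_texture: float
    n_lobes: int = 1  # > 1 renders an overlapping multinucleate cluster

    def __post_init__(self) -> None:
        if self.base_radius <= 0:
            raise ValueError("base_radius must be positive")
        if self.dna_content <= 0:
            raise ValueError("dna_content must be positive")
        if self.aspect_ratio < 1:
            raise ValueError("aspect_ratio must be >= 1")
        if self.boundary_irregularity < 0 or self.chromatin_texture < 0:
            raise ValueError("irregularity and texture must be non-negative")

    @property
    def extent(self) -> float:
        """Conservative outer radius in pixels, including lobes."""
        r = self.base_radius * math.sqrt(self.aspect_ratio) * (1 + self.boundary_irregularity + 0.1)
        if self.n_lobes > 1:
            r += 1.1 * self.base_radius * (self.n_lobes - 1) ** 0.5
        return r


@dataclass
class SyntheticSceneSpec:
    """Full parameterisation of one generated scene."""

    width: int
    height: int
    nuclei: list[NucleusSpec]
    stage_preset: str = "normal"
    background_level: float = 220.0
    illumination_gradient: tuple[float, float] = (0.0, 0.0)
    noise_sd: float = 0.0
    od_per_C: float = 28.0
    touching_pair_fraction: float = 0.0
    multinucleate_fraction: float = 0.0
    seed: int = 0

    def to_dict(self) -> dict:
        def plain(v):
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, (list, tuple)):
                return [plain(x) for x in v]
            if isinstance(v, dict):
                return {k: plain(x) for k, x in v.items()}
            return v

        d = plain(asdict(self))
        d["illumination_gradient"] = list(d["illumination_gradient"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSceneSpec":
        d = dict(d)
        d["nuclei"] = [
            NucleusSpec(**{**n, "centre": tuple(n["centre"])}) for n in d["nuclei"]
        ]
        d["illumination_gradient"] = tuple(d["illumination_gradient"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        import pathlib

        import yaml

        pathlib.Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSceneSpec":
        import pathlib

        import yaml

        return cls.from_dict(yaml.safe_load(pathlib.Path(path).read_text()))


@dataclass
class GroundTruth:
    """Per-pixel and per-nucleus truth for a rendered scene."""

    label_mask: LabelMask
    table: pd.DataFrame  # columns: label, morphotype, dna_content, true_iod


def sample_dna_contents(
    stage: str,
    n: int,
    rng: np.random.Generator,
    cv: float | None = None,
    weights: Sequence[float] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Draw DNA contents (C-units) and morphotypes from a stage mixture."""
    if stage not in STAGE_MIXTURES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    mixture = STAGE_MIXTURES[stage]
    w = np.array([m[1] for m in mixture] if weights is None else weights, float)
    if len(w) != len(mixture) or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("mixture weights must be non-negative, one per component")
    w = w / w.sum()
    comp = rng.choice(len(mixture), size=n, p=w)
    dna = np.empty(n)
    morphotypes: list[str] = []
    for i, c in enumerate(comp):
        centre, _, comp_cv, morph = mixture[c]
        comp_cv = cv if cv is not None else comp_cv
        value = rng.normal(centre, comp_cv * centre)
        dna[i] = max(value, 0.05 * centre)
        if morph == "AB":
            morph = "A" if rng.random() < 0.5 else "B"
        morphotypes.append(morph)
    return dna, morphotypes


def _make_nucleus(
    dna: float, morphotype: str, rng: np.random.Generator
) -> NucleusSpec:
    if morphotype == "multi":
        lobes = int(rng.integers(3, 7))
        geo = _MORPHOLOGY["B"]
        lobe_dna = dna / lobes
        radius = max(float(rng.normal(geo["radius"], geo["radius_sd"])), 2.5)
        return NucleusSpec(
            centre=(0.0, 0.0),
            morphotype="B",
            base_radius=radius * lobe_dna ** geo["dna_exponent"],
            aspect_ratio=1.0 + abs(rng.normal(0, geo["aspect_spread"])),
            orientation=float(rng.uniform(0, math.pi)),
            boundary_irregularity=geo["irregularity"],
            dna_content=dna,
            chromatin_texture=geo["texture"],
            n_lobes=lobes,
        )
    geo = _MORPHOLOGY[morphotype]
    radius = max(float(rng.normal(geo["radius"], geo["radius_sd"])), 2.5)
    return NucleusSpec(
        centre=(0.0, 0.0),
        morphotype=morphotype,
        base_radius=radius * dna ** geo["dna_exponent"],
        aspect_ratio=1.0 + abs(rng.normal(0, geo["aspect_spread"])),
        orientation=float(rng.uniform(0, math.pi)),
        boundary_irregularity=geo["irregularity"],
        dna_content=dna,
        chromatin_texture=geo["texture"],
    )


def _place_nuclei(
    nuclei: list[NucleusSpec],
    width: int,
    height: int,
    touching_pair_fraction: float,
    rng: np.random.Generator,
) -> None:
    """Assign centres in place: rejection sampling on a coarse occupancy grid.

    Most nuclei are placed so their outer extents do not touch; a requested
    fraction is placed as overlapping pairs (distinct ground-truth nuclei
    whose binary union is connected).
    """
    placed: list[tuple[float, float, float]] = []  # (x, y, extent)
    cell = max(24.0, 2.2 * max((n.extent for n in nuclei), default=12.0))
    grid: dict[tuple[int, int], list[int]] = {}

    def conflicts(x: float, y: float, e: float, gap: float) -> bool:
        cx, cy = int(x // cell), int(y // cell)
        for gx in range(cx - 1, cx + 2):
            for gy in range(cy - 1, cy + 2):
                for k in grid.get((gx, gy), []):
                    px, py, pe = placed[k]
                    if math.hypot(px - x, py - y) < e + pe + gap:
                        return True
        return False

    def register(x: float, y: float, e: float) -> None:
        placed.append((x, y, e))
        grid.setdefault((int(x // cell), int(y // cell)), []).append(len(placed) - 1)

    def free_spot(e: float, gap: float) -> tuple[float, float]:
        for _ in range(4000):
            x = rng.uniform(e + 1, width - e - 2)
            y = rng.uniform(e + 1, height - e - 2)
            if not conflicts(x, y, e, gap):
                return x, y
        raise RuntimeError(
            f"could not place {len(nuclei)} nuclei on a {width}x{height} canvas; "
            "enlarge the frame or reduce the count"
        )

    n_pairs = int(round(touching_pair_fraction * len(nuclei) / 2))
    order = list(rng.permutation(len(nuclei)))
    pair_members = order[: 2 * n_pairs]
    singles = order[2 * n_pairs:]

    singles.sort(key=lambda i: -nuclei[i].extent)  # big blobs first packs better
    for i in singles:
        e = nuclei[i].extent
        x, y = free_spot(e, gap=2.0)
        nuclei[i].centre = (x, y)
        register(x, y, e)
    for a, b in zip(pair_members[0::2], pair_members[1::2]):
        ea, eb = nuclei[a].extent, nuclei[b].extent
        x, y = free_spot(ea + 2 * eb, gap=2.0)
        nuclei[a].centre = (x, y)
        register(x, y, ea)
        theta = rng.uniform(0, 2 * math.pi)
        # overlap slightly so the rendered union is a single component
        d = 0.82 * (nuclei[a].base_radius + nuclei[b].base_radius)
        bx, by = x + d * math.cos(theta), y + d * math.sin(theta)
        bx = min(max(bx, eb + 1), width - eb - 2)
        by = min(max(by, eb + 1), height - eb - 2)
        nuclei[b].centre = (bx, by)
        register(bx, by, eb)


def stage_preset(
    stage: str,
    n_nuclei: int,
    seed: int,
    width: int | None = None,
    height: int | None = None,
    cv: float | None = None,
    weights: Sequence[float] | None = None,
    touching_pair_fraction: float = 0.0,
    noise_sd: float = 0.0,
    illumination_gradient: tuple[float, float] = (0.0, 0.0),
    od_per_C: float = 28.0,
    background_level: float = 220.0,
    flat_multinucleate: bool = False,
) -> SyntheticSceneSpec:
    """Scene spec for a disease-stage preset.

    DNA contents are drawn from the stage's ploidy mixture (see
    ``STAGE_MIXTURES``); morphotypes follow the stage (A-type only at light,
    A and B mixed with normal cells at moderate, B-type only at heavy, with
    the highest-ploidy component rendered as multinucleate clusters unless
    ``flat_multinucleate``). The canvas auto-sizes to the nucleus count when
    width/height are omitted.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    if n_nuclei < 1:
        raise ValueError("a scene needs at least one nucleus")
    rng = np.random.default_rng(seed)
    dna, morphs = sample_dna_contents(stage, n_nuclei, rng, cv=cv, weights=weights)
    if flat_multinucleate:
        morphs = ["B" if m == "multi" else m for m in morphs]
    nuclei = [_make_nucleus(d, m, rng) for d, m in zip(dna, morphs)]
    n_multi = sum(1 for n in nuclei if n.n_lobes > 1)

    if width is None or height is None:
        rms_ext = float(np.sqrt(np.mean([n.extent**2 for n in nuclei])))
        max_ext = float(max(n.extent for n in nuclei))
        side = int(math.ceil(math.sqrt(n_nuclei * (3.6 * rms_ext) ** 2)) + 4 * max_ext)
        width = width or max(side, 128)
        height = height or max(side, 128)

    _place_nuclei(nuclei, width, height, touching_pair_fraction, rng)
    return SyntheticSceneSpec(
        width=width,
        height=height,
        nuclei=nuclei,
        stage_preset=stage,
        background_level=background_level,
        illumination_gradient=illumination_gradient,
        noise_sd=noise_sd,
        od_per_C=od_per_C,
        touching_pair_fraction=touching_pair_fraction,
        multinucleate_fraction=n_multi / n_nuclei,
        seed=seed,
    )


def custom_scene(
    dna_contents: Sequence[float],
    morphotypes: Sequence[str] | None = None,
    seed: int = 0,
    width: int | None = None,
    height: int | None = None,
    touching_pair_fraction: float = 0.0,
    **scene_kwargs,
) -> SyntheticSceneSpec:
    """Scene with explicitly chosen DNA contents (and optional morphotypes).

    Useful for calibration experiments, e.g. a noise-free linearity scene
    with DNA contents spanning a range. Morphotypes default to ``A``.
    """
    dna = [float(d) for d in dna_contents]
    if not dna:
        raise ValueError("a scene needs at least one nucleus")
    morphs = list(morphotypes) if morphotypes is not None else ["A"] * len(dna)
    if len(morphs) != len(dna):
        raise ValueError("morphotypes and dna_contents lengths differ")
    rng = np.random.default_rng(seed)
    nuclei = [_make_nucleus(d, m, rng) for d, m in zip(dna, morphs)]
    if width is None or height is None:
        rms_ext = float(np.sqrt(np.mean([n.extent**2 for n in nuclei])))
        max_ext = float(max(n.extent for n in nuclei))
        side = int(math.ceil(math.sqrt(len(dna) * (3.6 * rms_ext) ** 2)) + 4 * max_ext)
        width = width or max(side, 128)
        height = height or max(side, 128)
    _place_nuclei(nuclei, width, height, touching_pair_fraction, rng)
    return SyntheticSceneSpec(
        width=width,
        height=height,
        nuclei=nuclei,
        stage_preset="custom",
        touching_pair_fraction=touching_pair_fraction,
        seed=seed,
        **scene_kwargs,
    )


def _radial_profile(rng: np.random.Generator, irregularity: float):
    """Random low-order harmonic perturbation of the nucleus outline."""
    ks = np.arange(2, 6)
    amp = rng.normal(0, 1, size=len(ks))
    phase = rng.uniform(0, 2 * math.pi, size=len(ks))
    norm = np.sum(np.abs(amp)) or 1.0

    def r_frac(theta: np.ndarray) -> np.ndarray:
        pert = sum(a * np.cos(k * theta + p) for a, k, p in zip(amp, ks, phase))
        return 1.0 + irregularity * pert / norm

    return r_frac


def _lobe_mask(
    shape: tuple[int, int],
    centre: tuple[float, float],
    radius: float,
    aspect: float,
    orientation: float,
    r_frac,
) -> np.ndarray:
    h, w = shape
    a = radius * math.sqrt(aspect)
    b = radius / math.sqrt(aspect)
    ext = int(math.ceil(a * 1.4)) + 2
    x0, y0 = centre
    xs = np.arange(max(0, int(x0) - ext), min(w, int(x0) + ext + 1))
    ys = np.arange(max(0, int(y0) - ext), min(h, int(y0) + ext + 1))
    if len(xs) == 0 or len(ys) == 0:
        return np.zeros(shape, bool)
    gx, gy = np.meshgrid(xs - x0, ys - y0)
    ct, st = math.cos(orientation), math.sin(orientation)
    u = gx * ct + gy * st
    v = -gx * st + gy * ct
    rho = np.hypot(u / a, v / b)
    theta = np.arctan2(v, u)
    inside = rho <= r_frac(theta)
    mask = np.zeros(shape, bool)
    mask[np.ix_(ys, xs)] = inside
    return mask


def _smooth_noise(shape: tuple[int, int], rng: np.random.Generator, scale: int = 4) -> np.ndarray:
    """Band-limited unit-variance noise for chromatin texture."""
    coarse = rng.normal(0, 1, size=(shape[0] // scale + 2, shape[1] // scale + 2))
    fine = ndi.zoom(coarse, scale, order=1)[: shape[0], : shape[1]]
    sd = fine.std() or 1.0
    return fine / sd


def render_scene(
    spec: SyntheticSceneSpec,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render a scene to ``(rgb, blank, ground_truth)``.

    Both images are float arrays on the 8-bit intensity scale (H, W, 3).
    The per-nucleus OD field sums exactly to ``od_per_C x dna_content``
    before noise; the blank field is the illumination field without nuclei.
    Ground-truth labels assign contested (overlapping) pixels to the nucleus
    contributing the most OD, so touching nuclei keep distinct labels.
    """
    for i, nuc in enumerate(spec.nuclei):
        if nuc.base_radius < 2:
            raise ValueError(f"nucleus {i}: radius {nuc.base_radius:.2f} px is below 2 px")
    h, w = spec.height, spec.width
    rng = np.random.default_rng([spec.seed, 2])

    od = np.zeros((h, w))
    owner = np.zeros((h, w), dtype=np.int32)
    best = np.zeros((h, w))
    texture_field = _smooth_noise((h, w), rng)

    truth_rows = []
    for idx, nuc in enumerate(spec.nuclei, start=1):
        mask = np.zeros((h, w), bool)
        if nuc.n_lobes <= 1:
            r_frac = _radial_profile(rng, nuc.boundary_irregularity)
            mask |= _lobe_mask((h, w), nuc.centre, nuc.base_radius, nuc.aspect_ratio,
                               nuc.orientation, r_frac)
        else:
            x0, y0 = nuc.centre
            step = 1.1 * nuc.base_radius
            for lobe in range(nuc.n_lobes):
                ang = rng.uniform(0, 2 * math.pi)
                rad = rng.uniform(0, step * math.sqrt(lobe / max(nuc.n_lobes - 1, 1)))
                lc = (x0 + rad * math.cos(ang), y0 + rad * math.sin(ang))
                r_frac = _radial_profile(rng, nuc.boundary_irregularity)
                mask |= _lobe_mask((h, w), lc, nuc.base_radius, 1.0, 0.0, r_frac)
        if not mask.any():
            raise ValueError(f"nucleus {idx} rendered no pixels (outside the frame?)")
        weight = np.clip(1.0 + nuc.chromatin_texture * texture_field[mask], 0.1, None)
        target = spec.od_per_C * nuc.dna_content
        contrib = weight * (target / weight.sum())
        od_vals = np.zeros((h, w))
        od_vals[mask] = contrib
        od += od_vals
        claim = mask & (od_vals > best)
        owner[claim] = idx
        best = np.maximum(best, od_vals)
        truth_rows.append(
            dict(label=idx, morphotype=nuc.morphotype, dna_content=nuc.dna_content,
                 true_iod=target)
        )

    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    gx, gy = spec.illumination_gradient
    ib = spec.background_level * (1 + gx * (xx / max(w - 1, 1) - 0.5)) * (
        1 + gy * (yy / max(h - 1, 1) - 0.5)
    )
    if np.any(ib * 10.0 ** (-od.max(initial=0.0)) < 1.0):
        warnings.warn(
            "peak optical density pushes transmitted intensity below one grey "
            "level; IOD will saturate", stacklevel=2,
        )

    absorb = {"R": 0.30, "G": 1.00, "B": 0.45}  # Feulgen magenta: green absorbs most
    rgb = np.stack([ib * 10.0 ** (-k * od) for k in absorb.values()], axis=-1)
    blank = np.repeat(ib[..., None], 3, axis=-1)
    if spec.noise_sd > 0:
        rgb = rgb + rng.normal(0, spec.noise_sd, size=rgb.shape)
    rgb = np.clip(rgb, 0.0, 255.0)

    truth = GroundTruth(
        label_mask=LabelMask(owner),
        table=pd.DataFrame(truth_rows, columns=["label", "morphotype", "dna_content", "true_iod"]),
    )
    return rgb, blank, truth


# --------------------------------------------------------------------------
# feature-level simulation (no images)

#: published descriptive statistics (mean, SD) of normal and neoplastic
#: mussel-haemocyte nuclei, incl. the A/B neoplastic morphotypes; pixel units
REFERENCE_FEATURE_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "normal": {
        "Perimeter": (44.90, 14.0), "Area": (117.1, 94.1), "IOD": (13.47, 34.5),
        "GrAverage": (0.1704, 0.05), "MinR": (6.283, 1.69), "MaxR": (10.65, 2.86),
        "Feret": (20.49, 5.37), "Breadth": (15.20, 3.71), "CHull": (42.92, 12.9),
        "MBCRadius": (10.28, 2.68), "AspRatio": (1.190, 0.42),
        "Circularity": (0.5980, 0.09), "Roundness": (0.3709, 0.140),
        "Compactness": (0.8139, 0.09), "Solidity": (0.7527, 0.032),
        "Concavity": (11.080, 10.82), "Convexity": (0.860, 0.017),
        "Shape": (12.065, 2.836), "ModRatio": (0.628, 0.1526),
        "Sphericity": (0.606, 0.1527), "Rectangularity": (0.493, 0.0482),
    },
    "neoplastic": {
        "Perimeter": (79.03, 21.3), "Area": (423.13, 226.9), "IOD": (177.13, 150.8),
        "GrAverage": (0.369, 0.211), "MinR": (8.540, 2.44), "MaxR": (14.47, 4.08),
        "Feret": (27.879, 7.69), "Breadth": (21.160, 5.55), "CHull": (75.99, 19.6),
        "MBCRadius": (13.977, 3.85), "AspRatio": (1.336, 0.267),
        "Circularity": (0.807, 0.074), "Roundness": (0.667, 0.115),
        "Compactness": (0.8136, 0.07), "Solidity": (0.961, 0.03),
        "Concavity": (18.13, 21.2), "Convexity": (0.964, 0.015),
        "Shape": (15.71, 1.701), "ModRatio": (0.625, 0.13),
        "Sphericity": (0.604, 0.13), "Rectangularity": (0.678, 0.04),
    },
    "A": {
        "Perimeter": (58.0, 0.72), "Area": (250.0, 87.2), "IOD": (133.0, 24.2),
        "GrAverage": (0.15, 0.02), "MinR": (5.09, 1.2), "MaxR": (9.12, 1.12),
        "Feret": (12.23, 11.76), "Breadth": (15.32, 3.24), "CHull": (54.12, 46.0),
        "MBCRadius": (8.59, 1.24), "AspRatio": (1.25, 0.12),
        "Circularity": (0.74, 0.2), "Roundness": (0.623, 0.2),
        "Compactness": (0.781, 0.02), "Solidity": (0.925, 0.02),
        "Concavity": (14.18, 8.1), "Convexity": (0.93, 0.02),
        "Shape": (16.90, 1.1), "ModRatio": (0.542, 0.14),
        "Sphericity": (0.53, 0.12), "Rectangularity": (0.527, 0.02),
    },
    "B": {
        "Perimeter": (70.03, 0.08), "Area": (389.9, 125.6), "IOD": (162.13, 12.2),
        "GrAverage": (0.41, 0.12), "MinR": (9.02, 0.01), "MaxR": (13.17, 13.12),
        "Feret": (26.31, 12.56), "Breadth": (22.014, 9.1), "CHull": (73.467, 25.0),
        "MBCRadius": (13.64, 5.76), "AspRatio": (1.242, 0.05),
        "Circularity": (0.580, 0.71), "Roundness": (0.497, 0.12),
        "Compactness": (0.586, 0.55), "Solidity": (0.625, 0.01),
        "Concavity": (6.71, 12.1), "Convexity": (0.671, 0.01),
        "Shape": (15.11, 1.2), "ModRatio": (0.473, 0.02),
        "Sphericity": (0.458, 0.01), "Rectangularity": (0.471, 0.01),
    },
}

#: hard physical bounds used by the optional truncation
VALID_RANGES: dict[str, tuple[float, float]] = {
    "Solidity": (0.0, 1.0), "Sphericity": (0.0, 1.0), "ModRatio": (0.0, 1.0),
    "Convexity": (0.0, 1.0), "Rectangularity": (0.0, 1.0),
    "Roundness": (0.0, 1.0), "Circularity": (0.0, 1.2), "Compactness": (0.0, 1.0),
    "AspRatio": (1.0, np.inf), "Concavity": (0.0, np.inf),
}


def sample_feature_table(
    group: str, n: int, seed: int, truncate: bool = False
) -> pd.DataFrame:
    """Feature table of ``n`` nuclei drawn from a group's published statistics.

    Each descriptor is an independent Gaussian with the group's (mean, SD).
    With ``truncate=True`` values are redrawn into each descriptor's hard
    physical range; note truncation biases sample means away from the
    published values, so it is off by default.
    """
    if group not in REFERENCE_FEATURE_STATS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    stats = REFERENCE_FEATURE_STATS[group]
    data = {}
    for name, (mean, sd) in stats.items():
        vals = rng.normal(mean, sd, size=n)
        if truncate:
            lo, hi = VALID_RANGES.get(name, (0.0, np.inf))
            bad = (vals < lo) | (vals > hi)
            for _ in range(200):
                if not bad.any():
                    break
                vals[bad] = rng.normal(mean, sd, size=int(bad.sum()))
                bad = (vals < lo) | (vals > hi)
            vals = np.clip(vals, lo, hi)
        data[name] = vals
    df = pd.DataFrame(data)
    df["cell_type"] = group
    return df
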