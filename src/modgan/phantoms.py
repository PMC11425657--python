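"""Synthetic activity phantoms and characterized non-clinical training images.

This module generates all data the reconstruction framework trains and
validates on: brain-like phantoms derived from tissue-label maps with
kinetically motivated uptake contrast, the standard image-quality phantom
(six fillable spheres in a uniform background with a cold central insert),
random hot lesions, and procedurally generated non-clinical training images
characterized by entropy, symmetry, contrast and fractal dimension.

Tissue labels: 0 background, 1 gray matter, 2 white matter, 3 vessels,
4 peri-brain fat.  Gray-matter uptake is four times white matter, the
contrast of a typical FDG scan; vessel and fat uptake are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon as draw_polygon
from skimage.filters import threshold_otsu

from .errors import (
    GeometryError,
    InvalidParameterError,
    MappingError,
    PlacementError,
    SamplingError,
)

__all__ = [
    "LABELS",
    "DEFAULT_UPTAKE",
    "TissueMap",
    "ActivityPhantom",
    "NemaPhantomSpec",
    "ImageCharacterization",
    "two_compartment_ki",
    "make_brain_phantom",
    "insert_lesions",
    "make_nema_phantom",
    "nema_region_masks",
    "characterize_image",
    "make_training_set",
    "toy_brain_tissue_map",
    "disc_phantom",
]

LABELS = {0: "background", 1: "gray_matter", 2: "white_matter", 3: "vessels", 4: "fat"}

#: relative uptake per tissue label; GM:WM = 4:1 is fixed by FDG contrast,
#: vessel and fat values are package defaults and overridable.
DEFAULT_UPTAKE = {0: 0.0, 1: 4.0, 2: 1.0, 3: 2.0, 4: 0.5}


@dataclass
class TissueMap:
    """2-D integer label grid with physical pixel size."""

    labels: np.ndarray
    pixel_size_mm: float = 1.0

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise InvalidParameterError("tissue map must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise InvalidParameterError("tissue labels must be integers")
        unknown = set(np.unique(self.labels)) - set(LABELS)
        if unknown:
            raise InvalidParameterError(f"unknown tissue labels: {sorted(unknown)}")
        if self.pixel_size_mm <= 0:
            raise InvalidParameterError("pixel_size_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class ActivityPhantom:
    """2-D non-negative tracer-uptake image (arbitrary activity units)."""

    values: np.ndarray
    labels: TissueMap | None = None
    pixel_size_mm: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise InvalidParameterError("phantom values must be 2-D")
        if np.any(self.values < 0):
            raise InvalidParameterError("phantom values must be non-negative")
        if self.labels is not None and self.labels.shape != self.values.shape:
            raise InvalidParameterError("labels and values must share a shape")
        if self.pixel_size_mm <= 0:
            raise InvalidParameterError("pixel_size_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def total_activity(self) -> float:
        return float(self.values.sum())


@dataclass
class NemaPhantomSpec:
    """Geometry of the image-quality phantom, 2-D slice through the sphere
    centres.  Defaults follow the standard body phantom: six fillable
    spheres of 10-37 mm inner diameter on a 57.2 mm-radius ring, the four
    smallest filled hot at an 8:1 sphere:background activity ratio, the two
    largest water-filled (cold), and a cold cylindrical insert in the
    centre."""

    sphere_diameters_mm: tuple[float, ...] = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)
    hot_sphere_count: int = 4
    sphere_to_background_ratio: float = 8.0
    body_radius_mm: float = 147.0
    insert_radius_mm: float = 25.0
    sphere_ring_radius_mm: float = 57.2
    grid_size: int = 256
    pixel_size_mm: float = 2.0

    def __post_init__(self):
        d = np.asarray(self.sphere_diameters_mm, dtype=float)
        if d.ndim != 1 or len(d) < 1 or np.any(d <= 0):
            raise GeometryError("sphere diameters must be positive")
        if np.any(np.diff(d) <= 0):
            raise GeometryError("sphere diameters must be strictly increasing")
        if not 0 <= self.hot_sphere_count <= len(d):
            raise GeometryError("hot_sphere_count must not exceed the sphere count")
        if self.sphere_to_background_ratio < 1:
            raise GeometryError("sphere:background ratio must be >= 1")
        if min(self.body_radius_mm, self.insert_radius_mm, self.pixel_size_mm) <= 0:
            raise GeometryError("radii and pixel size must be positive")
        if self.grid_size < 8:
            raise GeometryError("grid too small")


@dataclass
class ImageCharacterization:
    """Training-image descriptors: Shannon entropy of the 256-bin intensity
    histogram (bits), mirror symmetry in [0, 1], RMS contrast, and the
    box-counting fractal dimension of the Otsu-binarized image."""

    entropy: float
    symmetry: float
    contrast: float
    fractal_dimension: float
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return {
            "entropy": self.entropy,
            "symmetry": self.symmetry,
            "contrast": self.contrast,
            "fractal_dimension": self.fractal_dimension,
        }


# ---------------------------------------------------------------------------
# kinetics and phantom construction
# ---------------------------------------------------------------------------


def two_compartment_ki(K1: float, k2: float, k3: float) -> float:
    """Net influx rate of the irreversible two-compartment FDG model.

    Ki = K1 * k3 / (k2 + k3), all rates in 1/min.  Ki scales the relative
    static uptake of a tissue: no trapping (k3 = 0) means no net uptake.
    """
    if K1 < 0 or k2 < 0 or k3 < 0:
        raise InvalidParameterError("kinetic rates must be non-negative")
    if k2 + k3 == 0:
        raise InvalidParameterError("k2 + k3 must be positive")
    return K1 * k3 / (k2 + k3)


def make_brain_phantom(tissue_map: TissueMap,
                       uptake_table: dict[int, float] | None = None) -> ActivityPhantom:
    """Paint each tissue label with its relative uptake value."""
    table = dict(DEFAULT_UPTAKE if uptake_table is None else uptake_table)
    present = set(np.unique(tissue_map.labels))
    missing = present - set(table)
    if missing:
        raise MappingError(f"uptake table lacks labels {sorted(missing)}")
    values = np.zeros(tissue_map.shape, dtype=np.float64)
    for label in present:
        values[tissue_map.labels == label] = table[int(label)]
    return ActivityPhantom(values, labels=tissue_map,
                           pixel_size_mm=tissue_map.pixel_size_mm)


def insert_lesions(phantom: ActivityPhantom, n: int,
                   radius_range_mm: tuple[float, float] = (2.0, 6.0),
                   uptake_factor: float = 2.0,
                   allowed_labels: set[int] = frozenset({1, 2}),
                   seed: int = 0,
                   max_retries: int = 1000) -> ActivityPhantom:
    """Place ``n`` disjoint circular hot lesions inside the allowed tissue.

    Each lesion multiplies the local pre-lesion uptake by ``uptake_factor``.
    Placement is rejection-sampled (circle fully inside the allowed labels,
    no overlap with earlier lesions) and deterministic for a fixed seed.
    """
    if n < 0:
        raise InvalidParameterError("lesion count must be >= 0")
    if n == 0:
        return ActivityPhantom(phantom.values.copy(), phantom.labels,
                               phantom.pixel_size_mm)
    if phantom.labels is None:
        raise InvalidParameterError("lesion insertion requires a tissue map")
    if uptake_factor <= 1:
        raise InvalidParameterError("uptake_factor must exceed 1")
    rng = np.random.default_rng(seed)
    allowed = np.isin(phantom.labels.labels, list(allowed_labels))
    if not allowed.any():
        raise PlacementError("no pixels carry the allowed labels")
    h, w = phantom.shape
    yy, xx = np.mgrid[0:h, 0:w]
    candidates = np.argwhere(allowed)
    values = phantom.values.copy()
    taken = np.zeros((h, w), dtype=bool)
    placed = 0
    for _ in range(max_retries):
        if placed == n:
            break
        r_mm = rng.uniform(*radius_range_mm)
        r_px = r_mm / phantom.pixel_size_mm
        cy, cx = candidates[rng.integers(len(candidates))]
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
        if not disc.any():
            continue
        if np.any(disc & ~allowed) or np.any(disc & taken):
            continue
        values[disc] *= uptake_factor
        taken |= disc
        placed += 1
    if placed < n:
        raise PlacementError(
            f"placed only {placed}/{n} disjoint lesions in {max_retries} retries"
        )
    return ActivityPhantom(values, phantom.labels, phantom.pixel_size_mm)


def _nema_geometry(spec: NemaPhantomSpec):
    n = spec.grid_size
    centre = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    y_mm = (yy - centre) * spec.pixel_size_mm
    x_mm = (xx - centre) * spec.pixel_size_mm
    body = y_mm**2 + x_mm**2 <= spec.body_radius_mm**2
    insert = y_mm**2 + x_mm**2 <= spec.insert_radius_mm**2
    spheres = []
    k = len(spec.sphere_diameters_mm)
    for i, d in enumerate(spec.sphere_diameters_mm):
        r = d / 2.0
        theta = 2 * math.pi * i / k
        cy = spec.sphere_ring_radius_mm * math.sin(theta)
        cx = spec.sphere_ring_radius_mm * math.cos(theta)
        if math.hypot(cy, cx) + r > spec.body_radius_mm:
            raise GeometryError(f"sphere of diameter {d} mm overlaps the body boundary")
        spheres.append((y_mm - cy) ** 2 + (x_mm - cx) ** 2 <= r**2)
    return body, insert, spheres


def make_nema_phantom(spec: NemaPhantomSpec | None = None) -> ActivityPhantom:
    """2-D slice through the sphere centres of the image-quality phantom.

    Background disc at activity 1.0, the ``hot_sphere_count`` smallest
    spheres at the sphere:background ratio (8.0 by default), the remaining
    (largest) spheres and the central insert cold, zero outside the body.
    """
    spec = spec or NemaPhantomSpec()
    body, insert, spheres = _nema_geometry(spec)
    values = np.where(body, 1.0, 0.0)
    for i, mask in enumerate(spheres):
        hot = i < spec.hot_sphere_count
        values[mask] = spec.sphere_to_background_ratio if hot else 0.0
    values[insert] = 0.0
    return ActivityPhantom(values, pixel_size_mm=spec.pixel_size_mm)


def nema_region_masks(spec: NemaPhantomSpec | None = None) -> dict:
    """Region masks for quantitation: per-sphere masks, the cold insert, and
    the uniform background (body minus spheres, insert and a 1-diameter
    guard band around each sphere)."""
    spec = spec or NemaPhantomSpec()
    body, insert, spheres = _nema_geometry(spec)
    guard = np.zeros_like(body)
    n = spec.grid_size
    centre = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    y_mm = (yy - centre) * spec.pixel_size_mm
    x_mm = (xx - centre) * spec.pixel_size_mm
    k = len(spec.sphere_diameters_mm)
    for i, d in enumerate(spec.sphere_diameters_mm):
        theta = 2 * math.pi * i / k
        cy = spec.sphere_ring_radius_mm * math.sin(theta)
        cx = spec.sphere_ring_radius_mm * math.cos(theta)
        guard |= (y_mm - cy) ** 2 + (x_mm - cx) ** 2 <= d**2
    background = body & ~insert & ~guard
    background &= y_mm**2 + x_mm**2 <= (0.9 * spec.body_radius_mm) ** 2
    return {"spheres": spheres, "insert": insert, "body": body,
            "background": background}


def disc_phantom(size: int = 128, radius_px: float = 20.0, value: float = 1.0,
                 pixel_size_mm: float = 1.0) -> ActivityPhantom:
    """Uniform disc — the workhorse phantom for projector/reconstruction
    oracles (its area, and hence every projection sum, is known in closed
    form)."""
    centre = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    disc = (yy - centre) ** 2 + (xx - centre) ** 2 <= radius_px**2
    return ActivityPhantom(np.where(disc, value, 0.0), pixel_size_mm=pixel_size_mm)


# ---------------------------------------------------------------------------
# image characterization
# ---------------------------------------------------------------------------


def _shannon_entropy_bits(image: np.ndarray, bins: int = 256) -> float:
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        return 0.0
    hist, _ = np.histogram(image, bins=bins, range=(lo, hi))
    p = hist / hist.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _mirror_symmetry(image: np.ndarray) -> float:
    rng_ = float(image.max() - image.min())
    if rng_ == 0:
        return 1.0
    scores = []
    for mirrored in (image[:, ::-1], image[::-1, :]):
        scores.append(1.0 - float(np.mean(np.abs(image - mirrored))) / rng_)
    return max(scores)


def _box_counting_dimension(binary: np.ndarray) -> float:
    n = min(binary.shape)
    sizes = []
    s = 2
    while s <= n // 2:
        sizes.append(s)
        s *= 2
    if len(sizes) < 2 or not binary.any():
        return 0.0
    counts = []
    for s in sizes:
        h = (binary.shape[0] // s) * s
        w = (binary.shape[1] // s) * s
        blocks = binary[:h, :w].reshape(h // s, s, w // s, s)
        counts.append(int(blocks.any(axis=(1, 3)).sum()))
    slope, _ = np.polyfit(np.log(1.0 / np.asarray(sizes)), np.log(counts), 1)
    return float(np.clip(slope, 0.0, 2.0))


def characterize_image(image: np.ndarray) -> ImageCharacterization:
    """Compute entropy, symmetry, RMS contrast and fractal dimension.

    A constant image is flagged degenerate: entropy 0, symmetry 1, contrast
    0 and fractal dimension reported as 0.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0 or image.ndim != 2:
        raise InvalidParameterError("image must be a non-empty 2-D grid")
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        return ImageCharacterization(0.0, 1.0, 0.0, 0.0, degenerate=True)
    unit = (image - lo) / (hi - lo)
    binary = unit >= threshold_otsu(unit)
    return ImageCharacterization(
        entropy=_shannon_entropy_bits(image),
        symmetry=_mirror_symmetry(image),
        contrast=float(unit.std()),
        fractal_dimension=_box_counting_dimension(binary),
    )


# ---------------------------------------------------------------------------
# toy tissue geometry
# ---------------------------------------------------------------------------


def toy_brain_tissue_map(size: int = 128, pixel_size_mm: float = 1.0,
                         seed: int | None = None) -> TissueMap:
    """Built-in brain-like label geometry: an elliptical head with a thin
    peri-brain fat rim, a cortical gray-matter band, white-matter interior
    and a few small vessels.  Stands in for an MRI segmentation."""
    rng = np.random.default_rng(0 if seed is None else seed)
    yy, xx = np.mgrid[0:size, 0:size]
    cy = cx = (size - 1) / 2.0
    a, b = 0.44 * size, 0.36 * size  # head semi-axes
    r2 = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2
    labels = np.zeros((size, size), dtype=np.int64)
    labels[r2 <= 1.00] = 4          # fat rim
    labels[r2 <= 0.92] = 1          # cortical gray matter band
    labels[r2 <= 0.62] = 2          # white matter interior
    # deep gray structures: two elliptical islands inside the white matter
    for sy, sx in ((-0.10, -0.12), (-0.10, 0.12)):
        d2 = ((yy - cy - sy * size) / (0.10 * size)) ** 2 + (
            (xx - cx - sx * size) / (0.06 * size)
        ) ** 2
        labels[(d2 <= 1.0) & (labels == 2)] = 1
    n_vessels = 3
    wm = np.argwhere(labels == 2)
    for _ in range(n_vessels):
        vy, vx = wm[rng.integers(len(wm))]
        d2 = (yy - vy) ** 2 + (xx - vx) ** 2
        labels[(d2 <= (0.015 * size) ** 2) & (labels == 2)] = 3
    return TissueMap(labels, pixel_size_mm)


# ---------------------------------------------------------------------------
# non-clinical training images
# ---------------------------------------------------------------------------


def _gen_ellipses(size: int, rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    img = np.zeros((size, size))
    for _ in range(rng.integers(3, 9)):
        cy, cx = rng.uniform(0.2, 0.8, 2) * size
        a, b = rng.uniform(0.05, 0.3, 2) * size
        theta = rng.uniform(0, math.pi)
        yr = (yy - cy) * math.cos(theta) + (xx - cx) * math.sin(theta)
        xr = -(yy - cy) * math.sin(theta) + (xx - cx) * math.cos(theta)
        img[(yr / a) ** 2 + (xr / b) ** 2 <= 1.0] += rng.uniform(0.3, 1.0)
    return img


def _gen_polygons(size: int, rng: np.random.Generator) -> np.ndarray:
    img = np.zeros((size, size))
    for _ in range(rng.integers(2, 6)):
        k = rng.integers(3, 8)
        cy, cx = rng.uniform(0.25, 0.75, 2) * size
        radius = rng.uniform(0.08, 0.3) * size
        angles = np.sort(rng.uniform(0, 2 * math.pi, k))
        ry = cy + radius * np.sin(angles)
        rx = cx + radius * np.cos(angles)
        rr, cc = draw_polygon(ry, rx, shape=img.shape)
        img[rr, cc] += rng.uniform(0.3, 1.0)
    return img


def _gen_texture(size: int, rng: np.random.Generator) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    noise = rng.normal(size=(size, size))
    img = gaussian_filter(noise, sigma=rng.uniform(2.0, 6.0))
    img -= img.min()
    # carve a compact support so the texture resembles an object on background
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    img[(yy - c) ** 2 + (xx - c) ** 2 > (0.45 * size) ** 2] = 0.0
    return img


def _gen_fractal(size: int, rng: np.random.Generator) -> np.ndarray:
    """Iterated shrinking discs: each level spawns child discs of half the
    radius at random offsets, giving a rough self-similar cluster."""
    img = np.zeros((size, size))
    yy, xx = np.mgrid[0:size, 0:size]

    def place(cy, cx, r, level):
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] += 0.5 + 0.2 * level
        if level == 0 or r < 2:
            return
        for _ in range(3):
            ang = rng.uniform(0, 2 * math.pi)
            dist = rng.uniform(1.0, 1.8) * r
            place(cy + dist * math.sin(ang), cx + dist * math.cos(ang),
                  r / 2.0, level - 1)

    place(size / 2, size / 2, 0.18 * size, 3)
    return img


_GENERATORS = {
    "ellipses": _gen_ellipses,
    "polygons": _gen_polygons,
    "texture": _gen_texture,
    "fractal": _gen_fractal,
}


@dataclass
class TrainingPair:
    """One supervised example: the normalized target image and the sinogram
    of the raw image (the network input domain)."""

    target: "object"      # ImageTensor (projection module)
    sinogram: "object"    # Sinogram   (projection module)
    characterization: ImageCharacterization = field(default=None)  # type: ignore


def make_training_set(n: int,
                      kinds: tuple[str, ...] = ("ellipses", "polygons",
                                                "texture", "fractal"),
                      target_metrics: dict[str, tuple[float, float]] | None = None,
                      seed: int = 0,
                      image_size: int = 128,
                      n_angles: int = 360) -> list[TrainingPair]:
    """Generate ``n`` (target image, sinogram) pairs of non-clinical images.

    Targets are procedurally generated (overlapping ellipses, polygons,
    smoothed noise textures, iterated fractal-like clusters), optionally
    rejection-sampled into ``target_metrics`` ranges keyed by
    characterization field name.  Inputs are forward projections of the
    targets over ``n_angles`` uniformly spaced angles covering 360 degrees.
    Deterministic for a fixed seed.
    """
    from .projection import normalize_for_network, radon_forward

    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    bad = [k for k in kinds if k not in _GENERATORS]
    if bad:
        raise InvalidParameterError(f"unknown generator kinds: {bad}")
    rng = np.random.default_rng(seed)
    angles = np.linspace(0.0, 360.0, n_angles, endpoint=False)
    pairs: list[TrainingPair] = []
    budget = 200 * n
    reject_counts: dict[str, int] = {}
    while len(pairs) < n and budget > 0:
        budget -= 1
        kind = kinds[rng.integers(len(kinds))]
        img = _GENERATORS[kind](image_size, rng)
        if img.max() <= 0:
            continue
        char = characterize_image(img)
        if target_metrics:
            ok = True
            for key, (lo, hi) in target_metrics.items():
                val = char.as_dict().get(key)
                if val is None:
                    raise InvalidParameterError(f"unknown metric {key!r}")
                if not lo <= val <= hi:
                    reject_counts[key] = reject_counts.get(key, 0) + 1
                    ok = False
                    break
            if not ok:
                continue
        phantom = ActivityPhantom(np.clip(img, 0, None))
        sino = radon_forward(phantom, angles)
        target = normalize_for_network(phantom.values, role="target")
        pairs.append(TrainingPair(target, sino, char))
    if len(pairs) < n:
        worst = max(reject_counts, key=reject_counts.get) if reject_counts else "?"
        raise SamplingError(
            f"generated {len(pairs)}/{n} images within budget; most often "
            f"unreachable metric range: {worst!r}"
        )
    return pairs
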