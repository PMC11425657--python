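"""Parallel-beam forward projection, artefact simulation and preprocessing.

The projector is a pixel-driven discrete Radon transform: the image is
resampled onto a rotated grid with bilinear weights and summed along rays.
Its adjoint (backprojection) uses the *same* interpolation weights, so the
projector/backprojector form an exactly matched pair — the property the
iterative reconstruction in :mod:`modgan.classical` relies on for its
monotone likelihood.

Artefact simulation covers the three classes used to stress-test the
reconstruction network: Poisson count noise at a target total-count level,
rigid in-plane rotation ("motion") blended as a weighted sum of projections,
and cavity/wedge removal from tissue ("attenuation"-like signal loss).

Scanner-style sinograms (half angular range, e.g. 140 angles x 360 radial
bins) are reorganised into the network's input domain by exploiting the
180-degree projection symmetry p(theta + 180, r) = p(theta, -r).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from .errors import InvalidParameterError, ShapeError
from .phantoms import ActivityPhantom

__all__ = [
    "Sinogram",
    "MotionSpec",
    "CavitySpec",
    "ImageTensor",
    "project_angle",
    "backproject_angle",
    "radon_forward",
    "add_poisson_noise",
    "simulate_motion_sinogram",
    "rotate_image",
    "carve_cavities",
    "radial_mirror",
    "extend_halfrange",
    "preprocess_scanner_sinogram",
    "normalize_for_network",
    "sinogram_to_network_input",
    "NOISE_PRESETS",
]

#: total-count presets for the "varying magnitudes" of Poisson noise
NOISE_PRESETS = {"low": 1e5, "medium": 1e6, "high": 1e7}


@dataclass
class Sinogram:
    """Angular x radial projection array with geometry metadata.

    Row ``i`` holds the parallel-beam projection at ``angles_deg[i]``.
    """

    values: np.ndarray
    angles_deg: np.ndarray
    radial_spacing_mm: float = 1.0
    counts_flag: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        if self.values.ndim != 2:
            raise ShapeError("sinogram values must be 2-D (angles x radial)")
        if self.values.shape[0] != self.angles_deg.size:
            raise ShapeError(
                f"{self.values.shape[0]} rows but {self.angles_deg.size} angles"
            )
        if self.counts_flag and np.any(self.values < 0):
            raise InvalidParameterError("count sinograms must be non-negative")
        if self.radial_spacing_mm <= 0:
            raise InvalidParameterError("radial_spacing_mm must be positive")

    @property
    def n_angles(self) -> int:
        return self.values.shape[0]

    @property
    def n_radial(self) -> int:
        return self.values.shape[1]


@dataclass
class MotionSpec:
    """Rigid in-plane rotation blend: angles and their mixture weights."""

    rotation_angles_deg: tuple[float, ...] = (2.0, 5.0, 10.0)
    weights: tuple[float, ...] | None = None

    def __post_init__(self):
        self.rotation_angles_deg = tuple(float(a) for a in self.rotation_angles_deg)
        if self.weights is None:
            k = len(self.rotation_angles_deg)
            self.weights = tuple([1.0 / k] * k)
        else:
            self.weights = tuple(float(w) for w in self.weights)
        if len(self.weights) != len(self.rotation_angles_deg):
            raise InvalidParameterError("weights and angles must have equal length")
        if any(w < 0 for w in self.weights):
            raise InvalidParameterError("weights must be non-negative")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise InvalidParameterError("weights must sum to 1 within 1e-9")


@dataclass
class CavitySpec:
    """Circular cavities and an optional wedge removed from chosen tissues.

    ``circles``: list of ((row, col), radius_mm).  ``wedge``: (apex (row,
    col), start_deg, extent_deg, radius_mm or None for unbounded).  Removal
    is restricted to ``target_labels`` when the phantom carries a tissue
    map; otherwise it applies anywhere.
    """

    circles: list = field(default_factory=list)
    wedge: tuple | None = None
    target_labels: frozenset = frozenset({1, 2})


@dataclass
class ImageTensor:
    """Normalized 3-channel network image in [-1, 1].

    Channels replicate a single 2-D plane; ``vmin``/``vmax`` retain the
    original intensity range so the normalization can be inverted.
    """

    values: np.ndarray
    role: str = "target"
    vmin: float = 0.0
    vmax: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[2] != 3:
            raise ShapeError("ImageTensor must be H x W x 3")
        if not np.isfinite(self.values).all():
            raise InvalidParameterError("ImageTensor must be finite")
        if self.values.min() < -1 - 1e-9 or self.values.max() > 1 + 1e-9:
            raise InvalidParameterError("ImageTensor values must lie in [-1, 1]")

    @property
    def plane(self) -> np.ndarray:
        return self.values[:, :, 0]

    def denormalize(self) -> np.ndarray:
        """Invert the min-max normalization back to original units."""
        return (self.values[:, :, 0] + 1.0) * 0.5 * (self.vmax - self.vmin) + self.vmin


# ---------------------------------------------------------------------------
# matched projector / backprojector
# ---------------------------------------------------------------------------


# cached bilinear sampling plans, keyed by (grid size, angle); the cache is
# bounded by total byte size and simply flushed when the budget is exceeded
_PLAN_CACHE: dict = {}
_PLAN_CACHE_BYTES = [0]
_PLAN_CACHE_BUDGET = 300 * 2**20


def _rotation_plan(n: int, angle_deg: float):
    """Bilinear sampling plan for rotating an n x n image.

    Returns flat corner indices (4, n*n) and weights such that
    rotated.ravel()[o] = sum_k w[k, o] * image.ravel()[idx[k, o]].
    Out-of-bounds corners carry zero weight (zero padding).
    """
    key = (n, round(angle_deg % 360.0, 9))
    plan = _PLAN_CACHE.get(key)
    if plan is not None:
        return plan
    c = n // 2  # pivot matches the FBP backend's rotation centre
    t = np.deg2rad(angle_deg)
    yy, xx = np.mgrid[0:n, 0:n]
    # inverse mapping: sample the source at the back-rotated position
    sy = c + (yy - c) * np.cos(t) - (xx - c) * np.sin(t)
    sx = c + (yy - c) * np.sin(t) + (xx - c) * np.cos(t)
    y0 = np.floor(sy).astype(np.int64)
    x0 = np.floor(sx).astype(np.int64)
    fy, fx = sy - y0, sx - x0
    idx = np.empty((4, n * n), dtype=np.int64)
    wts = np.empty((4, n * n), dtype=np.float64)
    k = 0
    for dy, wy in ((0, 1 - fy), (1, fy)):
        for dx, wx in ((0, 1 - fx), (1, fx)):
            yi, xi = y0 + dy, x0 + dx
            valid = (yi >= 0) & (yi < n) & (xi >= 0) & (xi < n)
            idx[k] = (np.where(valid, yi, 0) * n + np.where(valid, xi, 0)).ravel()
            wts[k] = (wy * wx * valid).ravel()
            k += 1
    nbytes = idx.nbytes + wts.nbytes
    if _PLAN_CACHE_BYTES[0] + nbytes > _PLAN_CACHE_BUDGET:
        _PLAN_CACHE.clear()
        _PLAN_CACHE_BYTES[0] = 0
    _PLAN_CACHE[key] = (idx, wts)
    _PLAN_CACHE_BYTES[0] += nbytes
    return idx, wts


def rotate_image(image: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate about the image centre, bilinear interpolation, zero padding."""
    image = np.asarray(image, dtype=np.float64)
    n = image.shape[0]
    if image.shape[0] != image.shape[1]:
        raise ShapeError("rotation requires a square image")
    if angle_deg % 360 == 0:
        return image.copy()
    idx, wts = _rotation_plan(n, angle_deg)
    flat = image.ravel()
    out = (wts * flat[idx]).sum(axis=0)
    return out.reshape(n, n)


def _projection_plan(n: int, angle_deg: float):
    """Pixel-driven projection plan: each source pixel lands at radial
    coordinate c + (x - c) cos(t) - (y - c) sin(t) and splits its value
    linearly between the two neighbouring bins.  The linear-hat weights of
    every in-range pixel sum to one, so projection mass is exact per angle.

    Returns flat bin indices (2, n*n) and weights (2, n*n).
    """
    key = ("proj", n, round(angle_deg % 360.0, 9))
    plan = _PLAN_CACHE.get(key)
    if plan is not None:
        return plan
    c = n // 2  # pivot matches the FBP backend's rotation centre
    t = np.deg2rad(angle_deg)
    yy, xx = np.mgrid[0:n, 0:n]
    r = c - (yy - c) * np.sin(t) + (xx - c) * np.cos(t)
    r0 = np.floor(r).astype(np.int64)
    fr = r - r0
    idx = np.empty((2, n * n), dtype=np.int64)
    wts = np.empty((2, n * n), dtype=np.float64)
    for k, (db, wb) in enumerate(((0, 1 - fr), (1, fr))):
        bi = r0 + db
        valid = (bi >= 0) & (bi < n)
        idx[k] = np.where(valid, bi, 0).ravel()
        wts[k] = (wb * valid).ravel()
    nbytes = idx.nbytes + wts.nbytes
    if _PLAN_CACHE_BYTES[0] + nbytes > _PLAN_CACHE_BUDGET:
        _PLAN_CACHE.clear()
        _PLAN_CACHE_BYTES[0] = 0
    _PLAN_CACHE[key] = (idx, wts)
    _PLAN_CACHE_BYTES[0] += nbytes
    return idx, wts


def project_angle(image: np.ndarray, angle_deg: float) -> np.ndarray:
    """One parallel-beam projection of a square image at ``angle_deg``."""
    image = np.asarray(image, dtype=np.float64)
    n = image.shape[0]
    idx, wts = _projection_plan(n, angle_deg)
    flat = image.ravel()
    out = np.bincount(idx[0], weights=wts[0] * flat, minlength=n)
    out += np.bincount(idx[1], weights=wts[1] * flat, minlength=n)
    return out


def backproject_angle(profile: np.ndarray, angle_deg: float, n: int) -> np.ndarray:
    """Exact adjoint of :func:`project_angle` for an n x n image (the same
    projection plan is gathered instead of scattered)."""
    profile = np.asarray(profile, dtype=np.float64)
    idx, wts = _projection_plan(n, angle_deg)
    out = wts[0] * profile[idx[0]] + wts[1] * profile[idx[1]]
    return out.reshape(n, n)


def radon_forward(image: ActivityPhantom | np.ndarray,
                  angles_deg: np.ndarray) -> Sinogram:
    """Discrete parallel-beam Radon transform of a square activity image.

    Row ``i`` of the result is the line-integral profile at
    ``angles_deg[i]``; the sum over radial bins at any angle equals the
    total image activity up to discretization error (mass preservation).
    """
    if isinstance(image, ActivityPhantom):
        values, spacing = image.values, image.pixel_size_mm
    else:
        values, spacing = np.asarray(image, dtype=np.float64), 1.0
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ShapeError("projection requires a square 2-D image")
    angles = np.atleast_1d(np.asarray(angles_deg, dtype=np.float64))
    if angles.size < 1:
        raise InvalidParameterError("at least one projection angle is required")
    sino = np.empty((angles.size, values.shape[0]))
    for i, a in enumerate(angles):
        sino[i] = project_angle(values, a)
    return Sinogram(sino, angles, radial_spacing_mm=spacing)


# ---------------------------------------------------------------------------
# artefacts
# ---------------------------------------------------------------------------


def add_poisson_noise(sino: Sinogram, total_counts: float, seed: int = 0) -> Sinogram:
    """Scale the sinogram to ``total_counts`` expected events and draw
    Poisson counts per bin.  Deterministic for a fixed seed."""
    if np.any(sino.values < 0):
        raise InvalidParameterError("sinogram bins must be non-negative")
    if total_counts <= 0:
        raise InvalidParameterError("total_counts must be positive")
    total = sino.values.sum()
    if total == 0:
        return Sinogram(np.zeros_like(sino.values), sino.angles_deg,
                        sino.radial_spacing_mm, counts_flag=True)
    rng = np.random.default_rng(seed)
    means = sino.values * (total_counts / total)
    draws = rng.poisson(means).astype(np.float64)
    return Sinogram(draws, sino.angles_deg, sino.radial_spacing_mm, counts_flag=True)


def simulate_motion_sinogram(image: ActivityPhantom | np.ndarray,
                             motion: MotionSpec,
                             angles_deg: np.ndarray) -> Sinogram:
    """Motion-corrupted sinogram: the weighted sum of the projections of the
    image rotated by each motion angle (rotation about the centre, bilinear
    interpolation).  Linear in the weights by construction."""
    if isinstance(image, ActivityPhantom):
        values, spacing = image.values, image.pixel_size_mm
    else:
        values, spacing = np.asarray(image, dtype=np.float64), 1.0
    acc = None
    for angle, weight in zip(motion.rotation_angles_deg, motion.weights):
        part = radon_forward(rotate_image(values, angle), angles_deg).values
        acc = weight * part if acc is None else acc + weight * part
    return Sinogram(np.clip(acc, 0.0, None), np.asarray(angles_deg, dtype=float),
                    radial_spacing_mm=spacing)


def carve_cavities(image: ActivityPhantom, spec: CavitySpec) -> ActivityPhantom:
    """Zero out circular cavities and an optional wedge inside the target
    tissues; everything else is untouched.  Idempotent."""
    values = image.values.copy()
    h, w = values.shape
    yy, xx = np.mgrid[0:h, 0:w]
    region = np.zeros((h, w), dtype=bool)
    px = image.pixel_size_mm
    for (cy, cx), radius_mm in spec.circles:
        r_px = radius_mm / px
        if not (0 <= cy < h and 0 <= cx < w):
            raise InvalidParameterError("cavity centre lies outside the image")
        region |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
    if spec.wedge is not None:
        (ay, ax), start_deg, extent_deg, radius_mm = spec.wedge
        ang = np.rad2deg(np.arctan2(yy - ay, xx - ax)) % 360.0
        rel = (ang - start_deg) % 360.0
        wedge = rel <= extent_deg
        if radius_mm is not None:
            wedge &= (yy - ay) ** 2 + (xx - ax) ** 2 <= (radius_mm / px) ** 2
        region |= wedge
    if image.labels is not None and spec.target_labels:
        region &= np.isin(image.labels.labels, list(spec.target_labels))
    values[region] = 0.0
    return ActivityPhantom(values, image.labels, image.pixel_size_mm)


# ---------------------------------------------------------------------------
# scanner sinogram reorganisation and normalization
# ---------------------------------------------------------------------------


def radial_mirror(values: np.ndarray) -> np.ndarray:
    """Mirror the radial axis about the projector's centre bin (n // 2):
    r -> -r means bin -> n - bin, i.e. a reversal followed by a one-bin
    roll.  Bin 0 wraps; real sinograms carry zero margins there."""
    return np.roll(values[:, ::-1], 1, axis=1)


def extend_halfrange(values: np.ndarray) -> np.ndarray:
    """Extend a half-range (0-180 degree) sinogram to full 360 coverage.

    Appends a radially mirrored copy along the angular axis, using the
    parallel-beam identity p(theta + 180, r) = p(theta, -r) bin-exactly
    (the mirror convention matches the discrete projector's centre bin).
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2:
        raise ShapeError("sinogram must be 2-D (angular x radial)")
    return np.concatenate([values, radial_mirror(values)], axis=0)


def _central_crop_radial(values: np.ndarray, rel_tol: float = 1e-6) -> np.ndarray:
    colsum = values.sum(axis=0)
    peak = colsum.max()
    if peak <= 0:
        return values
    keep = np.nonzero(colsum >= rel_tol * peak)[0]
    return values[:, keep[0] : keep[-1] + 1]


def _pad_to_square(values: np.ndarray) -> np.ndarray:
    h, w = values.shape
    if h == w:
        return values
    if h > w:
        pad = h - w
        return np.pad(values, ((0, 0), (pad // 2, pad - pad // 2)))
    pad = w - h
    return np.pad(values, ((pad // 2, pad - pad // 2), (0, 0)))


def normalize_for_network(image: np.ndarray, role: str = "target") -> ImageTensor:
    """Min-max normalize a 2-D plane to [-1, 1] and replicate to 3 channels.

    A constant image maps to all zeros with a degenerate-normalization
    warning; the original range is retained for de-normalization.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0 or image.ndim != 2:
        raise ShapeError("expected a non-empty 2-D image")
    vmin, vmax = float(image.min()), float(image.max())
    if vmax == vmin:
        warnings.warn("constant image: degenerate normalization, emitting zeros")
        plane = np.zeros_like(image)
    else:
        plane = 2.0 * (image - vmin) / (vmax - vmin) - 1.0
    return ImageTensor(np.repeat(plane[:, :, None], 3, axis=2), role=role,
                       vmin=vmin, vmax=vmax)


def preprocess_scanner_sinogram(raw: Sinogram | np.ndarray,
                                angular_axis: int = 0,
                                out_size: int = 256) -> ImageTensor:
    """Reorganise a scanner-style half-range sinogram into a network input.

    Steps: (1) extend the angular range from 180 to 360 degrees via the
    projection symmetry; (2) centrally crop radial margins whose column sums
    are below 1e-6 of the maximum, then pad symmetrically to square;
    (3) bilinearly resize to ``out_size``; (4) min-max normalize to [-1, 1];
    (5) replicate to 3 channels.  ``angular_axis`` selects which axis of a
    raw array indexes the projection angle.
    """
    values = raw.values if isinstance(raw, Sinogram) else np.asarray(raw, dtype=float)
    if values.ndim != 2:
        raise ShapeError("raw sinogram must be 2-D")
    if angular_axis == 1:
        values = values.T
    extended = extend_halfrange(values)
    cropped = _pad_to_square(_central_crop_radial(extended))
    resized = _sk_resize(cropped, (out_size, out_size), order=1, mode="constant",
                         anti_aliasing=False, preserve_range=True)
    return normalize_for_network(resized, role="sinogram")


def sinogram_to_network_input(sino: Sinogram, size: int) -> ImageTensor:
    """Resize a full-range simulated sinogram to the square network input
    and normalize (the training-data path; scanner data instead go through
    :func:`preprocess_scanner_sinogram`)."""
    resized = _sk_resize(sino.values, (size, size), order=1, mode="constant",
                         anti_aliasing=False, preserve_range=True)
    return normalize_for_network(resized, role="sinogram")
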