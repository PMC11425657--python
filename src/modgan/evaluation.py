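"""Image-quality metrics and statistical comparisons.

Per-image fidelity is summarised by SSIM, PSNR and relative root mean
squared error (rRMSE = ||x_hat - x||_2 / ||x||_2); region-based quality by
the contrast-to-noise ratio CNR = (mean(ROI) - mean(background)) /
std(background) and by percentage contrast recovery against the known true
activity ratio of the image-quality phantom.  Paired comparisons between
reconstruction methods use the one-tailed paired t-test, with Shapiro-Wilk
as the normality check.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st
from skimage.metrics import structural_similarity as _sk_ssim

from .errors import DegenerateSampleError, InvalidParameterError, ShapeError
from .phantoms import NemaPhantomSpec, nema_region_masks

__all__ = [
    "RoiSpec",
    "MetricsReport",
    "ssim_index",
    "psnr",
    "rrmse",
    "cnr",
    "contrast_recovery",
    "paired_one_tailed_t",
    "shapiro_wilk",
    "compare_images",
]


@dataclass
class RoiSpec:
    """Region of interest: an explicit boolean mask or a circle
    (centre in pixel coordinates, radius in mm)."""

    name: str
    mask: np.ndarray | None = None
    centre: tuple[float, float] | None = None
    radius_mm: float | None = None
    role: str = "target"

    def resolve(self, shape: tuple[int, int], pixel_size_mm: float = 1.0) -> np.ndarray:
        if self.mask is not None:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != shape:
                raise ShapeError(f"ROI {self.name!r} mask does not match the image")
        else:
            if self.centre is None or self.radius_mm is None:
                raise InvalidParameterError(
                    f"ROI {self.name!r} needs a mask or centre + radius"
                )
            yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
            r_px = self.radius_mm / pixel_size_mm
            mask = (yy - self.centre[0]) ** 2 + (xx - self.centre[1]) ** 2 <= r_px**2
        if not mask.any():
            raise InvalidParameterError(f"ROI {self.name!r} is empty")
        return mask


@dataclass
class MetricsReport:
    """Collected evaluation results, exportable as CSV/JSON."""

    per_image: list[dict] = field(default_factory=list)
    per_roi: list[dict] = field(default_factory=list)
    statistics: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_image)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None):
        payload = {
            "per_image": self.per_image,
            "per_roi": self.per_roi,
            "statistics": self.statistics,
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# image fidelity
# ---------------------------------------------------------------------------


def ssim_index(t_hat: np.ndarray, t: np.ndarray,
               data_range: float | None = None) -> float:
    """Structural similarity (scikit-image backend, Gaussian window
    sigma 1.5 — the same windowing as the differentiable SSIM in
    :mod:`modgan.losses`)."""
    t_hat, t = np.asarray(t_hat, float), np.asarray(t, float)
    if t_hat.shape != t.shape:
        raise ShapeError("images must share a shape")
    if data_range is None:
        data_range = float(t.max() - t.min()) or 1.0
    return float(
        _sk_ssim(t, t_hat, data_range=data_range, gaussian_weights=True,
                 sigma=1.5, use_sample_covariance=False)
    )


def psnr(t_hat: np.ndarray, t: np.ndarray, data_range: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    t_hat, t = np.asarray(t_hat, float), np.asarray(t, float)
    if t_hat.shape != t.shape:
        raise ShapeError("images must share a shape")
    if data_range is None:
        data_range = float(t.max() - t.min())
    if data_range <= 0:
        raise InvalidParameterError("data_range must be positive")
    mse = float(np.mean((t_hat - t) ** 2))
    if mse == 0:
        return math.inf
    return 10.0 * math.log10(data_range**2 / mse)


def rrmse(t_hat: np.ndarray, t: np.ndarray, normalizer: str = "l2") -> float:
    """Relative RMSE.  Default normaliser is the L2 norm of the reference
    (so a zero estimate scores exactly 1); ``"mean"`` and ``"range"``
    divide the RMS error by the reference mean or range instead."""
    t_hat, t = np.asarray(t_hat, float), np.asarray(t, float)
    if t_hat.shape != t.shape:
        raise ShapeError("images must share a shape")
    if normalizer == "l2":
        denom = float(np.linalg.norm(t))
        if denom == 0:
            raise InvalidParameterError("reference image is all zero")
        return float(np.linalg.norm(t_hat - t) / denom)
    rms = float(np.sqrt(np.mean((t_hat - t) ** 2)))
    if normalizer == "mean":
        denom = float(np.abs(t.mean()))
    elif normalizer == "range":
        denom = float(t.max() - t.min())
    else:
        raise InvalidParameterError(f"unknown normalizer {normalizer!r}")
    if denom == 0:
        raise InvalidParameterError("degenerate reference for rRMSE")
    return rms / denom


# ---------------------------------------------------------------------------
# region-based quality
# ---------------------------------------------------------------------------


def cnr(image: np.ndarray, roi: RoiSpec, background: RoiSpec,
        pixel_size_mm: float = 1.0) -> float:
    """Contrast-to-noise ratio (mean ROI - mean background) / std background
    (sample standard deviation, n - 1)."""
    image = np.asarray(image, float)
    roi_mask = roi.resolve(image.shape, pixel_size_mm)
    bkg_mask = background.resolve(image.shape, pixel_size_mm)
    bkg = image[bkg_mask]
    if bkg.size < 2:
        raise InvalidParameterError("background ROI needs at least 2 pixels")
    sd = float(bkg.std(ddof=1))
    if sd == 0:
        raise DegenerateSampleError("background ROI has zero variance")
    return float((image[roi_mask].mean() - bkg.mean()) / sd)


def _background_roi_means(image: np.ndarray, spec: NemaPhantomSpec,
                          diameter_mm: float, n_rois: int = 12) -> np.ndarray:
    """Means of ``n_rois`` circular background ROIs of the given diameter,
    placed on a ring in the uniform region (a simplification of the
    60-ROI standard protocol)."""
    n = spec.grid_size
    centre = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    ring_mm = 0.5 * (spec.sphere_ring_radius_mm + max(spec.sphere_diameters_mm) / 2.0
                     + 0.9 * spec.body_radius_mm)
    r_px = (diameter_mm / 2.0) / spec.pixel_size_mm
    means = []
    for k in range(n_rois):
        theta = 2 * math.pi * (k + 0.5) / n_rois
        cy = centre + (ring_mm / spec.pixel_size_mm) * math.sin(theta)
        cx = centre + (ring_mm / spec.pixel_size_mm) * math.cos(theta)
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
        if mask.any():
            means.append(float(image[mask].mean()))
    return np.asarray(means)


def contrast_recovery(image: np.ndarray, spec: NemaPhantomSpec | None = None,
                      masks: dict | None = None) -> list[dict]:
    """Percentage contrast recovery per sphere of the image-quality phantom.

    Hot spheres: 100 * (C_s / C_b - 1) / (a_s / a_b - 1); cold spheres:
    100 * (1 - C_s / C_b); C are measured ROI means, a the true activities
    from the spec.  Background C_b averages 12 circular ROIs of the
    sphere's own diameter placed in the uniform region.
    """
    spec = spec or NemaPhantomSpec()
    image = np.asarray(image, float)
    masks = masks or nema_region_masks(spec)
    results = []
    for i, sphere_mask in enumerate(masks["spheres"]):
        d = spec.sphere_diameters_mm[i]
        c_sphere = float(image[sphere_mask].mean())
        bkg_means = _background_roi_means(image, spec, d)
        c_bkg = float(bkg_means.mean())
        if c_bkg == 0:
            raise InvalidParameterError("background ROI mean is zero")
        hot = i < spec.hot_sphere_count
        if hot:
            true_ratio = spec.sphere_to_background_ratio
            recovery = 100.0 * (c_sphere / c_bkg - 1.0) / (true_ratio - 1.0)
        else:
            recovery = 100.0 * (1.0 - c_sphere / c_bkg)
        results.append({
            "diameter_mm": d,
            "hot": hot,
            "measured_ratio": c_sphere / c_bkg,
            "contrast_recovery_pct": recovery,
        })
    return results


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def paired_one_tailed_t(x, y) -> tuple[float, float]:
    """Paired t-test on x - y with the directional alternative
    mean(x) > mean(y); returns (t, one-tailed p).

    Identical samples give (0, 0.5) — the symmetric null.  A constant
    non-zero difference has no variance to test against and raises.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size != y.size or x.size < 2:
        raise InvalidParameterError("paired samples must have equal length >= 2")
    d = x - y
    sd = float(d.std(ddof=1))
    if sd == 0:
        if float(d.mean()) == 0:
            return 0.0, 0.5
        raise DegenerateSampleError("differences are constant and non-zero")
    n = d.size
    t = float(d.mean() / (sd / math.sqrt(n)))
    p = float(_st.t.sf(t, df=n - 1))
    return t, p


def shapiro_wilk(sample) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, p) for 3 <= n <= 5000."""
    sample = np.asarray(sample, float).ravel()
    if not 3 <= sample.size <= 5000:
        raise InvalidParameterError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(sample) == 0:
        raise DegenerateSampleError("constant sample")
    w, p = _st.shapiro(sample)
    return float(w), float(p)


def compare_images(t_hat: np.ndarray, t: np.ndarray,
                   data_range: float | None = None) -> dict[str, float]:
    """SSIM, PSNR and rRMSE of one reconstruction against its reference."""
    return {
        "ssim": ssim_index(t_hat, t, data_range),
        "psnr_db": psnr(t_hat, t, data_range),
        "rrmse": rrmse(t_hat, t),
    }
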