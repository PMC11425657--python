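"""Classical reconstruction baselines: filtered backprojection and OSEM.

Both baselines run on the package's matched projector/backprojector pair
(:mod:`modgan.projection`).  FBP applies a frequency-domain ramp filter
(optionally Hann-apodized) to each projection and backprojects with the
adjoint operator, scaled by pi / (2 N_angles).  OSEM performs
multiplicative expectation-maximisation updates cycled over interleaved
angle subsets,

    x <- x * A_sub^T( y_sub / (A_sub x + eps) ) / A_sub^T 1 ,

which with a single subset reduces to MLEM and, because the pair is an
exact adjoint, inherits MLEM's non-decreasing Poisson log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, InvalidParameterError
from .phantoms import ActivityPhantom
from .projection import Sinogram, backproject_angle, project_angle

__all__ = ["OsemConfig", "fbp", "osem", "mlem", "poisson_log_likelihood"]

_FILTERS = ("ramp", "hann", "none")


@dataclass
class OsemConfig:
    n_subsets: int = 4
    n_iterations: int = 10
    initial_value: float = 1.0
    epsilon: float = 1e-8

    def __post_init__(self):
        if self.n_subsets < 1 or self.n_iterations < 1:
            raise ConfigError("n_subsets and n_iterations must be >= 1")
        if self.initial_value <= 0 or self.epsilon <= 0:
            raise ConfigError("initial_value and epsilon must be positive")


def _filtered_projections(values: np.ndarray, filter_name: str) -> np.ndarray:
    n = values.shape[1]
    pad = max(64, int(2 ** np.ceil(np.log2(2 * n))))
    freqs = np.fft.rfftfreq(pad)
    response = 2.0 * np.abs(freqs)
    if filter_name == "hann":
        response *= 0.5 + 0.5 * np.cos(np.pi * freqs / freqs.max())
    spectra = np.fft.rfft(values, pad, axis=1) * response
    return np.fft.irfft(spectra, pad, axis=1)[:, :n]


def fbp(sino: Sinogram, filter_name: str = "ramp",
        clip_negatives: bool = True) -> ActivityPhantom:
    """Filtered backprojection of a parallel-beam sinogram.

    Frequency-domain ramp filtering of each projection (optionally Hann
    apodized, or unfiltered with ``"none"``) followed by adjoint
    backprojection scaled by pi / (2 N_angles) — a linear operator.
    Negative ripples are clipped to zero by default so the result is a
    valid activity image; pass ``clip_negatives=False`` for the raw linear
    output.
    """
    if filter_name not in _FILTERS:
        raise ConfigError(
            f"unknown filter {filter_name!r}; choose from {sorted(_FILTERS)}"
        )
    if sino.n_angles < 16:
        raise InvalidParameterError("FBP needs at least 16 angles to be meaningful")
    n = sino.n_radial
    proj = (sino.values if filter_name == "none"
            else _filtered_projections(sino.values, filter_name))
    recon = np.zeros((n, n))
    for profile, angle in zip(proj, sino.angles_deg):
        recon += backproject_angle(profile, angle, n)
    recon *= np.pi / (2.0 * sino.n_angles)
    if clip_negatives:
        return ActivityPhantom(np.clip(recon, 0.0, None),
                               pixel_size_mm=sino.radial_spacing_mm)
    phantom = ActivityPhantom(np.zeros_like(recon),
                              pixel_size_mm=sino.radial_spacing_mm)
    phantom.values = recon  # bypass the non-negativity check deliberately
    return phantom


def _project_subset(x: np.ndarray, angles: np.ndarray) -> np.ndarray:
    return np.stack([project_angle(x, a) for a in angles])


def _backproject_subset(profiles: np.ndarray, angles: np.ndarray,
                        n: int) -> np.ndarray:
    out = np.zeros((n, n))
    for profile, a in zip(profiles, angles):
        out += backproject_angle(profile, a, n)
    return out


def poisson_log_likelihood(sino: Sinogram, image: np.ndarray,
                           epsilon: float = 1e-8) -> float:
    """Poisson data log-likelihood of ``image`` (up to the y!-constant)."""
    proj = _project_subset(np.asarray(image, dtype=float), sino.angles_deg)
    return float(np.sum(sino.values * np.log(proj + epsilon) - proj))


def osem(sino: Sinogram, config: OsemConfig | None = None,
         return_loglik: bool = False):
    """Ordered-subset EM reconstruction on the matched projector pair.

    Angle subsets are interleaved (subset k takes angles k, k+S, ...).
    Pixels with zero sensitivity in any subset are masked to zero rather
    than producing NaNs.  With ``return_loglik`` the per-full-iteration
    Poisson log-likelihood trajectory is returned alongside the image.
    """
    config = config or OsemConfig()
    if np.any(sino.values < 0):
        raise InvalidParameterError("OSEM requires a non-negative sinogram")
    n = sino.n_radial
    n_angles = sino.n_angles
    if config.n_subsets > n_angles:
        raise ConfigError("more subsets than projection angles")
    subsets = [np.arange(k, n_angles, config.n_subsets)
               for k in range(config.n_subsets)]
    sens = []
    support = np.ones((n, n), dtype=bool)
    ones = np.ones(n)
    for idx in subsets:
        s = _backproject_subset(np.tile(ones, (idx.size, 1)),
                                sino.angles_deg[idx], n)
        sens.append(s)
        support &= s > 1e-8
    x = np.where(support, config.initial_value, 0.0)
    logliks = []
    for _ in range(config.n_iterations):
        for idx, s in zip(subsets, sens):
            proj = _project_subset(x, sino.angles_deg[idx])
            ratio = sino.values[idx] / (proj + config.epsilon)
            update = _backproject_subset(ratio, sino.angles_deg[idx], n)
            with np.errstate(invalid="ignore", divide="ignore"):
                x = np.where(support, x * update / np.where(support, s, 1.0), 0.0)
        if return_loglik:
            logliks.append(poisson_log_likelihood(sino, x, config.epsilon))
    phantom = ActivityPhantom(np.clip(x, 0.0, None),
                              pixel_size_mm=sino.radial_spacing_mm)
    return (phantom, logliks) if return_loglik else phantom


def mlem(sino: Sinogram, n_iterations: int = 20, **kwargs):
    """MLEM = OSEM with a single subset."""
    return osem(sino, OsemConfig(n_subsets=1, n_iterations=n_iterations), **kwargs)
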