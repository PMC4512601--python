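"""Vesselness Measure (VNM): multiscale tubular-structure detection.

Vessels appear in the green plane as dark curvilinear structures on a brighter
background.  At a pixel, the eigenvalues (l1, l2), |l1| <= |l2|, of the
scale-normalized Hessian describe the local second-order geometry: a tube has
l1 ~ 0 along its axis and a large |l2| across it (positive for a dark tube on
a bright background).  The Frangi-style tubularity

    V = exp(-R_b^2 / (2 beta^2)) * (1 - exp(-S^2 / (2 c^2))),
    R_b = |l1| / |l2|,   S = sqrt(l1^2 + l2^2),

penalizes blobs (R_b -> 1) and flat noise (small S) and approaches 1 on a
well-contrasted ideal tube.  The vessel-diameter search criteria (VDSC) give
the diameter range to look for; each diameter d is probed at Gaussian scale
sigma = d/4 and the per-pixel response is the maximum across scales.  The
response is floored to exactly 0 in background (the black-background
angiogram-like rendering) and rescaled so the per-image maximum maps to 255.

A documented limitation inherited from the approach: laser scars, the field
edge and vascular loops are all picked up as "tubes"; distinguishing them is
left to the clinical reading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .image_io import GreyPlane, quantize_u8
from .preprocess import _map_images

__all__ = [
    "VDSC",
    "TubularityParams",
    "vdsc_to_scales",
    "hessian_eigenvalues",
    "tubularity",
    "vesselness_measure",
    "binarize_vessels",
    "VesselnessFilter",
    "DEFAULT_FLOOR",
    "DEFAULT_BINARIZE_THRESHOLD",
]

#: tubularity responses below this (pre-rescale, on the [0, 1] response scale)
#: render as pure black background; diffuse background and residual noise
#: respond at ~1e-3 or less, faint terminal capillaries at ~2e-2
DEFAULT_FLOOR = 0.01

#: default threshold (0-255) used when a binary vessel mask is needed
DEFAULT_BINARIZE_THRESHOLD = 25

#: sigma = diameter / SIGMA_PER_DIAMETER for a Gaussian-profile tube
SIGMA_PER_DIAMETER = 4.0

POLARITIES = ("dark_on_bright", "bright_on_dark")

#: Gaussian kernel support in standard deviations.  Wide enough that residual
#: kernel moments vanish, making the Hessian exact on quadratics and the
#: response invariant to constant intensity offsets.
GAUSS_TRUNCATE = 8.0


@dataclass
class VDSC:
    """Vessel-diameter search criteria: probe diameters in [d_min, d_max] pixels
    at ``n_scales`` log-spaced analysis scales.  Small d_min targets the small
    calibre vessels characteristic of ROP imaging."""

    d_min: float = 2.0
    d_max: float = 12.0
    n_scales: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.d_min <= self.d_max:
            raise ValueError("require 0 < d_min <= d_max")
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")


@dataclass
class TubularityParams:
    """Frangi-style sensitivities: ``beta`` for blobness, ``c`` for structureness
    (on the 0-255 intensity scale), and the expected vessel polarity."""

    beta: float = 0.5
    c: float = 15.0
    polarity: str = "dark_on_bright"

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.c <= 0:
            raise ValueError("beta and c must be positive")
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}")


def vdsc_to_scales(vdsc: VDSC) -> np.ndarray:
    """Log-spaced analysis scales sigma_i over [d_min/4, d_max/4] (ascending)."""
    lo = vdsc.d_min / SIGMA_PER_DIAMETER
    hi = vdsc.d_max / SIGMA_PER_DIAMETER
    return np.geomspace(lo, hi, vdsc.n_scales)


def _eig2_symmetric(ixx: np.ndarray, ixy: np.ndarray, iyy: np.ndarray):
    """Eigenvalues of per-pixel symmetric 2x2 Hessians, ordered |l1| <= |l2|."""
    half_tr = 0.5 * (ixx + iyy)
    disc = np.sqrt((0.5 * (ixx - iyy)) ** 2 + ixy**2)
    e1 = half_tr + disc
    e2 = half_tr - disc
    swap = np.abs(e1) > np.abs(e2)
    l1 = np.where(swap, e2, e1)
    l2 = np.where(swap, e1, e2)
    return l1, l2


def hessian_eigenvalues(plane: GreyPlane | np.ndarray, sigma: float):
    """Scale-normalized Hessian eigenvalues (l1, l2) with |l1| <= |l2|.

    Second derivatives are computed by Gaussian-derivative filtering at scale
    ``sigma`` and multiplied by sigma^2 (gamma-normalization), making responses
    comparable across scales.
    """
    if sigma < 0.5:
        raise ValueError("sigma must be >= 0.5 (sub-pixel scales are unresolvable)")
    values = plane.values if isinstance(plane, GreyPlane) else np.asarray(plane, float)
    s2 = sigma * sigma
    # order=(row derivative, column derivative)
    iyy = gaussian_filter(values, sigma, order=(2, 0), mode="nearest",
                          truncate=GAUSS_TRUNCATE) * s2
    ixx = gaussian_filter(values, sigma, order=(0, 2), mode="nearest",
                          truncate=GAUSS_TRUNCATE) * s2
    ixy = gaussian_filter(values, sigma, order=(1, 1), mode="nearest",
                          truncate=GAUSS_TRUNCATE) * s2
    return _eig2_symmetric(ixx, ixy, iyy)


def tubularity(l1: np.ndarray, l2: np.ndarray,
               params: TubularityParams | None = None) -> np.ndarray:
    """Per-pixel Frangi-style tubular response in [0, 1].

    Zero wherever l2 fails the polarity condition (dark-on-bright vessels
    require l2 > 0) — in particular wherever l2 == 0, so no division occurs.
    """
    params = params or TubularityParams()
    l1 = np.asarray(l1, float)
    l2 = np.asarray(l2, float)
    if params.polarity == "dark_on_bright":
        accept = l2 > 0
    else:
        accept = l2 < 0
    safe_l2 = np.where(l2 == 0, 1.0, l2)
    rb2 = (l1 / safe_l2) ** 2
    s2 = l1 * l1 + l2 * l2
    resp = np.exp(-rb2 / (2.0 * params.beta**2)) * (
        1.0 - np.exp(-s2 / (2.0 * params.c**2)))
    return np.where(accept, resp, 0.0)


def vesselness_measure(plane: GreyPlane | np.ndarray,
                       vdsc: VDSC | None = None,
                       params: TubularityParams | None = None,
                       floor: float = DEFAULT_FLOOR) -> np.ndarray:
    """VNM protocol: max tubularity across VDSC scales on a black background.

    Returns an 8-bit map: responses below ``floor`` are exactly 0; surviving
    responses are rescaled linearly so the per-image maximum maps to 255
    (all-zero map when nothing survives).  Input should normally be the
    noise-filtered green plane.
    """
    vdsc = vdsc or VDSC()
    params = params or TubularityParams()
    values = plane.values if isinstance(plane, GreyPlane) else np.asarray(plane, float)
    scales = np.maximum(vdsc_to_scales(vdsc), 0.5)
    resp = np.zeros_like(values, dtype=np.float64)
    for sigma in scales:
        l1, l2 = hessian_eigenvalues(values, float(sigma))
        np.maximum(resp, tubularity(l1, l2, params), out=resp)
    resp[resp < floor] = 0.0
    peak = resp.max()
    if peak <= 0:
        return np.zeros(values.shape, dtype=np.uint8)
    return quantize_u8(resp * (255.0 / peak))


def binarize_vessels(vmap: np.ndarray, threshold: int = DEFAULT_BINARIZE_THRESHOLD
                     ) -> np.ndarray:
    """Binary vessel mask: true where the 8-bit map value >= threshold."""
    if not 0 <= int(threshold) <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    vmap = np.asarray(vmap)
    return vmap >= threshold


class VesselnessFilter(TransformerMixin, BaseEstimator):
    """VNM transformer: filtered grey plane(s) -> 8-bit vesselness map(s)."""

    def __init__(self, d_min: float = 2.0, d_max: float = 12.0, n_scales: int = 5,
                 beta: float = 0.5, c: float = 15.0,
                 polarity: str = "dark_on_bright", floor: float = DEFAULT_FLOOR):
        self.d_min = d_min
        self.d_max = d_max
        self.n_scales = n_scales
        self.beta = beta
        self.c = c
        self.polarity = polarity
        self.floor = floor

    def _params(self):
        return (VDSC(self.d_min, self.d_max, self.n_scales),
                TubularityParams(self.beta, self.c, self.polarity))

    def fit(self, X, y=None):
        self._params()
        return self

    def transform(self, X):
        vdsc, tp = self._params()
        return _map_images(
            lambda p: vesselness_measure(np.asarray(p, float), vdsc, tp, self.floor), X)
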