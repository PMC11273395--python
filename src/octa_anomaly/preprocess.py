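"""En face image standardization and Hessian-based vessel enhancement.

Standardization resizes to a common working size, centre-crops to trim
border artifacts, and min-max rescales to [0, 1] (the clinical pipeline uses
512 -> 480; the desk-scale phantoms are already square so the identity
config is common there).

Vessel enhancement is a Frangi-style multiscale ridge filter built from the
eigenvalues of the scale-normalized Hessian: at each scale the image is
Gaussian-smoothed, second derivatives are taken, and per-pixel 2x2
eigenvalues |lambda1| <= |lambda2| drive a bright-ridge response (lambda2
strongly negative, anisotropic).  The maximum response over scales is
returned, rescaled to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize as _sk_resize

from .errors import ConfigurationError


@dataclass(frozen=True)
class PreprocessConfig:
    resize_to: int = 512
    crop_to: int = 480
    vesselness_scales: Tuple[float, ...] = (1.0, 2.0, 4.0)
    enhance: bool = False

    def validate(self) -> None:
        if self.crop_to > self.resize_to:
            raise ConfigurationError("crop_to must be <= resize_to")
        if any(s <= 0 for s in self.vesselness_scales):
            raise ConfigurationError("vesselness scales must be positive")


DESK_PREPROCESS = PreprocessConfig(resize_to=128, crop_to=128,
                                   vesselness_scales=(1.0, 2.0, 4.0))


def _minmax(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi - lo <= 0:
        return np.zeros_like(img)          # constant image convention: all 0
    return (img - lo) / (hi - lo)


def standardize(image: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Resize (bilinear) -> centre crop -> min-max rescale to [0, 1].

    The crop is centred with ties broken toward the top-left.  Idempotent on
    its own output when crop_to == resize_to target geometry.
    """
    cfg.validate()
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got ndim={img.ndim}")
    if img.shape == (cfg.crop_to, cfg.crop_to):
        return _minmax(img)                # already standardized: idempotence
    if img.shape != (cfg.resize_to, cfg.resize_to):
        img = _sk_resize(img, (cfg.resize_to, cfg.resize_to), order=1,
                         anti_aliasing=img.shape[0] > cfg.resize_to,
                         preserve_range=True)
    off = (cfg.resize_to - cfg.crop_to) // 2
    img = img[off:off + cfg.crop_to, off:off + cfg.crop_to]
    return _minmax(img)


def hessian_matrix(image: np.ndarray, scale: float) -> np.ndarray:
    """Per-pixel 2x2 Hessian of the Gaussian-smoothed image.

    Returns an (H, W, 2, 2) symmetric field with axis 0 of the image as the
    first coordinate.  Derivatives are plain (not scale-normalized); callers
    that need gamma-normalization multiply by ``scale**2``.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    img = np.asarray(image, dtype=np.float64)
    # de-meaning makes the response exactly invariant to constant offsets:
    # truncated derivative kernels do not annihilate constants on their own
    img = img - img.mean()
    hrr = gaussian_filter(img, scale, order=(2, 0), truncate=8.0)
    hcc = gaussian_filter(img, scale, order=(0, 2), truncate=8.0)
    hrc = gaussian_filter(img, scale, order=(1, 1), truncate=8.0)
    H = np.empty(img.shape + (2, 2), dtype=np.float64)
    H[..., 0, 0] = hrr
    H[..., 0, 1] = hrc
    H[..., 1, 0] = hrc
    H[..., 1, 1] = hcc
    return H


def hessian_eigenvalues(H: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Closed-form eigenvalues of a symmetric 2x2 field, |l1| <= |l2|.

    Ties in absolute value are broken by signed value ascending.
    """
    a, b, d = H[..., 0, 0], H[..., 0, 1], H[..., 1, 1]
    mid = 0.5 * (a + d)
    disc = np.sqrt((0.5 * (a - d)) ** 2 + b * b)
    lo, hi = mid - disc, mid + disc          # signed ascending
    swap = np.abs(lo) > np.abs(hi)           # on |.|-ties keep signed order
    l1 = np.where(swap, hi, lo)
    l2 = np.where(swap, lo, hi)
    return l1, l2


def vesselness_enhance(image: np.ndarray, cfg: PreprocessConfig,
                       beta: float = 0.5) -> np.ndarray:
    """Multiscale bright-ridge (Frangi-style) response in [0, 1]."""
    cfg.validate()
    img = np.asarray(image, dtype=np.float64)
    best = np.zeros_like(img)
    for s in cfg.vesselness_scales:
        H = hessian_matrix(img, s) * (s * s)     # gamma-normalized derivatives
        l1, l2 = hessian_eigenvalues(H)
        with np.errstate(divide="ignore", invalid="ignore"):
            rb2 = np.where(l2 != 0, (l1 / l2) ** 2, 0.0)
        s2 = l1 * l1 + l2 * l2
        c = 0.5 * np.sqrt(s2.max()) if s2.max() > 0 else 1.0
        v = np.exp(-rb2 / (2 * beta ** 2)) * (1.0 - np.exp(-s2 / (2 * c ** 2)))
        v = np.where(l2 < 0, v, 0.0)             # bright ridges only
        np.maximum(best, v, out=best)
    if best.max() > 0:
        best = best / best.max()
    return best
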