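"""Preprocessing ahead of feature extraction.

Steps mirror the standard CT radiomics protocol: isotropic B-spline
resampling to 1 mm, re-segmentation to the soft-tissue HU window
[-150, 180], a filter bank (original, Laplacian-of-Gaussian at several
scales, and a single-level stationary coiflet-1 wavelet decomposition into
8 sub-bands), and fixed-bin-count discretization of the in-mask
intensities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import ImageVolume, Mask

__all__ = [
    "PreprocessConfig",
    "resample_pair",
    "resegment",
    "filter_bank",
    "discretize",
]

# coiflet-1 decomposition filters (standard 6-tap constants)
_COIF1_LO = np.array([
    -0.01565572813546454, -0.0727326195128539, 0.38486484686420286,
    0.8525720202122554, 0.3378976624578092, -0.0727326195128539,
])
# quadrature mirror: hi[n] = (-1)^n lo[L-1-n]
_COIF1_HI = np.array([(-1) ** n * _COIF1_LO[len(_COIF1_LO) - 1 - n]
                      for n in range(len(_COIF1_LO))])


@dataclass
class PreprocessConfig:
    """Preprocessing and filter-bank parameters.

    Defaults: 1 mm isotropic grid, HU re-segmentation window [-150, 180],
    fixed bin counts {50..350 step 50}, LoG sigmas {1, 3, 6} mm and the
    8-sub-band coiflet-1 stationary wavelet bank.
    """

    target_spacing_mm: float = 1.0
    resegment_hu: tuple[float, float] = (-150.0, 180.0)
    bin_counts: tuple[int, ...] = (50, 100, 150, 200, 250, 300, 350)
    log_sigmas_mm: tuple[float, ...] = (1.0, 3.0, 6.0)
    wavelet: bool = True

    def __post_init__(self) -> None:
        if self.target_spacing_mm <= 0:
            raise ValueError("target spacing must be positive")
        lo, hi = self.resegment_hu
        if lo >= hi:
            raise ValueError("re-segmentation window must have lo < hi")
        if any(b < 2 for b in self.bin_counts):
            raise ValueError("bin counts must be >= 2")
        if any(s <= 0 for s in self.log_sigmas_mm):
            raise ValueError("LoG sigma must be positive")


def resample_pair(image: ImageVolume, mask: Mask,
                  spacing_mm: float = 1.0) -> tuple[ImageVolume, Mask]:
    """Resample image and mask to an isotropic grid.

    The image uses cubic B-spline interpolation; the mask linear
    interpolation with a 0.5 threshold so it stays binary.  Raises if the
    resampling empties a non-empty mask.
    """
    if spacing_mm <= 0:
        raise ValueError("target spacing must be positive")
    image.require_same_grid(mask)
    zoom = np.asarray(image.spacing) / spacing_mm
    out_img = ndimage.zoom(np.asarray(image.array, dtype=float), zoom, order=3,
                           mode="nearest", grid_mode=True)
    out_mask = ndimage.zoom(mask.array.astype(float), zoom, order=1,
                            mode="nearest", grid_mode=True) > 0.5
    new_spacing = (spacing_mm,) * 3
    if not mask.is_empty and not out_mask.any():
        raise ValueError("mask emptied by resampling")
    return (ImageVolume(out_img, new_spacing, image.origin),
            Mask(out_mask, new_spacing, mask.origin))


def resegment(image: ImageVolume, mask: Mask,
              hu_range: tuple[float, float] = (-150.0, 180.0)) -> Mask:
    """Restrict the mask to voxels inside the HU window (soft tissue).

    An empty result is legal (flagged with a warning); downstream feature
    extraction marks affected features missing.
    """
    image.require_same_grid(mask)
    lo, hi = hu_range
    arr = np.asarray(image.array)
    out = mask.array & (arr >= lo) & (arr <= hi)
    if mask.array.any() and not out.any():
        warnings.warn("re-segmentation produced an empty intensity mask",
                      stacklevel=2)
    return Mask(out, mask.spacing, mask.origin)


def _swt3_subbands(arr: np.ndarray) -> dict[str, np.ndarray]:
    """Single-level undecimated separable 3-D wavelet decomposition.

    Letters index axes (axis 0, 1, 2); L = low-pass, H = high-pass with the
    coiflet-1 filters; sub-bands keep the input grid (symmetric padding).
    """
    out: dict[str, np.ndarray] = {}
    # half-sample symmetric extension to keep filters zero-phase-ish
    origin = -1  # centre the even-length filter
    for name in ("LLL", "HLL", "LHL", "LLH", "LHH", "HLH", "HHL", "HHH"):
        sub = arr
        for axis, letter in enumerate(name):
            filt = _COIF1_LO if letter == "L" else _COIF1_HI
            sub = ndimage.correlate1d(sub, filt, axis=axis, mode="mirror",
                                      origin=origin)
        out[f"wavelet-{name}"] = sub
    return out


def filter_bank(image: ImageVolume,
                config: PreprocessConfig | None = None) -> dict[str, ImageVolume]:
    """Derive the named filtered images used for feature extraction.

    Returns the original plus one LoG image per sigma (sigma in mm,
    converted to voxels on the isotropic grid) and, if enabled, the eight
    stationary coiflet-1 wavelet sub-bands.  With the default config that is
    12 images; names are stable across runs.
    """
    config = config or PreprocessConfig()
    arr = np.asarray(image.array, dtype=float)
    spacing = np.asarray(image.spacing)
    out: dict[str, ImageVolume] = {
        "original": ImageVolume(arr.copy(), image.spacing, image.origin)
    }
    for sigma in config.log_sigmas_mm:
        sig_vox = sigma / spacing
        # discrete Laplacian of the Gaussian-smoothed image: exactly zero on
        # constant input; scale-normalised by sigma^2
        smoothed = ndimage.gaussian_filter(arr, sig_vox)
        filtered = ndimage.laplace(smoothed) / spacing.mean() ** 2 * sigma ** 2
        out[f"log-sigma-{sigma:g}mm"] = ImageVolume(filtered, image.spacing,
                                                    image.origin)
    if config.wavelet:
        for name, sub in _swt3_subbands(arr).items():
            out[name] = ImageVolume(sub, image.spacing, image.origin)
    return out


def discretize(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Fixed-bin-count discretization of ROI intensities.

    Equal-width bins span [min, max] of the supplied values; indices run
    1..n_bins with the minimum mapped to 1 and the maximum to n_bins.
    Interior bin edges belong to the lower bin.  A constant input collapses
    to a single occupied bin (with a warning).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot discretize an empty value set")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        warnings.warn("constant input: all voxels assigned bin 1", stacklevel=2)
        return np.ones(values.shape, dtype=np.int64)
    width = (hi - lo) / n_bins
    idx = np.ceil((values - lo) / width).astype(np.int64)
    return np.clip(idx, 1, n_bins)
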