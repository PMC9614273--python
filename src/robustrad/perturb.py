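"""Image and segmentation perturbations used as "raters" in the ICC analysis.

Four perturbation modes emulate realistic acquisition and delineation
variability:

* rigid translation (per-axis, mm) and rotation about the SI axis, applied to
  image and mask simultaneously — patient positioning variation;
* an additive Gaussian noise field — scanner noise-level variation;
* randomized contours generated from smoothed random deformable vector fields,
  accepted only if they stay within Dice and Hausdorff bounds of the original
  mask — inter-observer delineation variability.

A perturbation grid enumerates the full factorial combination of mode
parameters; per patient a fixed number of grid cells is drawn without
replacement, with a stream that is a pure function of (seed, patient id).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .types import ImageVolume, Mask

__all__ = [
    "PerturbationGrid",
    "PerturbationSpec",
    "build_perturbation_grid",
    "default_grid",
    "sample_perturbations",
    "apply_rigid",
    "add_noise_field",
    "randomize_contour",
    "apply_perturbation",
    "dice",
    "hausdorff",
    "ContourConstraintError",
]


class ContourConstraintError(RuntimeError):
    """Raised when no randomized contour satisfies the constraints."""


def _frange(start: float, stop: float, step: float) -> list[float]:
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    n = int(round((stop - start) / step))
    values = [round(start + i * step, 10) for i in range(n + 1)]
    if not values or values[-1] > stop + 1e-9:
        raise ValueError(f"empty or ill-ordered range ({start}, {stop}, {step})")
    return values


@dataclass(frozen=True)
class PerturbationSpec:
    """One sampled perturbation: translation (mm), rotation (deg about SI),
    noise level, and the seed of the contour-randomization draw."""

    t_ap: float
    t_si: float
    t_lm: float
    rotation_deg: float
    noise_level: int
    contour_seed: int

    def to_dict(self) -> dict:
        return {
            "t_ap": self.t_ap, "t_si": self.t_si, "t_lm": self.t_lm,
            "rotation_deg": self.rotation_deg,
            "noise_level": self.noise_level, "contour_seed": self.contour_seed,
        }


@dataclass(frozen=True)
class PerturbationGrid:
    """Factorial grid of perturbation parameters.

    The grid size is ``|translations|^3 x |rotations| x |noise levels| x
    n_contours``; the default reproduces the published factorial of
    4,423,680 combinations (4,096 translation vectors).
    """

    translations_mm: tuple[float, ...]
    rotations_deg: tuple[float, ...]
    noise_levels: tuple[int, ...]
    n_contours: int

    def __post_init__(self) -> None:
        if (not self.translations_mm or not self.rotations_deg
                or not self.noise_levels or self.n_contours < 1):
            raise ValueError("all grid factors must be non-empty")

    @property
    def n_translations(self) -> int:
        return len(self.translations_mm) ** 3

    @property
    def size(self) -> int:
        return (self.n_translations * len(self.rotations_deg)
                * len(self.noise_levels) * self.n_contours)

    def spec_at(self, index: int) -> PerturbationSpec:
        """Decode a flat grid index into a PerturbationSpec."""
        if not 0 <= index < self.size:
            raise IndexError(index)
        t = self.translations_mm
        dims = (len(t), len(t), len(t), len(self.rotations_deg),
                len(self.noise_levels), self.n_contours)
        idx = np.unravel_index(index, dims)
        return PerturbationSpec(
            t_ap=t[idx[0]], t_si=t[idx[1]], t_lm=t[idx[2]],
            rotation_deg=self.rotations_deg[idx[3]],
            noise_level=self.noise_levels[idx[4]],
            contour_seed=int(idx[5]),
        )


def build_perturbation_grid(
    translation_range: tuple[float, float, float] = (0.0, 3.0, 0.2),
    rotation_range: tuple[float, float, float] = (-20.0, 20.0, 5.0),
    noise_levels: tuple[int, ...] = (0, 1, 2, 3),
    n_contours: int = 30,
) -> PerturbationGrid:
    """Build the factorial perturbation grid from (start, stop, step) ranges.

    Defaults give translations 0–3 mm in 0.2 mm steps on each of the three
    axes (16 values, 4,096 vectors), rotations −20..20° in 5° steps (9),
    four noise levels and 30 contour randomizations: 4,423,680 combinations.
    """
    return PerturbationGrid(
        translations_mm=tuple(_frange(*translation_range)),
        rotations_deg=tuple(_frange(*rotation_range)),
        noise_levels=tuple(int(v) for v in noise_levels),
        n_contours=int(n_contours),
    )


def default_grid() -> PerturbationGrid:
    return build_perturbation_grid()


def _patient_rng(seed: int, patient_id: str) -> np.random.Generator:
    """Deterministic per-patient generator: hash the id into the seed stream."""
    digest = hashlib.sha256(patient_id.encode()).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def sample_perturbations(grid: PerturbationGrid, n: int, patient_id: str,
                         seed: int) -> list[PerturbationSpec]:
    """Draw ``n`` distinct perturbations from the grid for one patient.

    The draw is a pure function of ``(seed, patient_id)``: re-running gives
    the identical list, and different patients get independent draws under
    the same seed.
    """
    if n > grid.size:
        raise ValueError(f"cannot draw {n} distinct specs from a grid of "
                         f"size {grid.size}")
    rng = _patient_rng(seed, patient_id)
    idx = rng.choice(grid.size, size=n, replace=False)
    return [grid.spec_at(int(i)) for i in idx]


def apply_rigid(image: ImageVolume, mask: Mask, t_mm: tuple[float, float, float],
                angle_deg: float) -> tuple[ImageVolume, Mask]:
    """Translate and rotate image and mask simultaneously.

    The rotation is about the SI axis (array axis 0) through the mask
    centroid; the translation is ``(t_si, t_ap, t_lm)`` in mm.  The image is
    resampled with cubic B-spline interpolation, the mask with linear
    interpolation followed by a 0.5 threshold (binary-preserving).  The
    output stays on the input grid.
    """
    image.require_same_grid(mask)
    if mask.is_empty:
        raise ValueError("cannot rotate about the centroid of an empty mask")
    spacing = np.asarray(image.spacing)
    centre_vox = np.argwhere(mask.array).mean(axis=0)

    theta = np.deg2rad(angle_deg)
    # rotation in the (AP, LM) plane, axis 0 (SI) fixed
    rot = np.array([
        [1.0, 0.0, 0.0],
        [0.0, np.cos(theta), -np.sin(theta)],
        [0.0, np.sin(theta), np.cos(theta)],
    ])
    shift_vox = np.asarray(t_mm, dtype=float) / spacing

    # world-isotropy: rotate in physical coords when spacing is anisotropic
    scale = np.diag(spacing)
    inv_scale = np.diag(1.0 / spacing)
    m = inv_scale @ rot.T @ scale  # output-voxel -> input-voxel rotation
    offset = centre_vox - m @ (centre_vox + shift_vox)

    out_img = ndimage.affine_transform(
        np.asarray(image.array, dtype=float), m, offset=offset, order=3,
        mode="nearest")
    out_mask = ndimage.affine_transform(
        mask.array.astype(float), m, offset=offset, order=1, mode="constant",
        cval=0.0) > 0.5
    return (ImageVolume(out_img, image.spacing, image.origin),
            Mask(out_mask, mask.spacing, mask.origin))


def add_noise_field(image: ImageVolume, level: int, sigma_base: float = 10.0,
                    seed: int = 0) -> ImageVolume:
    """Add a zero-mean Gaussian noise field with sd = ``level * sigma_base``.

    ``level`` is the integer noise step from the perturbation grid (0 leaves
    the image untouched); ``sigma_base`` is in HU (default 10 HU per step).
    """
    if level < 0:
        raise ValueError("noise level must be non-negative")
    if sigma_base < 0:
        raise ValueError("sigma_base must be non-negative")
    if level == 0:
        return ImageVolume(np.asarray(image.array, dtype=float).copy(),
                           image.spacing, image.origin)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, level * sigma_base, size=image.shape)
    return ImageVolume(np.asarray(image.array, dtype=float) + noise,
                       image.spacing, image.origin)


def dice(a: Mask, b: Mask) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|); two empty masks score 1.0."""
    a.require_same_grid(b)
    na, nb = a.n_voxels, b.n_voxels
    if na + nb == 0:
        return 1.0
    inter = int(np.logical_and(a.array, b.array).sum())
    return 2.0 * inter / (na + nb)


def _surface_coords_mm(mask: Mask) -> np.ndarray:
    """World coordinates of surface voxels (foreground with an exposed face)."""
    eroded = ndimage.binary_erosion(mask.array)
    surface = mask.array & ~eroded
    idx = np.argwhere(surface)
    return idx * np.asarray(mask.spacing) + np.asarray(mask.origin)


def hausdorff(a: Mask, b: Mask) -> float:
    """Symmetric (100th percentile) Hausdorff distance between mask surfaces, mm."""
    a.require_same_grid(b)
    if a.is_empty or b.is_empty:
        raise ValueError("Hausdorff distance of an empty mask is undefined")
    pa, pb = _surface_coords_mm(a), _surface_coords_mm(b)
    d_ab = cKDTree(pb).query(pa)[0].max()
    d_ba = cKDTree(pa).query(pb)[0].max()
    return float(max(d_ab, d_ba))


def _smooth_random_field(shape, smooth_vox, rng) -> np.ndarray:
    """One channel of white noise smoothed by a Gaussian kernel, unit-scaled."""
    f = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(f, smooth_vox)
    sd = f.std()
    return f / sd if sd > 0 else f


def randomize_contour(mask: Mask, contour_seed: int, dice_min: float = 0.75,
                      hd_max_mm: float = 5.0, smooth_mm: float = 5.0,
                      amplitude_mm: float = 2.0,
                      max_attempts: int = 100) -> Mask:
    """Deform the mask with a random smooth vector field, under constraints.

    A 3-channel white-noise field is smoothed with a Gaussian kernel
    (``smooth_mm``), scaled to a mean surface displacement of
    ``amplitude_mm``, and used to warp the mask (linear interpolation, 0.5
    threshold).  Candidates are rejection-sampled until the result satisfies
    ``Dice >= dice_min`` and ``Hausdorff <= hd_max_mm`` against the original;
    generation is deterministic per ``contour_seed``.

    Raises
    ------
    ContourConstraintError
        If no candidate passes within ``max_attempts``, naming the violated
        constraint of the last candidate.
    """
    if mask.is_empty:
        raise ValueError("cannot randomize an empty mask")
    if not 0.0 < dice_min <= 1.0:
        raise ValueError("dice_min must lie in (0, 1]")
    if hd_max_mm <= 0:
        raise ValueError("hd_max_mm must be positive")
    spacing = np.asarray(mask.spacing)
    smooth_vox = smooth_mm / spacing
    if amplitude_mm == 0:
        return Mask(mask.array.copy(), mask.spacing, mask.origin)

    rng = np.random.default_rng(np.random.SeedSequence([contour_seed, 0x5EED]))
    grid = np.indices(mask.shape).astype(float)
    surface = mask.array & ~ndimage.binary_erosion(mask.array)
    last_fail = "no attempt made"
    for _ in range(max_attempts):
        disp_mm = np.stack([_smooth_random_field(mask.shape, smooth_vox, rng)
                            for _ in range(3)])
        mag = np.sqrt((disp_mm ** 2).sum(axis=0))
        mean_surface = mag[surface].mean()
        if mean_surface == 0:
            continue
        disp_mm *= amplitude_mm / mean_surface
        disp_vox = disp_mm / spacing[:, None, None, None]
        coords = grid + disp_vox  # backward warp
        warped = ndimage.map_coordinates(mask.array.astype(float), coords,
                                         order=1, mode="constant", cval=0.0)
        cand = Mask(warped > 0.5, mask.spacing, mask.origin)
        if cand.is_empty:
            last_fail = "warped mask empty"
            continue
        d = dice(mask, cand)
        if d < dice_min:
            last_fail = f"Dice {d:.3f} < {dice_min}"
            continue
        hd = hausdorff(mask, cand)
        if hd > hd_max_mm:
            last_fail = f"Hausdorff {hd:.2f} mm > {hd_max_mm}"
            continue
        return cand
    raise ContourConstraintError(
        f"no contour satisfied the constraints in {max_attempts} attempts "
        f"(last failure: {last_fail})")


def apply_perturbation(image: ImageVolume, mask: Mask, spec: PerturbationSpec,
                       sigma_base: float = 10.0, noise_seed: int = 0,
                       dice_min: float = 0.75, hd_max_mm: float = 5.0,
                       **contour_kwargs) -> tuple[ImageVolume, Mask]:
    """Apply one full perturbation: rigid transform, then noise, then
    contour randomization (constraints checked on the final mask)."""
    img, msk = apply_rigid(image, mask,
                           (spec.t_si, spec.t_ap, spec.t_lm),
                           spec.rotation_deg)
    img = add_noise_field(img, spec.noise_level, sigma_base,
                          seed=noise_seed + spec.contour_seed)
    msk = randomize_contour(msk, spec.contour_seed, dice_min=dice_min,
                            hd_max_mm=hd_max_mm, **contour_kwargs)
    return img, msk
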