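"""Deformable registration of bank images to a target, and warping.

A self-contained multi-resolution demons-style algorithm: at each pyramid
level the displacement field is updated by a metric-gradient force (local
normalized cross-correlation by default, or plain intensity difference),
the update and the running field are Gaussian-smoothed for regularity, and
the final field is accepted only if it improves the similarity metric inside
the mask. Displacements follow the pull-back convention in voxel units —
``warped(x) = moving(x + disp(x))`` — so applying a field is a single
interpolation pass.

This deliberately trades peak accuracy for determinism, zero external
dependencies and speed at phantom scale; an external registration package can
be dropped in behind :func:`register_deformable` without touching any other
module, since downstream fusion consumes only the ``DeformationField``
contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import BinaryMask, LabelVolume, ScalarVolume


@dataclass
class DeformationField:
    """Per-voxel displacement vectors in voxel units (pull-back convention)."""

    disp: np.ndarray  # (X, Y, Z, 3)

    def __post_init__(self):
        self.disp = np.asarray(self.disp, dtype=float)
        if self.disp.ndim != 4 or self.disp.shape[-1] != 3:
            raise ValueError("displacement field must have shape (X, Y, Z, 3)")
        if not np.isfinite(self.disp).all():
            raise ValueError("displacement field contains non-finite values")

    @property
    def shape(self):
        return self.disp.shape[:-1]


@dataclass
class RegistrationConfig:
    levels: int = 3
    iters_per_level: tuple = (80, 40, 20)   # coarse → fine
    step_vox: float = 2.0                    # max update magnitude per iteration
    smooth_update_vox: float = 1.5
    smooth_total_vox: float = 1.5
    metric: str = "LNCC"                     # or "MSE"
    lncc_radius_vox: int = 3

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.metric not in ("LNCC", "MSE"):
            raise ValueError("metric must be LNCC or MSE")
        if self.lncc_radius_vox < 1:
            raise ValueError("lncc_radius_vox must be >= 1")
        if len(self.iters_per_level) < self.levels:
            raise ValueError("need iters_per_level for every level")


def _identity_coords(shape):
    return np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")


def warp(vol, fld, interp="linear"):
    """Resample a volume through a displacement field.

    Trilinear interpolation for intensities, nearest-neighbour for labels;
    samples falling outside the grid take the background value 0.
    """
    disp = fld.disp if isinstance(fld, DeformationField) else np.asarray(fld)
    if vol.shape != disp.shape[:-1]:
        raise ValueError("volume grid does not match field grid")
    is_labels = isinstance(vol, LabelVolume)
    if is_labels and interp == "linear":
        raise ValueError("linear interpolation is invalid for label volumes")
    order = 0 if interp == "nearest" else 1
    idx = _identity_coords(vol.shape)
    coords = [idx[a] + disp[..., a] for a in range(3)]
    out = ndimage.map_coordinates(np.asarray(vol.data, dtype=float), coords,
                                  order=order, mode="constant", cval=0.0)
    if is_labels:
        return LabelVolume(out.astype(np.int16), vol.spacing, vol.affine)
    if isinstance(vol, BinaryMask):
        return BinaryMask(out > 0.5, vol.spacing, vol.affine)
    return vol.like(out)


def jacobian_determinant(disp):
    """det ∂(x + u)/∂x by central differences, per voxel."""
    disp = np.asarray(disp)
    J = np.empty(disp.shape[:-1] + (3, 3))
    for comp in range(3):
        for axis in range(3):
            J[..., comp, axis] = np.gradient(disp[..., comp], axis=axis)
        J[..., comp, comp] += 1.0
    return np.linalg.det(J)


def jacobian_min(fld, mask):
    """Minimum Jacobian determinant of the warp over the mask (QC: > 0 means
    the transform preserves orientation there)."""
    det = jacobian_determinant(fld.disp)
    return float(det[mask.data].min())


def _local_sums(x, radius):
    size = 2 * radius + 1
    return ndimage.uniform_filter(x, size=size, mode="nearest") * size ** 3


def _lncc_force(fixed, warped, radius, eps=1e-5):
    """Gradient of local normalized cross-correlation wrt the warped image.

    Classic windowed-CC derivative: with zero-mean local images I, J and
    window sums A=ΣIJ, B=ΣI², C=ΣJ², d(CC²)/dJ ∝ (2A/(BC))·(I − (A/C)·J).
    """
    size = 2 * radius + 1
    n = size ** 3
    mI = ndimage.uniform_filter(fixed, size, mode="nearest")
    mJ = ndimage.uniform_filter(warped, size, mode="nearest")
    A = ndimage.uniform_filter(fixed * warped, size, mode="nearest") * n - n * mI * mJ
    B = ndimage.uniform_filter(fixed * fixed, size, mode="nearest") * n - n * mI * mI
    C = ndimage.uniform_filter(warped * warped, size, mode="nearest") * n - n * mJ * mJ
    scale = np.mean(B[B > 0]) if (B > 0).any() else 1.0
    denom = B * C + eps * scale ** 2
    I0 = fixed - mI
    J0 = warped - mJ
    return (2.0 * A / denom) * (I0 * C - A * J0)


def _similarity(fixed, warped, mask, config):
    if config.metric == "MSE":
        return -float(np.mean((fixed[mask] - warped[mask]) ** 2))
    r = config.lncc_radius_vox
    size = 2 * r + 1
    mI = ndimage.uniform_filter(fixed, size, mode="nearest")
    mJ = ndimage.uniform_filter(warped, size, mode="nearest")
    A = ndimage.uniform_filter(fixed * warped, size, mode="nearest") - mI * mJ
    B = ndimage.uniform_filter(fixed * fixed, size, mode="nearest") - mI * mI
    C = ndimage.uniform_filter(warped * warped, size, mode="nearest") - mJ * mJ
    cc = A * A / (B * C + 1e-8 * max(float(np.mean(B[mask])), 1e-12) ** 2)
    return float(np.mean(cc[mask]))


def _gradient(img):
    return np.stack(np.gradient(img), axis=-1)


def _downsample(img, factor):
    sm = ndimage.gaussian_filter(img, sigma=factor / 2.0)
    return ndimage.zoom(sm, 1.0 / factor, order=1)


def _upsample_field(disp, target_shape, factor):
    out = np.empty(target_shape + (3,))
    zoom = [t / s for t, s in zip(target_shape, disp.shape[:-1])]
    for a in range(3):
        out[..., a] = ndimage.zoom(disp[..., a], zoom, order=1) * factor
    return out


def register_deformable(moving, fixed, mask, config=None):
    """Estimate the deformation mapping the fixed grid into the moving image.

    Both images must share the grid and a common intensity scale. The returned
    field never degrades the similarity metric inside the mask relative to no
    deformation (monotone acceptance: the best field seen is returned).
    """
    if config is None:
        config = RegistrationConfig()
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed must share grid shape")
    if not mask.data.any():
        raise ValueError("empty mask")
    fx_full = np.asarray(fixed.data, dtype=float)
    mv_full = np.asarray(moving.data, dtype=float)
    norm = max(np.abs(fx_full).max(), np.abs(mv_full).max(), 1e-12)
    fx_full = fx_full / norm
    mv_full = mv_full / norm

    disp = None
    levels = list(range(config.levels - 1, -1, -1))  # coarse → fine
    for li, level in enumerate(levels):
        factor = 2 ** level
        if factor > 1:
            fx = _downsample(fx_full, factor)
            mv = _downsample(mv_full, factor)
            mk = ndimage.zoom(mask.data.astype(float), [a / b for a, b in zip(fx.shape, mask.shape)], order=0) > 0.5
        else:
            fx, mv, mk = fx_full, mv_full, mask.data
        if disp is None:
            disp = np.zeros(fx.shape + (3,))
        else:
            disp = _upsample_field(disp, fx.shape, 2.0)
        vol_mv = ScalarVolume(mv)
        n_iter = config.iters_per_level[config.levels - 1 - level]
        for _ in range(n_iter):
            warped = warp(vol_mv, DeformationField(disp), "linear").data
            if config.metric == "MSE":
                diff = fx - warped
                g = _gradient(warped)
                g2 = (g ** 2).sum(-1)
                denom = g2 + (diff ** 2) + 1e-12
                force = (diff / denom)[..., None] * g
            else:
                dsim = _lncc_force(fx, warped, max(1, config.lncc_radius_vox // (1 if factor == 1 else 2)))
                force = dsim[..., None] * _gradient(warped)
            for a in range(3):
                force[..., a] = ndimage.gaussian_filter(force[..., a],
                                                        config.smooth_update_vox)
            mag = np.sqrt((force ** 2).sum(-1))
            peak = mag.max()
            if peak < 1e-12:
                break
            update = force * (config.step_vox / peak)
            disp = disp + update
            if config.smooth_total_vox > 0:
                for a in range(3):
                    disp[..., a] = ndimage.gaussian_filter(disp[..., a],
                                                           config.smooth_total_vox)
    field = DeformationField(disp)
    # monotone acceptance on the full-resolution mask
    base = _similarity(fx_full, mv_full, mask.data, config)
    final = _similarity(fx_full,
                        warp(ScalarVolume(mv_full), field, "linear").data,
                        mask.data, config)
    if final < base:
        field = DeformationField(np.zeros(mask.shape + (3,)))
    return field
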