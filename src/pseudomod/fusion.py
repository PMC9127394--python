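"""Multi-atlas joint intensity fusion: the registration-based synthesis core.

Pipeline (for one target T1w and a bank of aligned T1w/T2w reference pairs):

1. deformably register every bank T1w to the target T1w and warp both of
   each member's modalities onto the target grid;
2. solve, at every masked voxel, for fusion weights over the bank that best
   reconstruct the *T1w* target from the warped bank T1w patches, accounting
   for correlated atlas errors through a pairwise error-product matrix;
3. apply those weights to the warped bank *T2w* images (a voxelwise convex
   combination);
4. histogram-match the fused image to each bank T2w (unwarped, within its
   own brain mask) and average the matched variants.

The weight solve is joint fusion applied to intensities: at voxel v, each
atlas contributes its best-matching patch (lowest SSD to the target patch
within a small search window); with residual patches e_i, the matrix
M_ij = ⟨|e_i|^β, |e_j|^β⟩ is formed and w ∝ (M + αI)⁻¹·1 is solved, clipped
to nonnegative and renormalized to the simplex.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .registration import RegistrationConfig, register_deformable, warp
from .volume import BinaryMask, LabelVolume, ScalarVolume


@dataclass
class AtlasBank:
    """Ordered reference set of within-subject-aligned image records."""

    members: list  # of AtlasMember

    def __post_init__(self):
        if len(self.members) < 1:
            raise ValueError("bank must have at least one member")
        for m in self.members:
            if not (m.t1w.shape == m.t2w.shape == m.mask.shape):
                raise ValueError("bank member images must share a grid")

    def __len__(self):
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


@dataclass
class AtlasMember:
    t1w: ScalarVolume
    t2w: ScalarVolume
    mask: BinaryMask
    labels: LabelVolume | None = None
    age_weeks: float | None = None


@dataclass
class FusionWeightMap:
    """Per-voxel weights over bank members: a simplex inside the mask, zeros
    outside."""

    weights: np.ndarray  # (X, Y, Z, n)
    mask: BinaryMask

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape[:-1] != self.mask.shape:
            raise ValueError("weight grid does not match mask grid")

    @property
    def n_atlases(self):
        return self.weights.shape[-1]

    def validate(self, atol=1e-6):
        m = self.mask.data
        w = self.weights
        if (w[m] < -atol).any():
            raise ValueError("negative fusion weight inside mask")
        s = w[m].sum(axis=-1)
        if np.abs(s - 1.0).max() > atol:
            raise ValueError("fusion weights do not sum to 1 inside mask")
        if w[~m].any():
            raise ValueError("nonzero fusion weight outside mask")
        return True


@dataclass
class FusionConfig:
    patch_radius_vox: int = 2
    search_radius_vox: int = 2
    beta: float = 2.0
    ridge_alpha: float = 0.1
    n_hist_landmarks: int = 256
    denoise: str = "off"        # or "gaussian" (sigma 0.5 vox)

    def __post_init__(self):
        if self.patch_radius_vox < 0 or self.search_radius_vox < 0:
            raise ValueError("radii must be >= 0")
        if self.beta <= 0 or self.ridge_alpha <= 0:
            raise ValueError("beta and ridge_alpha must be positive")
        if self.denoise not in ("off", "gaussian"):
            raise ValueError("denoise must be 'off' or 'gaussian'")


def _offsets(radius):
    rng = range(-radius, radius + 1)
    offs = list(itertools.product(rng, rng, rng))
    # deterministic tie-breaking: smallest displacement first, then lexicographic
    offs.sort(key=lambda o: (o[0] ** 2 + o[1] ** 2 + o[2] ** 2, o))
    return offs


def _shift(arr, off):
    """arr sampled at x + off, edge-clamped."""
    pad = [(max(-o, 0), max(o, 0)) for o in off]
    padded = np.pad(arr, pad, mode="edge")
    sl = tuple(slice(p0 + o, p0 + o + n)
               for (p0, _), o, n in zip(pad, off, arr.shape))
    return padded[sl]


def _best_offsets(target, atlas, patch_radius, search_radius):
    """Per-voxel search-window offset minimizing patch SSD, for one atlas."""
    size = 2 * patch_radius + 1
    offs = _offsets(search_radius)
    best_ssd = None
    best_idx = None
    for k, off in enumerate(offs):
        d = _shift(atlas, off) - target
        ssd = ndimage.uniform_filter(d * d, size=size, mode="nearest")
        if best_ssd is None:
            best_ssd = ssd.copy()
            best_idx = np.zeros(target.shape, dtype=np.int16)
        else:
            better = ssd < best_ssd  # strict: earlier (smaller) offsets win ties
            best_ssd[better] = ssd[better]
            best_idx[better] = k
    return best_idx, offs


def _gather_patches(img, centers, patch_offs):
    """(n_vox, n_patch) array of img values at centers + each patch offset,
    with indices clipped to the grid (edge clamp)."""
    n_vox = centers.shape[0]
    out = np.empty((n_vox, len(patch_offs)), dtype=np.float32)
    shape = img.shape
    for j, p in enumerate(patch_offs):
        ix = np.clip(centers[:, 0] + p[0], 0, shape[0] - 1)
        iy = np.clip(centers[:, 1] + p[1], 0, shape[1] - 1)
        iz = np.clip(centers[:, 2] + p[2], 0, shape[2] - 1)
        out[:, j] = img[ix, iy, iz]
    return out


def joint_fusion_weights(target_t1, reg_bank_t1, mask, config=None):
    """Solve per-voxel fusion weights from registered bank T1w images.

    Returns a :class:`FusionWeightMap` satisfying the simplex invariant
    inside the mask.
    """
    if config is None:
        config = FusionConfig()
    n = len(reg_bank_t1)
    if n == 0:
        raise ValueError("empty bank")
    tgt = np.asarray(target_t1.data, dtype=np.float32)
    for b in reg_bank_t1:
        if b.shape != tgt.shape:
            raise ValueError("bank image grid does not match target")
    m = mask.data
    centers = np.argwhere(m)
    patch_offs = _offsets(config.patch_radius_vox)
    n_vox = centers.shape[0]

    tgt_patches = _gather_patches(tgt, centers, patch_offs)
    E = np.empty((n, n_vox, len(patch_offs)), dtype=np.float32)
    for i, bank_vol in enumerate(reg_bank_t1):
        atlas = np.asarray(bank_vol.data, dtype=np.float32)
        if config.search_radius_vox > 0:
            idx, offs = _best_offsets(tgt, atlas, config.patch_radius_vox,
                                      config.search_radius_vox)
            off_arr = np.asarray(offs, dtype=np.int64)
            ctr = centers + off_arr[idx[m.nonzero()]]
        else:
            ctr = centers
        patches = _gather_patches(atlas, ctr, patch_offs)
        E[i] = np.abs(patches - tgt_patches)

    U = E ** np.float32(config.beta)          # (n, n_vox, n_patch)
    # normalize to a unit global scale so the ridge is pure conditioning
    # rather than a data-dependent prior toward uniform weights
    u_scale = float(U.mean())
    if u_scale > 0:
        U = U / np.float32(u_scale)
    # M_ij(v) = <U_i(v), U_j(v)>  over the patch axis
    M = np.einsum("ivp,jvp->vij", U, U, optimize=True).astype(np.float64)
    M += config.ridge_alpha * np.eye(n)
    ones = np.ones((n_vox, n, 1))
    w = np.linalg.solve(M, ones)[..., 0]
    w = np.clip(w, 0.0, None)
    s = w.sum(axis=1, keepdims=True)
    flat = s[:, 0] <= 0
    if flat.any():
        w[flat] = 1.0 / n
        s[flat] = 1.0
    w = w / s
    weights = np.zeros(tgt.shape + (n,), dtype=float)
    weights[m] = w
    return FusionWeightMap(weights, mask)


def apply_weights(weight_map, reg_bank_t2):
    """Voxelwise convex combination of the registered bank T2w images."""
    n = weight_map.n_atlases
    if len(reg_bank_t2) != n:
        raise ValueError("weight vector length does not match bank size")
    shape = weight_map.mask.shape
    out = np.zeros(shape)
    for i, vol in enumerate(reg_bank_t2):
        if vol.shape != shape:
            raise ValueError("bank image grid does not match weights")
        out += weight_map.weights[..., i] * np.asarray(vol.data, dtype=float)
    out[~weight_map.mask.data] = 0.0
    ref = reg_bank_t2[0]
    return ScalarVolume(out, ref.spacing, ref.affine, "pseudoT2w")


def histogram_match(source, reference, mask, n_landmarks=256, ref_mask=None):
    """Monotone quantile-landmark intensity mapping within the mask.

    Maps ``n_landmarks`` equally spaced within-mask quantiles of the source
    onto the corresponding quantiles of the reference, with piecewise-linear
    interpolation between landmarks. Voxels outside the mask are untouched.
    Reference quantiles are taken within ``ref_mask`` when given (so an
    unwarped reference can contribute its native intensity distribution),
    otherwise within ``mask``.
    """
    m = mask.data
    src = np.asarray(source.data, dtype=float)
    ref = np.asarray(reference.data, dtype=float)
    rm = mask.data if ref_mask is None else ref_mask.data
    s_vals, r_vals = src[m], ref[rm]
    if s_vals.max() <= s_vals.min() or r_vals.max() <= r_vals.min():
        raise ValueError("degenerate intensity range within mask")
    q = np.linspace(0.0, 100.0, n_landmarks)
    s_land = np.percentile(s_vals, q)
    r_land = np.percentile(r_vals, q)
    # enforce strictly nondecreasing landmark table (monotone map)
    s_land = np.maximum.accumulate(s_land)
    r_land = np.maximum.accumulate(r_land)
    out = src.copy()
    out[m] = np.interp(src[m], s_land, r_land)
    return source.like(out)


def synthesize_multiatlas_t2w(target_t1, target_mask, bank, reg_config=None,
                          fusion_config=None, return_intermediates=False):
    """End-to-end multi-atlas pseudo-T2w synthesis.

    Registers each bank T1w to the target T1w, warps both modalities, solves
    fusion weights on the warped T1w images, applies them to the warped T2w
    images, optionally denoises, histogram-matches the fused image to every
    bank T2w (native images, each within its own brain mask, so warp-induced
    background never contaminates the reference distribution) and averages
    the matched variants. Output is brain-masked.
    """
    if reg_config is None:
        reg_config = RegistrationConfig()
    if fusion_config is None:
        fusion_config = FusionConfig()
    if len(bank) == 0:
        raise ValueError("empty bank")
    warped_t1, warped_t2 = [], []
    for member in bank:
        fld = register_deformable(member.t1w, target_t1, target_mask, reg_config)
        warped_t1.append(warp(member.t1w, fld, "linear"))
        warped_t2.append(warp(member.t2w, fld, "linear"))
    wmap = joint_fusion_weights(target_t1, warped_t1, target_mask, fusion_config)
    wmap.validate()
    fused = apply_weights(wmap, warped_t2)
    if fusion_config.denoise == "gaussian":
        sm = ndimage.gaussian_filter(fused.data, 0.5)
        fused = fused.like(np.where(target_mask.data, sm, 0.0))
    variants = [histogram_match(fused, member.t2w, target_mask,
                                fusion_config.n_hist_landmarks,
                                ref_mask=member.mask)
                for member in bank]
    mean = np.mean([v.data for v in variants], axis=0)
    mean[~target_mask.data] = 0.0
    result = ScalarVolume(mean, target_t1.spacing, target_t1.affine, "pseudoT2w")
    if return_intermediates:
        return result, {"weights": wmap, "warped_t1": warped_t1,
                        "warped_t2": warped_t2, "fused": fused}
    return result
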