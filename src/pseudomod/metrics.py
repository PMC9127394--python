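"""Structural evaluation battery for synthesized images.

Relative MAE, mean SSIM, DICE overlap, gray/white contrast-to-noise ratio
(with the erosion-based ROI construction that minimizes partial-volume
voxels), and joint-histogram mutual information. All intensity metrics assume
both images were brought to a common scale (0–2000 by convention) and are
restricted to the brain mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
import warnings

import numpy as np
from scipy import ndimage

from .volume import GM, WM, BinaryMask, ScalarVolume

#: 6-connected (face-adjacent) structuring element used for all erosions
STRUCT_6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class MetricReport:
    """Named scalar results plus the parameters they were computed with."""

    values: dict = dc_field(default_factory=dict)
    params: dict = dc_field(default_factory=dict)

    def __getitem__(self, key):
        return self.values[key]


def _check(a, b, mask):
    if a.shape != b.shape or (mask is not None and a.shape != mask.shape):
        raise ValueError("image/mask grids do not match")


def error_map(a, b, mask):
    """Voxelwise absolute intensity difference |a − b| inside the mask."""
    _check(a, b, mask)
    out = np.abs(np.asarray(a.data, float) - np.asarray(b.data, float))
    out[~mask.data] = 0.0
    return ScalarVolume(out, a.spacing, a.affine, "other")


def mae_relative(a, b, mask, scale=2000.0):
    """Mean absolute error within the mask as a percentage of the working
    intensity scale."""
    _check(a, b, mask)
    if not mask.data.any():
        raise ValueError("empty mask")
    m = mask.data
    err = np.abs(np.asarray(a.data, float)[m] - np.asarray(b.data, float)[m])
    return float(err.mean() / scale * 100.0)


def _ssim_interior(mask, radius):
    """Voxels whose (cubic) SSIM window lies fully inside the mask."""
    struct = np.ones((2 * radius + 1,) * 3, dtype=bool)
    return ndimage.binary_erosion(mask, structure=struct)


def gaussian_window_radius(sigma, truncate=3.5):
    return int(truncate * sigma + 0.5)


def mssim(a, b, mask, window_sigma=1.5, k1=0.01, k2=0.03, dynamic_range=2000.0):
    """Mean structural similarity index over the mask interior.

    Local means/variances/covariance use a Gaussian window (σ =
    ``window_sigma``, truncated at 3.5σ); the SSIM map is averaged over voxels
    whose window lies entirely inside the mask, so background voxels never
    inflate the score.
    """
    _check(a, b, mask)
    x = np.asarray(a.data, float)
    y = np.asarray(b.data, float)
    radius = gaussian_window_radius(window_sigma)
    interior = _ssim_interior(mask.data, radius)
    if not interior.any():
        raise ValueError("mask too thin: no window fits fully inside")
    flt = lambda v: ndimage.gaussian_filter(v, window_sigma, truncate=3.5)
    mu_x, mu_y = flt(x), flt(y)
    xx, yy, xy = flt(x * x), flt(y * y), flt(x * y)
    var_x = xx - mu_x * mu_x
    var_y = yy - mu_y * mu_y
    cov = xy - mu_x * mu_y
    c1 = (k1 * dynamic_range) ** 2
    c2 = (k2 * dynamic_range) ** 2
    ssim_map = ((2 * mu_x * mu_y + c1) * (2 * cov + c2)) / \
               ((mu_x ** 2 + mu_y ** 2 + c1) * (var_x + var_y + c2))
    return float(ssim_map[interior].mean())


def dice(mask_a, mask_b):
    """DICE overlap 2|A∩B| / (|A| + |B|); two empty masks count as identical."""
    a = mask_a.data if isinstance(mask_a, BinaryMask) else np.asarray(mask_a, bool)
    b = mask_b.data if isinstance(mask_b, BinaryMask) else np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise ValueError("mask grids do not match")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def build_cnr_rois(labels):
    """Partial-volume-minimizing GM and WM ROIs for CNR.

    GM: erode the GM segmentation by 1 and by 2 voxels and keep their
    difference — a one-voxel-thick sheet strictly inside GM. WM: erode the WM
    segmentation by 5 voxels. Erosion is 6-connected, applied iteratively.
    """
    gm = labels.data == GM
    wm = labels.data == WM
    if not gm.any() or not wm.any():
        raise ValueError("labels must contain both GM and WM")
    gm1 = ndimage.binary_erosion(gm, STRUCT_6, iterations=1)
    gm2 = ndimage.binary_erosion(gm, STRUCT_6, iterations=2)
    gm_roi = gm1 & ~gm2
    wm_roi = ndimage.binary_erosion(wm, STRUCT_6, iterations=5)
    if not gm_roi.any() or not wm_roi.any():
        raise ValueError("ROI vanished; segmentation too thin for the "
                         "erosion-based ROI recipe")
    sp, af = labels.spacing, labels.affine
    return BinaryMask(gm_roi, sp, af), BinaryMask(wm_roi, sp, af)


def cnr(vol, gm_roi, wm_roi):
    """Gray/white contrast-to-noise ratio.

    CNR = |μ(GM) − μ(WM)| / sqrt((σ(GM)² + σ(WM)²) / 2) with population
    (divide-by-N) standard deviations. Invariant to common affine intensity
    rescaling.
    """
    g = np.asarray(vol.data, float)[gm_roi.data]
    w = np.asarray(vol.data, float)[wm_roi.data]
    if g.size == 0 or w.size == 0:
        raise ValueError("empty ROI")
    sg, sw = g.std(), w.std()  # population SD
    if sg == 0 and sw == 0:
        raise ValueError("zero variance in both ROIs; CNR undefined")
    return float(abs(g.mean() - w.mean()) / np.sqrt((sg ** 2 + sw ** 2) / 2.0))


def mutual_information(a, b, mask, bins=64):
    """Plug-in mutual information (nats) from the within-mask joint histogram.

    Equal-width bins over each image's within-mask range. Returns 0 with a
    warning if either image is constant inside the mask.
    """
    _check(a, b, mask)
    m = mask.data
    if not m.any():
        raise ValueError("empty mask")
    x = np.asarray(a.data, float)[m]
    y = np.asarray(b.data, float)[m]
    if x.max() == x.min() or y.max() == y.min():
        warnings.warn("constant image within mask: MI is 0", stacklevel=2)
        return 0.0
    joint, _, _ = np.histogram2d(x, y, bins=bins,
                                 range=[[x.min(), x.max()], [y.min(), y.max()]])
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    mi = float((p[nz] * np.log(p[nz] / (px @ py)[nz])).sum())
    return max(mi, 0.0)


def evaluate_pair(a, b, mask, labels=None, scale=2000.0):
    """All applicable metrics for one image pair, as a MetricReport."""
    values = {
        "mae_rel_pct": mae_relative(a, b, mask, scale),
        "mssim": mssim(a, b, mask, dynamic_range=scale),
        "mi_nats": mutual_information(a, b, mask),
    }
    params = {"scale": scale, "mi_bins": 64, "ssim_window_sigma": 1.5}
    if labels is not None:
        gm_roi, wm_roi = build_cnr_rois(labels)
        values["cnr_a"] = cnr(a, gm_roi, wm_roi)
        values["cnr_b"] = cnr(b, gm_roi, wm_roi)
    return MetricReport(values, params)
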