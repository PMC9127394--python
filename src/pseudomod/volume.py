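"""Volumetric data model, NIfTI I/O, intensity normalization, bias correction.

All images in this package are carried as :class:`ScalarVolume` — a 3D scalar
grid plus voxel spacing and a voxel→world affine. Geometry is handled in voxel
units throughout; the affine is carried along and only matters at the I/O
boundary, since the synthesis pipeline operates on rigidly pre-aligned,
same-grid images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

log = logging.getLogger(__name__)

MODALITIES = ("T1w", "T2w", "pseudoT2w", "labels", "other")

#: label coding for tissue volumes
BACKGROUND, CSF, GM, WM = 0, 1, 2, 3
LABEL_CODING = (BACKGROUND, CSF, GM, WM)


@dataclass
class ScalarVolume:
    """A 3D intensity image with geometry metadata.

    Parameters
    ----------
    data : ndarray, shape (X, Y, Z)
        Voxel intensities (arbitrary units).
    spacing : tuple of 3 floats
        Voxel edge lengths in mm.
    affine : ndarray, shape (4, 4)
        Voxel-index → world-mm map (NIfTI convention).
    modality : str
        One of ``T1w, T2w, pseudoT2w, labels, other``.
    """

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    modality: str = "other"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        if any(s < 1 for s in self.data.shape):
            raise ValueError("all dimensions must be >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be 3 positive components")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def shape(self):
        return self.data.shape

    def like(self, data, modality=None):
        """New volume sharing this volume's geometry."""
        return replace(self, data=data,
                       modality=self.modality if modality is None else modality)


@dataclass
class BinaryMask:
    """Boolean region-of-interest on the same grid as its paired volume."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self):
        return self.data.shape

    @property
    def n_voxels(self):
        return int(self.data.sum())


@dataclass
class LabelVolume:
    """Integer tissue-label grid: 0=background, 1=CSF, 2=GM, 3=WM."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    coding: tuple = LABEL_CODING

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D label volume, got {self.data.ndim}D")
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded):
                raise ValueError("label volume has non-integer values")
            self.data = rounded.astype(np.int16)
        extra = set(np.unique(self.data)) - set(self.coding)
        if extra:
            raise ValueError(f"labels outside declared coding: {sorted(extra)}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self):
        return self.data.shape

    def mask_of(self, label):
        """Binary mask of one tissue class."""
        return BinaryMask(self.data == label, self.spacing, self.affine)


def read_volume(path, kind="scalar", modality="other"):
    """Read a NIfTI-1 file as a ScalarVolume (or LabelVolume with kind='labels').

    Non-finite voxels are replaced with 0 (logged): a defensive default for
    real scanner exports.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path}")
    data = np.asarray(data, dtype=np.int16 if kind == "labels" else np.float64)
    bad = ~np.isfinite(data)
    if bad.any():
        log.warning("%s: %d non-finite voxels replaced with 0", path, bad.sum())
        data = np.where(bad, 0, data)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    affine = np.asarray(img.affine, dtype=float)
    if kind == "labels":
        return LabelVolume(data, spacing, affine)
    if kind == "mask":
        return BinaryMask(data > 0.5, spacing, affine)
    return ScalarVolume(data, spacing, affine, modality)


def write_volume(vol, path):
    """Write a ScalarVolume / LabelVolume / BinaryMask as NIfTI-1.

    Scalar data is stored float32; labels and masks as integers (exact).
    """
    if isinstance(vol, BinaryMask):
        data = vol.data.astype(np.uint8)
    elif isinstance(vol, LabelVolume):
        data = vol.data.astype(np.int16)
    else:
        data = np.asarray(vol.data, dtype=np.float32)
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def rescale_to_range(vol, mask, lo=0.0, hi=2000.0):
    """Normalize within-mask intensities onto a common scale.

    The robust within-mask range (0.5th–99.5th percentile) is mapped affinely
    onto ``[lo, hi]`` and the result clipped; voxels outside the mask are set
    to 0. Robust bounds keep single hot voxels from compressing tissue
    contrast. Percentiles are order statistics (outer-rounded), which makes
    the operation exactly idempotent: the clipped tails re-produce the same
    bounds on a second application.
    """
    m = mask.data
    if not m.any():
        raise ValueError("empty mask")
    vals = vol.data[m]
    p_lo = np.percentile(vals, 0.5, method="lower")
    p_hi = np.percentile(vals, 99.5, method="higher")
    if p_hi <= p_lo:
        raise ValueError("degenerate intensity range within mask")
    out = (vol.data - p_lo) * ((hi - lo) / (p_hi - p_lo)) + lo
    out = np.clip(out, lo, hi)
    out = np.where(m, out, 0.0)
    return vol.like(out)


def _kmeans_1d(x, k, n_iter=20):
    """Deterministic 1D Lloyd clustering, quantile-initialized."""
    centers = np.percentile(x, np.linspace(100.0 / (2 * k), 100 - 100.0 / (2 * k), k))
    for _ in range(n_iter):
        assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        new = np.array([x[assign == c].mean() if (assign == c).any() else centers[c]
                        for c in range(k)])
        if np.allclose(new, centers):
            break
        centers = new
    return assign, centers


def correct_bias(vol, mask, degree=3, n_classes=3, n_iter=5):
    """Remove smooth multiplicative inhomogeneity from an MR volume.

    Models within-mask log-intensity as (piecewise tissue level) + (smooth
    polynomial log-bias of total degree <= ``degree``) and divides out the
    polynomial part, preserving the within-mask mean. The tissue levels are
    estimated by deterministic 1D k-means (``n_classes`` clusters) and
    alternated with the polynomial fit: without them a plain least-squares fit
    absorbs anatomy (e.g. the radial CSF/GM/WM layout) into the "bias" and
    *adds* inhomogeneity. A lightweight stand-in for dedicated bias-field
    correctors — the synthesis pipeline only requires low-frequency
    inhomogeneity to be gone before fusion weights are computed.
    """
    m = mask.data
    exps = [(i, j, k) for i in range(degree + 1) for j in range(degree + 1)
            for k in range(degree + 1) if i + j + k <= degree]
    if m.sum() < len(exps):
        raise ValueError("mask smaller than number of polynomial coefficients")
    vals = vol.data[m]
    shift = (1e-6 * max(1.0, vals.max()) - vals.min()) if vals.min() <= 0 else 0.0
    logv = np.log(vals + shift)
    # coordinates normalized to [-1, 1] for conditioning
    coords = [2.0 * np.arange(n) / max(n - 1, 1) - 1.0 for n in vol.shape]
    xs = np.meshgrid(*coords, indexing="ij")
    A = np.stack([xs[0][m] ** i * xs[1][m] ** j * xs[2][m] ** k
                  for i, j, k in exps], axis=1)
    pinv = np.linalg.pinv(A)
    fit_m = np.zeros(logv.shape)
    coef = np.zeros(len(exps))
    for _ in range(n_iter):
        assign, centers = _kmeans_1d(logv - fit_m, n_classes)
        resid = logv - centers[assign]
        coef = pinv @ resid
        fit_m = A @ coef
    fit = np.zeros(vol.shape)
    for c, (i, j, k) in zip(coef, exps):
        fit += c * xs[0] ** i * xs[1] ** j * xs[2] ** k
    fit -= fit[m].mean()  # zero-mean log bias so overall level is untouched
    out = vol.data / np.exp(fit)
    out = out * (vals.mean() / out[m].mean())  # exact mean preservation
    return vol.like(np.where(m | (vol.data != 0), out, 0.0))
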