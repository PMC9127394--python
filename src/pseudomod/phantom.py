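"""Synthetic neonatal-brain phantom.

Generates paired, voxel-aligned T1w/T2w volumes with tissue labels and brain
masks, plus "bank" subjects derived from a common base anatomy by smooth
random deformations. Two facts of neonatal MR contrast are built in as hard
invariants of every rendered pair:

* gray–white contrast is *inverted* between T1w and T2w (the sign of the
  GM−WM mean difference flips), and
* the T2w gray–white contrast magnitude is at least as large as the T1w one.

Everything is a pure function of ``(spec, seed)``: the same inputs give
bit-identical volumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume import (BACKGROUND, CSF, GM, WM, BinaryMask, LabelVolume,
                     ScalarVolume, write_volume)


@dataclass
class PhantomSpec:
    """Parameters of the synthetic anatomy and its rendering.

    Tissue means live on the 0–2000 working scale. Defaults encode the
    contrast inversion (T1w: GM 1000 > WM 700; T2w: GM 700 < WM 1200) and the
    larger T2w contrast magnitude (500 vs 300).
    """

    grid_shape: tuple = (48, 56, 48)
    tissue_means_t1w: dict = field(default_factory=lambda: {CSF: 400.0, GM: 1000.0, WM: 700.0})
    tissue_means_t2w: dict = field(default_factory=lambda: {CSF: 1800.0, GM: 700.0, WM: 1200.0})
    tissue_sd: dict = field(default_factory=lambda: {CSF: 120.0, GM: 100.0, WM: 90.0})
    bias_amplitude: float = 0.1      # peak log-bias of the multiplicative field
    noise_sd: float = 40.0           # additive scanner noise
    deform_sd_vox: float = 2.5       # displacement SD of bank deformations
    deform_smooth_vox: float = 5.0   # Gaussian smoothing of the random field
    lumpiness: float = 0.06          # radial perturbation of the base shapes
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        d1 = self.tissue_means_t1w[GM] - self.tissue_means_t1w[WM]
        d2 = self.tissue_means_t2w[GM] - self.tissue_means_t2w[WM]
        if np.sign(d1) == np.sign(d2):
            raise ValueError("GM-WM contrast must invert between T1w and T2w")
        if abs(d2) < abs(d1):
            raise ValueError("T2w GM-WM contrast must be >= T1w contrast")
        if self.bias_amplitude < 0 or self.noise_sd < 0 or self.deform_sd_vox < 0:
            raise ValueError("amplitudes must be nonnegative")
        if self.deform_smooth_vox <= 0:
            raise ValueError("deform_smooth_vox must be positive")


@dataclass
class PhantomSubject:
    """One synthetic subject: aligned T1w/T2w, labels, mask, and (for bank
    members) the ground-truth deformation that produced it."""

    t1w: ScalarVolume
    t2w: ScalarVolume
    labels: LabelVolume
    mask: BinaryMask
    true_field: np.ndarray | None = None  # (X,Y,Z,3) voxel displacements


def _smooth_noise(shape, sigma, rng):
    """Unit-variance smooth random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


def make_base_labels(spec):
    """Concentric smooth tissue shapes: CSF shell, GM ribbon, WM core.

    A single smooth 'radius-like' scalar field is thresholded at three nested
    levels, so WM ⊂ GM-shell ⊂ CSF-shell nesting holds by construction; seeded
    lumpiness makes the shapes non-spherical.
    """
    shape = spec.grid_shape
    if min(shape) < 16:
        raise ValueError("grid_shape too small: need >= 16 in every dimension")
    rng = np.random.default_rng(spec.seed)
    coords = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    center = [(n - 1) / 2.0 for n in shape]
    # normalized ellipsoidal radius, ~1 at the grid face
    r = np.sqrt(sum(((c - mu) / (0.5 * n)) ** 2
                    for c, mu, n in zip(coords, center, shape)))
    r = r + spec.lumpiness * _smooth_noise(shape, min(shape) / 8.0, rng)
    data = np.full(shape, BACKGROUND, dtype=np.int16)
    data[r < 0.82] = CSF
    data[r < 0.68] = GM
    data[r < 0.46] = WM
    labels = LabelVolume(data)
    mask = BinaryMask(data != BACKGROUND)
    return labels, mask


def render_modality(labels, spec, modality, seed):
    """Render an intensity image from tissue labels.

    intensity = tissue mean + N(0, tissue_sd), times a smooth multiplicative
    bias exp(B) with peak |B| = bias_amplitude, plus N(0, noise_sd); clipped
    at 0.
    """
    if modality == "T1w":
        means = spec.tissue_means_t1w
    elif modality == "T2w":
        means = spec.tissue_means_t2w
    else:
        raise ValueError(f"unknown modality {modality!r}")
    rng = np.random.default_rng(seed)
    data = np.zeros(labels.shape)
    for lab, mu in means.items():
        data[labels.data == lab] = mu
    for lab, sd in spec.tissue_sd.items():
        if sd > 0:
            sel = labels.data == lab
            data[sel] += sd * rng.standard_normal(int(sel.sum()))
    if spec.bias_amplitude > 0:
        b = _smooth_noise(labels.shape, min(labels.shape) / 6.0, rng)
        b *= spec.bias_amplitude / max(np.abs(b).max(), 1e-12)
        data *= np.exp(b)
    if spec.noise_sd > 0:
        data += spec.noise_sd * rng.standard_normal(labels.shape)
    data[labels.data == BACKGROUND] = 0.0
    data = np.clip(data, 0.0, None)
    return ScalarVolume(data, modality=modality)


def _random_displacement(shape, spec, rng):
    """Smooth random displacement with min Jacobian determinant > 0.2.

    The field is rescaled (halved) until the warp x ↦ x + u(x) is safely
    orientation-preserving; raises if even a strongly shrunk field fails.
    """
    from .registration import jacobian_determinant

    if spec.deform_sd_vox == 0:
        return np.zeros(shape + (3,))
    u = np.stack([_smooth_noise(shape, spec.deform_smooth_vox, rng)
                  for _ in range(3)], axis=-1)
    u *= spec.deform_sd_vox
    for _ in range(24):
        det = jacobian_determinant(u)
        if det.min() > 0.2:
            return u
        u = u * 0.8
    raise ValueError("deform_sd_vox too large: warp folds even after shrinking; "
                     "reduce deform_sd_vox or increase deform_smooth_vox")


def _warp_labels_nn(data, disp):
    from scipy.ndimage import map_coordinates

    shape = data.shape
    idx = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    coords = [idx[a] + disp[..., a] for a in range(3)]
    return map_coordinates(data.astype(float), coords, order=0,
                           mode="constant", cval=BACKGROUND).astype(np.int16)


def _make_subject(base_labels, spec, rng, deform):
    disp = _random_displacement(spec.grid_shape, spec, rng) if deform \
        else np.zeros(spec.grid_shape + (3,))
    warped = _warp_labels_nn(base_labels.data, disp)
    labels = LabelVolume(warped)
    mask = BinaryMask(warped != BACKGROUND)
    s1 = int(rng.integers(0, 2 ** 31 - 1))
    s2 = int(rng.integers(0, 2 ** 31 - 1))
    t1w = render_modality(labels, spec, "T1w", s1)
    t2w = render_modality(labels, spec, "T2w", s2)
    return PhantomSubject(t1w, t2w, labels, mask, disp)


def make_bank(spec, n, seed):
    """Generate n bank subjects, each an independently deformed rendering of
    the base anatomy (mirrors an age-matched reference bank)."""
    if n < 1:
        raise ValueError("bank size must be >= 1")
    base_labels, _ = make_base_labels(spec)
    rng = np.random.default_rng(seed)
    return [_make_subject(base_labels, spec, rng, deform=spec.deform_sd_vox > 0)
            for _ in range(n)]


def make_target(spec, seed):
    """One held-out subject; its t2w is the synthesis ground truth."""
    base_labels, _ = make_base_labels(spec)
    rng = np.random.default_rng(seed)
    return _make_subject(base_labels, spec, rng, deform=spec.deform_sd_vox > 0)


def write_phantom_dataset(spec, n_bank, seed, out_dir):
    """Write a bank + target to NIfTI files with a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bank = make_bank(spec, n_bank, seed)
    target = make_target(spec, seed + 1)
    manifest = {"spec": {**asdict(spec),
                         "tissue_means_t1w": {int(k): v for k, v in spec.tissue_means_t1w.items()},
                         "tissue_means_t2w": {int(k): v for k, v in spec.tissue_means_t2w.items()},
                         "tissue_sd": {int(k): v for k, v in spec.tissue_sd.items()}},
                "bank": [], "target": {}}

    def _dump(subj, stem):
        rec = {}
        for key, obj in (("t1w", subj.t1w), ("t2w", subj.t2w),
                         ("labels", subj.labels), ("mask", subj.mask)):
            p = out / f"{stem}_{key}.nii.gz"
            write_volume(obj, p)
            rec[key] = p.name
        return rec

    for i, subj in enumerate(bank):
        manifest["bank"].append(_dump(subj, f"bank{i:02d}"))
    manifest["target"] = _dump(target, "target")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out / "manifest.json"
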