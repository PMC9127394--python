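"""Functional-connectivity comparison stage.

Parcel-level Pearson FC matrices from BOLD timeseries tables, similarity of
group-average connectomes, and paired-t-test difference maps with a
Bonferroni-corrected threshold over parcel pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ParcelTimeseries:
    """T timepoints × P parcels of (preprocessed) BOLD signal."""

    data: np.ndarray           # (T, P)
    tr_seconds: float
    parcel_ids: list = None
    networks: list = None      # optional network assignment per parcel

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("timeseries must be 2D (time × parcels)")
        if self.data.shape[0] < 3:
            raise ValueError("need at least 3 timepoints")
        if not np.isfinite(self.data).all():
            raise ValueError("timeseries contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("TR must be positive")
        if self.parcel_ids is None:
            self.parcel_ids = [f"p{i:03d}" for i in range(self.data.shape[1])]
        if len(self.parcel_ids) != self.data.shape[1]:
            raise ValueError("parcel_ids length mismatch")

    @property
    def n_frames(self):
        return self.data.shape[0]

    @property
    def n_parcels(self):
        return self.data.shape[1]

    @property
    def duration_minutes(self):
        """Run length in minutes (frames × TR / 60); e.g. 420 frames at
        TR = 0.8 s is a 5.6-minute run."""
        return self.n_frames * self.tr_seconds / 60.0

    @classmethod
    def from_tsv(cls, path, tr_seconds):
        df = pd.read_csv(path, sep="\t")
        return cls(df.to_numpy(float), tr_seconds, list(df.columns))


@dataclass
class FCMatrix:
    """Symmetric parcel × parcel Pearson correlation matrix, unit diagonal."""

    data: np.ndarray
    parcel_ids: list = None
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        p = self.data.shape[0]
        if self.data.ndim != 2 or self.data.shape != (p, p):
            raise ValueError("FC matrix must be square")
        if not np.allclose(self.data, self.data.T, atol=1e-10):
            raise ValueError("FC matrix must be symmetric")
        if not np.allclose(np.diag(self.data), 1.0, atol=1e-10):
            raise ValueError("FC matrix must have unit diagonal")
        if np.abs(self.data).max() > 1.0 + 1e-10:
            raise ValueError("correlations must lie in [-1, 1]")
        if self.parcel_ids is None:
            self.parcel_ids = [f"p{i:03d}" for i in range(p)]

    @property
    def n_parcels(self):
        return self.data.shape[0]

    def upper_triangle(self):
        iu = np.triu_indices(self.n_parcels, k=1)
        return self.data[iu]

    def to_csv(self, path):
        pd.DataFrame(self.data, index=self.parcel_ids,
                     columns=self.parcel_ids).to_csv(path)


@dataclass
class DiffTestResult:
    p_values: np.ndarray       # symmetric off-diagonal p matrix (diag = 1)
    threshold: float
    percent_significant: float
    parcel_ids: list = None


def fc_matrix(ts):
    """Pairwise Pearson correlation of parcel timeseries; diagonal forced
    to exactly 1."""
    span = ts.data.max(axis=0) - ts.data.min(axis=0)  # exact for constants
    dead = np.flatnonzero(span == 0)
    if dead.size:
        names = [ts.parcel_ids[i] for i in dead[:5]]
        raise ValueError(f"zero-variance parcel(s): {names}")
    c = np.corrcoef(ts.data, rowvar=False)
    np.fill_diagonal(c, 1.0)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    return FCMatrix(c, list(ts.parcel_ids))


def dconn_similarity(avg_a, avg_b):
    """Pearson r between the vectorized strict upper triangles of two
    (average) connectivity matrices."""
    if avg_a.n_parcels != avg_b.n_parcels:
        raise ValueError("parcel sets do not match")
    x, y = avg_a.upper_triangle(), avg_b.upper_triangle()
    return float(np.corrcoef(x, y)[0, 1])


def group_mean_var(mats):
    """Elementwise mean and sample (n−1) variance across subjects."""
    if len(mats) < 2:
        raise ValueError("need at least 2 subjects for a variance")
    p = mats[0].n_parcels
    if any(m.n_parcels != p for m in mats):
        raise ValueError("parcel sets do not match")
    stack = np.stack([m.data for m in mats])
    mean = stack.mean(axis=0)
    np.fill_diagonal(mean, 1.0)
    var = stack.var(axis=0, ddof=1)
    return FCMatrix(mean, list(mats[0].parcel_ids)), var


def bonferroni_threshold(n_parc, alpha=0.05):
    """Family-wise corrected per-test threshold alpha / n_parc (for the
    paper-scale 333-parcel scheme at alpha 0.05 this is ~0.00015)."""
    if n_parc < 1:
        raise ValueError("n_parc must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / n_parc


def paired_difference_test(mats_a, mats_b, alpha=0.05, fisher_z=False):
    """Two-sided paired t-test per unique parcel pair, Bonferroni-thresholded.

    The threshold divides alpha by the number of tests actually performed —
    the unique off-diagonal pairs — which is what controls the family-wise
    error of the pair family. (Dividing by the parcel count instead, as is
    sometimes done for parcel-level summaries, is anti-conservative by a
    factor of (P−1)/2 here.) Pairs with identically zero differences across
    subjects get p = 1, so identical input groups yield exactly zero
    detections. The reported percent significant uses unique off-diagonal
    pairs as the denominator.
    """
    if len(mats_a) != len(mats_b):
        raise ValueError("subject counts do not match")
    n = len(mats_a)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    p_parc = mats_a[0].n_parcels
    iu = np.triu_indices(p_parc, k=1)
    A = np.stack([m.data[iu] for m in mats_a])   # (n, n_pairs)
    B = np.stack([m.data[iu] for m in mats_b])
    if fisher_z:
        A, B = np.arctanh(np.clip(A, -1 + 1e-12, 1 - 1e-12)), \
               np.arctanh(np.clip(B, -1 + 1e-12, 1 - 1e-12))
    d = A - B
    sd = d.std(axis=0, ddof=1)
    pvals = np.ones(d.shape[1])
    ok = sd > 0
    if ok.any():
        t = d[:, ok].mean(axis=0) / (sd[ok] / np.sqrt(n))
        pvals[ok] = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    thr = bonferroni_threshold(pvals.size, alpha)
    n_sig = int((pvals < thr).sum())
    pct = 100.0 * n_sig / pvals.size
    pmat = np.ones((p_parc, p_parc))
    pmat[iu] = pvals
    pmat[(iu[1], iu[0])] = pvals
    return DiffTestResult(pmat, thr, pct, list(mats_a[0].parcel_ids))
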