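# Methods

`pseudomod` synthesizes a missing T2-weighted MR volume from a subject's
T1-weighted volume, targeting the neonatal setting where gray–white tissue
contrast is inverted relative to adults and where T2w contrast is the
stronger of the two. Two independent synthesis routes are implemented, with
the structural and functional evaluation battery used to compare them, and a
synthetic phantom that makes the whole pipeline testable end-to-end without
any data download.

## Multi-atlas joint-fusion synthesis (registration-based route)

Given a target T1w image and a bank of reference subjects with
within-subject-aligned T1w/T2w pairs, the pipeline is:

1. **Deformable registration.** Each bank T1w is registered to the target
   T1w; the estimated deformation is applied to that member's T1w and T2w.
   Registration is a multi-resolution demons-style iteration: at each pyramid
   level the displacement field `u` is updated by a metric-gradient force,
   the update and running field are Gaussian-smoothed, and the final field is
   accepted only if it does not degrade the similarity metric inside the
   brain mask. Displacements are pull-back, in voxel units:
   `warped(x) = moving(x + u(x))`.
   The default metric is local normalized cross-correlation (LNCC, radius 3
   voxels), whose windowed-CC derivative drives the force; a plain
   intensity-difference (MSE/demons) force is available. Defaults
   (3 levels, 80/40/20 iterations, update/total smoothing 1.5/1.5 voxels,
   step cap 2 voxels) were chosen so that on the phantom a known 3-voxel
   translation is recovered to < 0.5 voxel mean error and warping bank labels
   raises WM DICE by ≥ 0.05; they are wholly owned by this package, not
   inherited from any external tool, and an external registration package can
   be substituted behind `register_deformable` without touching other
   modules.
2. **Joint fusion weights.** At each masked voxel `v`, each atlas `i`
   contributes its best-matching patch (lowest SSD to the target patch,
   radius 2, searched within ±2 voxels; ties broken by smallest displacement,
   then lexicographic offset — fully deterministic). With absolute residual
   patches `e_i` raised to power β (default 2) and globally normalized to
   unit mean, the error-product matrix `M_ij = ⟨|e_i|^β, |e_j|^β⟩` is formed
   and `w ∝ (M + αI)⁻¹·1` solved (α = 0.1 pure conditioning; negatives
   clipped, renormalized). This is joint fusion applied to intensities:
   correlated atlas errors are jointly down-weighted rather than each atlas
   being scored independently. The weight map is a per-voxel simplex inside
   the mask and zero outside — validated on every synthesis run.
3. **Weight transfer.** The T1w-derived weights are applied voxelwise to the
   warped bank T2w images (a convex combination, so the fused image is
   bounded by the warped-bank envelope).
4. **Histogram matching and averaging.** The fused image is
   quantile-landmark matched (256 landmarks, monotone piecewise-linear map,
   within-mask) to each bank T2w and the matched variants are averaged.
   References are the *unwarped* bank T2w images, each within its own brain
   mask: warped references import background zeros near mask edges into the
   reference quantiles and measurably degrade the result (3.9% vs 1.5%
   relative MAE in the exact-copy control experiment).

Outputs are brain-masked; skull/background re-synthesis is out of scope, and
every metric in the battery is computed within the brain mask anyway.

## 3D CycleGAN synthesis

Two volumetric generators (T1→T2, T2→T1) and two least-squares patch
discriminators are trained simultaneously from *unpaired* volume sets. The
generator is a shallow encoder–decoder: six 3×3×3 convolutions with ReLU,
the fifth strided (one ×2 downsampling), then two transposed convolutions
restoring the grid, and a 1×1×1 convolution with tanh. Because the published
description pairs one ×2 downsampling with *two* upsampling transpose
convolutions, the second transpose convolution here is stride 1 (a
refinement stage), which is the only reading that preserves the output
shape. Channel widths per stage are `base_kernels × (1,2,4,8,8,8)`
(config-exposed; kernel counts are not pinned by the source description).

Losses: adversarial terms are MSE between discriminator scores and
real/fake labels (least-squares GAN); the cycle term is
`MAE(G_BA(G_AB(a)), a) + MAE(G_AB(G_BA(b)), b)`, weighted by
`λ_cycle = 10` (the customary CycleGAN value; the weight is not stated in
the source). Optimization is Adam (lr 2·10⁻⁴, β₁ = 0.5), alternating a
generator step (both cycle directions, discriminators frozen) with a
discriminator step on detached fakes.

The numerical substrate is a purpose-built numpy layer library with
hand-written backpropagation: each 3D convolution runs as k³ slice/GEMM
pairs, gradients are the exact adjoints, and everything is float32 and
deterministic on CPU — two runs with the same seed produce bit-identical
loss histories. Gradients are verified against central finite differences in
the test suite. The supported test scale is 32³ volumes with
`base_kernels = 4` and capped widths `(1,2,2,4,4,4)` (≈ 30-epoch training in
~2 CPU-minutes); full-resolution training (140×168×144) is accepted by the
shape logic but is a GPU-scale exercise outside the test path.

Intensities map to the tanh range as `x/1000 − 1` from the 0–2000 working
scale, inverted and clipped on output.

## Evaluation battery

* **Relative MAE**: mean |a−b| within the mask, as a percentage of the
  0–2000 working scale (the normalizing constant is the scale itself; if a
  study normalized by mean intensity instead, absolute percentages shift).
* **MSSIM**: Gaussian-windowed (σ = 1.5, truncated at 3.5σ) local SSIM with
  stabilizers (0.01·L)², (0.03·L)², L = 2000, averaged over voxels whose
  window lies entirely inside the mask — background can never inflate the
  score. The entirely-inside rule means thin masks (< 11 voxels across) are
  rejected rather than silently averaged.
* **DICE**: 2|A∩B|/(|A|+|B|); two empty masks count as identical.
* **CNR**: |μ(GM) − μ(WM)| / √((σ²(GM)+σ²(WM))/2) with population (divide-
  by-N) standard deviations — the source is silent on the estimator; the
  choice is fixed and documented. ROIs minimize partial-volume voxels: GM is
  the 1-voxel erosion minus the 2-voxel erosion of the GM segmentation (a
  one-voxel sheet strictly inside GM); WM is the 5-voxel erosion of the WM
  segmentation. Erosion is 6-connected (face-adjacent), iterated. ROIs that
  vanish raise an error: the recipe requires structures thick enough to
  survive it.
* **Mutual information**: plug-in estimate in nats from a 64-bin equal-width
  joint histogram of within-mask intensities. The plug-in estimator is
  positively biased at small samples (≈ (bins−1)²/2N nats), which the
  independence test bound accounts for.
* Each metric is checked against an independent direct-loop oracle to 1e-8
  relative (1e-3 for MI, where binning edge arithmetic differs harmlessly).

## Functional-connectivity comparison

Parcel FC matrices are Pearson correlations of parcel-mean BOLD timeseries
(any parcellation; the 333-parcel scheme of the source is just an input
size). Group connectomes are compared by Pearson r over vectorized strict
upper triangles; arm differences by two-sided paired t-tests per unique
parcel pair. The significance threshold is `α / n_tests` with `n_tests` the
number of unique pairs actually tested: dividing by the parcel count instead
(as the per-parcel arithmetic `α/N_parc` does) is anti-conservative by a
factor (P−1)/2 for the pair family and fails family-wise error calibration —
measured FWER ≈ 0.5 at P = 30 under the null, versus ≈ 0.04 with the pair
count. The helper `bonferroni_threshold(n, α)` performs the plain `α/n`
arithmetic for either convention. Correlations are compared raw by default
(`fisher_z=True` available): the tested pipelines differ only in anatomical
preprocessing, so differences live on the raw correlation scale. Pairs with
identically zero differences return p = 1, making "identical inputs → zero
detections" exact.

## The phantom: what it emulates, and what it does not

Three nested smooth tissue shells (CSF, GM ribbon, WM core) are produced by
thresholding one lumpy radial field, so their nesting is guaranteed by
construction. Rendering assigns tissue-mean intensities plus per-tissue
Gaussian noise, a smooth multiplicative bias field (peak log-amplitude 0.1),
and additive Gaussian noise, clipped at zero. Default means (T1w
CSF/GM/WM = 400/1000/700; T2w = 1800/700/1200) encode the two neonatal
contrast facts as hard invariants of the PhantomSpec object: GM−WM sign inversion
between modalities, and larger T2w contrast magnitude. Bank subjects warp
the base anatomy with smooth random displacement fields (SD 2.5 voxels
before the safety rescale, smoothing 5 voxels), shrunk by 0.8× until the
minimum warp Jacobian exceeds 0.2 — approximately diffeomorphic by
rescaling rather than by exponential maps, which is sufficient for testing.
Default grid 48×56×48 keeps the full suite in CPU-minutes; the shape is
configurable up to full resolution.

Deliberate non-realism, and what that implies for test evidence:

* Gaussian, not Rician, noise — no downstream method depends on the noise
  law, and Gaussian keeps the metric oracles analytic.
* Tissue SDs (CSF/GM/WM = 120/100/90, additive 40) are small relative to
  tissue means so that zero-clipping is negligible and rendered moments
  match their nominal values. Real neonatal gray–white CNR (~0.6–0.8 with
  partial-volume-minimizing ROIs) reflects partial-volume averaging and
  physiological variability the phantom does not model, so phantom CNR runs
  several-fold higher; CNR comparisons on the phantom exercise the
  arithmetic and ROI construction, not the empirical operating point.
* No cortical folding, skull, or scalp; no BOLD generation — FC inputs are
  synthetic timeseries tables.
* Passing phantom tests therefore demonstrates correctness of the
  algorithms and their contracts, not clinical-grade synthesis quality on
  real neonatal data.

## Numerical choices and degenerate inputs

* Intensity normalization maps the robust within-mask range (0.5th–99.5th
  percentile as outer-rounded order statistics) onto [0, 2000], clips and
  zeroes the background. Order-statistic bounds make the operation exactly
  idempotent. Constant images are rejected.
* Bias correction models within-mask log-intensity as K tissue levels
  (deterministic 1D k-means, K = 3) plus a total-degree-≤3 polynomial,
  alternated 5 rounds, and divides out the zero-mean polynomial part,
  preserving the within-mask mean exactly. A plain least-squares polynomial
  fit without the level term absorbs the concentric anatomy into the "bias"
  and *adds* inhomogeneity — the level term is what makes the stand-in
  usable. Masks with fewer voxels than polynomial coefficients are rejected.
* Warping uses trilinear interpolation for intensities, nearest-neighbour
  for labels (linear on labels is an error), out-of-grid samples take
  background 0.
* Non-finite voxels encountered at read time become 0, with a log message.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; every generator operation is a pure function
  of (spec, seed).

## Known limitations

* The demons-style registration is accurate to a few tenths of a voxel on
  smooth phantom deformations but is not a match for state-of-the-art
  symmetric diffeomorphic tools on real data; the adapter seam exists for
  that reason.
* The joint-fusion weight solve is O(bank² · patch · voxels) in time and
  holds all residual patches in memory (float32); banks beyond a few dozen
  members at full resolution would need tiling.
* CPU-only GAN training limits practical experiments to toy scale; the
  architecture is the published one, the training budget is not. At toy
  scale (≈180 optimization steps) the learned T1→T2 mapping beats the
  untranslated-input baseline only by a small margin and plateaus with
  further epochs — the toy path demonstrates the training mechanics
  (loss decrease, determinism, shape/range contracts), not translation
  quality, which requires full-scale training.
* The histogram-matching average can bias absolute intensities when bank
  histograms differ systematically from the target's true T2w — visible as
  the gap between pre-matching and final MAE in the exact-copy control.
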