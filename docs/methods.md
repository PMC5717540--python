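# Methods note

This note records the statistical model, the assumptions behind each
correction, the synthetic-data generator's scope, and the numerical and design
decisions baked into `eitmap`.

## Model

At each voxel v inside the analysis mask, the n recording images for one time
bin are treated as independent draws x₁(v), …, xₙ(v) and tested with a
one-sample t statistic

  t(v) = x̄(v) / (s(v) / √n),  df = n − 1,

against the one-sided alternative of a positive mean change. Voxels that are
zero or non-finite in any recording are excluded (implicit masking); voxels
with zero sample variance are also dropped. Standardised residuals
rᵢ(v) = (xᵢ(v) − x̄(v)) / ‖x − x̄‖₂ (unit sum of squares per voxel) are retained
for smoothness estimation.

Time bins are analysed independently. The family-wise alpha is divided across
bins by a temporal Bonferroni: the number of effectively independent tests is
max(1, round(analysed span / temporal resolution)), where the span is
(n_bins − 1) × bin spacing. With alpha 0.05, 21 bins at 2 ms spacing and 8 ms
resolution this gives 5 independent tests and a per-bin alpha of 0.01.

## FWE corrections

**Bonferroni.** Per-voxel alpha = alpha_bin / n_masked_voxels; the threshold
is the corresponding upper quantile of Student's t with n − 1 df. Valid for
any dependence but conservative when neighbouring voxels are correlated.

**Random field theory.** Assumes the t image behaves like a smooth
stationary random field. The effective FWHM per axis a is estimated from the
mean squared forward difference of the standardised residuals over masked
voxel pairs, λ_a, via FWHM_a = √(4 ln 2 / λ_a). The search region is
approximated by the bounding box of the mask and converted to resel counts
R₀…R₃ (box approximation: edge lengths in FWHM units and their products). The
threshold t* solves

  Σ_d R_d ρ_d(t*) = alpha_bin,

with the Euler-characteristic densities ρ_d for t fields (d = 0…3). The
left-hand side is the expected Euler characteristic of the suprathreshold
field — at high thresholds, the expected number of false-positive blobs. The
root is found with Brent's method on the decreasing branch of the expected
EC curve; the bracket start is placed at the curve's maximum, and the upper
end is doubled adaptively (heavy polynomial tails at low df can keep the
expected EC above alpha until very large t). The result is capped at the
Bonferroni threshold, which also guarantees a finite answer when the RFT
equation has no root below the cap.

**Sign-flip permutation.** Under the null the distribution of each
recording's image is symmetric about zero, so the 2ⁿ sign patterns are
exchangeable relabelings. For each pattern the maximum t over the mask is
computed; the threshold is the k-th smallest maximum with k = ⌈(1 − alpha)
N⌉ (a "ceil_plus_one" rule is available as an option), and voxels are
significant when strictly above it. When 2ⁿ ≤ the requested number of
permutations the enumeration is exhaustive and the test exact; otherwise a
Monte Carlo subset is used that always contains the identity pattern and
distinct random patterns, with half-width 2√(p(1−p)/N′) quantifying the
Monte Carlo error of an estimated p (0.0063 at p = 0.01, N′ = 1000).
Requested alphas with alpha × N < 1 are rejected rather than silently
rounded. Corrected p-values come from the rank of the observed statistic in
the sorted null. The implementation exploits that Σxᵢ² is invariant under
sign flips, so only the flipped means require a matrix product; patterns are
processed in chunks of 128.

## Synthetic generator

Noise volumes are white Gaussian fields convolved with an isotropic Gaussian
kernel (periodic boundary, truncated at 4 sigma) and divided by the kernel's
L2 norm, giving exactly unit marginal variance and a field autocorrelation
FWHM equal to the kernel FWHM. Activation is a hard-edged ellipsoid (default
radii 300 × 300 × 150 µm) scaled by `effect_size`, a unimodal time course in
[0, 1], and optionally an exponential depth attenuation; it is added after
smoothing, so the activation boundary is sharp. Randomness is hierarchical:
`SeedSequence((seed, recording, bin))`, so any recording/bin is reproducible
in isolation and groups with effect 0 are bit-identical to null groups.

The generator emulates: spatially smooth reconstruction noise with known
smoothness, a localised positive conductivity change with a known time
course, and depth-dependent sensitivity loss. It does not emulate: the
forward/inverse EIT reconstruction itself, spatially varying noise
covariance, inter-recording variance heterogeneity, negative or biphasic
responses, or physiological artefacts.

## Geometry and conditioning

Mesh-based reconstructions are mapped to voxel grids by: triangle-centroid
extraction, least-squares plane fit to the cortical surface, Rodrigues
rotation aligning the plane normal with +z (the antiparallel case uses
diag(1, −1, −1)), a depth crop measured from the rotated surface, and
piecewise-linear (Delaunay) interpolation onto the grid; points outside the
convex hull are masked. Conditioning offers a separable zero-phase Gaussian
FIR smoother — the kernel FWHM must be at least twice the voxel spacing to be
representable — and proportional scaling: each recording is divided by the
mean of its suprathreshold values (above half of the global maximum) at its
peak bin, yielding one factor per recording.

## Parameters and defaults

| parameter | default | units |
|---|---|---|
| recordings per group | 22 | — |
| grid spacing | 25 | µm |
| noise field FWHM | 150 | µm |
| noise SD | 1 | arbitrary conductivity units |
| activation radii | 300 × 300 × 150 | µm |
| effect size | 5 | multiples of noise SD |
| time bins / spacing | 21 / 2 | — / ms |
| temporal resolution | 8 | ms |
| family-wise alpha | 0.05 | — |
| permutations | 1000 (studies: 500) | — |
| smoothing truncation | 4 | sigma |

## Validation studies

`eitmap.validation` measures operating characteristics on synthetic groups;
the acceptance suite and `scripts/acceptance.py` run them at these sizes:

- **FWE calibration**: 500 null groups (n = 12, 32³ voxels, FWHM 4 voxels,
  500 permutations, alpha 0.05); the permutation family-wise false-positive
  rate must fall in the 95% binomial interval [0.032, 0.071] and the RFT rate
  must not exceed 0.08.
- **Threshold ordering**: 100 active groups at df = 21; Bonferroni ≥ RFT
  always (by the cap), RFT ≥ permutation in ≥ 90%.
- **Smoothness recovery**: estimated FWHM within 15% of generating kernels of
  3–8 voxels at n = 22 on a 48³ grid.
- **Null control**: 100 zero-effect series through the full per-bin pipeline
  at per-bin alpha 0.01; ≥ 95% must be entirely clean.
- **Detection**: 50 active groups; both methods detect the activation at the
  peak bin, the significant-region centroid lies within one activation radius
  of truth, and the permutation significant volume dominates the RFT volume
  at every bin, each in ≥ 90% of seeds.

Study sizes are the package's own choices, sized so the regime of interest
(field FWHM of several voxels, realistic group df) is preserved at a few
minutes of single-CPU compute.

## Design decisions and limitations

- The resel computation uses the bounding box of the mask, not its exact
  intrinsic volumes; for near-box masks (the common case after depth
  cropping) the approximation is tight, for sparse masks it is conservative
  in R₃ but can misstate the lower-order terms.
- The permutation threshold uses the ⌈(1 − alpha)N⌉ order statistic with a
  strict exceedance rule; together these are slightly conservative under
  ties. A `ceil_plus_one` rule is exposed for sensitivity analysis.
- Proportional scaling takes "suprathreshold" as strictly greater than half
  the global maximum; values exactly at half-maximum are excluded.
- The smoothness estimator assumes stationarity; a spatially varying FWHM
  biases the pooled estimate toward the smoother regions.
- One-sided positive inference only; negative conductivity changes are not
  tested.
- Permutation inference needs alpha × N ≥ 1; very small per-bin alphas
  require correspondingly many permutations (exhaustive enumeration is used
  automatically when 2ⁿ is small enough).
- All empirical claims above are outputs of the validation studies in this
  package; no external datasets are bundled.
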