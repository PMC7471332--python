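# Methods

## Signal model and T1 estimation

The spoiled-gradient-echo steady state at repetition time TR and effective
flip angle α_eff is

    S = M0 · sin(α_eff) · (1 − E1) / (1 − E1 · cos(α_eff)),   E1 = exp(−TR/T1).

M0 absorbs proton density, receive sensitivity and the fixed TE/T2* decay of
the single-echo protocol — the pipeline never estimates T2*, which is a
modeling assumption, not an approximation error, as long as TE is constant
across flip angles (it is: 3 ms).

T1 and M0 are fitted voxel-wise by the DESPOT1 linearization: with
Y = S/sin(α_eff) and X = S/tan(α_eff), the model is the line
Y = E1·X + M0(1−E1), solved by **unweighted** ordinary least squares over
the six flip angles (2°, 5°, 10°, 15°, 20°, 30°; TR 16 ms). Then
T1 = −TR/ln(slope), M0 = intercept/(1−slope). Unweighted OLS in the
linearized domain is a deliberate choice (it is the estimator the analysis
emulates); a nonlinear grid-search fit exists in the test suite purely as
an independent oracle — at zero noise the two coincide exactly, and at 2%
noise they agree to a few percent (median).

Voxels whose slope falls outside (0, 1), with non-finite intermediates or
all-zero signals are set to NaN in both T1 and M0: invalid fits are
dropped, never clamped, consistent with the downstream strict filter that
removes T1 > 5000 ms (and T1 ≤ 0). The filter is idempotent and inclusive
at the boundary (exactly 5000 ms survives).

## B1⁺ mapping and resampling

Transmit inhomogeneity scales every nominal angle by a voxel-wise factor κ.
κ is measured by the double-angle method from a fully relaxed RARE pair at
70°/140° (TR 10 s ≫ T1, so S(α) ∝ M0·sin(κα) and
κ = arccos(S₁₄₀/2S₇₀)/70°). Out-of-domain ratios (|r| ≥ 1, zero
denominator) become NaN and are counted.

The RARE grid is coarser than the SPGR grid (0.24 mm in-plane, 36 slices of
0.3 mm with 0.2 mm gaps → 0.5 mm center-to-center). The κ map is lightly
smoothed (Gaussian, σ = 1 RARE voxel — switchable off) to suppress ratio
noise, NaNs are filled from the nearest valid voxel, and the field is
trilinearly interpolated in world coordinates onto the SPGR grid, with
edge-value (nearest) extrapolation outside the sampled slab. Voxel
convention everywhere: 0-based indices, world position of a voxel center
= (index + 0.5) · voxel size; degrees at the API surface, radians inside.

## Quantification

* **Relaxivity.** 1/T1_post = 1/T1_pre + r1·C with rates in s⁻¹, C in mM.
  The default r1 = 3.5 L·mmol⁻¹·s⁻¹ (Gd-DOTA at 9.4 T) is a documented,
  configurable default; no headline result depends on its exact value
  beyond forward/inverse consistency, which holds to machine precision.
  Inverse concentrations may be negative when noise pushes T1_post above
  T1_pre; they are reported as-is and flagged, never clipped, because the
  negative tail is a useful noise diagnostic.
* **Trimmed ROI mean.** "Mean over the 90 percentiles" is implemented as
  the mean of ROI voxels at or below the 90th percentile
  (linear-interpolated) of the valid values — i.e. the top 10% tail,
  dominated by CSF partial-volume voxels, is dropped. This is the reading
  under which the trim changes the statistic in the intended direction.
* **GS cluster.** The set of brain-mask voxels with 1 ms ≤ T1 ≤ 1800 ms
  (inclusive bounds, NaN excluded); reported as voxel count and mm³. It is
  a threshold set, not a connected component — an optional 26-connectivity
  labeling exists but is not used in headline numbers.
* **COV** = sample SD / mean × 100%; sample (n−1) SDs are used throughout,
  the usual convention for small-n group summaries.

## Statistics

Pairwise group comparisons use Welch's unequal-variances t-test, two-sided,
with Welch–Satterthwaite df, in both raw-sample and summary-statistic
(mean, SD, n) forms; region-level tests are not multiplicity-adjusted.
Zero-variance degenerates return p = 1 (equal means) or p = 0 (flagged).

The one-way repeated-measures ANOVA (regions within subject) tests
F = MS_region / MS_(region×subject) with df (k−1), (k−1)(n−1); the
split-plot mixed ANOVA (time within, group between) tests the group effect
against subject-within-group MS and the within effects against the
time×subject(group) MS. Both are direct sums-of-squares implementations
(vectorized, which keeps the 5000-replicate null calibration in the test
suite cheap) and are cross-checked in the tests against pingouin and
against hand-written SS decompositions. Sphericity is assumed — df are
reported uncorrected — with a Greenhouse–Geisser option off by default.

Voxel-wise analysis smooths each subject's T1 map with an isotropic
Gaussian (FWHM 0.4 mm → σ ≈ 0.944 voxels at 0.18 mm), NaN-aware via
normalized convolution with reflective boundaries, then applies a per-voxel
Welch test (a plain two-group contrast; the design has no covariates, so no
fuller GLM is needed) and Benjamini–Hochberg FDR at q = 0.05 over the valid
voxels. Null calibration: on i.i.d. normal groups the fraction of voxels
with p < 0.05 is 0.05 ± 0.01 (10⁴ voxels), and the RM-ANOVA type-I rate is
0.05 ± 0.01 over 5000 null tables (n = 7, k = 7).

## The synthetic cohort

The phantom is parametric geometry in a common space — nested ellipsoids on
an 18 mm cube: a soft-tissue head, a brain with seven named regions
(brainstem, cerebellum, hippocampus, hypothalamus, midbrain, olfactory
bulb, thalamus), three CSF ventricles, and paired dcLN/smLN in the neck.
Because all subjects share the space by construction, the registration /
segmentation machinery a real study needs (atlas alignment, bias
correction, tissue probability maps) is out of scope here, not merely
omitted.

Planted control values: brain-region T1 1900–2100 ms, generic brain tissue
2000 ms, CSF 3000 ms, muscle 1500 ms, dcLN 1895 ms and smLN 2172 ms (the
saline group means of the emulated design); M0 ≈ 1000 a.u. (1200 CSF).
Group uptake is planted by inverting the relaxivity relation from target
fractional reductions — KX+Gd: brainstem 50%, olfactory bulb 40%,
hypothalamus 35%, midbrain 30%, cerebellum 27%, hippocampus 15%, thalamus
12%, generic tissue 8%, CSF 60%, and node reductions fixed exactly by the
group-mean pre/post pairs (dcLN 1895→1093 ms, smLN 2172→1853 ms). The ISO
profile is not published region-by-region; it is chosen once at roughly
half the KX brain uptake (and leaves hippocampus/thalamus above the 1800 ms
cluster cutoff), which reproduces the qualitative KX > ISO cluster
contrast. Group sizes follow the design: control 9, KX+Gd 7, ISO+Gd 7.

Stochastic elements, all seeded through a stable SeedSequence derivation
from (group seed, subject index):

* **Inter-subject variability** — multiplicative Gaussian jitter (3% SD)
  on each compartment's T1 and each region's C; enough to produce
  between-subject SDs of the right order without extra machinery.
* **B1⁺ field** — a Gaussian random field (length scale 4 mm) centered and
  scaled to mean exactly 1 and amplitude 0.2 by default.
* **Noise** — Rician on magnitude images, σ in M0 units. The emulated
  study does not state its SNR; the default is SNR 50 at the peak tissue
  SPGR signal, a typical regime for 3D acquisitions at this field, and is
  documented rather than claimed to match any measurement.

The RARE acquisition is simulated in the fully relaxed regime (the regime
the double-angle method requires) by box-averaging M0 and κ into each
excited slab (slice thickness only — the gap is not sampled) and in-plane
pixel, then applying S ∝ M0·sin(κα).

What the phantom does **not** emulate: k-space effects, motion and
respiratory artefacts (the dominant confound for neck ROIs in the real
experiment), slice-profile effects, receive-coil (B1⁻) bias, partial-volume
mixing at tissue boundaries (compartments are piecewise constant), and
anatomical realism of shapes. Passing tests therefore demonstrate the
correctness of the estimators and statistics under the stated noise model,
not robustness to those real-world effects. The dcLN compartments are drawn
at 0.8×1.2×0.8 mm — slightly above the anatomical 0.2–0.5 mm extent — so
the ROI holds ~130 voxels at 0.18 mm and the trimmed mean is stable.

## Problem sizes and numerical choices

Acceptance-grade runs use the full 100³ grid (the node-recovery pipeline
runs in seconds; everything is vectorized). Unit and property tests use the
same 18 mm field of view on coarser grids (32³–50³), which preserves the
anatomy while keeping the suite around ten seconds; grids below ~32³ start
to lose the smallest compartments (a rasterized compartment with zero
voxels warns). Noiseless pipeline closure holds to <0.1% with a flat B1
field; with the default 20%-amplitude field the residual ~0.1–0.5% error is
dominated by B1 slab-averaging and interpolation, not the fit. Ties and
degenerate inputs: overlapping compartments resolve last-listed-wins;
empty ROIs raise naming the region; all-NaN B1 sources raise; existing
output directories require an explicit force flag.
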