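# glymph-t1

Quantifying glymphatic transport and cervical lymph-node drainage by
"snapshot" T1 mapping — as a tested, reusable pipeline on synthetic mouse
head-and-neck MRI.

## The problem

Gadolinium contrast (Gd-DOTA) delivered into cerebrospinal fluid is carried
through the brain's glymphatic system (GS) and drains to the deep cervical
(dcLN) and submandibular (smLN) lymph nodes. Because Gd shortens the
longitudinal relaxation time T1 in proportion to its local concentration,

```
1/T1_post = 1/T1_pre + r1 · C        (rates in s⁻¹, C in mM)
```

a single post-contrast T1 map quantifies transport without pre-contrast
baseline scans: tissue that took up contrast shows reduced T1 relative to
saline controls (~2000 ms for normal brain tissue at 9.4 T, ~3000 ms for
CSF). This package implements that analysis for synthetic cohorts:

1. **Phantom simulation** (`glymph_t1.phantom`) — a parametric digital mouse
   head-and-neck phantom (brain regions, ventricles, lymph nodes) with
   planted T1/M0/C/B1 truth; simulated variable-flip-angle SPGR
   (TR 16 ms / TE 3 ms, flip angles 2–30°, 0.18 mm isotropic, 100³) and a
   fully relaxed 70°/140° RARE pair on a coarse gapped grid, with Rician
   magnitude noise.
2. **Relaxometry** (`glymph_t1.relaxometry`) — the SPGR signal model
   `S = M0·sin α·(1−E1)/(1−E1·cos α)`, `E1 = exp(−TR/T1)`; voxel-wise T1/M0
   by the DESPOT1 linearization (`S/sin α` vs `S/tan α`, unweighted least
   squares) with double-angle B1⁺ correction
   (`κ = arccos(S₂ₐ/2Sₐ)/α`); T1 > 5000 ms filtering.
3. **Quantification** (`glymph_t1.quantify`) — relaxivity forward/inverse
   maps, 90th-percentile-trimmed ROI means, percent reductions, the
   GS cluster (voxels with 1 ms ≤ T1 ≤ 1800 ms) and its volume, COV.
4. **Statistics** (`glymph_t1.group_stats`) — Welch's unequal-variances
   t-test (raw and summary-statistic forms), one-way repeated-measures and
   split-plot (mixed) ANOVA, 0.4 mm FWHM Gaussian smoothing, population
   averages, voxel-wise Welch maps with Benjamini–Hochberg FDR.
5. **Pipeline + CLI** (`glymph_t1.pipeline`, `glymph-t1`) — config-driven
   end-to-end runs producing tidy CSVs, summary JSON and NIfTI maps.

## Worked example

```python
import numpy as np
import glymph_t1 as g

# single-voxel T1 fit from a noiseless six-angle SPGR signal
angles = (2, 5, 10, 15, 20, 30)
sig = g.spgr_signal(1000.0, 1994.0, np.array(angles), 16.0)
fit = g.fit_despot1(sig.reshape(-1, 1, 1, 1), angles, 16.0)
print(f"recovered T1 = {fit.t1.data.ravel()[0]:.1f} ms")

# full synthetic study (23 subjects) on a reduced 50³ grid
cfg = g.default_config(phantom={"grid_shape": [50, 50, 50]}, seed=1)
summary = g.run_pipeline(cfg)
```

prints (run with seed 1):

```
recovered T1 = 1994.0 ms
control  n=9  brainstem T1 = 1920 +/- 44 ms  GS-cluster = 202 +/- 86 voxels
KX+Gd    n=7  brainstem T1 = 982 +/- 16 ms  GS-cluster = 4488 +/- 1300 voxels
ISO+Gd   n=7  brainstem T1 = 1074 +/- 11 ms  GS-cluster = 2356 +/- 612 voxels
GS-cluster control vs KX+Gd: t = -8.71, df = 6.0, p = 1.22e-04
dcLN reduction vs control: 41.5%
voxel-wise KX vs ISO: 1731 significant voxels (FDR q = 0.05)
```

Reading this: the KX+Gd group's brainstem T1 is roughly half the control
value (the planted ~50% reduction recovered through the full acquisition →
B1 mapping → fit → ROI chain), its GS cluster is ~20× the saline cluster,
the dcLN drains enough Gd for a ~40% T1 drop, and the voxel-wise map
localizes the KX-vs-ISO transport difference.

The same study runs from the shell:

```
glymph-t1 run-all --out results/run1 --seed 1
glymph-t1 simulate --out cohort/ --seed 1       # write raw NIfTI cohort
glymph-t1 fit --subject cohort/KX+Gd_00 --b1 dam
glymph-t1 quantify --subject cohort/KX+Gd_00
```

Configs are YAML (`--config`); see `glymph_t1.config` for the schema. All
analysis constants (cluster bounds 1–1800 ms, trim percentile 90, FWHM
0.4 mm, FDR q 0.05, relaxivity r1) are configurable; `r1` must be stated
explicitly (default study value 3.5 L·mmol⁻¹·s⁻¹ for Gd-DOTA at 9.4 T).

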