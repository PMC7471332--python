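"""Group and voxel-wise statistics.

ROI-level comparisons use Welch's unequal-variances two-sample t-test
(two-sided, Welch-Satterthwaite degrees of freedom), with no multiple-
comparison adjustment at the region level. Repeated-measures designs use
classical sums-of-squares ANOVA: a one-way within-subject (region) model
F = MS_region / MS_(region x subject), and a split-plot (mixed) model with
a within factor (time) and a between factor (group), testing the group
effect against subject-within-group MS and the within effects against the
time x subject(group) MS. Sphericity is assumed by default; a
Greenhouse-Geisser correction is available but off.

Voxel-wise analysis: per-voxel Welch test across subjects on Gaussian-
smoothed maps (default FWHM 0.4 mm), with Benjamini-Hochberg FDR control
over the valid voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .volume import ImageVolume

__all__ = [
    "TestResult",
    "AnovaResult",
    "StatMap",
    "welch_t",
    "welch_t_summary",
    "rm_anova_oneway",
    "mixed_anova",
    "fwhm_to_sigma_mm",
    "smooth_gaussian",
    "population_average",
    "voxelwise_welch",
    "bh_fdr",
]


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    mean_diff: float
    method: str = "welch"
    degenerate: bool = False


@dataclass
class AnovaResult:
    F: float
    df_num: float
    df_den: float
    p: float
    effect: str


@dataclass
class StatMap:
    t_map: ImageVolume
    p_map: ImageVolume
    fdr_mask: np.ndarray
    q: float


def welch_t_summary(m1: float, s1: float, n1: int, m2: float, s2: float, n2: int) -> TestResult:
    """Welch's two-sided t-test from summary statistics (mean, SD, n).

    Degenerate zero-variance cases: equal means -> p = 1; unequal means ->
    p = 0, flagged.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 < 0 or s2 < 0:
        raise ValueError("SDs must be non-negative")
    diff = m1 - m2
    v1, v2 = s1**2 / n1, s2**2 / n2
    if v1 + v2 == 0:
        if diff == 0:
            return TestResult(0.0, float(n1 + n2 - 2), 1.0, 0.0, degenerate=True)
        return TestResult(np.inf if diff > 0 else -np.inf, float(n1 + n2 - 2), 0.0,
                          diff, degenerate=True)
    t = diff / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), float(diff))


def welch_t(sample_a, sample_b) -> TestResult:
    """Welch's two-sided t-test on raw samples."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return welch_t_summary(a.mean(), 0.0, a.size, b.mean(), 0.0, b.size)
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue),
                      float(a.mean() - b.mean()))


def rm_anova_oneway(data: np.ndarray, gg_correction: bool = False) -> AnovaResult:
    """One-way repeated-measures ANOVA on a complete subjects x conditions matrix.

    F = MS_condition / MS_(condition x subject), df = (k-1), (k-1)(n-1).
    Sphericity is assumed; ``gg_correction=True`` applies the Greenhouse-
    Geisser epsilon to both df (off by default). Missing cells raise.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a 2D matrix with >= 2 subjects and >= 2 conditions")
    if not np.isfinite(x).all():
        raise ValueError("missing cells are not supported (no imputation)")
    n, k = x.shape
    grand = x.mean()
    subj_means = x.mean(axis=1)
    cond_means = x.mean(axis=0)
    ss_cond = n * ((cond_means - grand) ** 2).sum()
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df_num, df_den = float(k - 1), float((k - 1) * (n - 1))
    if gg_correction:
        eps = _gg_epsilon(x)
        df_num *= eps
        df_den *= eps
    ms_cond = ss_cond / df_num
    ms_err = ss_err / df_den
    if ms_err == 0:
        f = 0.0 if ss_cond == 0 else np.inf
    else:
        f = ms_cond / ms_err
    p = float(sps.f.sf(f, df_num, df_den)) if np.isfinite(f) else 0.0
    return AnovaResult(float(f), df_num, df_den, p, effect="region")


def _gg_epsilon(x: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity epsilon from the sample covariance."""
    k = x.shape[1]
    s = np.cov(x, rowvar=False)
    mean_diag = np.trace(s) / k
    mean_all = s.mean()
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * ((s**2).sum() - 2 * k * (s.mean(axis=1) ** 2).sum() + k**2 * mean_all**2)
    return float(num / den) if den > 0 else 1.0


def mixed_anova(data: np.ndarray, group_labels) -> list[AnovaResult]:
    """Split-plot ANOVA: within factor (columns, e.g. time) x between factor.

    ``data`` is subjects x timepoints (complete); ``group_labels`` assigns
    each row to a group. The between (group) effect is tested against the
    subject-within-group mean square; the within (time) and interaction
    effects against the time x subject(group) mean square. Balanced within
    (every subject has every timepoint); group sizes may differ.
    """
    x = np.asarray(data, dtype=float)
    groups = np.asarray(group_labels)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a subjects x timepoints matrix with >= 2 timepoints")
    if groups.shape[0] != x.shape[0]:
        raise ValueError("one group label per subject row")
    if not np.isfinite(x).all():
        raise ValueError("missing cells are not supported")
    levels = list(dict.fromkeys(groups.tolist()))
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    n_subj, k = x.shape
    grand = x.mean()

    subj_means = x.mean(axis=1)
    group_masks = [groups == g for g in levels]
    n_g = np.array([m.sum() for m in group_masks])
    group_means = np.array([x[m].mean() for m in group_masks])
    time_means = x.mean(axis=0)
    cell_means = np.array([x[m].mean(axis=0) for m in group_masks])  # g x k

    ss_between_subj = k * ((subj_means - grand) ** 2).sum()
    ss_group = k * (n_g * (group_means - grand) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_group

    ss_time = n_subj * ((time_means - grand) ** 2).sum()
    ss_inter = (n_g[:, None] * (cell_means - group_means[:, None]
                                - time_means[None, :] + grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err_within = ss_total - ss_between_subj - ss_time - ss_inter

    g = len(levels)
    df_group, df_sw = g - 1.0, float(n_subj - g)
    df_time, df_inter = k - 1.0, float((g - 1) * (k - 1))
    df_err = float((n_subj - g) * (k - 1))

    def result(ss, df_num, ms_den, df_den, effect):
        ms = ss / df_num
        f = ms / ms_den if ms_den > 0 else (0.0 if ss == 0 else np.inf)
        p = float(sps.f.sf(f, df_num, df_den)) if np.isfinite(f) else 0.0
        return AnovaResult(float(f), df_num, df_den, p, effect)

    ms_sw = ss_subj_within / df_sw if df_sw > 0 else 0.0
    ms_err = ss_err_within / df_err if df_err > 0 else 0.0
    return [
        result(ss_group, df_group, ms_sw, df_sw, "group"),
        result(ss_time, df_time, ms_err, df_err, "time"),
        result(ss_inter, df_inter, ms_err, df_err, "interaction"),
    ]


def fwhm_to_sigma_mm(fwhm_mm: float) -> float:
    return fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def smooth_gaussian(vol: ImageVolume, fwhm_mm: float = 0.4) -> ImageVolume:
    """NaN-aware isotropic Gaussian smoothing (normalized convolution).

    The kernel width is given as full width at half maximum in mm and
    converted to per-axis sigma in voxels; boundaries are reflective.
    Voxels with no valid support stay NaN.
    """
    if fwhm_mm <= 0:
        return vol.copy()
    sigma_vox = [fwhm_to_sigma_mm(fwhm_mm) / v for v in vol.voxel_size]
    data = vol.data
    valid = np.isfinite(data)
    filled = np.where(valid, data, 0.0)
    sv = ndimage.gaussian_filter(filled, sigma_vox, mode="reflect")
    sw = ndimage.gaussian_filter(valid.astype(float), sigma_vox, mode="reflect")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sw > 1e-12, sv / sw, np.nan)
    out[~valid & (sw <= 1e-12)] = np.nan
    return ImageVolume(out, vol.voxel_size, units=vol.units)


def population_average(maps: list[ImageVolume]) -> tuple[ImageVolume, np.ndarray]:
    """Voxel-wise mean across subjects, ignoring NaNs; also returns per-voxel n."""
    if not maps:
        raise ValueError("no maps given")
    stack = np.stack([m.data for m in maps])
    n = np.isfinite(stack).sum(axis=0)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    return ImageVolume(mean, maps[0].voxel_size, units=maps[0].units), n


def voxelwise_welch(group_a_maps: list[ImageVolume], group_b_maps: list[ImageVolume],
                    q: float = 0.05) -> StatMap:
    """Per-voxel Welch test between two groups of co-registered maps.

    Voxels with fewer than two valid subjects in either group are NaN and
    excluded from the FDR correction. The t-map sign follows group A minus
    group B.
    """
    if len(group_a_maps) < 2 or len(group_b_maps) < 2:
        raise ValueError("each group needs >= 2 subjects")
    a = np.stack([m.data for m in group_a_maps])
    b = np.stack([m.data for m in group_b_maps])
    na = np.isfinite(a).sum(axis=0)
    nb = np.isfinite(b).sum(axis=0)
    ok = (na >= 2) & (nb >= 2)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        ma, mb = np.nanmean(a, axis=0), np.nanmean(b, axis=0)
        va = np.nanvar(a, axis=0, ddof=1) / na
        vb = np.nanvar(b, axis=0, ddof=1) / nb
        t = (ma - mb) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
        p = 2.0 * sps.t.sf(np.abs(t), df)
    t = np.where(ok, t, np.nan)
    p = np.where(ok & np.isfinite(p), p, np.nan)
    mask = bh_fdr(p, q)
    vs = group_a_maps[0].voxel_size
    return StatMap(ImageVolume(t, vs), ImageVolume(p, vs), mask, q)


def bh_fdr(pvalues: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask; NaN p-values never reject."""
    p = np.asarray(pvalues, dtype=float)
    mask = np.zeros(p.shape, dtype=bool)
    valid = np.isfinite(p)
    if valid.any():
        rej, *_ = multipletests(p[valid], alpha=q, method="fdr_bh")
        mask[valid] = rej
    return mask
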