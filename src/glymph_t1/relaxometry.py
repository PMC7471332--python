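"""SPGR relaxometry: signal model, linearized T1/M0 fitting, B1 mapping.

The steady-state spoiled gradient echo signal at effective flip angle
``alpha_eff`` is

    S = M0 * sin(alpha_eff) * (1 - E1) / (1 - E1 * cos(alpha_eff)),
    E1 = exp(-TR / T1).

Dividing by sin/tan linearizes this to Y = E1 * X + M0 * (1 - E1) with
Y = S / sin(alpha_eff) and X = S / tan(alpha_eff), so an ordinary
(unweighted) least-squares line through the variable-flip-angle points gives
T1 = -TR / ln(slope) and M0 = intercept / (1 - slope).

Transmit-field (B1+) inhomogeneity scales every nominal flip angle by a
voxel-wise factor kappa. Kappa is measured with the double-angle method from
a fully relaxed (long-TR) pair S(alpha), S(2*alpha):

    kappa = arccos(S(2a) / (2 * S(a))) / alpha.

External angle unit is degrees; radians are used internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .protocol import RareGrid
from .volume import B1Map, ImageVolume, T1Map, voxel_centers

__all__ = [
    "spgr_signal",
    "FitResult",
    "fit_despot1",
    "dam_b1_map",
    "resample_b1",
    "filter_t1",
    "derive_pdw",
    "derive_spgr_lowfa",
]

logger = logging.getLogger(__name__)

T1_MAX_MS = 5000.0


def spgr_signal(m0, t1_ms, alpha_eff_deg, tr_ms):
    """Noiseless SPGR steady-state magnitude signal.

    Broadcasts over array inputs. ``t1_ms`` and ``tr_ms`` must be positive;
    the signal is 0 exactly where ``alpha_eff_deg`` is 0 or ``m0`` is 0.
    """
    m0 = np.asarray(m0, dtype=float)
    t1 = np.asarray(t1_ms, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("t1_ms must be positive")
    if tr_ms <= 0:
        raise ValueError("tr_ms must be positive")
    alpha = np.deg2rad(np.asarray(alpha_eff_deg, dtype=float))
    e1 = np.exp(-tr_ms / t1)
    return m0 * np.sin(alpha) * (1.0 - e1) / (1.0 - e1 * np.cos(alpha))


@dataclass
class FitResult:
    """Voxel-wise DESPOT1 fit output; t1 and m0 are NaN on the same voxels."""

    t1: T1Map
    m0: ImageVolume
    r_squared: ImageVolume
    n_valid: int


def fit_despot1(
    signals: np.ndarray,
    flip_angles_deg,
    tr_ms: float,
    b1map: np.ndarray | B1Map | None = None,
    voxel_size=(1.0, 1.0, 1.0),
) -> FitResult:
    """Linearized unweighted least-squares T1/M0 fit.

    Parameters
    ----------
    signals
        Array of shape ``(n_angles,) + vol_shape`` (vol_shape may be any
        dimensionality, typically 3D).
    flip_angles_deg
        Nominal flip angles matching axis 0 of ``signals``.
    b1map
        Voxel-wise kappa on the same grid (after :func:`resample_b1`), or
        None for kappa = 1. NaN kappa invalidates the voxel.

    Voxels whose linearized slope falls outside (0, 1), with non-finite
    intermediate values, or with all-zero signals are returned as NaN in both
    T1 and M0 — invalid fits are dropped, not repaired.
    """
    signals = np.asarray(signals, dtype=float)
    angles = np.deg2rad(np.asarray(flip_angles_deg, dtype=float))
    if signals.shape[0] != angles.size:
        raise ValueError(
            f"signals first axis ({signals.shape[0]}) must match flip angle count ({angles.size})"
        )
    if angles.size < 2:
        raise ValueError("need at least two flip angles")
    vol_shape = signals.shape[1:]
    if b1map is None:
        kappa = np.ones(vol_shape)
    else:
        kappa = b1map.data if isinstance(b1map, B1Map) else np.asarray(b1map, dtype=float)
        if kappa.shape != vol_shape:
            raise ValueError(f"b1 map shape {kappa.shape} != volume shape {vol_shape}")

    alpha_eff = kappa[None] * angles.reshape((-1,) + (1,) * len(vol_shape))
    with np.errstate(divide="ignore", invalid="ignore"):
        y = signals / np.sin(alpha_eff)
        x = signals / np.tan(alpha_eff)
        n = float(angles.size)
        sx = x.sum(axis=0)
        sy = y.sum(axis=0)
        sxx = (x * x).sum(axis=0)
        sxy = (x * y).sum(axis=0)
        denom = n * sxx - sx * sx
        slope = (n * sxy - sx * sy) / denom
        intercept = (sy - slope * sx) / n

        valid = (
            np.isfinite(slope)
            & np.isfinite(intercept)
            & (slope > 0.0)
            & (slope < 1.0)
            & np.any(signals != 0.0, axis=0)
        )
        t1 = np.where(valid, -tr_ms / np.log(np.where(valid, slope, 0.5)), np.nan)
        m0 = np.where(valid, intercept / (1.0 - slope), np.nan)

        # goodness of fit in the linearized domain
        yhat = slope[None] * x + intercept[None]
        ss_res = np.nansum((y - yhat) ** 2, axis=0)
        ss_tot = np.nansum((y - y.mean(axis=0, keepdims=True)) ** 2, axis=0)
        r2 = np.where(valid, 1.0 - ss_res / np.where(ss_tot > 0, ss_tot, np.inf), np.nan)
        r2 = np.where(valid & (ss_tot == 0), 1.0, r2)

    return FitResult(
        t1=T1Map(t1, voxel_size),
        m0=ImageVolume(m0, voxel_size, units="a.u."),
        r_squared=ImageVolume(r2, voxel_size),
        n_valid=int(valid.sum()),
    )


def dam_b1_map(s_alpha, s_2alpha, alpha_nominal_deg: float = 70.0,
               voxel_size=(1.0, 1.0, 1.0)) -> B1Map:
    """Double-angle B1+ map from a fully relaxed (long-TR) pair.

    kappa = arccos(r) / alpha with r = S(2a) / (2 S(a)); voxels with r
    outside (-1, 1) or with zero/non-finite S(a) become NaN (counted in the
    log — these are domain violations, e.g. background noise).
    """
    s1 = np.asarray(s_alpha.data if isinstance(s_alpha, ImageVolume) else s_alpha, dtype=float)
    s2 = np.asarray(s_2alpha.data if isinstance(s_2alpha, ImageVolume) else s_2alpha, dtype=float)
    if isinstance(s_alpha, ImageVolume):
        voxel_size = s_alpha.voxel_size
    if s1.shape != s2.shape:
        raise ValueError("double-angle volumes must share one grid")
    alpha = np.deg2rad(alpha_nominal_deg)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = s2 / (2.0 * s1)
        ok = np.isfinite(r) & (s1 > 0) & (r > -1.0) & (r < 1.0)
        kappa = np.where(ok, np.arccos(np.clip(r, -1.0, 1.0)) / alpha, np.nan)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("dam_b1_map: %d voxels outside the arccos domain set to NaN", n_bad)
    return B1Map(kappa, voxel_size)


def _fill_nan_nearest(data: np.ndarray) -> np.ndarray:
    """Replace NaNs by the value of the nearest valid voxel."""
    invalid = ~np.isfinite(data)
    if not invalid.any():
        return data
    if invalid.all():
        raise ValueError("cannot resample an all-NaN B1 map")
    idx = ndimage.distance_transform_edt(invalid, return_distances=False, return_indices=True)
    return data[tuple(idx)]


def resample_b1(
    b1map: B1Map | ImageVolume,
    rare_grid: RareGrid,
    target_shape: tuple[int, int, int],
    target_voxel_mm,
    presmooth_sigma_vox: float = 1.0,
) -> B1Map:
    """Resample a RARE-grid B1 map onto the SPGR grid.

    Trilinear interpolation in world coordinates (slice positions include
    the inter-slice gap, i.e. thickness + gap center-to-center spacing).
    Outside the source extent values are extrapolated with the nearest
    sample; NaNs are filled from the nearest valid neighbor first. A light
    Gaussian smooth (``presmooth_sigma_vox`` source voxels; 0 disables)
    suppresses ratio noise before interpolation.
    """
    data = np.asarray(b1map.data, dtype=float)
    if data.shape != tuple(rare_grid.shape):
        raise ValueError(f"B1 data shape {data.shape} != RARE grid {rare_grid.shape}")
    if min(data.shape) < 2:
        raise ValueError("source field needs >= 2 samples per axis")
    data = _fill_nan_nearest(data)
    if presmooth_sigma_vox > 0:
        data = ndimage.gaussian_filter(data, presmooth_sigma_vox, mode="nearest")

    src_axes = rare_grid.axis_centers_mm()
    interp = RegularGridInterpolator(src_axes, data, method="linear",
                                     bounds_error=False, fill_value=None)
    tgt_axes = [voxel_centers(n, v) for n, v in zip(target_shape, target_voxel_mm)]
    # clamp to the source extent: edge-value (nearest) extrapolation per axis
    tgt_axes = [np.clip(t, s[0], s[-1]) for t, s in zip(tgt_axes, src_axes)]
    mesh = np.meshgrid(*tgt_axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    out = interp(pts).reshape(target_shape)
    return B1Map(out, tuple(target_voxel_mm))


def filter_t1(t1map: T1Map | ImageVolume, max_ms: float = T1_MAX_MS) -> tuple[T1Map, int]:
    """Exclude implausible T1 values: strictly above ``max_ms`` or <= 0 -> NaN.

    Returns the filtered map and the number of newly excluded voxels.
    Idempotent: already-NaN voxels are not recounted.
    """
    data = np.asarray(t1map.data, dtype=float).copy()
    bad = np.isfinite(data) & ((data > max_ms) | (data <= 0.0))
    data[bad] = np.nan
    return T1Map(data, t1map.voxel_size), int(bad.sum())


def derive_pdw(fit: FitResult, for_display: bool = False) -> ImageVolume:
    """Proton-density-weighted image: the fitted M0 map.

    ``for_display=True`` returns a copy with NaNs set to 0 (visualization);
    the analysis copy keeps NaNs.
    """
    data = fit.m0.data.copy()
    if for_display:
        data = np.nan_to_num(data, nan=0.0)
    return ImageVolume(data, fit.m0.voxel_size, units="a.u.")


def derive_spgr_lowfa(vol_2deg: ImageVolume, vol_5deg: ImageVolume) -> ImageVolume:
    """Summed low-flip-angle (2 + 5 degree) SPGR anatomical image."""
    if vol_2deg.shape != vol_5deg.shape:
        raise ValueError("low-FA volumes must share one grid")
    return ImageVolume(vol_2deg.data + vol_5deg.data, vol_2deg.voxel_size, units="a.u.")
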