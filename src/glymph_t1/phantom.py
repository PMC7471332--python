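"""Digital mouse head-and-neck phantom and MRI acquisition simulator.

The phantom is parametric geometry, not a registered atlas: nested
ellipsoids/boxes tagged with region names stand in for mouse anatomy, on an
18 mm cube imaged at 0.18 mm isotropic (100^3) by default. A "subject" is
the planted ground truth (labels, pre/post-contrast T1, M0, Gd concentration
C, transmit field B1) plus the two simulated acquisitions: the six-angle
VFA-SPGR stack on the fine grid and the fully relaxed 70/140-degree RARE
pair on the coarse gapped grid.

Group design mirrors the study: a saline control group (C = 0 everywhere,
n = 9 after pooling) and two Gd-DOTA groups under different anesthetics
(KX, n = 7; ISO, n = 7). Per-region concentrations are obtained by
inverting the relaxivity relation from target fractional T1 reductions
(KX: brainstem 50%, olfactory bulb 40%, hypothalamus 35%, cerebellum 27%;
lymph nodes from their group-mean pre/post T1). Magnitude noise is Rician;
inter-subject variability is multiplicative Gaussian jitter on region T1
and C.

Modeling assumptions: TE/T2* decay is absorbed into M0 (single-TE
protocol); the RARE pair is fully relaxed (TR 10 s >> T1), so its signal is
proportional to M0 * sin(kappa * alpha) after box-averaging the truth onto
the coarse grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .protocol import AcquisitionProtocol, RareGrid, default_protocol
from .quantify import DEFAULT_R1, apply_relaxivity, gd_concentration
from .relaxometry import spgr_signal
from .volume import B1Map, ImageVolume, voxel_centers

__all__ = [
    "Compartment",
    "PhantomSpec",
    "GroupSpec",
    "GroundTruth",
    "SubjectDataset",
    "build_phantom",
    "make_group_truth",
    "simulate_b1_field",
    "simulate_vfa_spgr",
    "simulate_dam_rare",
    "simulate_subject",
    "concentration_for_reduction",
    "default_phantom_spec",
    "default_groups",
    "default_noise_sigma",
    "BRAIN_REGION_TAGS",
]

BRAIN_REGION_TAGS = (
    "brain",
    "brainstem",
    "cerebellum",
    "hippocampus",
    "hypothalamus",
    "midbrain",
    "olfactory bulb",
    "thalamus",
    "CSF",
)


@dataclass(frozen=True)
class Compartment:
    """One parametric tissue compartment.

    ``geometry`` is "ellipsoid" (center + semi-axes, mm) or "box" (center +
    half-extents, mm). Compartments listed later overwrite earlier ones
    where they overlap (last-listed wins).
    """

    label: int
    name: str
    geometry: str
    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    t1_pre_ms: float
    m0: float
    region_tag: str

    def __post_init__(self) -> None:
        if self.label <= 0:
            raise ValueError("compartment labels must be > 0 (0 is background)")
        if self.geometry not in ("ellipsoid", "box"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if not 100.0 < self.t1_pre_ms <= 4000.0:
            raise ValueError(f"{self.name}: T1_pre must lie in (100, 4000] ms")
        if self.m0 < 0:
            raise ValueError("M0 must be non-negative")


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    compartments: tuple[Compartment, ...]

    def __post_init__(self) -> None:
        labels = [c.label for c in self.compartments]
        if len(set(labels)) != len(labels):
            raise ValueError("compartment labels must be unique")
        fov = [n * v for n, v in zip(self.grid_shape, self.voxel_size_mm)]
        for c in self.compartments:
            for ax in range(3):
                if c.center_mm[ax] - c.radii_mm[ax] < 0 or c.center_mm[ax] + c.radii_mm[ax] > fov[ax]:
                    raise ValueError(f"compartment {c.name!r} extends outside the grid")

    @property
    def fov_mm(self) -> tuple[float, float, float]:
        return tuple(n * v for n, v in zip(self.grid_shape, self.voxel_size_mm))

    def labels_for_tag(self, tag: str) -> list[int]:
        return [c.label for c in self.compartments if c.region_tag == tag]

    def names(self) -> dict[int, str]:
        """Label -> region-tag map for building an ROISet."""
        return {c.label: c.region_tag for c in self.compartments}


@dataclass(frozen=True)
class GroupSpec:
    """Study-group recipe: per-region Gd concentration and variability."""

    group_name: str
    concentrations_mM: dict[str, float]  # by region_tag; absent = 0
    r1: float = DEFAULT_R1
    n_subjects: int = 1
    t1_jitter_frac: float = 0.03
    c_jitter_frac: float = 0.03
    noise_sigma: float = 0.0  # Rician sigma, same arbitrary units as M0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.concentrations_mM.values()):
            raise ValueError("concentrations must be non-negative")
        if self.r1 <= 0:
            raise ValueError("r1 must be positive")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass
class GroundTruth:
    """The phantom's planted truth on the fine (SPGR) grid."""

    labels: np.ndarray
    t1_pre: np.ndarray  # ms
    t1_post: np.ndarray  # ms
    m0: np.ndarray
    c: np.ndarray  # mM
    b1: np.ndarray  # kappa
    voxel_size_mm: tuple[float, float, float]

    def copy(self) -> "GroundTruth":
        return GroundTruth(
            self.labels.copy(), self.t1_pre.copy(), self.t1_post.copy(),
            self.m0.copy(), self.c.copy(), self.b1.copy(), self.voxel_size_mm,
        )


@dataclass
class SubjectDataset:
    subject_id: str
    group_name: str
    spgr_volumes: list[ImageVolume]
    dam_volumes: tuple[ImageVolume, ImageVolume]
    truth: GroundTruth
    roi_labels: np.ndarray


def _compartment_mask(comp: Compartment, shape, voxel_size) -> np.ndarray:
    axes = [voxel_centers(n, v) - c for n, v, c in zip(shape, voxel_size, comp.center_mm)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij", sparse=True)
    rx, ry, rz = comp.radii_mm
    if comp.geometry == "ellipsoid":
        return (gx / rx) ** 2 + (gy / ry) ** 2 + (gz / rz) ** 2 <= 1.0
    return (np.abs(gx) <= rx) & (np.abs(gy) <= ry) & (np.abs(gz) <= rz)


def build_phantom(spec: PhantomSpec) -> GroundTruth:
    """Rasterize the compartment list into piecewise-constant truth volumes.

    Background (label 0) has M0 = 0 and a nominal T1 of 1000 ms (it emits no
    signal, so the value never matters). Returns pre-contrast truth: T1_post
    = T1_pre, C = 0, B1 = 1.
    """
    shape = tuple(spec.grid_shape)
    labels = np.zeros(shape, dtype=np.int32)
    t1 = np.full(shape, 1000.0)
    m0 = np.zeros(shape)
    for comp in spec.compartments:
        mask = _compartment_mask(comp, shape, spec.voxel_size_mm)
        if not mask.any():
            warnings.warn(f"compartment {comp.name!r} rasterizes to zero voxels")
            continue
        labels[mask] = comp.label
        t1[mask] = comp.t1_pre_ms
        m0[mask] = comp.m0
    return GroundTruth(
        labels=labels, t1_pre=t1, t1_post=t1.copy(), m0=m0,
        c=np.zeros(shape), b1=np.ones(shape), voxel_size_mm=tuple(spec.voxel_size_mm),
    )


def make_group_truth(truth_pre: GroundTruth, spec: PhantomSpec, group: GroupSpec,
                     subject_index: int) -> GroundTruth:
    """Plant a subject's concentrations and jitter into pre-contrast truth.

    Deterministic in (group.seed, subject_index): the same pair always
    yields bit-identical truth. Jitter is multiplicative Gaussian on each
    compartment's T1_pre and on each region's C, clipped so T1 stays
    positive. Unknown region names raise.
    """
    known_tags = {c.region_tag for c in spec.compartments}
    unknown = sorted(set(group.concentrations_mM) - known_tags)
    if unknown:
        raise ValueError(f"group {group.group_name!r} names unknown regions: {unknown}")

    rng = np.random.default_rng(np.random.SeedSequence(group.seed, spawn_key=(subject_index,)))
    truth = truth_pre.copy()

    for comp in spec.compartments:  # deterministic compartment order
        mask = truth.labels == comp.label
        t1_jit = 1.0 + group.t1_jitter_frac * rng.standard_normal()
        truth.t1_pre[mask] = comp.t1_pre_ms * max(t1_jit, 0.5)
        c_region = group.concentrations_mM.get(comp.region_tag, 0.0)
        if c_region > 0:
            c_jit = 1.0 + group.c_jitter_frac * rng.standard_normal()
            truth.c[mask] = c_region * max(c_jit, 0.0)

    # exact equality on the C = 0 support (avoids 1/(1/T1) rounding)
    truth.t1_post = np.where(truth.c > 0,
                             apply_relaxivity(truth.t1_pre, truth.c, group.r1),
                             truth.t1_pre)
    return truth


def simulate_b1_field(shape, voxel_size_mm, amplitude: float = 0.2,
                      length_scale_mm: float = 4.0, seed: int = 0) -> B1Map:
    """Smooth random transmit-field profile with mean exactly 1.

    A Gaussian random field (white noise smoothed at ``length_scale_mm``) is
    centered and rescaled so values span at most [1 - amplitude,
    1 + amplitude]. ``amplitude`` must lie in [0, 0.5); 0 returns a field
    identically 1.
    """
    if not 0.0 <= amplitude < 0.5:
        raise ValueError("B1 amplitude must lie in [0, 0.5)")
    shape = tuple(int(n) for n in shape)
    if amplitude == 0.0:
        return B1Map(np.ones(shape), tuple(voxel_size_mm))
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(shape)
    sigma_vox = [length_scale_mm / v for v in voxel_size_mm]
    smooth = ndimage.gaussian_filter(noise, sigma_vox, mode="reflect")
    smooth -= smooth.mean()
    peak = np.abs(smooth).max()
    field_ = 1.0 + amplitude * (smooth / peak if peak > 0 else smooth)
    return B1Map(field_, tuple(voxel_size_mm))


def _rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of the signal plus complex Gaussian noise."""
    if sigma == 0:
        return signal
    re = signal + sigma * rng.standard_normal(signal.shape)
    im = sigma * rng.standard_normal(signal.shape)
    return np.hypot(re, im)


def simulate_vfa_spgr(truth: GroundTruth, protocol: AcquisitionProtocol,
                      noise_sigma: float = 0.0, seed: int = 0) -> list[ImageVolume]:
    """Simulate the variable-flip-angle SPGR stack on the fine grid.

    Each voxel's noiseless value is the SPGR closed form evaluated at the
    B1-scaled flip angle; Rician noise of scale ``noise_sigma`` (same
    arbitrary units as M0) is then applied. ``noise_sigma = 0`` returns the
    noiseless signal exactly.
    """
    if tuple(truth.t1_post.shape) != tuple(protocol.spgr_shape):
        raise ValueError("truth grid does not match the protocol SPGR grid")
    rng = np.random.default_rng(seed)
    vols = []
    for alpha in protocol.flip_angles_deg:
        s = spgr_signal(truth.m0, truth.t1_post, truth.b1 * alpha, protocol.tr_ms)
        vols.append(ImageVolume(_rician(s, noise_sigma, rng), truth.voxel_size_mm, units="a.u."))
    return vols


def _rare_slab_average(fine: np.ndarray, fine_voxel, grid: RareGrid) -> np.ndarray:
    """Box-average a fine-grid volume onto the gapped RARE grid.

    In-plane: mean over fine voxels whose centers fall inside each coarse
    pixel. Slice axis: mean over fine voxels whose centers lie within the
    excited slab (slice center +/- thickness/2); the gap is not sampled.
    """
    nx, ny, nz = grid.shape
    out = np.zeros(grid.shape)
    # in-plane bin index per fine voxel
    def bins(n_fine, v_fine, pitch, n_coarse):
        x = voxel_centers(n_fine, v_fine)
        b = np.floor(x / pitch).astype(int)
        ok = (b >= 0) & (b < n_coarse)
        return b, ok

    bx, okx = bins(fine.shape[0], fine_voxel[0], grid.in_plane_mm, nx)
    by, oky = bins(fine.shape[1], fine_voxel[1], grid.in_plane_mm, ny)
    zf = voxel_centers(fine.shape[2], fine_voxel[2])
    zc = voxel_centers(nz, grid.slice_spacing_mm)
    # fine z indices belonging to each slice's excited slab
    half = grid.slice_thickness_mm / 2.0
    for k in range(nz):
        in_slab = np.abs(zf - zc[k]) <= half + 1e-9
        if not in_slab.any():
            continue
        sub = fine[:, :, in_slab].mean(axis=2)
        plane = np.zeros((nx, ny))
        cnt = np.zeros((nx, ny))
        np.add.at(plane, (bx[okx][:, None], by[oky][None, :]),
                  sub[np.ix_(okx, oky)])
        np.add.at(cnt, (bx[okx][:, None], by[oky][None, :]), 1.0)
        with np.errstate(invalid="ignore"):
            out[:, :, k] = np.where(cnt > 0, plane / cnt, 0.0)
    return out


def simulate_dam_rare(truth: GroundTruth, protocol: AcquisitionProtocol,
                      noise_sigma: float = 0.0, seed: int = 0,
                      ) -> tuple[ImageVolume, ImageVolume]:
    """Simulate the fully relaxed double-angle RARE pair on the coarse grid.

    With TR = 10 s >> T1 the magnetization recovers completely between
    excitations, so S(alpha) is proportional to M0 * sin(kappa * alpha)
    after box-averaging M0 and kappa onto the RARE grid. Returns the
    (alpha, 2*alpha) volumes, Rician noise applied independently.
    """
    grid = protocol.rare_grid
    m0c = _rare_slab_average(truth.m0, truth.voxel_size_mm, grid)
    b1c = _rare_slab_average(truth.b1, truth.voxel_size_mm, grid)
    rng = np.random.default_rng(seed)
    vols = []
    for alpha in protocol.dam_angles_deg:
        s = m0c * np.sin(np.deg2rad(b1c * alpha))
        vols.append(ImageVolume(_rician(s, noise_sigma, rng), grid.voxel_size, units="a.u."))
    return vols[0], vols[1]


def simulate_subject(spec: PhantomSpec, group: GroupSpec, subject_index: int,
                     protocol: AcquisitionProtocol | None = None,
                     b1_amplitude: float = 0.2, b1_length_scale_mm: float = 4.0,
                     ) -> SubjectDataset:
    """Build one subject: truth + B1 field + both simulated acquisitions.

    Stage seeds derive from (group.seed, subject_index) through a stable
    SeedSequence spawn so every subject is bit-reproducible.
    """
    if protocol is None:
        protocol = default_protocol(spec.grid_shape, spec.fov_mm[0])
    ss = np.random.SeedSequence(group.seed, spawn_key=(subject_index,))
    seed_b1, seed_spgr, seed_dam = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    truth_pre = build_phantom(spec)
    truth = make_group_truth(truth_pre, spec, group, subject_index)
    truth.b1 = simulate_b1_field(spec.grid_shape, spec.voxel_size_mm,
                                 b1_amplitude, b1_length_scale_mm, seed_b1).data
    spgr = simulate_vfa_spgr(truth, protocol, group.noise_sigma, seed_spgr)
    dam = simulate_dam_rare(truth, protocol, group.noise_sigma, seed_dam)
    return SubjectDataset(
        subject_id=f"{group.group_name}_{subject_index:02d}",
        group_name=group.group_name,
        spgr_volumes=spgr, dam_volumes=dam, truth=truth, roi_labels=truth.labels,
    )


def concentration_for_reduction(t1_pre_ms: float, reduction_frac: float,
                                r1: float = DEFAULT_R1) -> float:
    """Concentration (mM) producing a given fractional T1 reduction."""
    if not 0.0 <= reduction_frac < 1.0:
        raise ValueError("reduction fraction must lie in [0, 1)")
    if reduction_frac == 0.0:
        return 0.0
    t1_post = t1_pre_ms * (1.0 - reduction_frac)
    return gd_concentration(t1_post, t1_pre_ms, r1)


# --- default study conditions ------------------------------------------------

# Control (pre-contrast) T1 per compartment, ms. Brain tissue sits in the
# 1800-2200 ms band typical of 9.4 T mouse brain, CSF at ~3000 ms; lymph-node
# values equal the saline group means of the study design.
_DEFAULT_T1 = {
    "muscle": 1500.0,
    "brain": 2000.0,
    "brainstem": 1950.0,
    "cerebellum": 1900.0,
    "hippocampus": 2000.0,
    "hypothalamus": 2050.0,
    "midbrain": 1950.0,
    "olfactory bulb": 2100.0,
    "thalamus": 2000.0,
    "CSF": 3000.0,
    "dcLN": 1895.0,
    "smLN": 2172.0,
}

_DEFAULT_M0 = {
    "muscle": 900.0, "CSF": 1200.0, "dcLN": 950.0, "smLN": 950.0,
}

# Target fractional post-contrast T1 reductions planted per group. KX brain
# values follow the measured regional profile (brainstem 50%, olfactory bulb
# 40%, hypothalamus 35%, cerebellum 27%); node values reproduce the group
# mean pre/post T1 pairs (dcLN 1895 -> 1093 ms, smLN 2172 -> 1853 ms). The
# ISO profile is roughly half the KX brain uptake, consistent with the
# smaller whole-brain cluster under isoflurane.
KX_REDUCTIONS = {
    "brainstem": 0.50,
    "olfactory bulb": 0.40,
    "hypothalamus": 0.35,
    "midbrain": 0.30,
    "cerebellum": 0.27,
    "hippocampus": 0.15,
    "thalamus": 0.12,
    "brain": 0.08,
    "CSF": 0.60,
    "dcLN": 1.0 - 1093.0 / 1895.0,
    "smLN": 1.0 - 1853.0 / 2172.0,
}

ISO_REDUCTIONS = {
    "brainstem": 0.45,
    "olfactory bulb": 0.20,
    "hypothalamus": 0.17,
    "midbrain": 0.15,
    "cerebellum": 0.22,
    "hippocampus": 0.07,
    "thalamus": 0.05,
    "brain": 0.04,
    "CSF": 0.55,
    "dcLN": 0.30,
    "smLN": 0.10,
}


def _default_compartments(fov: float) -> tuple[Compartment, ...]:
    """Parametric head-and-neck anatomy scaled to an ``fov`` mm cube.

    Axis convention: x = left-right, y = rostro-caudal (olfactory bulb at
    small y), z = ventro-dorsal (neck/nodes at small z, brain at large z).
    """
    s = fov / 18.0  # geometry is authored on the 18 mm cube

    def C(label, name, geom, center, radii, tag=None):
        tag = tag or name
        return Compartment(label, name, geom,
                           tuple(c * s for c in center), tuple(r * s for r in radii),
                           _DEFAULT_T1[tag], _DEFAULT_M0.get(tag, 1000.0), tag)

    return (
        C(1, "muscle", "ellipsoid", (9, 9, 9), (8.5, 8.5, 8.5)),
        C(2, "brain", "ellipsoid", (9, 9, 11.5), (4.2, 6.0, 3.5)),
        C(3, "brainstem", "ellipsoid", (9, 13.5, 10.0), (1.6, 2.0, 1.6)),
        C(4, "cerebellum", "ellipsoid", (9, 13.0, 12.8), (2.3, 1.6, 1.5)),
        C(5, "hippocampus", "ellipsoid", (9, 10.8, 12.6), (2.2, 1.2, 1.0)),
        C(6, "hypothalamus", "ellipsoid", (9, 9.5, 9.3), (1.6, 1.4, 1.0)),
        C(7, "midbrain", "ellipsoid", (9, 11.5, 11.0), (1.5, 1.3, 1.3)),
        C(8, "olfactory bulb", "ellipsoid", (9, 3.8, 11.5), (1.5, 1.3, 1.5)),
        C(9, "thalamus", "ellipsoid", (9, 9.0, 11.8), (1.7, 1.5, 1.3)),
        C(10, "lateral ventricle L", "ellipsoid", (7.6, 8.2, 12.5), (0.5, 1.2, 0.6), "CSF"),
        C(11, "lateral ventricle R", "ellipsoid", (10.4, 8.2, 12.5), (0.5, 1.2, 0.6), "CSF"),
        C(12, "third ventricle", "ellipsoid", (9, 9.2, 10.6), (0.3, 1.0, 0.8), "CSF"),
        C(13, "dcLN L", "ellipsoid", (6.5, 13.0, 5.0), (0.4, 0.6, 0.4), "dcLN"),
        C(14, "dcLN R", "ellipsoid", (11.5, 13.0, 5.0), (0.4, 0.6, 0.4), "dcLN"),
        C(15, "smLN L", "ellipsoid", (6.0, 8.0, 3.5), (0.8, 1.0, 0.8), "smLN"),
        C(16, "smLN R", "ellipsoid", (12.0, 8.0, 3.5), (0.8, 1.0, 0.8), "smLN"),
    )


def default_phantom_spec(grid_shape=(100, 100, 100), fov_mm: float = 18.0) -> PhantomSpec:
    grid_shape = tuple(int(n) for n in grid_shape)
    voxel = tuple(fov_mm / n for n in grid_shape)
    return PhantomSpec(grid_shape, voxel, _default_compartments(fov_mm))


def default_noise_sigma(snr: float = 50.0, m0: float = 1000.0, t1_ms: float = 2000.0,
                        protocol: AcquisitionProtocol | None = None) -> float:
    """Rician sigma giving the requested SNR at the peak tissue SPGR signal."""
    if protocol is None:
        protocol = AcquisitionProtocol()
    peak = max(spgr_signal(m0, t1_ms, a, protocol.tr_ms) for a in protocol.flip_angles_deg)
    return float(peak / snr)


def default_groups(noise_snr: float | None = 50.0, r1: float = DEFAULT_R1,
                   seed: int = 0) -> list[GroupSpec]:
    """The three study groups: control saline (n=9), KX+Gd (n=7), ISO+Gd (n=7)."""
    sigma = 0.0 if noise_snr is None else default_noise_sigma(noise_snr)

    def conc(reductions):
        return {tag: concentration_for_reduction(_DEFAULT_T1[tag], f, r1)
                for tag, f in reductions.items()}

    return [
        GroupSpec("control", {}, r1=r1, n_subjects=9, noise_sigma=sigma, seed=seed),
        GroupSpec("KX+Gd", conc(KX_REDUCTIONS), r1=r1, n_subjects=7,
                  noise_sigma=sigma, seed=seed + 1),
        GroupSpec("ISO+Gd", conc(ISO_REDUCTIONS), r1=r1, n_subjects=7,
                  noise_sigma=sigma, seed=seed + 2),
    ]
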