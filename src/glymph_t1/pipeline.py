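"""End-to-end driver: simulate -> fit -> quantify -> group statistics.

The pipeline reproduces the study workflow on a synthetic cohort: for each
subject it simulates the two acquisitions, maps B1 with the double-angle
method, fits the linearized VFA-SPGR model with B1 correction, filters the
T1 map, extracts trimmed ROI means, Gd concentrations (against the control
group's pre-contrast regional means) and the GS cluster, and finally runs
Welch tests, percent reductions and a voxel-wise comparison between the two
anesthetic groups. Phantom subjects share one space by construction, so no
registration step exists.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import GroupConfig, PipelineConfig
from .group_stats import TestResult, smooth_gaussian, voxelwise_welch, welch_t
from .io import file_sha256, write_json, write_labels, write_volume
from .phantom import (
    BRAIN_REGION_TAGS,
    GroupSpec,
    PhantomSpec,
    SubjectDataset,
    concentration_for_reduction,
    default_noise_sigma,
    default_phantom_spec,
    simulate_subject,
)
from .protocol import AcquisitionProtocol, default_protocol
from .quantify import ROISet, gd_concentration, gs_cluster, percent_reduction, roi_trimmed_mean
from .relaxometry import FitResult, dam_b1_map, filter_t1, fit_despot1, resample_b1
from .volume import T1Map

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "fit_subject", "generate_cohort", "PipelineError", "SubjectResult"]

REPORT_REGIONS = (
    "brainstem", "cerebellum", "hippocampus", "hypothalamus",
    "midbrain", "olfactory bulb", "thalamus", "dcLN", "smLN",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, subject: str | None, cause: Exception):
        self.stage, self.subject = stage, subject
        super().__init__(f"stage {stage!r}" + (f" subject {subject!r}" if subject else "")
                         + f" failed: {cause}")


@dataclass
class SubjectResult:
    subject_id: str
    group_name: str
    t1: T1Map
    region_stats: dict[str, object]
    cluster_n: int
    cluster_mm3: float
    n_valid: int
    n_excluded: int


def _protocol_from_config(cfg: PipelineConfig) -> AcquisitionProtocol:
    base = default_protocol(tuple(cfg.phantom.grid_shape), cfg.phantom.fov_mm)
    return dataclasses.replace(
        base,
        tr_ms=cfg.protocol.tr_ms,
        te_ms=cfg.protocol.te_ms,
        flip_angles_deg=tuple(cfg.protocol.flip_angles_deg),
        dam_angles_deg=tuple(cfg.protocol.dam_angles_deg),
    )


def _group_specs(cfg: PipelineConfig, spec: PhantomSpec) -> list[GroupSpec]:
    t1_by_tag = {c.region_tag: c.t1_pre_ms for c in spec.compartments}
    sigma = 0.0 if cfg.simulation.noise_snr is None else default_noise_sigma(cfg.simulation.noise_snr)
    out = []
    for gi, g in enumerate(cfg.groups):
        unknown = sorted(set(g.reductions) - set(t1_by_tag))
        if unknown:
            raise ValueError(f"group {g.name!r} names unknown regions: {unknown}")
        conc = {tag: concentration_for_reduction(t1_by_tag[tag], f, cfg.analysis.r1)
                for tag, f in g.reductions.items()}
        out.append(GroupSpec(g.name, conc, r1=cfg.analysis.r1, n_subjects=g.n_subjects,
                             t1_jitter_frac=g.t1_jitter_frac, c_jitter_frac=g.c_jitter_frac,
                             noise_sigma=sigma, seed=cfg.seed + gi))
    return out


def fit_subject(subject: SubjectDataset, protocol: AcquisitionProtocol,
                b1_mode: str = "dam") -> tuple[FitResult, T1Map, int]:
    """Double-angle B1 map, resample, linearized fit, T1 filter.

    ``b1_mode``: "dam" (measure B1 from the RARE pair) or "unity" (assume a
    flat transmit field). Returns (fit, filtered T1 map, n excluded).
    """
    stack = np.stack([v.data for v in subject.spgr_volumes])
    voxel = subject.spgr_volumes[0].voxel_size
    if b1_mode == "dam":
        b1_coarse = dam_b1_map(*subject.dam_volumes, alpha_nominal_deg=protocol.dam_angles_deg[0])
        b1 = resample_b1(b1_coarse, protocol.rare_grid, stack.shape[1:], voxel)
    elif b1_mode == "unity":
        b1 = None
    else:
        raise ValueError(f"unknown b1_mode {b1_mode!r}")
    fit = fit_despot1(stack, protocol.flip_angles_deg, protocol.tr_ms, b1, voxel_size=voxel)
    t1f, n_excluded = filter_t1(fit.t1)
    return fit, t1f, n_excluded


def _quantify_subject(subject: SubjectDataset, t1f: T1Map, roi: ROISet,
                      cfg: PipelineConfig) -> SubjectResult:
    stats = {}
    for region in REPORT_REGIONS:
        stats[region] = roi_trimmed_mean(t1f, roi.get_mask(region),
                                         cfg.analysis.trim_percentile, region)
    brain_mask = np.isin(subject.roi_labels,
                         [lab for lab, n in roi.names.items() if n in BRAIN_REGION_TAGS])
    cluster = gs_cluster(t1f, brain_mask, cfg.analysis.cluster_lo_ms, cfg.analysis.cluster_hi_ms)
    frac_nan = np.mean(~np.isfinite(t1f.data[brain_mask]))
    if frac_nan > 0.10:
        logger.warning("subject %s: %.1f%% of brain voxels failed the T1 fit",
                       subject.subject_id, 100 * frac_nan)
    return SubjectResult(subject.subject_id, subject.group_name, t1f, stats,
                         cluster.n_voxels, cluster.volume_mm3, 0, 0)


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None,
                 force: bool = False, write_volumes: bool = False) -> dict:
    """Run the full synthetic study and return the summary report.

    Returns a dict with ``subjects`` (tidy per-subject rows), ``groups``
    (region mean +/- SD per group), ``tests`` (Welch results), ``reductions``
    (percent reductions vs control), ``voxelwise`` (significant-voxel counts)
    and ``manifest``. With ``out_dir`` the tidy CSV, summary JSON, statistic
    maps and manifest are written to disk.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        if out.exists() and any(out.iterdir()) and not force:
            raise FileExistsError(f"output directory {out} exists; pass force=True to overwrite")
        out.mkdir(parents=True, exist_ok=True)

    t_start = time.time()
    spec = default_phantom_spec(tuple(cfg.phantom.grid_shape), cfg.phantom.fov_mm)
    protocol = _protocol_from_config(cfg)
    groups = _group_specs(cfg, spec)
    roi_names = spec.names()

    results: dict[str, list[SubjectResult]] = {}
    t1_maps: dict[str, list[T1Map]] = {}
    written: list[Path] = []
    for group in groups:
        results[group.group_name] = []
        t1_maps[group.group_name] = []
        for si in range(group.n_subjects):
            subj_id = f"{group.group_name}_{si:02d}"
            try:
                subject = simulate_subject(spec, group, si, protocol,
                                           cfg.simulation.b1_amplitude,
                                           cfg.simulation.b1_length_scale_mm)
            except Exception as exc:
                raise PipelineError("simulate", subj_id, exc) from exc
            try:
                fit, t1f, n_excl = fit_subject(subject, protocol)
            except Exception as exc:
                raise PipelineError("fit", subj_id, exc) from exc
            try:
                roi = ROISet(subject.roi_labels, roi_names)
                res = _quantify_subject(subject, t1f, roi, cfg)
                res.n_valid, res.n_excluded = fit.n_valid, n_excl
            except Exception as exc:
                raise PipelineError("quantify", subj_id, exc) from exc
            results[group.group_name].append(res)
            t1_maps[group.group_name].append(t1f)
            if out is not None and write_volumes:
                written.append(write_volume(t1f, out / "maps" / f"{subj_id}_t1.nii.gz"))

    # --- tidy per-subject table ---------------------------------------------
    rows = []
    for gname, subs in results.items():
        for r in subs:
            for region, st in r.region_stats.items():
                rows.append(dict(subject=r.subject_id, group=gname, region=region,
                                 mean_t1=st.mean_t1, n_voxels=st.n_voxels, n_used=st.n_used,
                                 cluster_count=r.cluster_n, volume_mm3=r.cluster_mm3))
    table = pd.DataFrame(rows)

    # --- control pre-contrast means and Gd concentrations --------------------
    control_name = cfg.groups[0].name
    control_means = {
        region: float(np.mean([r.region_stats[region].mean_t1 for r in results[control_name]]))
        for region in REPORT_REGIONS
    } if results.get(control_name) else {}

    concentrations = {}
    for gname, subs in results.items():
        if gname == control_name or not control_means:
            continue
        concentrations[gname] = {
            region: float(gd_concentration(
                np.mean([r.region_stats[region].mean_t1 for r in subs]),
                control_means[region], cfg.analysis.r1))
            for region in REPORT_REGIONS
        }

    # --- group summaries and Welch tests -------------------------------------
    def region_values(gname, region):
        return np.array([r.region_stats[region].mean_t1 for r in results[gname]])

    group_summary = {}
    for gname in results:
        group_summary[gname] = {
            "n": len(results[gname]),
            "regions": {region: {
                "mean": float(region_values(gname, region).mean()),
                "sd": float(region_values(gname, region).std(ddof=1))
                if len(results[gname]) > 1 else 0.0,
            } for region in REPORT_REGIONS},
            "cluster": {
                "mean": float(np.mean([r.cluster_n for r in results[gname]])),
                "sd": float(np.std([r.cluster_n for r in results[gname]], ddof=1))
                if len(results[gname]) > 1 else 0.0,
            },
        }

    def _test_dict(res: TestResult):
        return {"t": res.statistic, "df": res.df, "p": res.p, "mean_diff": res.mean_diff}

    tests = []
    gnames = list(results)
    for i, ga in enumerate(gnames):
        for gb in gnames[i + 1:]:
            if len(results[ga]) < 2 or len(results[gb]) < 2:
                continue
            for region in REPORT_REGIONS:
                res = welch_t(region_values(ga, region), region_values(gb, region))
                tests.append({"contrast": f"{ga}:{gb}", "measure": region, **_test_dict(res)})
            res = welch_t([r.cluster_n for r in results[ga]],
                          [r.cluster_n for r in results[gb]])
            tests.append({"contrast": f"{ga}:{gb}", "measure": "GS-cluster", **_test_dict(res)})

    reductions = {}
    for gname in gnames:
        if gname == control_name or not control_means:
            continue
        reductions[gname] = {
            region: percent_reduction(group_summary[gname]["regions"][region]["mean"],
                                      control_means[region])
            for region in REPORT_REGIONS
        }

    # --- voxel-wise comparison between the two Gd groups ----------------------
    voxelwise = None
    gd_groups = [g for g in gnames if g != control_name and len(results[g]) >= 2]
    if len(gd_groups) >= 2:
        ga, gb = gd_groups[0], gd_groups[1]
        sm_a = [smooth_gaussian(m, cfg.analysis.smoothing_fwhm_mm) for m in t1_maps[ga]]
        sm_b = [smooth_gaussian(m, cfg.analysis.smoothing_fwhm_mm) for m in t1_maps[gb]]
        stat = voxelwise_welch(sm_a, sm_b, q=cfg.analysis.fdr_q)
        voxelwise = {
            "contrast": f"{ga}:{gb}",
            "q": cfg.analysis.fdr_q,
            "n_tested": int(np.isfinite(stat.p_map.data).sum()),
            "n_significant": int(stat.fdr_mask.sum()),
        }
        if out is not None:
            written.append(write_volume(stat.t_map, out / "stats" / "voxelwise_t.nii.gz"))
            written.append(write_volume(stat.p_map, out / "stats" / "voxelwise_p.nii.gz"))
            written.append(write_labels(stat.fdr_mask.astype(np.int16),
                                        stat.t_map.voxel_size,
                                        out / "stats" / "voxelwise_fdr_mask.nii.gz"))

    summary = {
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "groups": group_summary,
        "control_pre_means": control_means,
        "concentrations_mM": concentrations,
        "reductions_pct": reductions,
        "tests": tests,
        "voxelwise": voxelwise,
    }

    manifest = {
        "config_hash": summary["config_hash"],
        "version": __version__,
        "elapsed_s": round(time.time() - t_start, 3),
        "files": {},
    }
    if out is not None:
        table.to_csv(out / "subjects.csv", index=False)
        written.append(out / "subjects.csv")
        write_json(summary, out / "summary.json")
        written.append(out / "summary.json")
        manifest["files"] = {str(p.relative_to(out)): file_sha256(p) for p in written}
        write_json(manifest, out / "manifest.json")

    summary["manifest"] = manifest
    summary["table"] = table
    return summary


def _config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(cfg.model_dump_json().encode()).hexdigest()[:16]


def generate_cohort(cfg: PipelineConfig, out_dir: str | Path, force: bool = False) -> dict:
    """Simulate every subject and write the raw cohort to disk.

    Per subject: the SPGR stack, the DAM pair, the planted truth maps and
    the ROI label volume, all NIfTI; plus a cohort manifest JSON listing
    files, groups, seeds and checksums. Bit-reproducible for a fixed config.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} exists; use force to overwrite")
    out.mkdir(parents=True, exist_ok=True)

    spec = default_phantom_spec(tuple(cfg.phantom.grid_shape), cfg.phantom.fov_mm)
    protocol = _protocol_from_config(cfg)
    groups = _group_specs(cfg, spec)

    manifest = {"config_hash": _config_hash(cfg), "version": __version__, "subjects": []}
    for group in groups:
        for si in range(group.n_subjects):
            subject = simulate_subject(spec, group, si, protocol,
                                       cfg.simulation.b1_amplitude,
                                       cfg.simulation.b1_length_scale_mm)
            sdir = out / subject.subject_id
            files = []
            for ai, vol in enumerate(subject.spgr_volumes):
                files.append(write_volume(
                    vol, sdir / f"spgr_fa{protocol.flip_angles_deg[ai]:g}.nii.gz"))
            for ang, vol in zip(protocol.dam_angles_deg, subject.dam_volumes):
                files.append(write_volume(vol, sdir / f"dam_fa{ang:g}.nii.gz"))
            tr = subject.truth
            files.append(write_volume(
                T1Map(tr.t1_post, tr.voxel_size_mm), sdir / "truth_t1_post.nii.gz"))
            files.append(write_volume(
                T1Map(tr.t1_pre, tr.voxel_size_mm), sdir / "truth_t1_pre.nii.gz"))
            files.append(write_labels(tr.labels, tr.voxel_size_mm, sdir / "roi_labels.nii.gz"))
            manifest["subjects"].append({
                "subject_id": subject.subject_id,
                "group": group.group_name,
                "seed": group.seed,
                "subject_index": si,
                "files": {p.name: file_sha256(p) for p in files},
            })
    write_json(manifest, out / "cohort_manifest.json")
    return manifest
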