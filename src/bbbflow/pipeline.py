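"""End-to-end orchestration: phantom -> relaxometry -> VIF -> Patlak -> flow -> stats.

Runs are driven by a :class:`RunConfig` (YAML-serializable), are
deterministic given the global seed, and write CSV tables, JSON QC/manifest
sidecars and NIfTI volumes. All volumes are assumed co-registered; a shape
consistency check guards that assumption (real-data registration is out of
scope — the phantom supplies aligned volumes by construction).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import cohort_stats, flow4d, patlak, relaxometry, vif
from .phantom import (
    AcquisitionParams,
    BrainPhantom,
    DCESeries,
    default_flow_truth,
    default_ground_truth,
    make_brain_phantom,
    make_flow_phantom,
    simulate_dce,
    simulate_vfa,
)

__all__ = [
    "RunConfig",
    "run_dce",
    "run_flow",
    "run_cohort",
    "save_volume",
    "load_volume",
    "write_manifest",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run; every field has a documented default."""

    seed: int = 0
    out_dir: str | None = None
    # phantom
    shape: tuple[int, int, int] = (32, 32, 32)
    n_regions: int = 3
    dce_noise_sd: float = 0.0  # a.u. (protocol noise level is a free parameter)
    b1_variation: float = 0.0
    # relaxometry
    n_baseline_frames: int = 3
    # VIF
    vif_seed_voxel: tuple[int, int, int] | None = None  # None = auto (max enhancement)
    correlation_threshold: float = 0.99
    n_centerline_averaged: int = 25
    # patlak
    peak_exclusion: bool = False
    exclude_regions: tuple[str, ...] = ()  # e.g. slab-edge regions
    # flow
    flow_shape: tuple[int, int, int] = (44, 44, 44)
    flow_spacing: float = 0.6875  # mm
    flow_noise_sd: float = 0.0  # cm/s
    cd_threshold: float = 10.0
    diameter_threshold: float = 1.25  # mm
    background_poly_order: int = 1

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("shape", "flow_shape", "exclude_regions"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if raw.get("vif_seed_voxel") is not None:
            raw["vif_seed_voxel"] = tuple(raw["vif_seed_voxel"])
        return cls(**raw)


# --------------------------------------------------------------------------
# NIfTI exchange
# --------------------------------------------------------------------------


def save_volume(path, data: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> None:
    """Write a volume as NIfTI-1 with an RAS diagonal affine (mm spacing)."""
    affine = np.diag([*spacing, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def write_manifest(out_dir: Path, config: RunConfig, extra: dict | None = None) -> dict:
    cfg = asdict(config)
    manifest = {
        "package": "bbbflow",
        "version": __version__,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": config.seed,
    }
    if extra:
        manifest.update(extra)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


# --------------------------------------------------------------------------
# DCE pipeline
# --------------------------------------------------------------------------


def _check_shapes(*volumes) -> None:
    shapes = {np.shape(v)[:3] for v in volumes}
    if len(shapes) > 1:
        raise ValueError(f"volume shape mismatch: {sorted(shapes)}")


def dce_chain(
    vfa_volumes,
    b1: np.ndarray,
    series: DCESeries,
    rois: np.ndarray,
    labels: dict[str, int],
    params: AcquisitionParams,
    config: RunConfig,
):
    """Run VFA fit -> concentration -> VIF -> Patlak on prepared volumes.

    Returns (regional table, QC dict, VIFExtraction). The regional table
    reports PS in 10^-3 min^-1 and v_p in % with frozen, unit-bearing column
    names; aggregate rows (cortex/WM/basal ganglia/whole brain) are appended
    when their constituent regions are present.
    """
    if b1 is None:
        raise ValueError("B1 map is required (missing B1)")
    if "sinus" not in labels:
        raise ValueError("label volume lacks a 'sinus' label required for the VIF")
    _check_shapes(*vfa_volumes, b1, series.data, rois)

    t1fit = relaxometry.vfa_fit(vfa_volumes, params.flip_angles_vfa, b1, params.tr_dce)
    r1series = relaxometry.signal_to_r1(
        series.data,
        series.times,
        t1fit.t10,
        params.flip_angle_dce,
        b1,
        params.tr_dce,
        config.n_baseline_frames,
    )
    conc, conc_qc = relaxometry.r1_to_concentration(
        r1series, t1fit.r10, params.r1_relaxivity
    )

    seed_voxel = config.vif_seed_voxel or vif.auto_seed(series, n_baseline_frames=config.n_baseline_frames)
    extraction = vif.extract_vif(
        series, conc, seed_voxel, params,
        threshold=config.correlation_threshold,
        n_averaged=config.n_centerline_averaged,
    )

    fit_labels = {k: v for k, v in labels.items() if k not in config.exclude_regions}
    table = patlak.fit_regions(conc, rois, fit_labels, extraction, series.times)

    by_region = dict(zip(table["region"], table["ps"]))
    vp_by_region = dict(zip(table["region"], table["vp"]))
    agg_rows = []
    for gname, gval in patlak.aggregate_regions(by_region).items():
        agg_rows.append(
            dict(region=gname, ps=gval,
                 vp=patlak.aggregate_regions(vp_by_region)[gname],
                 residual_norm=np.nan, n_voxels=0, n_frames_used=0,
                 note="aggregate (unweighted mean of member regions)")
        )
    agg = pd.DataFrame([r for r in agg_rows if np.isfinite(r["ps"])])
    out = pd.concat([table, agg], ignore_index=True)
    out["PS_1e-3_per_min"] = out["ps"] * 1e3
    out["vp_percent"] = out["vp"] * 100.0

    qc = {
        "negative_concentration_fraction": conc_qc["fraction_negative"],
        "n_invalid_t1_voxels": int((~t1fit.valid).sum()),
        "n_invalid_frame_samples": int((~r1series.valid).sum()),
        "vif_seed_voxel": list(seed_voxel),
        "vif_centerline_length": int(len(extraction.centerline_voxels)),
        "vif_plasma_peak_mM": float(np.nanmax(extraction.plasma_curve)),
        "vif_curve_mM": [float(v) for v in extraction.plasma_curve],
        "frame_times_s": [float(t) for t in series.times],
        "skipped_regions": [
            {"region": r.region, "reason": r.note}
            for r in table.itertuples()
            if r.note and "skipped" in r.note
        ],
    }
    return out, qc, extraction


def run_dce(config: RunConfig, params: AcquisitionParams | None = None):
    """Generate the brain phantom and run the full DCE chain.

    Returns (table, qc, extraction, truth). With ``config.out_dir`` set,
    writes the regional CSV, QC JSON, ground-truth sidecar, NIfTI volumes
    and a reproducibility manifest.
    """
    params = params or AcquisitionParams()
    truth = default_ground_truth(config.n_regions)
    phantom = make_brain_phantom(
        config.shape, params, truth, seed=config.seed, b1_variation=config.b1_variation
    )
    vfa_vols = simulate_vfa(phantom, params, config.dce_noise_sd, seed=config.seed + 1)
    series = simulate_dce(phantom, truth, params, config.dce_noise_sd, seed=config.seed + 2)

    table, qc, extraction = dce_chain(
        vfa_vols, phantom.b1, series, phantom.rois, phantom.labels, params, config
    )

    pairing = None
    if config.peak_exclusion:
        window = patlak.default_peak_window(
            series.times, truth.injection_start, truth.injection_duration, params.frame_interval
        )
        t1fit = relaxometry.vfa_fit(vfa_vols, params.flip_angles_vfa, phantom.b1, params.tr_dce)
        r1s = relaxometry.signal_to_r1(
            series.data, series.times, t1fit.t10, params.flip_angle_dce,
            phantom.b1, params.tr_dce, config.n_baseline_frames,
        )
        conc, _ = relaxometry.r1_to_concentration(r1s, t1fit.r10, params.r1_relaxivity)
        curves = np.array(
            [np.nanmean(conc[phantom.region_mask(name)], axis=0) for name in truth.regions]
        )
        paired, agreement = patlak.peak_exclusion_sensitivity(
            curves, extraction.plasma_curve, series.times, window
        )
        pairing = {"paired": paired, "icc": agreement}
        qc["peak_exclusion_icc"] = agreement

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cols = ["region", "PS_1e-3_per_min", "vp_percent", "n_voxels", "n_frames_used", "note"]
        table[cols].to_csv(out / "regional_ps_vp.csv", index=False, float_format="%.6f")
        (out / "qc.json").write_text(json.dumps(qc, indent=2))
        truth_sidecar = {
            "regions": {k: asdict(v) for k, v in truth.regions.items()},
            "injection_start_s": truth.injection_start,
            "injection_duration_s": truth.injection_duration,
        }
        (out / "ground_truth.json").write_text(json.dumps(truth_sidecar, indent=2))
        save_volume(out / "t1_map.nii.gz", phantom.t1)
        save_volume(out / "b1_map.nii.gz", phantom.b1)
        save_volume(out / "rois.nii.gz", phantom.rois)
        save_volume(out / "dce.nii.gz", series.data)
        if pairing is not None:
            pairing["paired"].to_csv(out / "peak_exclusion_paired.csv", index=False, float_format="%.10f")
        write_manifest(out, config)
    return table, qc, extraction, truth


# --------------------------------------------------------------------------
# 4D-flow pipeline
# --------------------------------------------------------------------------


def run_flow(config: RunConfig, params: AcquisitionParams | None = None):
    """Generate the flow phantom and derive per-vessel PI and total CBF.

    Returns (table, phantom). Large-vessel waveforms are sampled at seeds on
    the known tube axes (the phantom stands in for manual seed placement);
    distal pulsatility comes from the normalized-median waveform over
    K-means-classified distal-artery branches. With ``config.out_dir`` set,
    writes the PI/tCBF CSV, velocity and CD NIfTIs and a manifest.
    """
    params = params or AcquisitionParams()
    truth = default_flow_truth(params.n_cardiac_frames)
    phantom = make_flow_phantom(
        truth, config.flow_shape, config.flow_spacing, params,
        noise_sd=config.flow_noise_sd, seed=config.seed,
    )
    velocity = phantom.velocity
    if config.flow_noise_sd > 0 or config.background_poly_order >= 0:
        static = phantom.tube_labels == 0
        velocity = flow4d.background_correct(velocity, static, config.background_poly_order)

    mask = flow4d.segment_vessels(phantom.cd, config.cd_threshold)
    tree = flow4d.skeletonize_tree(mask, config.flow_spacing)
    flow4d.estimate_direction(tree)

    def tube_seed(name):
        spec = next(t for t in truth.tubes if t.name == name)
        mid = spec.points.mean(axis=0) / config.flow_spacing
        return mid

    rows = []
    large = {}
    for name in ("ICA-L", "ICA-R", "BA"):
        if name not in phantom.tube_names:
            raise ValueError(f"missing seed for required vessel {name}")
        w, diam = flow4d.vessel_waveform(tree, velocity, phantom.cd, tube_seed(name))
        large[name] = w
        res = flow4d.pulsatility_index(w, vessel_id=name)
        rows.append(dict(vessel=name, pi=res.pi, mean_flow_ml_min=res.mean_flow, diameter_mm=diam))

    ica_avg = flow4d.average_waveforms(large["ICA-L"], large["ICA-R"])
    res = flow4d.pulsatility_index(ica_avg, vessel_id="ICA")
    rows.append(dict(vessel="ICA-avg", pi=res.pi, mean_flow_ml_min=res.mean_flow, diameter_mm=np.nan))

    waveforms, diameters, per_voxel = flow4d.branch_waveforms(tree, velocity, phantom.cd)
    labels = flow4d.classify_branches(waveforms, diameters, config.diameter_threshold)
    tree.branch_class = labels
    distal_idx = [i for i, lab in enumerate(labels) if lab == "distal-artery"]
    if distal_idx:
        distal = flow4d.distal_waveform([per_voxel[i] for i in distal_idx])
        dres = flow4d.pulsatility_index(distal, vessel_id="distal")
        rows.append(dict(vessel="distal", pi=dres.pi, mean_flow_ml_min=np.nan, diameter_mm=float(np.nanmedian(diameters[distal_idx]))))
    else:
        rows.append(dict(vessel="distal", pi=np.nan, mean_flow_ml_min=np.nan, diameter_mm=np.nan))

    tcbf = flow4d.total_cbf(large["ICA-L"], large["ICA-R"], large["BA"])
    rows.append(dict(vessel="tCBF", pi=np.nan, mean_flow_ml_min=tcbf, diameter_mm=np.nan))
    table = pd.DataFrame(rows)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "flow_pi_tcbf.csv", index=False, float_format="%.6f")
        save_volume(out / "cd.nii.gz", phantom.cd, (config.flow_spacing,) * 3)
        for c, axis in enumerate("xyz"):
            save_volume(out / f"velocity_{axis}.nii.gz", phantom.velocity[c], (config.flow_spacing,) * 3)
        write_manifest(out, config)
    return table, phantom


# --------------------------------------------------------------------------
# Cohort statistics pipeline
# --------------------------------------------------------------------------

_SEX_CODES = {"M": 0.0, "F": 1.0}


def run_cohort(table: pd.DataFrame, out_dir: str | None = None) -> dict[str, pd.DataFrame]:
    """Association report over a cohort table.

    Emits descriptives with PS-v_p correlations per region, age and MoCA
    regressions per region, tCBF/PI regressions per aggregate region, and
    unadjusted plus age-and-sex-adjusted PS-MoCA slopes for the cortex, WM,
    basal ganglia, hippocampus and whole-brain aggregates. Regions with a
    constant column are skipped with a note. Missing required columns raise
    a named error.
    """
    for col in ("age", "sex", "moca"):
        if col not in table.columns:
            raise KeyError(f"cohort table lacks required column {col!r}")
    regions = [c[3:] for c in table.columns if c.startswith("ps_")]
    if not regions:
        raise KeyError("cohort table lacks 'ps_<region>' columns")

    desc_rows, assoc_rows, skipped = [], [], []
    for r in regions:
        ps = table[f"ps_{r}"].to_numpy()
        if np.ptp(ps) == 0:
            skipped.append({"region": r, "reason": "constant PS column"})
            continue
        d = cohort_stats.describe(ps)
        row = dict(region=r, ps_mean=d.mean, ps_ci_low=d.ci_low, ps_ci_high=d.ci_high,
                   ps_skewness=d.skewness, ps_kurtosis=d.kurtosis)
        if f"vp_{r}" in table.columns:
            vp = table[f"vp_{r}"].to_numpy()
            dv = cohort_stats.describe(vp)
            row.update(vp_mean=dv.mean, vp_ci_low=dv.ci_low, vp_ci_high=dv.ci_high)
            rr, pp = cohort_stats.pearson(ps, vp)
            row.update(ps_vp_r=rr, ps_vp_p=pp)
        desc_rows.append(row)

        reg_age = cohort_stats.simple_regression(ps, table["age"].to_numpy())
        reg_moca = cohort_stats.simple_regression(table["moca"].to_numpy(), ps)
        assoc_rows.append(dict(
            region=r,
            age_ps_beta=reg_age.beta, age_ps_ci_low=reg_age.ci_low, age_ps_ci_high=reg_age.ci_high, age_ps_p=reg_age.p_value,
            ps_moca_beta=reg_moca.beta, ps_moca_ci_low=reg_moca.ci_low, ps_moca_ci_high=reg_moca.ci_high, ps_moca_p=reg_moca.p_value,
            low_n=len(table) < 10,
        ))

    descriptives = pd.DataFrame(desc_rows)
    regressions = pd.DataFrame(assoc_rows)

    usable = [r["region"] for r in desc_rows]
    aggregates = {
        "cortex": [r for r in usable if r.endswith("_cortex")],
        "white_matter": [r for r in usable if r.endswith("_wm")],
        "basal_ganglia": [r for r in usable if r in ("caudate", "putamen", "pallidum")],
        "hippocampus": ["hippocampus"] if "hippocampus" in usable else [],
        "whole_brain": usable,
    }
    sex_num = table["sex"].map(_SEX_CODES).fillna(table["sex"]).astype(float).to_numpy() \
        if table["sex"].dtype == object else table["sex"].astype(float).to_numpy()
    covariates = np.column_stack([table["age"].to_numpy(), sex_num])

    fig_rows, hemo_rows = [], []
    for gname, members in aggregates.items():
        if not members:
            continue
        ps_agg = table[[f"ps_{m}" for m in members]].to_numpy().mean(axis=1)
        moca = table["moca"].to_numpy()
        unadj = cohort_stats.simple_regression(moca, ps_agg)
        row = dict(
            region=gname,
            beta_unadjusted=unadj.beta, ci_low_unadjusted=unadj.ci_low,
            ci_high_unadjusted=unadj.ci_high, p_unadjusted=unadj.p_value,
        )
        if len(table) > covariates.shape[1] + 2:
            ps_adj = cohort_stats.residualize(ps_agg, covariates)
            moca_adj = cohort_stats.residualize(moca, covariates)
            adj = cohort_stats.simple_regression(moca_adj, ps_adj)
            row.update(beta_adjusted=adj.beta, ci_low_adjusted=adj.ci_low,
                       ci_high_adjusted=adj.ci_high, p_adjusted=adj.p_value)
        else:  # too few subjects to adjust for age and sex
            row.update(beta_adjusted=np.nan, ci_low_adjusted=np.nan,
                       ci_high_adjusted=np.nan, p_adjusted=np.nan)
        fig_rows.append(row)
        row = dict(region=gname)
        if "tcbf" in table.columns:
            reg = cohort_stats.simple_regression(ps_agg, table["tcbf"].to_numpy() / 1000.0)
            row.update(tcbf_ps_beta=reg.beta, tcbf_ps_p=reg.p_value)
        if "distal_pi" in table.columns:
            reg = cohort_stats.simple_regression(ps_agg, table["distal_pi"].to_numpy())
            row.update(dpi_ps_beta=reg.beta, dpi_ps_ci_low=reg.ci_low, dpi_ps_ci_high=reg.ci_high, dpi_ps_p=reg.p_value)
        hemo_rows.append(row)

    pca = None
    if len(usable) >= 2:
        matrix = table[[f"ps_{m}" for m in usable]].to_numpy()
        res = cohort_stats.shared_variance_pca(matrix)
        pca = pd.DataFrame([{k: v for k, v in res.items() if k != "eigenvalues"}])

    report = {
        "descriptives": descriptives,
        "regressions": regressions,
        "ps_moca": pd.DataFrame(fig_rows),
        "hemodynamics": pd.DataFrame(hemo_rows),
        "shared_variance": pca,
        "skipped": pd.DataFrame(skipped),
    }
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in report.items():
            if df is not None and len(df):
                df.to_csv(out / f"{name}.csv", index=False, float_format="%.6f")
    return report
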