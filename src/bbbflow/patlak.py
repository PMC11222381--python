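"""Patlak-model estimation of PS and fractional plasma volume.

The Patlak model assumes unidirectional (irreversible) tracer transfer from
plasma to tissue:

    C_tissue(t) = PS * int_0^t C_VIF(tau) dtau + v_p * C_VIF(t)

and is solved for PS (min^-1) and v_p (dimensionless) by two-regressor,
no-intercept ordinary least squares, with the integral evaluated by
cumulative trapezoid on the frame time stamps converted to minutes. No
non-negativity constraint or value-based exclusion is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .vif import VIFExtraction

__all__ = [
    "PatlakResult",
    "patlak_fit",
    "fit_regions",
    "aggregate_regions",
    "default_peak_window",
    "peak_exclusion_sensitivity",
    "AGGREGATE_GROUPS",
]

# Region groupings used for aggregate summaries: cortex, white matter and
# basal ganglia are unweighted means of their constituent regions; the whole
# brain is the unweighted mean over all 15 regions.
from .phantom import BASAL_GANGLIA_REGIONS, CORTEX_REGIONS, REGIONS, WM_REGIONS

AGGREGATE_GROUPS: Mapping[str, tuple[str, ...]] = {
    "cortex": CORTEX_REGIONS,
    "white_matter": WM_REGIONS,
    "basal_ganglia": BASAL_GANGLIA_REGIONS,
    "whole_brain": REGIONS,
}


@dataclass
class PatlakResult:
    ps: float  # min^-1
    vp: float  # fraction
    residual_norm: float  # mM
    n_frames_used: int
    frame_mask: np.ndarray  # True = used


def patlak_fit(
    c_tissue: np.ndarray,
    c_vif: np.ndarray,
    times: np.ndarray,
    frame_mask: np.ndarray | None = None,
) -> PatlakResult:
    """Fit PS and v_p to one tissue concentration curve.

    Parameters
    ----------
    c_tissue, c_vif : arrays (T,)
        Tissue and plasma concentration in mM.
    times : array (T,)
        Frame time stamps in seconds.
    frame_mask : bool array (T,), optional
        True for frames used in the regression (NaN frames are dropped
        additionally). The VIF integral is always accumulated over the full
        time grid; masking applies to the regression rows only.
    """
    c_tissue = np.asarray(c_tissue, dtype=float)
    c_vif = np.asarray(c_vif, dtype=float)
    times = np.asarray(times, dtype=float)
    if frame_mask is None:
        frame_mask = np.ones_like(times, dtype=bool)
    frame_mask = np.asarray(frame_mask, dtype=bool) & np.isfinite(c_tissue) & np.isfinite(c_vif)
    if frame_mask.sum() < 3:
        raise ValueError("at least 3 unmasked frames are required")

    integral = cumulative_trapezoid(np.nan_to_num(c_vif), times / 60.0, initial=0.0)
    design = np.column_stack([integral[frame_mask], c_vif[frame_mask]])
    if not np.any(c_vif[frame_mask]):
        raise ValueError("vascular input function is zero on all unmasked frames")
    if np.linalg.matrix_rank(design) < 2:
        raise ValueError("singular Patlak design matrix (collinear regressors)")
    coef, _, _, _ = np.linalg.lstsq(design, c_tissue[frame_mask], rcond=None)
    resid = c_tissue[frame_mask] - design @ coef
    return PatlakResult(
        ps=float(coef[0]),
        vp=float(coef[1]),
        residual_norm=float(np.linalg.norm(resid)),
        n_frames_used=int(frame_mask.sum()),
        frame_mask=frame_mask,
    )


def fit_regions(
    concentration: np.ndarray,
    rois: np.ndarray,
    labels: Mapping[str, int],
    vif: VIFExtraction,
    times: np.ndarray,
    mode: str = "roi",
    frame_mask: np.ndarray | None = None,
    exclude: Sequence[str] = ("sinus",),
) -> pd.DataFrame:
    """Fit the Patlak model per region (or per voxel within each region).

    In ``roi`` mode the concentration curves are averaged over all voxels in
    each region — with no thresholding or exclusion based on extreme values
    (NaN frames from invalid inversions are the only omissions) — and fitted
    once per region. In ``voxel`` mode every labeled voxel is fitted and the
    region row carries the mean and SD of the voxelwise estimates.

    Returns a DataFrame with columns region, ps, vp, residual_norm,
    n_voxels, n_frames_used (plus ps_sd/vp_sd in voxel mode). Empty regions
    are skipped with a warning row (ps/vp NaN, reason noted).
    """
    if mode not in ("roi", "voxel"):
        raise ValueError("mode must be 'roi' or 'voxel'")
    rows = []
    for name, label in labels.items():
        if name in exclude:
            continue
        mask = rois == label
        n_vox = int(mask.sum())
        if n_vox == 0:
            rows.append(
                dict(region=name, ps=np.nan, vp=np.nan, residual_norm=np.nan,
                     n_voxels=0, n_frames_used=0, note="empty region; skipped")
            )
            continue
        curves = concentration[mask]  # (n_vox, T)
        if mode == "roi":
            mean_curve = np.nanmean(curves, axis=0)
            res = patlak_fit(mean_curve, vif.plasma_curve, times, frame_mask)
            rows.append(
                dict(region=name, ps=res.ps, vp=res.vp, residual_norm=res.residual_norm,
                     n_voxels=n_vox, n_frames_used=res.n_frames_used, note="")
            )
        else:
            ps_v, vp_v = [], []
            for c in curves:
                r = patlak_fit(c, vif.plasma_curve, times, frame_mask)
                ps_v.append(r.ps)
                vp_v.append(r.vp)
            rows.append(
                dict(region=name, ps=float(np.mean(ps_v)), vp=float(np.mean(vp_v)),
                     ps_sd=float(np.std(ps_v, ddof=1)) if n_vox > 1 else 0.0,
                     vp_sd=float(np.std(vp_v, ddof=1)) if n_vox > 1 else 0.0,
                     residual_norm=np.nan, n_voxels=n_vox,
                     n_frames_used=len(times), note="")
            )
    return pd.DataFrame(rows)


def aggregate_regions(
    values: Mapping[str, float],
    groups: Mapping[str, Sequence[str]] = AGGREGATE_GROUPS,
) -> dict[str, float]:
    """Unweighted means of per-region values over named groups.

    Groups whose constituent regions are absent from ``values`` are reduced
    to the available ones; a group with none available yields NaN.
    """
    out = {}
    for gname, members in groups.items():
        vals = [values[m] for m in members if m in values]
        out[gname] = float(np.mean(vals)) if vals else float("nan")
    return out


def default_peak_window(
    times: np.ndarray, injection_start: float, injection_duration: float, frame_interval: float
) -> np.ndarray:
    """Frames overlapping the contrast injection peak (True = excluded).

    Covers frames from the injection start through one frame past the end of
    the injection.
    """
    times = np.asarray(times, dtype=float)
    return (times >= injection_start) & (times <= injection_start + injection_duration + frame_interval)


def peak_exclusion_sensitivity(
    c_tissue: np.ndarray,
    c_vif: np.ndarray,
    times: np.ndarray,
    exclusion_window: np.ndarray,
) -> tuple[pd.DataFrame, float]:
    """Compare Patlak fits with full curves versus injection-peak-excluded curves.

    Parameters
    ----------
    c_tissue : array (M, T)
        One tissue curve per subject/region pair.
    c_vif : array (T,) or (M, T)
        Shared or per-curve plasma input function.
    exclusion_window : bool array (T,)
        True marks peak frames to exclude in the second fit.

    Returns the paired estimates and the absolute-agreement ICC of PS across
    the M curves (identical pairs give ICC = 1 by convention).
    """
    from .cohort_stats import icc

    c_tissue = np.atleast_2d(np.asarray(c_tissue, dtype=float))
    exclusion_window = np.asarray(exclusion_window, dtype=bool)
    keep = ~exclusion_window
    if keep.sum() < 3:
        raise ValueError("exclusion window leaves fewer than 3 frames")
    c_vif = np.asarray(c_vif, dtype=float)
    vifs = np.broadcast_to(c_vif, c_tissue.shape) if c_vif.ndim == 1 else c_vif

    rows = []
    for ct, cv in zip(c_tissue, vifs):
        full = patlak_fit(ct, cv, times)
        part = patlak_fit(ct, cv, times, frame_mask=keep)
        rows.append(dict(ps_full=full.ps, vp_full=full.vp, ps_excl=part.ps, vp_excl=part.vp))
    paired = pd.DataFrame(rows)
    ratings = paired[["ps_full", "ps_excl"]].to_numpy()
    if np.allclose(ratings[:, 0], ratings[:, 1], rtol=1e-12, atol=1e-15):
        agreement = 1.0
    else:
        agreement = icc(ratings)
    return paired, float(agreement)
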