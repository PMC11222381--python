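"""Synthetic DCE-MRI, 4D-flow and cohort phantoms with exact ground truth.

The phantoms use analytic geometry (spheres for brain regions, a cylinder
for the superior sagittal sinus, cylinders for arteries and veins) so that
every downstream estimate — T1, gadolinium concentration, Patlak PS/v_p,
flow waveforms, pulsatility — can be compared against a known truth.

All generators are deterministic given an explicit seed; there is no global
random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import gaussian_filter

__all__ = [
    "AcquisitionParams",
    "VIFModel",
    "RegionSpec",
    "GroundTruth",
    "BrainPhantom",
    "DCESeries",
    "TubeSpec",
    "FlowPhantomTruth",
    "FlowPhantom",
    "CohortSpec",
    "REGIONS",
    "CORTEX_REGIONS",
    "WM_REGIONS",
    "BASAL_GANGLIA_REGIONS",
    "REFERENCE_PS_MEANS",
    "REFERENCE_VP_MEANS",
    "REFERENCE_VP_CORTEX_PCT",
    "REFERENCE_VP_WM_PCT",
    "default_ground_truth",
    "tissue_signal_curve",
    "tissue_concentration",
    "spgr_signal",
    "rician",
    "make_brain_phantom",
    "simulate_vfa",
    "simulate_dce",
    "make_flow_phantom",
    "default_flow_truth",
    "sinusoidal_waveform",
    "loadings_for_first_pc_share",
    "simulate_cohort",
]


# --------------------------------------------------------------------------
# Region inventory and published-style reference values
# --------------------------------------------------------------------------

CORTEX_REGIONS = (
    "frontal_cortex",
    "parietal_cortex",
    "temporal_cortex",
    "occipital_cortex",
    "cingulate_cortex",
)
WM_REGIONS = (
    "frontal_wm",
    "parietal_wm",
    "temporal_wm",
    "occipital_wm",
    "cingulate_wm",
)
SUBCORTICAL_REGIONS = ("thalamus", "caudate", "putamen", "pallidum", "hippocampus")
BASAL_GANGLIA_REGIONS = ("caudate", "putamen", "pallidum")

#: The 15 gray/white-matter regions evaluated at ROI level.
REGIONS = CORTEX_REGIONS + WM_REGIONS + SUBCORTICAL_REGIONS

#: Cohort-mean PS per region, 10^-3 min^-1 (used as cohort-generator defaults).
REFERENCE_PS_MEANS: Mapping[str, float] = {
    "frontal_cortex": 0.52,
    "parietal_cortex": 0.52,
    "temporal_cortex": 0.72,
    "occipital_cortex": 0.86,
    "cingulate_cortex": 0.56,
    "frontal_wm": 0.52,
    "parietal_wm": 0.48,
    "temporal_wm": 0.49,
    "occipital_wm": 0.39,
    "cingulate_wm": 0.58,
    "thalamus": 0.54,
    "caudate": 0.45,
    "putamen": 0.66,
    "pallidum": 0.63,
    "hippocampus": 0.64,
}

#: Cohort-mean fractional plasma volume per region, percent.
REFERENCE_VP_MEANS: Mapping[str, float] = {
    "frontal_cortex": 1.18,
    "parietal_cortex": 1.22,
    "temporal_cortex": 1.32,
    "occipital_cortex": 1.73,
    "cingulate_cortex": 1.49,
    "frontal_wm": 0.81,
    "parietal_wm": 0.79,
    "temporal_wm": 0.82,
    "occipital_wm": 0.80,
    "cingulate_wm": 0.91,
    "thalamus": 1.68,
    "caudate": 1.47,
    "putamen": 1.65,
    "pallidum": 1.20,
    "hippocampus": 1.78,
}

#: Cohort-average cortical and white-matter v_p, percent (tissue-weighted
#: averages; not the unweighted means of the per-region values above).
REFERENCE_VP_CORTEX_PCT = 1.29
REFERENCE_VP_WM_PCT = 0.81


# --------------------------------------------------------------------------
# Acquisition parameters
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AcquisitionParams:
    """Pulse-sequence and physiological constants of the DCE/4D-flow protocol.

    Defaults follow a 3 T protocol: spoiled gradient echo with TR 4.5 ms and
    flip angle 12 deg for the dynamic series, variable-flip-angle T1 mapping
    at 2/8/12 deg, 60 frames at 17.5 s, gadolinium relaxivity
    r1 = 3.5 L mmol^-1 s^-1, hematocrit 0.45, 20 reconstructed cardiac
    frames and a velocity-encoding limit of 110 cm/s.
    """

    tr_dce: float = 4.5  # ms
    flip_angles_vfa: tuple[float, ...] = (2.0, 8.0, 12.0)  # degrees
    flip_angle_dce: float = 12.0  # degrees
    frame_interval: float = 17.5  # s
    n_frames: int = 60
    r1_relaxivity: float = 3.5  # L mmol^-1 s^-1
    hematocrit: float = 0.45
    n_cardiac_frames: int = 20
    venc: float = 110.0  # cm/s

    def __post_init__(self) -> None:
        if self.tr_dce <= 0:
            raise ValueError("tr_dce must be positive")
        angles = (*self.flip_angles_vfa, self.flip_angle_dce)
        if any(not 0 < a <= 90 for a in angles):
            raise ValueError("flip angles must lie in (0, 90] degrees")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if not 0 <= self.hematocrit < 1:
            raise ValueError("hematocrit must lie in [0, 1)")
        if self.n_cardiac_frames < 2:
            raise ValueError("n_cardiac_frames must be >= 2")

    @property
    def frame_times(self) -> np.ndarray:
        """DCE frame time stamps in seconds."""
        return np.arange(self.n_frames) * self.frame_interval


# --------------------------------------------------------------------------
# Ground-truth vascular input function
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class VIFModel:
    """Plasma input function: box-car bolus convolved with bi-exponential washout.

    The injection is modelled as a unit-height box of length
    ``injection_duration`` convolved with ``sum_i a_i exp(-k_i t)`` (t in
    minutes), which has the closed form used below. Amplitudes are in
    mM min^-1 and rates in min^-1; the slow-injection defaults give a broad,
    low plasma peak of ~2.5 mM in blood terms.
    """

    amplitudes: tuple[float, ...] = (5.0, 1.0)  # mM / min
    rates: tuple[float, ...] = (3.0, 0.1)  # min^-1

    def concentration(
        self, times_s: np.ndarray, injection_start_s: float, injection_duration_s: float
    ) -> np.ndarray:
        """Plasma concentration C_VIF(t) in mM at times given in seconds."""
        t = (np.asarray(times_s, dtype=float) - injection_start_s) / 60.0  # min
        dur = injection_duration_s / 60.0
        c = np.zeros_like(t)
        rising = (t > 0) & (t <= dur)
        decaying = t > dur
        for a, k in zip(self.amplitudes, self.rates):
            c[rising] += a / k * (1.0 - np.exp(-k * t[rising]))
            c[decaying] += a / k * np.exp(-k * t[decaying]) * (np.exp(k * dur) - 1.0)
        return c


@dataclass(frozen=True)
class RegionSpec:
    """Per-region tissue ground truth."""

    t1: float  # s
    m0: float  # a.u.
    ps: float = 0.0  # min^-1
    vp: float = 0.0  # fraction

    def __post_init__(self) -> None:
        if self.t1 <= 0:
            raise ValueError("t1 must be positive")
        if self.ps < 0:
            raise ValueError("ps must be non-negative")
        if not 0 <= self.vp < 1:
            raise ValueError("vp must lie in [0, 1)")


@dataclass(frozen=True)
class GroundTruth:
    """Full ground truth of the brain phantom.

    ``regions`` maps region names to their tissue properties; a blood-filled
    "sinus" structure is always added by :func:`make_brain_phantom`. The
    contrast injection starts at ``injection_start`` seconds and lasts
    ``injection_duration`` seconds (a slow ~1-minute injection beginning
    ~1 minute into the scan by default).
    """

    regions: Mapping[str, RegionSpec]
    sinus: RegionSpec = RegionSpec(t1=1.6, m0=1200.0)
    background: RegionSpec = RegionSpec(t1=1.0, m0=600.0)
    vif: VIFModel = VIFModel()
    injection_start: float = 60.0  # s
    injection_duration: float = 60.0  # s

    def __post_init__(self) -> None:
        if self.injection_start < 0:
            raise ValueError("injection_start must be non-negative")
        if len(self.regions) < 1:
            raise ValueError("at least one tissue region required")


def default_ground_truth(n_regions: int = 3) -> GroundTruth:
    """A small ground truth with distinct (T1, PS, v_p) per region."""
    names = list(REGIONS[:n_regions])
    t1s = np.linspace(0.9, 1.6, n_regions)
    ps = np.linspace(0.3e-3, 1.0e-3, n_regions)
    vp = np.linspace(0.007, 0.019, n_regions)
    regions = {
        name: RegionSpec(t1=float(t1s[i]), m0=1000.0, ps=float(ps[i]), vp=float(vp[i]))
        for i, name in enumerate(names)
    }
    return GroundTruth(regions=regions)


# --------------------------------------------------------------------------
# SPGR signal model and Rician noise
# --------------------------------------------------------------------------


def spgr_signal(t1, m0, flip_angle: float, b1=1.0, tr: float = 4.5):
    """Steady-state spoiled gradient-echo signal.

    S = M0 sin(b1*alpha) (1 - E1) / (1 - cos(b1*alpha) E1), E1 = exp(-TR/T1).

    Parameters are broadcast; ``t1`` in seconds, ``tr`` in milliseconds,
    ``flip_angle`` in degrees, ``b1`` the achieved/nominal flip-angle ratio.
    """
    t1 = np.asarray(t1, dtype=float)
    alpha = np.deg2rad(flip_angle) * np.asarray(b1, dtype=float)
    e1 = np.exp(-(tr / 1000.0) / t1)
    return np.asarray(m0, dtype=float) * np.sin(alpha) * (1.0 - e1) / (1.0 - np.cos(alpha) * e1)


def rician(signal: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Rician-distributed magnitude: Gaussian noise on two quadrature channels."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd == 0:
        return np.asarray(signal, dtype=float).copy()
    real = signal + rng.normal(0.0, noise_sd, size=np.shape(signal))
    imag = rng.normal(0.0, noise_sd, size=np.shape(signal))
    return np.hypot(real, imag)


# --------------------------------------------------------------------------
# Brain phantom geometry
# --------------------------------------------------------------------------


@dataclass
class BrainPhantom:
    """Voxelized brain phantom: parameter maps plus a label volume.

    ``labels`` maps region names (including "sinus") to positive integer
    labels in ``rois``; background is 0. The sinus is a cylinder running the
    full length of axis 0 so its centerline is long enough for input-function
    extraction.
    """

    t1: np.ndarray  # s
    m0: np.ndarray  # a.u.
    b1: np.ndarray  # dimensionless
    rois: np.ndarray  # int labels
    labels: dict[str, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # mm

    def region_mask(self, name: str) -> np.ndarray:
        return self.rois == self.labels[name]


def make_brain_phantom(
    shape: Sequence[int],
    params: AcquisitionParams,
    truth: GroundTruth,
    seed: int = 0,
    b1_variation: float = 0.0,
    sinus_radius: float = 2.5,
    region_radius: float | None = None,
) -> BrainPhantom:
    """Place spherical tissue regions and a cylindrical sinus on a grid.

    T1/M0 are constant within each region; B1 is 1 plus an optional smooth
    spatial deviation of amplitude ``b1_variation`` (e.g. 0.1 for +/-~10%).
    Deterministic given ``seed``.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 16:
        raise ValueError("phantom shape must be 3D with every dimension >= 16")
    names = list(truth.regions)
    n = len(names)

    # sinus: cylinder along axis 0, near the +y face
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    cj, ck = shape[1] - 5, shape[2] // 2
    sinus_mask = (jj - cj) ** 2 + (kk - ck) ** 2 <= sinus_radius**2

    # spheres on a regular grid of slots in the remaining volume
    if region_radius is None:
        region_radius = max(2.0, min(shape) / 10.0)
    slots_per_axis = int(np.ceil(n ** (1 / 3)))
    margin = region_radius + 1
    centers = []
    axes_pts = [
        np.linspace(margin, s - margin, slots_per_axis)
        for s in (shape[0], shape[1] - 2 * sinus_radius - 6, shape[2])
    ]
    for a in axes_pts[0]:
        for b in axes_pts[1]:
            for c in axes_pts[2]:
                centers.append((a, b, c))
    if len(centers) < n or axes_pts[1][0] > axes_pts[1][-1] + 1e-9:
        raise ValueError("phantom shape too small to contain all regions")

    rois = np.zeros(shape, dtype=np.int32)
    labels = {"sinus": 1}
    rois[sinus_mask] = 1
    for i, name in enumerate(names):
        ci, cj2, ck2 = centers[i]
        sphere = (ii - ci) ** 2 + (jj - cj2) ** 2 + (kk - ck2) ** 2 <= region_radius**2
        if sphere.sum() < 27:
            raise ValueError("phantom shape too small to contain all regions")
        if np.any(rois[sphere] != 0):
            raise ValueError("phantom shape too small to contain all regions")
        labels[name] = i + 2
        rois[sphere] = i + 2

    t1 = np.full(shape, truth.background.t1)
    m0 = np.full(shape, truth.background.m0)
    t1[sinus_mask] = truth.sinus.t1
    m0[sinus_mask] = truth.sinus.m0
    for name in names:
        mask = rois == labels[name]
        t1[mask] = truth.regions[name].t1
        m0[mask] = truth.regions[name].m0

    rng = np.random.default_rng(seed)
    if b1_variation > 0:
        raw = rng.normal(size=shape)
        smooth = gaussian_filter(raw, sigma=min(shape) / 4.0)
        smooth /= max(np.abs(smooth).max(), 1e-12)
        b1 = 1.0 + b1_variation * smooth
    else:
        b1 = np.ones(shape)
    return BrainPhantom(t1=t1, m0=m0, b1=b1, rois=rois, labels=labels)


# --------------------------------------------------------------------------
# Forward signal simulation
# --------------------------------------------------------------------------


@dataclass
class DCESeries:
    """4D dynamic magnitude series with frame time stamps (seconds)."""

    data: np.ndarray  # (x, y, z, t)
    times: np.ndarray  # s

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]


def simulate_vfa(
    phantom: BrainPhantom,
    params: AcquisitionParams,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[np.ndarray]:
    """Pre-contrast SPGR volumes at each variable flip angle."""
    rng = np.random.default_rng(seed)
    vols = []
    for alpha in params.flip_angles_vfa:
        s = spgr_signal(phantom.t1, phantom.m0, alpha, phantom.b1, params.tr_dce)
        vols.append(rician(s, noise_sd, rng))
    return vols


def tissue_concentration(
    truth: GroundTruth, params: AcquisitionParams, ps: float, vp: float
) -> np.ndarray:
    """Forward Patlak tissue concentration on the DCE frame grid (mM).

    C_tissue(t) = PS * int_0^t C_VIF + v_p * C_VIF(t), with the integral
    evaluated by cumulative trapezoid on the frame times (minutes) — the same
    discretization the fitting stage uses, so noiseless round trips are exact.
    """
    times = params.frame_times
    cvif = truth.vif.concentration(times, truth.injection_start, truth.injection_duration)
    integral = cumulative_trapezoid(cvif, times / 60.0, initial=0.0)
    return ps * integral + vp * cvif


def tissue_signal_curve(
    truth: GroundTruth,
    params: AcquisitionParams,
    spec: RegionSpec,
    b1: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless single-voxel tissue signal and concentration curves.

    Convenience for curve-level Monte-Carlo studies: returns
    (signal (T,), concentration (T,) in mM) for one tissue voxel following
    the forward Patlak model.
    """
    conc = tissue_concentration(truth, params, spec.ps, spec.vp)
    r1_t = 1.0 / spec.t1 + params.r1_relaxivity * conc
    signal = spgr_signal(1.0 / r1_t, spec.m0, params.flip_angle_dce, b1, params.tr_dce)
    return signal, conc


def simulate_dce(
    phantom: BrainPhantom,
    truth: GroundTruth,
    params: AcquisitionParams,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DCESeries:
    """Forward-simulate the dynamic contrast-enhanced magnitude series.

    Tissue regions follow the forward Patlak model driven by the plasma input
    function; the sinus carries whole-blood concentration
    C_b = (1 - HCT) * C_VIF. Concentration maps to signal through
    R1(t) = R10 + r1 C(t) and the SPGR equation; optional Rician noise.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if params.n_frames < 10:
        raise ValueError("n_frames must be >= 10")
    times = params.frame_times
    cvif = truth.vif.concentration(times, truth.injection_start, truth.injection_duration)

    shape = phantom.rois.shape
    data = np.empty(shape + (params.n_frames,), dtype=float)

    def fill(mask: np.ndarray, t1_0: float, conc: np.ndarray) -> None:
        r1_t = 1.0 / t1_0 + params.r1_relaxivity * conc  # (T,)
        t1_t = 1.0 / r1_t
        b1v = phantom.b1[mask][:, None]
        m0v = phantom.m0[mask][:, None]
        data[mask, :] = spgr_signal(t1_t[None, :], m0v, params.flip_angle_dce, b1v, params.tr_dce)

    background = phantom.rois == 0
    fill(background, truth.background.t1, np.zeros_like(cvif))
    fill(phantom.region_mask("sinus"), truth.sinus.t1, (1.0 - params.hematocrit) * cvif)
    for name, spec in truth.regions.items():
        ct = tissue_concentration(truth, params, spec.ps, spec.vp)
        fill(phantom.region_mask(name), spec.t1, ct)

    rng = np.random.default_rng(seed)
    return DCESeries(data=rician(data, noise_sd, rng), times=times)


# --------------------------------------------------------------------------
# Flow phantom
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TubeSpec:
    """One vessel: a polyline axis (mm), radius (mm), flow waveform (ml/min)."""

    name: str
    points: np.ndarray  # (P, 3) mm
    radius: float  # mm
    waveform: np.ndarray  # (n_cardiac,) ml/min
    vessel_class: str  # "artery" | "vein"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if np.any(np.asarray(self.waveform) <= 0):
            raise ValueError("waveform must be strictly positive")
        if self.vessel_class not in ("artery", "vein"):
            raise ValueError("vessel_class must be 'artery' or 'vein'")


@dataclass(frozen=True)
class FlowPhantomTruth:
    tubes: tuple[TubeSpec, ...]


@dataclass
class FlowPhantom:
    """Voxelized vascular phantom: velocities (cm/s), CD angiogram, truth labels."""

    velocity: np.ndarray  # (3, x, y, z, n_cardiac) cm/s
    cd: np.ndarray  # (x, y, z)
    spacing: float  # mm, isotropic
    tube_labels: np.ndarray  # int, 0 = background
    tube_names: dict[str, int]
    truth: FlowPhantomTruth


def sinusoidal_waveform(mean: float, pi: float, n_frames: int = 20) -> np.ndarray:
    """q(t) = mean (1 + PI/2 sin(2 pi t/T)): amplitude/mean equals ``pi`` exactly."""
    t = np.arange(n_frames) / n_frames
    return mean * (1.0 + 0.5 * pi * np.sin(2 * np.pi * t))


def default_flow_truth(
    n_cardiac_frames: int = 20,
    ica_pi: float = 1.14,
    distal_pi: float = 0.99,
    vein_pi: float = 0.2,
    length_mm: float = 23.0,
) -> FlowPhantomTruth:
    """Straight parallel tubes emulating the major cerebral inflow vessels,
    a few distal arteries, and veins. Mean inflows sum to ~556 ml/min."""

    def tube(name, x, y, r, mean, pi, cls):
        pts = np.array([[x, y, 3.5], [x, y, 3.5 + length_mm]])
        return TubeSpec(name, pts, r, sinusoidal_waveform(mean, pi, n_cardiac_frames), cls)

    tubes = (
        tube("ICA-L", 5.0, 5.0, 2.0, 215.0, ica_pi, "artery"),
        tube("ICA-R", 15.0, 5.0, 2.0, 215.0, ica_pi, "artery"),
        tube("BA", 25.0, 5.0, 1.6, 126.0, ica_pi, "artery"),
        tube("distal-1", 5.0, 15.0, 0.5, 20.0, distal_pi, "artery"),
        tube("distal-2", 15.0, 15.0, 0.5, 15.0, distal_pi, "artery"),
        tube("distal-3", 25.0, 15.0, 0.5, 12.0, distal_pi, "artery"),
        tube("vein-1", 5.0, 25.0, 2.3, 280.0, vein_pi, "vein"),
        tube("vein-2", 20.0, 25.0, 2.3, 240.0, vein_pi, "vein"),
    )
    return FlowPhantomTruth(tubes=tubes)


def _polyline_geometry(points: np.ndarray, xyz: np.ndarray):
    """Distance from each coordinate to a polyline and the local tangent."""
    best_d = np.full(xyz.shape[0], np.inf)
    best_dir = np.zeros((xyz.shape[0], 3))
    for a, b in zip(points[:-1], points[1:]):
        ab = b - a
        L2 = float(ab @ ab)
        t = np.clip((xyz - a) @ ab / L2, 0.0, 1.0)
        proj = a + t[:, None] * ab
        d = np.linalg.norm(xyz - proj, axis=1)
        closer = d < best_d
        best_d[closer] = d[closer]
        best_dir[closer] = ab / np.sqrt(L2)
    return best_d, best_dir


def make_flow_phantom(
    truth: FlowPhantomTruth,
    shape: Sequence[int],
    spacing: float,
    params: AcquisitionParams,
    noise_sd: float = 0.0,
    cd_noise_sd: float = 0.0,
    background_gradient: np.ndarray | None = None,
    seed: int = 0,
) -> FlowPhantom:
    """Voxelize tubes into a 4D velocity field and a CD angiogram.

    Velocity is parallel to the local tube axis with a parabolic cross-section
    profile scaled so the cross-sectional integral equals the tube's waveform.
    The CD angiogram is flat across each lumen (proportional to the tube's
    time-averaged mean cross-section speed), emulating the saturated in-lumen
    contrast of complex-difference angiograms. Optional linear background
    drift per velocity component (``background_gradient``: (3, 4) array of
    [offset, d/dx, d/dy, d/dz] in cm/s and cm/s/mm) plus Gaussian noise.
    """
    shape = tuple(int(s) for s in shape)
    n_t = params.n_cardiac_frames
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    xyz = idx * spacing

    velocity = np.zeros((3,) + shape + (n_t,), dtype=float)
    cd = np.zeros(shape, dtype=float)
    tube_labels = np.zeros(shape, dtype=np.int32)
    tube_names: dict[str, int] = {}
    class_of = np.zeros(shape, dtype=np.int8)  # 0 none, 1 artery, 2 vein

    for ti, tube in enumerate(truth.tubes, start=1):
        pts = np.asarray(tube.points, dtype=float)
        if np.any(pts.min(axis=0) < 0) or np.any(pts.max(axis=0) > (np.array(shape) - 1) * spacing):
            raise ValueError(f"tube {tube.name!r} does not fit inside the grid")
        d, direction = _polyline_geometry(pts, xyz)
        inside = d <= tube.radius
        flat = inside.reshape(shape)
        cls = 1 if tube.vessel_class == "artery" else 2
        clash = (class_of[flat] != 0) & (class_of[flat] != cls)
        if np.any(clash):
            raise ValueError(
                f"tube {tube.name!r} overlaps a tube of a different vessel class"
            )
        class_of[flat] = cls
        tube_labels[flat] = ti
        tube_names[tube.name] = ti

        area = np.pi * tube.radius**2  # mm^2
        # ml/min over mm^2 -> cm/s: 1 ml/min = 1000/60 mm^3/s; /mm^2 -> mm/s; /10 -> cm/s
        v_mean = np.asarray(tube.waveform, dtype=float) * (1000.0 / 60.0 / 10.0) / area
        v_max = 2.0 * v_mean  # parabolic profile
        profile = 1.0 - (d[inside] / tube.radius) ** 2  # (Nin,)
        speed = profile[:, None] * v_max[None, :]  # (Nin, T) cm/s
        if np.any(np.abs(speed) >= params.venc):
            raise ValueError(f"tube {tube.name!r} peak speed exceeds venc")
        vox = np.where(inside)[0]
        comp = direction[inside]  # (Nin, 3)
        flat_view = velocity.reshape(3, -1, n_t)
        for c in range(3):
            flat_view[c, vox, :] += comp[:, c : c + 1] * speed
        cd.reshape(-1)[vox] = v_mean.mean()

    rng = np.random.default_rng(seed)
    if background_gradient is not None:
        bg = np.asarray(background_gradient, dtype=float)
        design = np.column_stack([np.ones(xyz.shape[0]), xyz])  # (N, 4)
        for c in range(3):
            drift = (design @ bg[c]).reshape(shape)
            velocity[c] += drift[..., None]
    if noise_sd > 0:
        velocity += rng.normal(0.0, noise_sd, size=velocity.shape)
    if cd_noise_sd > 0:
        cd = np.abs(cd + rng.normal(0.0, cd_noise_sd, size=cd.shape))

    return FlowPhantom(
        velocity=velocity,
        cd=cd,
        spacing=spacing,
        tube_labels=tube_labels,
        tube_names=tube_names,
        truth=truth,
    )


# --------------------------------------------------------------------------
# Cohort simulation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """One-factor cohort model for regional PS plus a linear PS->MoCA effect.

    PS_ij = mu_j + lambda_j f_i + eps_ij with f_i ~ N(0,1) (units
    10^-3 min^-1); MoCA_i = intercept + slope * mean_j PS_ij + noise.
    Pulsatility, total flow and age are drawn independently of PS (a null
    association by construction). Defaults reproduce the reference cohort
    structure: between-region correlation ~0.74, i.e. a first-principal-
    component variance share of ~0.76 over 15 regions, and a MoCA slope of
    -2.9 per 10^-3 min^-1.
    """

    n_subjects: int = 50
    region_means_ps: Mapping[str, float] = field(
        default_factory=lambda: dict(REFERENCE_PS_MEANS)
    )
    factor_loading: float = 0.172  # 10^-3 min^-1
    noise_sd: float = 0.101  # 10^-3 min^-1
    moca_slope: float = -2.9  # MoCA per 10^-3 min^-1
    moca_intercept: float = 27.96
    moca_noise_sd: float = 2.1
    region_means_vp: Mapping[str, float] = field(
        default_factory=lambda: dict(REFERENCE_VP_MEANS)
    )
    vp_factor_loading: float = 0.17  # percent
    vp_noise_sd: float = 0.11  # percent
    ica_pi_mean: float = 1.14
    ica_pi_sd: float = 0.20
    distal_pi_mean: float = 0.99
    distal_pi_sd: float = 0.16
    tcbf_mean: float = 556.0
    tcbf_sd: float = 98.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        if self.noise_sd < 0 or self.moca_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")


def loadings_for_first_pc_share(share: float, n_regions: int, noise_sd: float) -> float:
    """Factor loading giving a population first-PC variance share ``share``.

    For equal loadings the population correlation is rho = l^2/(l^2+s^2) and
    the first eigenvalue share of the correlation matrix is
    (1+(p-1) rho)/p; inverting gives l = s sqrt(rho/(1-rho)).
    """
    p = n_regions
    rho = (p * share - 1.0) / (p - 1.0)
    if not 0 < rho < 1:
        raise ValueError("share not attainable for this number of regions")
    return noise_sd * np.sqrt(rho / (1.0 - rho))


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a per-subject cohort table (PS in 10^-3 min^-1, v_p in %)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    regions = list(spec.region_means_ps)
    p = len(regions)

    f = rng.normal(size=n)
    eps = rng.normal(0.0, spec.noise_sd, size=(n, p))
    mu = np.array([spec.region_means_ps[r] for r in regions])
    ps = mu[None, :] + spec.factor_loading * f[:, None] + eps

    f2 = rng.normal(size=n)
    eps2 = rng.normal(0.0, spec.vp_noise_sd, size=(n, p))
    mu2 = np.array([spec.region_means_vp.get(r, 1.0) for r in regions])
    vp = mu2[None, :] + spec.vp_factor_loading * f2[:, None] + eps2

    whole_brain_ps = ps.mean(axis=1)
    moca = (
        spec.moca_intercept
        + spec.moca_slope * whole_brain_ps
        + rng.normal(0.0, spec.moca_noise_sd, size=n)
    )

    table = pd.DataFrame({"subject_id": [f"sub-{i:03d}" for i in range(n)]})
    table["age"] = rng.uniform(68.0, 84.0, size=n)
    table["sex"] = rng.choice(["M", "F"], size=n, p=[0.6, 0.4])
    table["moca"] = moca
    for j, r in enumerate(regions):
        table[f"ps_{r}"] = ps[:, j]
    for j, r in enumerate(regions):
        table[f"vp_{r}"] = vp[:, j]
    table["ica_pi"] = rng.normal(spec.ica_pi_mean, spec.ica_pi_sd, size=n)
    table["distal_pi"] = rng.normal(spec.distal_pi_mean, spec.distal_pi_sd, size=n)
    table["tcbf"] = rng.normal(spec.tcbf_mean, spec.tcbf_sd, size=n)
    return table
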