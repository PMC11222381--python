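"""B1-corrected variable-flip-angle T1 mapping and concentration conversion.

The VFA fit uses the standard linearization of the SPGR equation:
y = S/sin(a) versus x = S/tan(a) is a line with slope E1 = exp(-TR/T1) and
intercept M0 (1 - E1), with a = B1-corrected flip angle per voxel. Dynamic
signals are inverted analytically frame by frame (exact under the
fast-water-exchange assumption), and concentration follows
C(t) = (R1(t) - R10) / r1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "T1FitResult",
    "RelaxationSeries",
    "vfa_fit",
    "signal_to_r1",
    "r1_to_concentration",
]


@dataclass
class T1FitResult:
    """Baseline T1 (s) and equilibrium magnetization with a validity mask.

    Invalid voxels (degenerate or out-of-range linearized slope) are flagged,
    never silently imputed; t10/m0 are NaN there.
    """

    t10: np.ndarray  # s
    m0: np.ndarray  # a.u.
    valid: np.ndarray  # bool

    @property
    def r10(self) -> np.ndarray:
        """Baseline relaxation rate 1/T10 in s^-1."""
        return 1.0 / self.t10


@dataclass
class RelaxationSeries:
    """Longitudinal relaxation rate R1(t) in s^-1 with per-frame validity."""

    r1: np.ndarray  # (..., T) s^-1
    times: np.ndarray  # s
    valid: np.ndarray  # bool, same shape as r1


def vfa_fit(signals, flip_angles, b1=None, tr: float = 4.5) -> T1FitResult:
    """Fit T1 and M0 per voxel from SPGR volumes at several flip angles.

    Parameters
    ----------
    signals : sequence of arrays
        One volume (or scalar/1D array) per flip angle, equal shapes.
    flip_angles : sequence of float
        Nominal flip angles in degrees (>= 2 distinct values).
    b1 : array, optional
        Achieved/nominal flip-angle ratio per voxel; effective angles are
        ``b1 * flip_angles``. Default 1 everywhere.
    tr : float
        Repetition time in ms.

    Voxels whose linearized slope falls outside (0, 1), or with degenerate
    (constant) regressors, are marked invalid.
    """
    flip_angles = np.asarray(flip_angles, dtype=float)
    if flip_angles.size < 2 or np.unique(flip_angles).size < 2:
        raise ValueError("at least 2 distinct flip angles are required")
    s = np.stack([np.asarray(v, dtype=float) for v in signals], axis=0)  # (A, ...)
    if s.shape[0] != flip_angles.size:
        raise ValueError("one signal volume per flip angle is required")
    if b1 is None:
        b1 = np.ones(s.shape[1:])
    b1 = np.asarray(b1, dtype=float)

    alpha = np.deg2rad(flip_angles).reshape((-1,) + (1,) * b1.ndim) * b1[None]
    with np.errstate(divide="ignore", invalid="ignore"):
        y = s / np.sin(alpha)
        x = s / np.tan(alpha)
    xm = x.mean(axis=0)
    ym = y.mean(axis=0)
    sxx = ((x - xm) ** 2).sum(axis=0)
    sxy = ((x - xm) * (y - ym)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        intercept = ym - slope * xm
        t10 = -(tr / 1000.0) / np.log(slope)
        m0 = intercept / (1.0 - slope)

    valid = (
        np.isfinite(slope)
        & (slope > 0)
        & (slope < 1)
        & (sxx > 0)
        & np.all(s > 0, axis=0)
        & (np.ptp(s, axis=0) > 0)  # identical signal at all angles: degenerate
    )
    t10 = np.where(valid, t10, np.nan)
    m0 = np.where(valid, m0, np.nan)
    return T1FitResult(t10=np.asarray(t10), m0=np.asarray(m0), valid=np.asarray(valid))


def signal_to_r1(
    signal,
    times,
    t10,
    flip_angle: float,
    b1=None,
    tr: float = 4.5,
    n_baseline_frames: int = 3,
) -> RelaxationSeries:
    """Invert a dynamic SPGR signal to R1(t) analytically, frame by frame.

    The dynamic equilibrium signal M0 is estimated per voxel from the mean of
    the first ``n_baseline_frames`` frames together with the baseline T10,
    so that the baseline mean of R1(t) reproduces R10 exactly. Each frame is
    then inverted through

        E1 = (S - M0 sin a) / (S cos a - M0 sin a),   R1 = -ln(E1)/TR,

    with a the B1-corrected flip angle. Frames whose E1 falls outside (0, 1)
    (e.g. zero signal) are flagged invalid and carry NaN.
    """
    if n_baseline_frames < 1:
        raise ValueError("n_baseline_frames must be >= 1")
    s = np.asarray(signal, dtype=float)  # (..., T)
    times = np.asarray(times, dtype=float)
    t10 = np.asarray(t10, dtype=float)
    if b1 is None:
        b1 = np.ones(np.shape(t10))
    a = np.deg2rad(flip_angle) * np.asarray(b1, dtype=float)[..., None]
    tr_s = tr / 1000.0

    e10 = np.exp(-tr_s / t10)[..., None]
    s_base = s[..., :n_baseline_frames].mean(axis=-1, keepdims=True)
    m0 = s_base * (1.0 - np.cos(a) * e10) / (np.sin(a) * (1.0 - e10))

    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (s - m0 * np.sin(a)) / (s * np.cos(a) - m0 * np.sin(a))
        valid = np.isfinite(e1) & (e1 > 0) & (e1 < 1)
        r1 = np.where(valid, -np.log(np.where(valid, e1, 0.5)) / tr_s, np.nan)
    return RelaxationSeries(r1=r1, times=times, valid=valid)


def r1_to_concentration(series: RelaxationSeries, r10, relaxivity: float = 3.5):
    """Convert R1(t) to gadolinium concentration, C(t) = (R1 - R10)/r1 in mM.

    Negative concentrations (noise) are preserved but counted in the QC
    report returned alongside the curves.

    Returns
    -------
    concentration : ndarray
        mM, same shape as ``series.r1`` (NaN where the source frame is invalid).
    qc : dict
        ``n_negative`` and ``fraction_negative`` over valid samples.
    """
    if relaxivity <= 0:
        raise ValueError("relaxivity must be positive")
    r10 = np.asarray(r10, dtype=float)
    c = (series.r1 - r10[..., None] if r10.ndim else series.r1 - r10) / relaxivity
    valid = series.valid & np.isfinite(c)
    # negatives below numerical rounding scale are genuine (noise), not fp dust
    n_neg = int(np.sum(c[valid] < -1e-12))
    n_valid = int(valid.sum())
    qc = {
        "n_negative": n_neg,
        "fraction_negative": n_neg / n_valid if n_valid else float("nan"),
    }
    return c, qc
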