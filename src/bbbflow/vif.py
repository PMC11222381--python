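"""Vascular input function extraction from the superior sagittal sinus.

A seed voxel placed in the sinus defines a reference time curve; voxels
whose signal curves correlate with it above a strict threshold (default
Pearson R >= 0.99) form the sinus mask, which is thinned to a one-voxel
centerline. The blood curve is the mean concentration over a contiguous run
of centerline voxels (default 25) around the seed, and the plasma input
function follows from the hematocrit: C_VIF = C_b / (1 - HCT).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .phantom import AcquisitionParams, DCESeries

__all__ = [
    "VIFExtraction",
    "correlation_mask",
    "mask_centerline",
    "extract_vif",
    "auto_seed",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class VIFExtraction:
    """Provenance and curves of one input-function extraction."""

    seed_voxel: tuple[int, int, int]
    correlation_threshold: float
    centerline_voxels: np.ndarray  # (N, 3) ordered along the path
    n_averaged: int
    blood_curve: np.ndarray  # C_b, mM
    plasma_curve: np.ndarray  # C_VIF, mM
    hematocrit: float


def correlation_mask(series: DCESeries, seed: tuple[int, int, int], threshold: float = 0.99) -> np.ndarray:
    """Voxels whose time curves correlate with the seed curve at >= threshold.

    Pearson correlation is computed on the raw signal curves. The seed voxel
    is always included. A constant seed curve is an error.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    data = series.data
    seed = tuple(int(i) for i in seed)
    ref = data[seed].astype(float)
    ref_c = ref - ref.mean()
    ref_norm = np.sqrt((ref_c**2).sum())
    if ref_norm == 0 or np.ptp(ref) == 0:
        raise ValueError("seed voxel time curve is constant")
    x = data - data.mean(axis=-1, keepdims=True)
    denom = np.sqrt((x**2).sum(axis=-1)) * ref_norm
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (x @ ref_c) / denom
    # 1e-12 slack keeps voxels with identical curves inside a threshold of 1.0
    mask = np.nan_to_num(r, nan=-1.0) >= threshold - 1e-12
    mask[seed] = True
    return mask


def _skeleton_graph(voxels: np.ndarray) -> nx.Graph:
    """26-connectivity graph over skeleton voxels, Euclidean edge weights."""
    g = nx.Graph()
    vset = {tuple(v): i for i, v in enumerate(map(tuple, voxels))}
    for v in vset:
        g.add_node(v)
    for v in vset:
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    if di == dj == dk == 0:
                        continue
                    w = (v[0] + di, v[1] + dj, v[2] + dk)
                    if w in vset:
                        g.add_edge(v, w, weight=float(np.sqrt(di * di + dj * dj + dk * dk)))
    return g


def _longest_path(g: nx.Graph) -> list[tuple[int, int, int]]:
    """Longest weighted shortest path through the graph (double sweep).

    Ties are broken lexicographically by voxel index for determinism.
    """
    start = min(g.nodes)
    def farthest(src):
        dist = nx.single_source_dijkstra_path_length(g, src)
        dmax = max(dist.values())
        return min(n for n, d in dist.items() if d == dmax), dmax
    u, _ = farthest(start)
    v, _ = farthest(u)
    a, b = sorted((u, v))
    return nx.dijkstra_path(g, a, b)


def mask_centerline(mask: np.ndarray) -> np.ndarray:
    """One-voxel-wide ordered centerline of a binary mask.

    3D thinning followed by extraction of the longest path through the
    thinned set. The mask must be non-empty and 26-connected; the returned
    array is (N, 3) voxel indices ordered along the path.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("centerline extraction failed: mask is empty")
    _, n_comp = ndimage.label(mask, structure=_STRUCT26)
    if n_comp > 1:
        raise ValueError(
            f"centerline extraction failed: mask has {n_comp} disconnected components"
        )
    if n == 1:
        return np.argwhere(mask)
    skel = skeletonize(mask)
    if not skel.any():  # tiny blobs can thin away entirely
        skel = mask
    voxels = np.argwhere(skel)
    g = _skeleton_graph(voxels)
    if g.number_of_edges() == 0:
        return voxels[:1]
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    path = _longest_path(g.subgraph(comps[0]))
    return np.array(path, dtype=int)


def _centerline_window(centerline: np.ndarray, seed: tuple[int, int, int], n: int) -> np.ndarray:
    """Contiguous run of ``n`` centerline voxels starting at the point closest
    to the seed, extended toward the longer limb of the path."""
    d = np.linalg.norm(centerline - np.asarray(seed, dtype=float), axis=1)
    i0 = int(np.argmin(d))
    lo = hi = i0
    while hi - lo + 1 < n:
        room_left = lo
        room_right = len(centerline) - 1 - hi
        if room_right >= room_left and room_right > 0:
            hi += 1
        elif room_left > 0:
            lo -= 1
        else:  # pragma: no cover - guarded by caller length check
            break
    return centerline[lo : hi + 1]


def extract_vif(
    series: DCESeries,
    concentration: np.ndarray,
    seed: tuple[int, int, int],
    params: AcquisitionParams,
    threshold: float = 0.99,
    n_averaged: int = 25,
) -> VIFExtraction:
    """Extract the plasma input function around a sinus seed voxel.

    ``concentration`` is the per-voxel concentration volume (..., T) from
    which the blood curve is averaged; the correlation mask itself is built
    on the raw signal ``series``. The blood curve C_b is the mean over the
    ``n_averaged`` centerline voxels nearest the seed, and
    C_VIF = C_b / (1 - HCT).
    """
    mask = correlation_mask(series, seed, threshold)
    centerline = mask_centerline(mask)
    if len(centerline) < n_averaged:
        raise ValueError(
            f"centerline has {len(centerline)} voxels, fewer than n_averaged="
            f"{n_averaged}; use n_averaged <= {len(centerline)}"
        )
    window = _centerline_window(centerline, seed, n_averaged)
    curves = concentration[tuple(window.T)]  # (n, T)
    blood = np.nanmean(curves, axis=0)
    plasma = blood / (1.0 - params.hematocrit)
    return VIFExtraction(
        seed_voxel=tuple(int(i) for i in seed),
        correlation_threshold=threshold,
        centerline_voxels=centerline,
        n_averaged=n_averaged,
        blood_curve=blood,
        plasma_curve=plasma,
        hematocrit=params.hematocrit,
    )


def auto_seed(series: DCESeries, mask: np.ndarray | None = None, n_baseline_frames: int = 3) -> tuple[int, int, int]:
    """Voxel of maximum signal enhancement (peak minus baseline mean).

    A convenience for pipelines; interactive use places the seed manually at
    the enhancement peak in the posterior sinus.
    """
    base = series.data[..., :n_baseline_frames].mean(axis=-1)
    enh = series.data.max(axis=-1) - base
    if mask is not None:
        enh = np.where(mask, enh, -np.inf)
    return tuple(int(i) for i in np.unravel_index(np.argmax(enh), enh.shape))
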