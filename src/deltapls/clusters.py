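"""Smoothness estimation and Monte-Carlo cluster-extent thresholding.

Voxelwise BSR maps are thresholded two-sided at p = .005 and surviving
voxels are grouped into connected components; a component is reported only
if it exceeds a minimum extent calibrated so that the chance of any
suprathreshold cluster that large in a smooth Gaussian null field is at
most alpha.  Smoothness (FWHM of the effective Gaussian autocorrelation)
is estimated from residual maps with the classical first-neighbor
variance-ratio estimator and fed to the null simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .io import MaskGeometry
from .simulate import smooth_gaussian_field


@dataclass
class SmoothnessEstimate:
    """Per-axis FWHM (mm) of the spatial autocorrelation, plus summary."""

    fwhm: np.ndarray            # per axis, mm
    fwhm_mean: float            # geometric mean across axes
    n_maps: int


def estimate_fwhm(
    residual_maps: list[np.ndarray] | np.ndarray,
    geometry: MaskGeometry,
) -> SmoothnessEstimate:
    """Estimate smoothness from in-mask residual maps.

    Per axis, FWHM = dx * sqrt(-2 ln 2 / ln(1 - s2_diff / (2 s2))) where
    s2_diff is the variance of first-neighbor differences inside the mask
    and s2 the voxel variance; estimates are averaged over maps.  Fields
    at least as rough as white noise (ratio >= 1) give FWHM 0 with a
    warning, as do degenerate constant maps.
    """
    maps = np.atleast_2d(np.asarray(residual_maps, float))
    if geometry.n_voxels < 100:
        raise ValueError("mask too small for smoothness estimation")
    mask = geometry.mask
    per_map = np.zeros((len(maps), 3))
    for mi, values in enumerate(maps):
        vol = geometry.unmask(values, fill=np.nan)
        v = values - values.mean()
        s2 = float(v @ v) / (v.size - 1)
        if s2 <= 0:
            warnings.warn("constant residual map: smoothness undefined, "
                          "FWHM set to 0", stacklevel=2)
            continue
        for axis in range(3):
            a = np.moveaxis(vol, axis, 0)
            d = a[1:] - a[:-1]
            d = d[np.isfinite(d)]
            if d.size < 10:
                continue
            s2_diff = float(np.var(d, ddof=1))
            ratio = s2_diff / (2.0 * s2)
            if ratio >= 1.0:
                warnings.warn(
                    "residuals rougher than white noise along axis "
                    f"{axis}; FWHM set to 0", stacklevel=2,
                )
                continue
            per_map[mi, axis] = geometry.voxel_size[axis] * np.sqrt(
                -2.0 * np.log(2.0) / np.log(1.0 - ratio)
            )
    fwhm = per_map.mean(axis=0)
    positive = fwhm[fwhm > 0]
    gmean = float(np.exp(np.mean(np.log(positive)))) if positive.size == 3 else 0.0
    return SmoothnessEstimate(fwhm=fwhm, fwhm_mean=gmean, n_maps=len(maps))


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, connectivity)


def simulate_cluster_threshold(
    geometry: MaskGeometry,
    fwhm: float,
    voxel_p: float = 0.005,
    alpha: float = 0.05,
    n_sim: int = 2000,
    connectivity: int = 1,
    seed: int | None = None,
) -> int:
    """Minimum cluster extent (voxels) controlling familywise error.

    Simulates ``n_sim`` smooth standard-normal null fields on the mask,
    thresholds two-sided at |z| > Phi^-1(1 - voxel_p/2), and records the
    largest suprathreshold cluster per field.  The returned minimum size is
    one more than the ceil((1-alpha)*n_sim)-th order statistic, so a
    cluster at least this large occurs in at most ~alpha of null fields.
    Deterministic given the seed.  Connectivity 1 = faces only (NN1).
    """
    if n_sim < 200:
        warnings.warn("n_sim < 200 gives a noisy cluster threshold",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    zcrit = stats.norm.ppf(1.0 - voxel_p / 2.0)
    struct = _structure(connectivity)
    mask = geometry.mask
    max_sizes = np.zeros(n_sim, dtype=int)
    for i in range(n_sim):
        field3d = smooth_gaussian_field(
            geometry.dims, geometry.voxel_size, fwhm, rng
        )
        supra = (np.abs(field3d) > zcrit) & mask
        if not supra.any():
            continue
        labels, n_lab = ndimage.label(supra, structure=struct)
        if n_lab:
            sizes = np.bincount(labels.ravel())[1:]
            max_sizes[i] = int(sizes.max())
    order = np.sort(max_sizes)
    k = int(np.ceil((1.0 - alpha) * n_sim)) - 1
    return int(order[k]) + 1


@dataclass
class ClusterTable:
    """Significant clusters of a thresholded statistic map.

    ``table`` rows (sorted by size, descending) report the |BSR|-weighted
    center of mass in template mm coordinates, the extent in voxels and
    mm^3, and the peak signed BSR.  ``labels`` assigns each in-mask voxel
    its cluster id (0 = not significant), so the significant-voxel set is
    ``labels > 0``.
    """

    table: pd.DataFrame
    labels: np.ndarray
    voxel_p: float
    min_size: int
    connectivity: int = 1

    @property
    def cluster_mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())


def extract_clusters(
    stat_map: np.ndarray,
    geometry: MaskGeometry,
    min_size: int,
    voxel_p: float = 0.005,
    connectivity: int = 1,
) -> ClusterTable:
    """Threshold a BSR map and report clusters exceeding the extent cutoff.

    Voxels with |BSR| >= Phi^-1(1 - voxel_p/2) are kept (two-sided);
    connected components below ``min_size`` voxels are dropped.  An empty
    table is a legitimate outcome.
    """
    stat_map = np.asarray(stat_map, float)
    zcrit = stats.norm.ppf(1.0 - voxel_p / 2.0)
    vol = geometry.unmask(stat_map)
    supra = (np.abs(vol) >= zcrit) & geometry.mask
    labels3d, n_lab = ndimage.label(supra, structure=_structure(connectivity))

    rows = []
    keep = np.zeros_like(labels3d)
    next_id = 0
    comps = []
    for lab in range(1, n_lab + 1):
        coords = np.argwhere(labels3d == lab)
        if len(coords) < min_size:
            continue
        vals = vol[tuple(coords.T)]
        w = np.abs(vals)
        com_vox = (coords * w[:, None]).sum(axis=0) / w.sum()
        com_mm = geometry.coords_mm(com_vox)
        peak = vals[int(np.argmax(w))]
        comps.append((len(coords), com_mm, peak, coords))
    comps.sort(key=lambda c: -c[0])
    for size, com_mm, peak, coords in comps:
        next_id += 1
        keep[tuple(coords.T)] = next_id
        rows.append({
            "cluster_id": next_id,
            "x_mm": float(com_mm[0]), "y_mm": float(com_mm[1]),
            "z_mm": float(com_mm[2]),
            "size_voxels": int(size),
            "size_mm3": float(size * geometry.voxel_volume),
            "peak_bsr": float(peak),
        })
    table = pd.DataFrame(
        rows, columns=["cluster_id", "x_mm", "y_mm", "z_mm",
                       "size_voxels", "size_mm3", "peak_bsr"],
    )
    return ClusterTable(
        table=table,
        labels=keep[geometry.mask],
        voxel_p=voxel_p,
        min_size=min_size,
        connectivity=connectivity,
    )
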