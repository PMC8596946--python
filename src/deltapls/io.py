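"""Data model and NIfTI/CSV input-output for masked brain parameter maps.

The pipeline operates on scalar parameter maps (CBF in ml/100 g/min, FA
dimensionless, MD on an mm^2/s-derived scale) sampled on a shared voxel
grid and restricted to a binary analysis mask.  Maps are stored on disk as
NIfTI-1 volumes (float32) and held in memory as float64 vectors over the
in-mask voxels, in a fixed linear order defined by :class:`MaskGeometry`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

SESSIONS = ("ACU", "RTP", "YR1")
MODALITIES = ("CBF", "FA", "MD")
GROUPS = ("control", "concussed")

MANIFEST_COLUMNS = [
    "subject_id", "group", "sex", "age", "hoc", "n_prior",
    "months_since_last", "sport", "days_to_rtp", "session", "modality",
    "volume_path",
]


class SchemaError(ValueError):
    """Manifest or table does not have the expected columns/values."""


class GeometryError(ValueError):
    """Volume dimensions or affine do not match the analysis mask."""


class DataError(ValueError):
    """Voxel data violate an invariant (non-finite values, range)."""


@dataclass
class SubjectRecord:
    """Demographics and group membership for one participant.

    ``sex`` is coded 0 = male, 1 = female; ``hoc`` flags a history of
    concussion prior to the study injury.
    """

    subject_id: str
    group: str
    sex: int
    age: float
    hoc: int
    n_prior_concussions: int = 0
    months_since_last: float | None = None
    sport: str = ""
    days_to_rtp: int | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise SchemaError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.sex not in (0, 1):
            raise SchemaError(f"sex must be 0 or 1, got {self.sex!r}")
        if self.hoc not in (0, 1):
            raise SchemaError(f"hoc must be 0 or 1, got {self.hoc!r}")
        if self.n_prior_concussions < 0:
            raise SchemaError("n_prior_concussions must be >= 0")
        if (self.n_prior_concussions > 0) != (self.hoc == 1):
            raise SchemaError(
                f"subject {self.subject_id}: n_prior_concussions>0 iff hoc=1"
            )
        if self.days_to_rtp is not None and self.group != "concussed":
            raise SchemaError(
                f"subject {self.subject_id}: days_to_rtp only valid for concussed"
            )


@dataclass
class MaskGeometry:
    """Voxel grid plus the bijection between in-mask voxels and columns.

    Voxel indices are 0-based; the mm coordinate of voxel ``(i,j,k)`` is
    ``origin + index * voxel_size`` (maps are assumed pre-aligned to a
    common template; no registration is performed here).
    """

    mask: np.ndarray                 # 3-D boolean
    voxel_size: np.ndarray = field(default_factory=lambda: np.array([3.0, 3.0, 3.0]))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise GeometryError("mask must be a 3-D array")
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.voxel_indices = np.argwhere(self.mask)  # (N, 3), linear order

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_size))

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(np.append(self.voxel_size, 1.0))
        aff[:3, 3] = self.origin
        return aff

    def coords_mm(self, voxel_indices: np.ndarray) -> np.ndarray:
        """Convert 0-based voxel indices (…,3) to template mm coordinates."""
        return self.origin + np.asarray(voxel_indices, float) * self.voxel_size

    def mask_values(self, volume: np.ndarray) -> np.ndarray:
        """Extract in-mask values from a 3-D volume in linear-index order."""
        volume = np.asarray(volume)
        if volume.shape != self.dims:
            raise GeometryError(
                f"volume shape {volume.shape} does not match mask {self.dims}"
            )
        return np.asarray(volume[self.mask], dtype=np.float64)

    def unmask(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a length-N vector back into a 3-D volume."""
        values = np.asarray(values)
        if values.shape != (self.n_voxels,):
            raise GeometryError(
                f"expected {self.n_voxels} values, got {values.shape}"
            )
        vol = np.full(self.dims, fill, dtype=np.float64)
        vol[self.mask] = values
        return vol


@dataclass
class ParameterMap:
    """One subject/session/modality scalar map over the in-mask voxels."""

    subject_id: str
    session: str
    modality: str
    values: np.ndarray
    geometry: MaskGeometry

    def __post_init__(self) -> None:
        if self.session not in SESSIONS + ("CONTROL",):
            raise SchemaError(f"unknown session {self.session!r}")
        if self.modality not in MODALITIES:
            raise SchemaError(f"unknown modality {self.modality!r}")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.geometry.n_voxels,):
            raise GeometryError(
                f"{self.subject_id}/{self.session}/{self.modality}: "
                f"{self.values.size} values for a {self.geometry.n_voxels}-voxel mask"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataError(
                f"non-finite voxel values for subject {self.subject_id} "
                f"({self.session}, {self.modality})"
            )
        if self.modality == "FA" and (
            self.values.min() < 0.0 or self.values.max() > 1.0
        ):
            raise DataError(
                f"FA values outside [0, 1] for subject {self.subject_id}"
            )


def read_mask(mask_path: str | Path) -> MaskGeometry:
    """Load a binary NIfTI mask and derive the voxel geometry from it."""
    img = nib.load(str(mask_path))
    data = np.asanyarray(img.dataobj)
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return MaskGeometry(mask=data > 0, voxel_size=zooms, origin=origin)


def read_cohort(
    manifest_path: str | Path,
    volume_dir: str | Path,
    mask_path: str | Path,
) -> tuple[list[SubjectRecord], list[ParameterMap], MaskGeometry]:
    """Read a cohort manifest and the NIfTI volumes it references.

    The manifest CSV has one row per (subject, session, modality) with the
    columns in :data:`MANIFEST_COLUMNS`; ``volume_path`` is relative to
    ``volume_dir``.  Returns one :class:`ParameterMap` per row, values
    extracted in mask linear order, plus one :class:`SubjectRecord` per
    distinct subject.
    """
    manifest = pd.read_csv(manifest_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise SchemaError(f"manifest is missing columns: {missing}")
    geometry = read_mask(mask_path)
    volume_dir = Path(volume_dir)

    records: dict[str, SubjectRecord] = {}
    maps: list[ParameterMap] = []
    for row in manifest.itertuples(index=False):
        sid = str(row.subject_id)
        if sid not in records:
            records[sid] = SubjectRecord(
                subject_id=sid,
                group=str(row.group),
                sex=int(row.sex),
                age=float(row.age),
                hoc=int(row.hoc),
                n_prior_concussions=int(row.n_prior),
                months_since_last=(
                    None if pd.isna(row.months_since_last)
                    else float(row.months_since_last)
                ),
                sport=str(row.sport),
                days_to_rtp=(
                    None if pd.isna(row.days_to_rtp) else int(row.days_to_rtp)
                ),
            )
        vol_path = volume_dir / str(row.volume_path)
        if not vol_path.exists():
            raise FileNotFoundError(f"volume not found: {vol_path}")
        img = nib.load(str(vol_path))
        data = np.asanyarray(img.dataobj)
        if data.shape != geometry.dims:
            raise GeometryError(
                f"{vol_path}: shape {data.shape} does not match mask "
                f"{geometry.dims}"
            )
        values = geometry.mask_values(data)
        if not np.all(np.isfinite(values)):
            raise DataError(f"NaN/Inf inside mask for subject {sid} ({vol_path})")
        maps.append(
            ParameterMap(
                subject_id=sid,
                session=str(row.session),
                modality=str(row.modality),
                values=values,
                geometry=geometry,
            )
        )
    return list(records.values()), maps, geometry


def write_stat_map(
    values: np.ndarray, geometry: MaskGeometry, path: str | Path
) -> Path:
    """Write a masked statistic vector as a float32 NIfTI volume.

    Out-of-mask voxels are set to 0.
    """
    vol = geometry.unmask(np.asarray(values, dtype=np.float64)).astype(np.float32)
    img = nib.Nifti1Image(vol, geometry.affine)
    img.header.set_zooms(tuple(geometry.voxel_size))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def write_mask(geometry: MaskGeometry, path: str | Path) -> Path:
    """Write the binary mask itself as a uint8 NIfTI volume."""
    img = nib.Nifti1Image(
        geometry.mask.astype(np.uint8), geometry.affine
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def _check_probability(name: str, p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.min() < 0.0 or p.max() > 1.0:
        raise DataError(f"{name} probabilities outside [0, 1]")
    return p


def build_gm_mask(
    p_gm: np.ndarray,
    p_wm: np.ndarray,
    p_csf: np.ndarray,
    mean_control_cbf: np.ndarray,
    cbf_floor: float = 20.0,
    exclusion_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Gray-matter analysis mask from tissue probabilities and control CBF.

    A voxel enters the mask iff p(GM) > p(WM) + p(CSF) and the mean control
    CBF strictly exceeds ``cbf_floor`` (ml/100 g/min); this suppresses
    white-matter partial-volume voxels.  An optional exclusion mask (e.g.
    manually traced ventricles) removes voxels regardless of the rules.
    """
    p_gm = _check_probability("GM", p_gm)
    p_wm = _check_probability("WM", p_wm)
    p_csf = _check_probability("CSF", p_csf)
    mean_control_cbf = np.asarray(mean_control_cbf, dtype=float)
    mask = (p_gm > p_wm + p_csf) & (mean_control_cbf > cbf_floor)
    if exclusion_mask is not None:
        mask = mask & ~np.asarray(exclusion_mask, dtype=bool)
    return mask


def build_wm_mask(
    template_fa: np.ndarray,
    fa_floor: float = 0.30,
    exclusion_mask: np.ndarray | None = None,
) -> np.ndarray:
    """White-matter analysis mask: template FA strictly above ``fa_floor``.

    An optional exclusion mask removes regions such as the brain stem where
    field inhomogeneity corrupts the diffusion fit.
    """
    fa = np.asarray(template_fa, dtype=float)
    if fa.min() < 0.0 or fa.max() > 1.0:
        raise DataError("FA template values outside [0, 1]")
    mask = fa > fa_floor
    if exclusion_mask is not None:
        mask = mask & ~np.asarray(exclusion_mask, dtype=bool)
    if not mask.any():
        warnings.warn("white-matter mask is empty", stacklevel=2)
    return mask


def maps_to_matrix(
    maps: Iterable[ParameterMap],
    subject_ids: Sequence[str],
    sessions: Sequence[str] = SESSIONS,
) -> np.ndarray:
    """Stack maps into a (subjects, sessions, voxels) array, NaN = missing."""
    maps = list(maps)
    if not maps:
        raise DataError("no maps supplied")
    V = maps[0].geometry.n_voxels
    out = np.full((len(subject_ids), len(sessions), V), np.nan)
    pos = {(s, t): (i, j) for i, s in enumerate(subject_ids)
           for j, t in enumerate(sessions)}
    for m in maps:
        key = (m.subject_id, m.session)
        if key in pos:
            i, j = pos[key]
            out[i, j] = m.values
    return out
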