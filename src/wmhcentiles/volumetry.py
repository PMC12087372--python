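"""Voxel-counting volumetry of WMH masks on a shared template grid.

All volumes are exact integer voxel counts scaled by the voxel volume; the
only floating-point step is the final multiply. Masks are restricted to
white matter by removing voxels whose WM probability falls below a
threshold (default 30%), and regional volumes are taken inside
probabilistic tract maps thresholded at 10%. Volumes are reported both in
mL and on the log10(v + 0.001) scale — the one-voxel offset makes empty
masks representable (log10(0.001) = -3).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .tracts import validate_tract_names

#: One 1 mm isotropic template voxel, in mL.
VOXEL_ML = 0.001

#: Offset added before log10 so zero volumes transform to -3.
LOG_OFFSET_ML = 0.001

DEFAULT_WM_THRESHOLD = 0.30
DEFAULT_TRACT_THRESHOLD = 0.10


@dataclass
class LabelVolume:
    """A binary lesion mask on the template grid."""

    grid: np.ndarray
    voxel_volume: float = VOXEL_ML

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {grid.shape}")
        if self.voxel_volume <= 0:
            raise ValueError("voxel_volume must be positive")
        if grid.dtype != bool:
            vals = np.unique(grid)
            if not np.isin(vals, (0, 1)).all():
                warnings.warn(
                    "non-binary mask input; binarizing at > 0.5", stacklevel=2
                )
                grid = grid > 0.5
            else:
                grid = grid.astype(bool)
        self.grid = grid

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())


@dataclass
class ProbabilityVolume:
    """A probabilistic map (WM prior or tract) on the template grid."""

    grid: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        if grid.ndim != 3:
            raise ValueError(f"probability volume must be 3D, got {grid.shape}")
        if np.nanmin(grid) < 0 or np.nanmax(grid) > 1:
            raise ValueError(f"probabilities outside [0,1] in {self.name!r}")
        self.grid = grid


@dataclass
class VolumeReport:
    """Total and per-tract WMH volumes for one subject."""

    subject_id: str
    total_ml: float
    total_log10: float
    per_tract: dict[str, tuple[float, float]] = field(default_factory=dict)
    wm_threshold: float = DEFAULT_WM_THRESHOLD
    tract_threshold: float = DEFAULT_TRACT_THRESHOLD

    def to_row(self, tract_order: Iterable[str] | None = None) -> dict:
        order = list(tract_order) if tract_order is not None else list(self.per_tract)
        row = {"id": self.subject_id, "total_ml": self.total_ml,
               "total_log10": self.total_log10}
        for t in order:
            ml, lg = self.per_tract[t]
            row[f"{t}_ml"] = ml
            row[f"{t}_log10"] = lg
        return row

    def to_json(self) -> str:
        return json.dumps(
            {
                "id": self.subject_id,
                "total_ml": self.total_ml,
                "total_log10": self.total_log10,
                "wm_threshold": self.wm_threshold,
                "tract_threshold": self.tract_threshold,
                "per_tract": {t: {"ml": ml, "log10": lg}
                              for t, (ml, lg) in self.per_tract.items()},
            },
            indent=2,
        )


def _check_same_grid(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(
            f"grid dimension mismatch: mask {a.shape} vs volume {b.shape}; "
            "inputs must share the template lattice (no resampling is done)"
        )


def restrict_to_wm(
    mask: LabelVolume,
    wm_prob: ProbabilityVolume,
    threshold: float = DEFAULT_WM_THRESHOLD,
) -> LabelVolume:
    """Remove mask voxels that fall below the WM probability threshold.

    A voxel survives iff it is set in the mask AND its WM probability is
    >= ``threshold`` (voxels "below" the threshold are removed, so the
    boundary is kept). Idempotent; never gains voxels.
    """
    _check_same_grid(mask.grid, wm_prob.grid)
    kept = mask.grid & (wm_prob.grid >= threshold)
    return LabelVolume(kept, voxel_volume=mask.voxel_volume)


def total_volume(mask: LabelVolume) -> float:
    """Total mask volume in mL (voxel count times voxel volume)."""
    return mask.n_voxels * mask.voxel_volume


def tract_volume(
    mask: LabelVolume,
    tract_prob: ProbabilityVolume,
    threshold: float = DEFAULT_TRACT_THRESHOLD,
) -> float:
    """Mask volume inside a probabilistic tract thresholded at ``threshold``.

    Tracts may overlap, so per-tract volumes need not sum to the total.
    """
    _check_same_grid(mask.grid, tract_prob.grid)
    n = int((mask.grid & (tract_prob.grid >= threshold)).sum())
    return n * mask.voxel_volume


def log_offset_transform(v_ml: float) -> float:
    """log10(v + 0.001); the offset is one template voxel."""
    v_ml = float(v_ml)
    if v_ml < 0:
        raise ValueError(f"volume must be nonnegative, got {v_ml}")
    return float(np.log10(v_ml + LOG_OFFSET_ML))


def back_transform(x_log10: float) -> float:
    """Inverse of :func:`log_offset_transform`, clipped at zero."""
    return float(max(10.0 ** float(x_log10) - LOG_OFFSET_ML, 0.0))


def report(
    mask: LabelVolume,
    wm_prob: ProbabilityVolume,
    atlas: Mapping[str, ProbabilityVolume] | Iterable[ProbabilityVolume] | None = None,
    wm_threshold: float = DEFAULT_WM_THRESHOLD,
    tract_threshold: float = DEFAULT_TRACT_THRESHOLD,
    subject_id: str = "",
) -> VolumeReport:
    """Full volumetry for one subject: WM restriction, total, per-tract.

    The WM restriction is applied once, before both the total and the
    regional volumes, so tract volumes are always measured on the
    restricted mask.
    """
    if atlas is None:
        tract_vols: dict[str, ProbabilityVolume] = {}
    elif isinstance(atlas, Mapping):
        tract_vols = dict(atlas)
        validate_tract_names(tract_vols)
    else:
        vols = list(atlas)
        validate_tract_names(v.name for v in vols)
        tract_vols = {v.name: v for v in vols}

    restricted = restrict_to_wm(mask, wm_prob, wm_threshold)
    tot = total_volume(restricted)
    per_tract = {}
    for name, prob in tract_vols.items():
        ml = tract_volume(restricted, prob, tract_threshold)
        per_tract[name] = (ml, log_offset_transform(ml))
    return VolumeReport(
        subject_id=subject_id,
        total_ml=tot,
        total_log10=log_offset_transform(tot),
        per_tract=per_tract,
        wm_threshold=wm_threshold,
        tract_threshold=tract_threshold,
    )


# ---------------------------------------------------------------------------
# NIfTI I/O


def _nifti_voxel_volume_ml(img) -> float:
    zooms = img.header.get_zooms()[:3]
    return float(np.prod(zooms)) * 0.001  # mm^3 -> mL


def load_mask(path) -> LabelVolume:
    """Read a binary mask from NIfTI; voxel volume comes from the header."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    return LabelVolume(data, voxel_volume=_nifti_voxel_volume_ml(img))


def load_probability(path, name: str = "") -> ProbabilityVolume:
    import nibabel as nib

    img = nib.load(str(path))
    return ProbabilityVolume(np.asanyarray(img.dataobj).astype(float), name=name)


def save_volume(grid: np.ndarray, path, voxel_mm: float = 1.0) -> None:
    """Write a grid as NIfTI-1 with an identity-like affine."""
    import nibabel as nib

    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(grid, dtype=np.float32), affine)
    nib.save(img, str(path))
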