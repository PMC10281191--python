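"""4-D voxel time-series container with NIfTI-1 round-trip.

A :class:`VolumeSeries` is one subject's resting-state scan: a ``(x, y, z, t)``
array on a regular voxel grid, plus the acquisition geometry (voxel size, TR)
and the subject metadata the downstream analysis needs (group arm, lesion
side). Synthetic cohorts and real NIfTI files are represented identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeSeries"]


@dataclass
class VolumeSeries:
    """One subject's 4-D voxel time series.

    Parameters
    ----------
    data
        Array of shape ``(x, y, z, t)``; finite values.
    voxel_size_mm
        Edge lengths of one voxel, in millimetres, per spatial axis.
    tr_seconds
        Repetition time between consecutive volumes, in seconds.
    subject_id, group, lesion_side
        Subject metadata; ``group`` is the study arm (``"control"`` /
        ``"BCI"``), ``lesion_side`` is ``"left"`` or ``"right"``.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tr_seconds: float = 3.0
    subject_id: str = ""
    group: str = ""
    lesion_side: str = "left"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4-D (x, y, z, t) data, got shape {self.data.shape}")
        if self.data.shape[3] < 1:
            raise ValueError("need at least one time point")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if self.lesion_side not in ("left", "right"):
            raise ValueError(f"lesion_side must be 'left' or 'right', got {self.lesion_side!r}")

    # -- geometry -----------------------------------------------------------
    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def n_voxels(self) -> int:
        x, y, z = self.grid_dims
        return x * y * z

    def timeseries_matrix(self) -> np.ndarray:
        """Return the data as a ``(t, voxels)`` matrix (C-order voxel raveling)."""
        return self.data.reshape(self.n_voxels, self.n_timepoints).T

    def replace(self, **changes) -> "VolumeSeries":
        """Copy with selected fields replaced (data is not copied unless given)."""
        return dataclasses.replace(self, **changes)

    # -- NIfTI I/O ----------------------------------------------------------
    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag([*self.voxel_size_mm, 1.0])
        img = nib.Nifti1Image(self.data.astype(np.float32), affine)
        img.header.set_zooms((*self.voxel_size_mm, self.tr_seconds))
        img.header.set_xyzt_units(xyz="mm", t="sec")
        return img

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(
        cls,
        path: str | Path,
        subject_id: str = "",
        group: str = "",
        lesion_side: str = "left",
    ) -> "VolumeSeries":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 else 1.0
        return cls(
            data=np.asanyarray(img.dataobj, dtype=np.float64),
            voxel_size_mm=tuple(float(z) for z in zooms[:3]),
            tr_seconds=tr,
            subject_id=subject_id,
            group=group,
            lesion_side=lesion_side,
        )
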