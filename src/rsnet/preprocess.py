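"""Minimal order-preserving preprocessing for synthetic resting-state volumes.

The stage order mirrors a conventional resting-state pipeline: discard the
first volumes of the run (signal equilibration), slice-timing and motion
correction (pass-through stages on synthetic data, which has no slices or
motion, kept so the provenance reflects the full order), hemispheric
flipping so all lesions sit on the left, then per-voxel standardization and
isotropic Gaussian spatial smoothing (6 mm FWHM by default).

No temporal filtering or nuisance regression is applied; see the methods
note. Every stage is recorded in a provenance list suitable for a JSON
sidecar.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volume import VolumeSeries

__all__ = [
    "discard_initial_volumes",
    "slice_timing_correction",
    "motion_correction",
    "flip_hemisphere",
    "standardize_and_smooth",
    "fwhm_to_sigma_voxels",
    "preprocess_subject",
]


def discard_initial_volumes(v: VolumeSeries, n: int) -> VolumeSeries:
    """Drop the first ``n`` volumes; the rest are unchanged and in order."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    if n >= v.n_timepoints:
        raise ValueError(f"cannot discard {n} of {v.n_timepoints} volumes")
    if n == 0:
        return v
    return v.replace(data=v.data[..., n:])


def slice_timing_correction(v: VolumeSeries) -> VolumeSeries:
    """Pass-through on synthetic volumes (no slice acquisition offsets exist)."""
    return v


def motion_correction(v: VolumeSeries) -> VolumeSeries:
    """Pass-through on synthetic volumes (no head motion exists)."""
    return v


def flip_hemisphere(v: VolumeSeries) -> VolumeSeries:
    """Mirror right-lesion volumes across the midsagittal plane.

    Subjects with a right-sided lesion are flipped along the x-axis and
    relabeled ``left`` so all affected hemispheres coincide; left-lesion
    volumes pass through unchanged. Flipping twice restores the original.
    """
    if v.lesion_side == "left":
        return v
    return v.replace(data=np.flip(v.data, axis=0).copy(), lesion_side="left")


def fwhm_to_sigma_voxels(fwhm_mm: float, voxel_size_mm: float) -> float:
    """Gaussian σ in voxel units for a kernel of the given FWHM in mm."""
    return fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm


def standardize_and_smooth(
    v: VolumeSeries, fwhm_mm: float = 6.0, mode: str = "reflect"
) -> VolumeSeries:
    """Center and scale each voxel series, then smooth each frame spatially.

    Standardization maps every voxel time series to mean 0, unit variance
    (zero-variance voxels stay 0). Smoothing applies an isotropic Gaussian
    of ``σ = FWHM / (2√(2 ln 2))`` per axis, in voxel units, with
    ``reflect`` boundary handling by default; ``fwhm_mm = 0`` skips it.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be nonnegative")
    data = v.data
    mean = data.mean(axis=3, keepdims=True)
    sd = data.std(axis=3, keepdims=True)
    safe = np.where(sd > 0, sd, 1.0)
    data = np.where(sd > 0, (data - mean) / safe, 0.0)
    if fwhm_mm > 0:
        sigmas = [fwhm_to_sigma_voxels(fwhm_mm, vs) for vs in v.voxel_size_mm]
        data = ndimage.gaussian_filter(data, sigma=(*sigmas, 0.0), mode=mode)
    return v.replace(data=data)


def preprocess_subject(
    v: VolumeSeries,
    discard_n: int = 10,
    fwhm_mm: float = 6.0,
    smoothing_mode: str = "reflect",
) -> tuple[VolumeSeries, list[dict]]:
    """Run the full stage order; returns the volume and a provenance list."""
    provenance: list[dict] = []

    v = discard_initial_volumes(v, discard_n)
    provenance.append({"stage": "discard_initial_volumes", "n": discard_n,
                       "n_timepoints": v.n_timepoints})
    v = slice_timing_correction(v)
    provenance.append({"stage": "slice_timing_correction", "action": "pass-through"})
    v = motion_correction(v)
    provenance.append({"stage": "motion_correction", "action": "pass-through"})
    flipped = v.lesion_side == "right"
    v = flip_hemisphere(v)
    provenance.append({"stage": "flip_hemisphere", "flipped": bool(flipped)})
    v = standardize_and_smooth(v, fwhm_mm, mode=smoothing_mode)
    provenance.append({"stage": "standardize_and_smooth", "fwhm_mm": fwhm_mm,
                       "boundary": smoothing_mode})
    return v, provenance
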