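"""Dynamic PET series I/O and time–activity curve extraction.

A dynamic cardiac PET acquisition is stored as a 4D NIfTI volume
(x, y, z, frame) of activity concentrations in Bq·mL⁻¹ together with a
BIDS-style JSON sidecar giving per-frame start times and durations.  All
times are converted to minutes internally; washout rates are therefore in
min⁻¹ throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "FrameSchedule",
    "VoxelGeometry",
    "DynamicImage",
    "TimeActivityCurve",
    "load_dynamic_series",
    "save_dynamic_series",
    "extract_tac",
    "default_frame_schedule",
]

_OVERLAP_TOL_MIN = 1e-9


class SchemaError(ValueError):
    """Inconsistent on-disk representation (e.g. frame-count mismatch)."""


@dataclass(frozen=True)
class FrameSchedule:
    """Per-frame start times and durations of a rebinned dynamic series, in minutes."""

    start_times: np.ndarray
    durations: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.start_times, dtype=float)
        dur = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "start_times", start)
        object.__setattr__(self, "durations", dur)
        if start.ndim != 1 or dur.shape != start.shape:
            raise ValueError("start_times and durations must be 1-D arrays of equal length")
        if start.size == 0:
            raise ValueError("schedule must contain at least one frame")
        if not np.all(np.diff(start) > 0):
            raise ValueError("frame start times must be strictly increasing")
        if not np.all(dur > 0):
            raise ValueError("frame durations must be positive")
        ends = start + dur
        if np.any(start[1:] - ends[:-1] < -_OVERLAP_TOL_MIN):
            raise ValueError("frames overlap")

    @property
    def n_frames(self) -> int:
        return int(self.start_times.size)

    @property
    def mid_times(self) -> np.ndarray:
        return self.start_times + self.durations / 2.0

    @property
    def end_times(self) -> np.ndarray:
        return self.start_times + self.durations

    @property
    def total_duration(self) -> float:
        return float(self.end_times[-1] - self.start_times[0])

    @classmethod
    def from_sidecar(cls, path: str | Path) -> "FrameSchedule":
        with open(path) as fh:
            meta = json.load(fh)
        try:
            start_s = np.asarray(meta["FrameTimesStart"], dtype=float)
            dur_s = np.asarray(meta["FrameDuration"], dtype=float)
        except KeyError as exc:
            raise SchemaError(f"timing sidecar missing key {exc}") from exc
        if start_s.shape != dur_s.shape:
            raise SchemaError("FrameTimesStart and FrameDuration differ in length")
        return cls(start_times=start_s / 60.0, durations=dur_s / 60.0)

    def to_sidecar(self, path: str | Path) -> None:
        meta = {
            "FrameTimesStart": (self.start_times * 60.0).tolist(),
            "FrameDuration": (self.durations * 60.0).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(meta, fh, indent=1)


def default_frame_schedule() -> FrameSchedule:
    """29-frame, 27-minute schedule: 12x5 s, 6x10 s, 4x30 s, 4x120 s, 3x300 s."""
    dur_s = np.array([5.0] * 12 + [10.0] * 6 + [30.0] * 4 + [120.0] * 4 + [300.0] * 3)
    start_s = np.concatenate([[0.0], np.cumsum(dur_s)[:-1]])
    return FrameSchedule(start_times=start_s / 60.0, durations=dur_s / 60.0)


@dataclass(frozen=True)
class VoxelGeometry:
    """Voxel size and origin in mm, axes assumed axis-aligned (RAS-style)."""

    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_labels: tuple[str, str, str] = ("R", "A", "S")

    def __post_init__(self):
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive lengths (mm)")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    @classmethod
    def from_affine(cls, affine: np.ndarray) -> "VoxelGeometry":
        size = tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))
        labels = tuple(nib.orientations.aff2axcodes(affine))
        return cls(voxel_size=size, origin=tuple(float(x) for x in affine[:3, 3]),
                   axis_labels=labels)


@dataclass
class TimeActivityCurve:
    """Region or voxel activity concentration vs time.

    ``times`` are frame mid-times in minutes, ``values`` in Bq·mL⁻¹ and
    ``durations`` the frame lengths in minutes.
    """

    times: np.ndarray
    values: np.ndarray
    durations: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        if not (self.times.shape == self.values.shape == self.durations.shape):
            raise ValueError("times, values and durations must share a shape")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @classmethod
    def from_schedule(cls, schedule: FrameSchedule, values: np.ndarray) -> "TimeActivityCurve":
        values = np.asarray(values, dtype=float)
        if values.shape != schedule.start_times.shape:
            raise ValueError("values length does not match schedule")
        return cls(times=schedule.mid_times.copy(), values=values,
                   durations=schedule.durations.copy())

    def frame_auc(self) -> float:
        """Area under the curve using frame-duration weights (Bq·mL⁻¹·min)."""
        return float(np.sum(self.values * self.durations))

    def to_tsv(self, path: str | Path) -> None:
        data = np.column_stack([self.times, self.values, self.durations])
        np.savetxt(path, data, delimiter="\t",
                   header="time_min\tvalue_Bq_per_mL\tduration_min", comments="")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TimeActivityCurve":
        data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
        return cls(times=data[:, 0], values=data[:, 1], durations=data[:, 2])


@dataclass
class DynamicImage:
    """4D dynamic PET volume with frame schedule and voxel geometry.

    Negative voxel values are legitimate reconstruction artefacts and are
    retained; ``n_negative_voxels`` flags them for QC.
    """

    values: np.ndarray
    schedule: FrameSchedule
    geometry: VoxelGeometry
    units: str = "Bq/mL"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ValueError("values must be a 4D (x, y, z, frame) array")
        if self.values.shape[3] != self.schedule.n_frames:
            raise SchemaError(
                f"image has {self.values.shape[3]} frames but schedule lists "
                f"{self.schedule.n_frames}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite voxel values")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]

    @property
    def n_negative_voxels(self) -> int:
        return int(np.count_nonzero(self.values < 0))

    def frame(self, i: int) -> np.ndarray:
        return self.values[..., i]


def load_dynamic_series(image_path: str | Path, timing_path: str | Path) -> DynamicImage:
    """Read a 4D NIfTI series and its JSON frame-timing sidecar."""
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise SchemaError(f"expected a 4D volume, got shape {data.shape}")
    schedule = FrameSchedule.from_sidecar(timing_path)
    if data.shape[3] != schedule.n_frames:
        raise SchemaError(
            f"image has {data.shape[3]} frames but sidecar lists {schedule.n_frames}")
    geometry = VoxelGeometry.from_affine(img.affine)
    return DynamicImage(values=data, schedule=schedule, geometry=geometry)


def save_dynamic_series(image: DynamicImage, image_path: str | Path,
                        timing_path: str | Path | None = None) -> None:
    nii = nib.Nifti1Image(image.values, image.geometry.affine)
    nii.to_filename(str(image_path))
    if timing_path is not None:
        image.schedule.to_sidecar(timing_path)


def load_mask(path: str | Path, spatial_shape: tuple[int, int, int] | None = None) -> np.ndarray:
    mask = np.asarray(nib.load(str(path)).dataobj) > 0.5
    if spatial_shape is not None and mask.shape != spatial_shape:
        raise SchemaError(f"mask shape {mask.shape} does not match image {spatial_shape}")
    return mask


def save_mask(mask: np.ndarray, geometry: VoxelGeometry, path: str | Path) -> None:
    nib.Nifti1Image(mask.astype(np.uint8), geometry.affine).to_filename(str(path))


def extract_tac(image: DynamicImage, mask: np.ndarray) -> TimeActivityCurve:
    """Unweighted per-frame mean of the masked voxels."""
    mask = np.asarray(mask).astype(bool)
    if mask.shape != image.spatial_shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image spatial shape {image.spatial_shape}")
    if not mask.any():
        raise ValueError("mask is empty")
    vals = image.values[mask].mean(axis=0)
    return TimeActivityCurve.from_schedule(image.schedule, vals)
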