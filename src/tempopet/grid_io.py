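"""Volumes, masks, frame schedules and grid operations.

All images live on axis-aligned grids described by a voxel spacing (mm) and a
world-space origin (mm, centre of voxel ``[0,0,0]``).  NIfTI is the on-disk
format (via nibabel); frame schedules travel as small CSV files.

Resampling is trilinear with the input and output grids aligned by their
world-space centres, and out-of-support samples clamped to the nearest edge
value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

logger = logging.getLogger(__name__)

__all__ = [
    "FrameSchedule",
    "Image3D",
    "VoiMask",
    "DynamicSeries",
    "read_volume",
    "write_volume",
    "read_series",
    "write_series",
    "resample_isotropic",
    "resample_mask",
    "extract_voi_values",
]


# ---------------------------------------------------------------------------
# frame schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameSchedule:
    """Acquisition timing of a dynamic series.

    Parameters
    ----------
    starts_s : array-like
        Frame start times, seconds post-injection, strictly increasing.
    durations_s : array-like
        Frame durations, seconds, all positive.  Frames may be contiguous or
        gapped but never overlap.
    """

    starts_s: np.ndarray
    durations_s: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts_s, dtype=float)
        durs = np.asarray(self.durations_s, dtype=float)
        if starts.ndim != 1 or starts.size == 0:
            raise ValueError("schedule needs at least one frame")
        if starts.shape != durs.shape:
            raise ValueError("starts and durations must have equal length")
        if np.any(durs <= 0):
            raise ValueError("frame durations must be positive")
        if np.any(np.diff(starts) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        ends = starts + durs
        if np.any(ends[:-1] > starts[1:] + 1e-9):
            raise ValueError("frames must not overlap")
        object.__setattr__(self, "starts_s", starts)
        object.__setattr__(self, "durations_s", durs)

    @property
    def n_frames(self) -> int:
        return int(self.starts_s.size)

    @property
    def ends_s(self) -> np.ndarray:
        return self.starts_s + self.durations_s

    @property
    def midpoints_s(self) -> np.ndarray:
        return self.starts_s + 0.5 * self.durations_s

    @property
    def midpoints_min(self) -> np.ndarray:
        return self.midpoints_s / 60.0

    @classmethod
    def uniform(cls, start_s: float, n_frames: int, duration_s: float) -> "FrameSchedule":
        """Contiguous schedule of ``n_frames`` equal frames from ``start_s``."""
        starts = start_s + duration_s * np.arange(n_frames)
        return cls(starts, np.full(n_frames, float(duration_s)))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "frame_index": np.arange(self.n_frames),
                "start_s": self.starts_s,
                "duration_s": self.durations_s,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FrameSchedule":
        df = pd.read_csv(path).sort_values("frame_index")
        return cls(df["start_s"].to_numpy(), df["duration_s"].to_numpy())


# ---------------------------------------------------------------------------
# image containers
# ---------------------------------------------------------------------------

def _as_triplet(x) -> np.ndarray:
    a = np.broadcast_to(np.asarray(x, dtype=float), (3,)).copy()
    return a


@dataclass
class Image3D:
    """A scalar 3D volume on an axis-aligned grid.

    ``values[i, j, k]`` sits at world position ``origin + spacing * (i, j, k)``.
    ``units`` tags the voxel values (e.g. ``"SUV g/mL"``, ``"Bq/mL"``,
    ``"min^-1"``).
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    units: str = "a.u."

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("Image3D requires a 3D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image contains non-finite values")
        self.spacing = _as_triplet(self.spacing)
        self.origin = _as_triplet(self.origin)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive on every axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def centre_world(self) -> np.ndarray:
        """World coordinate of the grid centre (between voxel centres)."""
        return self.origin + self.spacing * (np.array(self.shape) - 1) / 2.0

    def with_values(self, values: np.ndarray, units: str | None = None) -> "Image3D":
        return Image3D(values, self.spacing.copy(), self.origin.copy(),
                       self.units if units is None else units)


@dataclass
class VoiMask:
    """Binary volume of interest on an image grid."""

    mask: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 3:
            raise ValueError("mask must be 3D")
        if m.dtype != bool:
            vals = np.unique(m)
            bad = [v for v in vals if v not in (0, 1)]
            if bad:
                raise ValueError(f"mask is not binary; offending values: {bad}")
            m = m.astype(bool)
        if not m.any():
            raise ValueError("mask is empty")
        self.mask = m
        self.spacing = _as_triplet(self.spacing)
        self.origin = _as_triplet(self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        idx = np.argwhere(self.mask)
        return idx.min(axis=0), idx.max(axis=0)

    def same_grid(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class DynamicSeries:
    """Ordered 3D frames sharing one grid: the 4D ``(x, y, z, t)`` object."""

    data: np.ndarray  # shape (nx, ny, nz, T)
    spacing: np.ndarray
    origin: np.ndarray
    schedule: FrameSchedule
    units: str = "Bq/mL"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DynamicSeries requires a 4D array (x, y, z, t)")
        if self.data.shape[3] != self.schedule.n_frames:
            raise ValueError(
                f"frame count {self.data.shape[3]} does not match schedule "
                f"length {self.schedule.n_frames}"
            )
        self.spacing = _as_triplet(self.spacing)
        self.origin = _as_triplet(self.origin)

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]  # type: ignore[return-value]

    def frame(self, t: int) -> Image3D:
        return Image3D(self.data[..., t], self.spacing.copy(), self.origin.copy(), self.units)

    @classmethod
    def from_frames(cls, frames: list[Image3D], schedule: FrameSchedule,
                    units: str | None = None) -> "DynamicSeries":
        first = frames[0]
        for f in frames[1:]:
            if f.shape != first.shape or not np.allclose(f.spacing, first.spacing) \
                    or not np.allclose(f.origin, first.origin):
                raise ValueError("all frames must share one grid")
        data = np.stack([f.values for f in frames], axis=-1)
        return cls(data, first.spacing.copy(), first.origin.copy(), schedule,
                   units if units is not None else first.units)


# ---------------------------------------------------------------------------
# NIfTI IO
# ---------------------------------------------------------------------------

def _grid_from_affine(affine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rot = affine[:3, :3]
    spacing = np.sqrt((rot ** 2).sum(axis=0))
    off_diag = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off_diag)) > 1e-6 * max(spacing.max(), 1.0):
        raise ValueError("only axis-aligned NIfTI affines are supported")
    if np.any(np.diag(rot) < 0):
        raise ValueError("negative-direction affines are not supported; reorient first")
    return spacing, affine[:3, 3].copy()


def read_volume(path: str | Path, kind: str = "image") -> Image3D | VoiMask:
    """Read a 3D NIfTI volume as an image or a binary mask.

    ``kind="mask"`` rejects files whose voxel values are not a subset of
    ``{0, 1}``, listing the offending values.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    spacing, origin = _grid_from_affine(img.affine)
    if kind == "mask":
        return VoiMask(data, spacing, origin)
    if kind != "image":
        raise ValueError("kind must be 'image' or 'mask'")
    return Image3D(data.astype(float), spacing, origin)


def write_volume(obj: Image3D | VoiMask, path: str | Path) -> None:
    if isinstance(obj, VoiMask):
        data = obj.mask.astype(np.uint8)
        aff = np.eye(4)
        aff[:3, :3] = np.diag(obj.spacing)
        aff[:3, 3] = obj.origin
    else:
        data = obj.values.astype(np.float64)
        aff = obj.affine
    nib.save(nib.Nifti1Image(data, aff), str(path))


def read_series(path: str | Path, schedule: FrameSchedule,
                units: str = "Bq/mL") -> DynamicSeries:
    """Read a 4D NIfTI file as a dynamic series with the given schedule."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected 4D data, got shape {data.shape}")
    spacing, origin = _grid_from_affine(img.affine)
    return DynamicSeries(data, spacing, origin, schedule, units)


def read_frame_dir(directory: str | Path, schedule_csv: str | Path | None = None,
                   units: str = "Bq/mL") -> DynamicSeries:
    """Read per-frame NIfTI volumes ``frame_NNN.nii.gz`` plus a schedule CSV."""
    directory = Path(directory)
    if schedule_csv is None:
        schedule_csv = directory / "schedule.csv"
    schedule = FrameSchedule.from_csv(schedule_csv)
    frames = []
    for t in range(schedule.n_frames):
        p = directory / f"frame_{t:03d}.nii.gz"
        if not p.exists():
            p = directory / f"frame_{t:03d}.nii"
        frames.append(read_volume(p, kind="image"))
    return DynamicSeries.from_frames(frames, schedule, units)


def write_series(series: DynamicSeries, directory: str | Path) -> None:
    """Write one NIfTI per frame plus ``schedule.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for t in range(series.n_frames):
        write_volume(series.frame(t), directory / f"frame_{t:03d}.nii.gz")
    series.schedule.to_csv(directory / "schedule.csv")


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def _target_grid(shape, spacing, origin, target_spacing):
    """Isotropic output grid covering the input extent, centres aligned.

    The voxel-centre span (fence-post convention) defines the extent, so an
    integer spacing ratio lands output samples exactly on input centres.
    """
    shape = np.asarray(shape)
    extent = (shape - 1) * spacing  # span between outermost voxel centres
    n_out = np.ceil(extent / target_spacing - 1e-9).astype(int) + 1
    centre_in = origin + spacing * (shape - 1) / 2.0
    origin_out = centre_in - target_spacing * (n_out - 1) / 2.0
    return n_out, origin_out


def _trilinear_resample(values, spacing, origin, target_spacing):
    n_out, origin_out = _target_grid(values.shape, spacing, origin, target_spacing)
    axes = [origin_out[a] + target_spacing * np.arange(n_out[a]) for a in range(3)]
    world = np.meshgrid(*axes, indexing="ij")
    coords = [(world[a] - origin[a]) / spacing[a] for a in range(3)]
    out = map_coordinates(values, np.stack(coords), order=1, mode="nearest")
    return out, origin_out


def resample_isotropic(image: Image3D, target_spacing_mm: float) -> Image3D:
    """Trilinearly resample onto an isotropic grid, centres aligned in world space.

    Samples outside the input support take the nearest edge value.
    """
    if target_spacing_mm <= 0:
        raise ValueError("target spacing must be positive")
    if min(image.shape) < 2:
        raise ValueError("cannot resample a volume with a single-voxel axis")
    out, origin_out = _trilinear_resample(
        image.values, image.spacing, image.origin, float(target_spacing_mm)
    )
    return Image3D(out, np.full(3, float(target_spacing_mm)), origin_out, image.units)


def resample_mask(mask: VoiMask, target_spacing_mm: float,
                  threshold: float = 0.5) -> VoiMask:
    """Resample a mask as a real-valued field and binarise at ``threshold``."""
    if target_spacing_mm <= 0:
        raise ValueError("target spacing must be positive")
    if min(mask.shape) < 2:
        raise ValueError("cannot resample a mask with a single-voxel axis")
    out, origin_out = _trilinear_resample(
        mask.mask.astype(float), mask.spacing, mask.origin, float(target_spacing_mm)
    )
    binar = out >= threshold
    if not binar.any():
        raise ValueError("mask is empty after resampling and thresholding")
    return VoiMask(binar, np.full(3, float(target_spacing_mm)), origin_out)


def resample_series(series: DynamicSeries, target_spacing_mm: float) -> DynamicSeries:
    """Resample each frame independently, then restack (frames are independent)."""
    frames = [resample_isotropic(series.frame(t), target_spacing_mm)
              for t in range(series.n_frames)]
    return DynamicSeries.from_frames(frames, series.schedule, series.units)


# ---------------------------------------------------------------------------
# VOI extraction
# ---------------------------------------------------------------------------

def extract_voi_values(image: Image3D, mask: VoiMask) -> tuple[np.ndarray, np.ndarray]:
    """Values of the masked voxels in deterministic lexicographic voxel order.

    Returns ``(values, coords)`` with ``coords`` the ``(n, 3)`` integer voxel
    indices, sorted lexicographically (the order ``np.argwhere`` yields).
    """
    if not mask.same_grid(image):
        raise ValueError("image and mask are not on the same grid")
    coords = np.argwhere(mask.mask)
    if coords.size == 0:
        raise ValueError("mask selects no voxels")
    values = image.values[mask.mask]
    return values, coords
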