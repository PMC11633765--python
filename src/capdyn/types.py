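"""Core data containers shared across the pipeline.

The central carrier is :class:`VolumeSeries`, a gray-matter-masked
frames-by-voxels matrix with its repetition time, per-frame validity flags
(motion scrubbing never deletes frames, it only flags them) and the voxel
geometry needed to go back to a 3-D grid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CapdynError",
    "ConfigurationError",
    "AlignmentError",
    "VolumeSeries",
    "MotionParams",
    "SeedMask",
    "FrameSet",
    "NOT_SELECTED",
    "UNASSIGNED",
    "CENSORED",
    "MOTION_COLUMNS",
]

# State-sequence sentinel labels.  CAP states are 0..K-1; everything
# negative is a gap that breaks runs and contributes no transitions.
NOT_SELECTED = -1
UNASSIGNED = -2
CENSORED = -3

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


class CapdynError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CapdynError):
    """Invalid configuration or parameter value."""


class AlignmentError(CapdynError):
    """Mask/series/atlas grids or voxel indices do not match."""


@dataclass
class VolumeSeries:
    """Masked 4-D series as a frames x voxels matrix.

    Parameters
    ----------
    data:
        ``(n_frames, n_voxels)`` float array of BOLD values (gray-matter
        voxels only).
    tr:
        Repetition time in seconds.
    voxel_coords:
        ``(n_voxels, 3)`` integer array mapping each column to its i,j,k
        grid coordinate.
    grid_shape:
        Shape of the originating 3-D grid.
    frame_valid:
        Per-frame boolean; ``False`` marks censored (scrubbed) frames.
    affine:
        4x4 voxel-to-world affine (identity for synthetic grids).
    zero_variance:
        Per-voxel flag set by z-scoring when a voxel had no variance.
    """

    data: np.ndarray
    tr: float
    voxel_coords: np.ndarray
    grid_shape: tuple[int, int, int]
    frame_valid: np.ndarray = None  # type: ignore[assignment]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    zero_variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ConfigurationError("series data must be 2-D (frames x voxels)")
        self.voxel_coords = np.asarray(self.voxel_coords)
        if self.voxel_coords.shape != (self.n_voxels, 3):
            raise AlignmentError(
                f"voxel_coords shape {self.voxel_coords.shape} does not match "
                f"{self.n_voxels} voxels"
            )
        if self.frame_valid is None:
            self.frame_valid = np.ones(self.n_frames, dtype=bool)
        self.frame_valid = np.asarray(self.frame_valid, dtype=bool)
        if self.frame_valid.shape != (self.n_frames,):
            raise ConfigurationError("frame_valid length must equal frame count")
        if self.tr <= 0:
            raise ConfigurationError("tr must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def n_valid(self) -> int:
        return int(self.frame_valid.sum())

    def copy(self, data: np.ndarray | None = None) -> "VolumeSeries":
        """Shallow-config copy, optionally substituting the data matrix."""
        return dataclasses.replace(
            self,
            data=self.data.copy() if data is None else data,
            frame_valid=self.frame_valid.copy(),
            zero_variance=None if self.zero_variance is None else self.zero_variance.copy(),
        )

    def to_grid(self, frame: int | np.ndarray) -> np.ndarray:
        """Embed one frame (index or 1-D vector) back into the 3-D grid."""
        vec = self.data[frame] if np.isscalar(frame) else np.asarray(frame)
        vol = np.zeros(self.grid_shape, dtype=np.float64)
        vol[tuple(self.voxel_coords.T)] = vec
        return vol


@dataclass
class MotionParams:
    """Six rigid-body realignment parameters per frame.

    Translations in mm, rotations in radians, columns ordered as
    ``trans_x, trans_y, trans_z, rot_x, rot_y, rot_z``.
    """

    values: np.ndarray  # (n_frames, 6)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise ConfigurationError(
                f"motion parameters must have 6 columns, got shape {self.values.shape}"
            )

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.values[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.values[:, 3:]


@dataclass
class SeedMask:
    """Per-voxel seed weight in [0, 1] over a series' voxel index.

    Supports probabilistic atlases (fractional weights) as well as binary
    masks; weights are used as-is in the weighted seed time course.
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 1:
            raise ConfigurationError("seed weights must be a 1-D voxel vector")
        if not np.all(np.isfinite(self.weights)):
            raise ConfigurationError("seed weights must be finite")
        if np.any(self.weights < 0):
            raise ConfigurationError("seed weights must be non-negative")
        if not np.any(self.weights > 0):
            raise ConfigurationError("seed mask has no strictly positive weight")

    @property
    def n_voxels(self) -> int:
        return self.weights.shape[0]

    @property
    def support(self) -> np.ndarray:
        """Indices of voxels with strictly positive weight."""
        return np.flatnonzero(self.weights > 0)


@dataclass
class FrameSet:
    """High-seed-activation frames retained for one subject.

    ``indices`` refer to the original acquisition timeline (strictly
    increasing) and point only at valid, non-censored frames.
    """

    subject_id: str
    indices: np.ndarray
    data: np.ndarray  # (n_selected, n_voxels)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.intp)
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.indices.ndim != 1:
            raise ConfigurationError("frame indices must be 1-D")
        if self.data.shape[0] != self.indices.shape[0]:
            raise ConfigurationError("frame data rows must match index count")
        if self.indices.size > 1 and not np.all(np.diff(self.indices) > 0):
            raise ConfigurationError("frame indices must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.indices.shape[0]

    def __len__(self) -> int:
        return self.n_frames
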