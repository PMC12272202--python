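"""Shared spatial containers: voxel grids, binary masks, label maps, 4D BOLD.

Every image in a run must live on one :class:`VolumeGrid`; all co-operating
functions check grid agreement up front (dimensions plus affine within a
small absolute tolerance) and fail loudly rather than resampling silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "GridMismatchError",
    "VolumeGrid",
    "BinaryMask",
    "VesselLabelMap",
    "Bold4D",
    "ARTERY_LABEL",
    "VEIN_LABEL",
]

#: Label convention for vessel label maps (documented in output sidecars).
ARTERY_LABEL = 1
VEIN_LABEL = 2

AFFINE_ATOL = 1e-4


class GridMismatchError(ValueError):
    """Two images that must share a grid do not."""


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D voxel grid: dimensions plus a NIfTI-style voxel-to-world affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"grid shape must be a positive triple, got {self.shape}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", aff)
        self.affine.setflags(write=False)

    @classmethod
    def from_spacing(
        cls, shape: tuple[int, int, int], voxel_size_mm: tuple[float, float, float]
    ) -> "VolumeGrid":
        aff = np.diag([*voxel_size_mm, 1.0])
        return cls(tuple(shape), aff)

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis voxel edge length in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def isclose(self, other: "VolumeGrid", atol: float = AFFINE_ATOL) -> bool:
        return self.shape == other.shape and bool(
            np.allclose(self.affine, other.affine, atol=atol)
        )

    def require_same(self, other: "VolumeGrid", what: str = "image") -> None:
        if not self.isclose(other):
            raise GridMismatchError(
                f"{what} is on a different grid: shape {other.shape} vs {self.shape} "
                f"(or affines differ beyond {AFFINE_ATOL})"
            )


def _as_grid(img: nib.Nifti1Image) -> VolumeGrid:
    return VolumeGrid(tuple(img.shape[:3]), np.asarray(img.affine))


@dataclass
class BinaryMask:
    """A boolean volume tied to a grid."""

    grid: VolumeGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {data.shape} does not match grid {self.grid.shape}"
            )
        self.data = data.astype(bool, copy=False)

    @property
    def n_true(self) -> int:
        return int(self.data.sum())

    def is_empty(self) -> bool:
        return not self.data.any()

    def flat_indices(self) -> np.ndarray:
        """Flat (C-order) indices of true voxels, sorted ascending."""
        return np.flatnonzero(self.data.ravel())

    def intersect(self, other: "BinaryMask") -> "BinaryMask":
        self.grid.require_same(other.grid, "mask operand")
        return BinaryMask(self.grid, self.data & other.data)

    def union(self, other: "BinaryMask") -> "BinaryMask":
        self.grid.require_same(other.grid, "mask operand")
        return BinaryMask(self.grid, self.data | other.data)

    def minus(self, other: "BinaryMask") -> "BinaryMask":
        self.grid.require_same(other.grid, "mask operand")
        return BinaryMask(self.grid, self.data & ~other.data)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.uint8), self.grid.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "BinaryMask":
        img = nib.load(str(path))
        return cls(_as_grid(img), np.asanyarray(img.dataobj) > 0)


@dataclass
class VesselLabelMap:
    """Integer-labeled volume: 0 background, 1 artery, 2 vein."""

    grid: VolumeGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.shape != self.grid.shape:
            raise ValueError(
                f"label map shape {data.shape} does not match grid {self.grid.shape}"
            )
        self.data = data.astype(np.int16, copy=False)
        bad = set(np.unique(self.data)) - {0, ARTERY_LABEL, VEIN_LABEL}
        if bad:
            raise ValueError(f"unexpected vessel labels {sorted(bad)}; allowed 0/1/2")

    def artery_mask(self) -> BinaryMask:
        return BinaryMask(self.grid, self.data == ARTERY_LABEL)

    def vein_mask(self) -> BinaryMask:
        return BinaryMask(self.grid, self.data == VEIN_LABEL)

    def vessel_mask(self) -> BinaryMask:
        return BinaryMask(self.grid, self.data > 0)

    def counts(self) -> dict[str, int]:
        return {
            "artery": int((self.data == ARTERY_LABEL).sum()),
            "vein": int((self.data == VEIN_LABEL).sum()),
        }

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.int16), self.grid.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "VesselLabelMap":
        img = nib.load(str(path))
        return cls(_as_grid(img), np.rint(np.asanyarray(img.dataobj)).astype(np.int16))


@dataclass
class Bold4D:
    """A 4D BOLD time series (x, y, z, t) with its repetition time in seconds."""

    grid: VolumeGrid
    data: np.ndarray
    tr_s: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 4 or data.shape[:3] != self.grid.shape:
            raise ValueError(
                f"BOLD shape {data.shape} does not match grid {self.grid.shape} + time"
            )
        if not (self.tr_s > 0):
            raise ValueError(f"tr_s must be positive, got {self.tr_s}")
        if not np.isfinite(data).all():
            raise ValueError("BOLD contains non-finite values")
        self.data = data
        self.tr_s = float(self.tr_s)

    @property
    def n_volumes(self) -> int:
        return int(self.data.shape[3])

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_s)

    def timeseries(self, mask: BinaryMask) -> np.ndarray:
        """(n_voxels, n_volumes) array of the series inside ``mask``."""
        self.grid.require_same(mask.grid, "mask")
        return self.data.reshape(-1, self.n_volumes)[mask.flat_indices()]

    def with_data(self, data: np.ndarray) -> "Bold4D":
        return Bold4D(self.grid, data, self.tr_s)

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.grid.affine)
        img.header.set_zooms((*self.grid.voxel_size_mm, self.tr_s))
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path, tr_s: float | None = None) -> "Bold4D":
        """Load from NIfTI; TR read from the header unless overridden."""
        img = nib.load(str(path))
        if img.ndim != 4:
            raise ValueError(f"{path}: expected a 4D image, got shape {img.shape}")
        if tr_s is None:
            zooms = img.header.get_zooms()
            tr_s = float(zooms[3]) if len(zooms) > 3 else 0.0
            if tr_s <= 0:
                raise ValueError(
                    f"{path}: repetition time missing from header; pass tr_s explicitly"
                )
        return cls(_as_grid(img), np.asanyarray(img.dataobj), tr_s)
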