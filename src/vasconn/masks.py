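"""Vessel-mask engineering: fusion, downsampling, artery/vein splitting,
GM restriction, and perivascular shells.

The conventions follow the angiography-processing stream of the analysis:
multi-orientation TOF segmentations are summed and binarized (union), brought
to the fMRI grid, split into arterial and venous maps by a label image, and
optionally restricted to gray matter before connectivity seeding.  Shells at
voxel distance 1..K from a vessel are built by iterated morphological
dilation and subtraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, generate_binary_structure

from .grid import BinaryMask, GridMismatchError, VesselLabelMap, VolumeGrid

__all__ = [
    "MaskError",
    "ShellSet",
    "combine_segmentations",
    "downsample_mask",
    "split_by_label",
    "restrict_to_gm",
    "make_shells",
    "structuring_element",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


class MaskError(ValueError):
    """Invalid mask operation."""


def structuring_element(connectivity: int) -> np.ndarray:
    """3x3x3 structuring element for 6-, 18- or 26-connected dilation."""
    try:
        rank = _CONNECTIVITY_RANK[int(connectivity)]
    except KeyError:
        raise MaskError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    return generate_binary_structure(3, rank)


def combine_segmentations(masks: list[BinaryMask]) -> BinaryMask:
    """Fuse segmentations by summing and binarizing (voxelwise union)."""
    if not masks:
        raise MaskError("no segmentations to combine")
    ref = masks[0].grid
    out = np.zeros(ref.shape, dtype=bool)
    for i, m in enumerate(masks):
        if not ref.isclose(m.grid):
            raise GridMismatchError(
                f"segmentation #{i} is on a different grid "
                f"({m.grid.shape} vs {ref.shape})"
            )
        out |= m.data
    return BinaryMask(ref, out)


def downsample_mask(
    mask: BinaryMask,
    target: VolumeGrid,
    occupancy_min: float | None = None,
) -> BinaryMask:
    """Downsample a high-resolution binary mask to a coarser nested grid.

    Each target voxel covers an integer block of source voxels; it is set
    true when the fraction of true source voxels in its footprint reaches
    ``occupancy_min``.  ``occupancy_min=None`` is the "any overlap" policy
    (fraction > 0), which preserves 1-voxel-thick vessels.
    """
    src = mask.grid
    if target.voxel_volume_mm3 < src.voxel_volume_mm3 - 1e-9:
        raise MaskError("target voxel volume must be >= source voxel volume")
    factors = []
    for ax in range(3):
        ratio = target.voxel_size_mm[ax] / src.voxel_size_mm[ax]
        f = int(round(ratio))
        if f < 1 or abs(ratio - f) > 1e-6:
            raise MaskError(
                f"grids are not nested: axis {ax} voxel-size ratio {ratio:.6g} "
                "is not a positive integer"
            )
        if src.shape[ax] != target.shape[ax] * f:
            raise MaskError(
                f"grids do not overlap as nested blocks on axis {ax}: "
                f"{src.shape[ax]} source voxels vs {target.shape[ax]} x {f}"
            )
        factors.append(f)
    if occupancy_min is not None and not (0.0 < occupancy_min <= 1.0):
        raise MaskError(f"occupancy_min must lie in (0, 1], got {occupancy_min}")

    fx, fy, fz = factors
    tx, ty, tz = target.shape
    blocks = mask.data.reshape(tx, fx, ty, fy, tz, fz)
    frac = blocks.mean(axis=(1, 3, 5))
    if occupancy_min is None:
        out = frac > 0.0
    else:
        out = frac >= occupancy_min - 1e-12
    return BinaryMask(target, out)


def split_by_label(
    mask: BinaryMask, labels: VesselLabelMap
) -> tuple[BinaryMask, BinaryMask]:
    """Partition a vessel mask into (arterial, venous) by the label map."""
    mask.grid.require_same(labels.grid, "label map")
    unlabeled = mask.data & (labels.data == 0)
    if unlabeled.any():
        coords = np.argwhere(unlabeled)[:10]
        raise MaskError(
            f"{int(unlabeled.sum())} vessel voxel(s) have no artery/vein label; "
            f"first offenders (x,y,z): {[tuple(int(v) for v in c) for c in coords]}"
        )
    arterial = mask.intersect(labels.artery_mask())
    venous = mask.intersect(labels.vein_mask())
    return arterial, venous


def restrict_to_gm(mask: BinaryMask, gm: BinaryMask) -> BinaryMask:
    """Restrict a vascular mask to gray matter (voxelwise intersection)."""
    return mask.intersect(gm)


@dataclass
class ShellSet:
    """Perivascular shells at voxel distances 1..K from a source mask.

    ``shells[k-1]`` holds the voxels whose distance from the source under the
    chosen connectivity is exactly k (Chebyshev for 26, city-block for 6).
    Shells are pairwise disjoint, disjoint from the source, and — when an
    exclusion mask is given — never contain any vessel voxel of either type.
    """

    source: BinaryMask
    shells: list[BinaryMask]
    connectivity: int

    @property
    def K(self) -> int:
        return len(self.shells)

    def shell(self, distance: int) -> BinaryMask:
        """Mask at voxel distance ``distance`` (1-based); 0 gives the source."""
        if distance == 0:
            return self.source
        if not (1 <= distance <= self.K):
            raise IndexError(f"shell distance {distance} outside 1..{self.K}")
        return self.shells[distance - 1]


def make_shells(
    mask: BinaryMask,
    K: int,
    connectivity: int = 26,
    brain: BinaryMask | None = None,
    exclude: BinaryMask | None = None,
) -> ShellSet:
    """Build perivascular shells by K-fold dilate-and-subtract.

    Parameters
    ----------
    mask:
        Source vessel mask (non-empty).
    K:
        Number of shells (distances 1..K).
    connectivity:
        6 (faces), 18 (faces+edges) or 26 (full cube) neighborhood for one
        dilation step; 26 corresponds to Chebyshev distance.
    brain:
        Optional mask shells are clipped to (e.g. the brain mask).
    exclude:
        Optional mask removed from every shell (typically the union of the
        arterial and venous vessels, so no shell contains a vessel voxel).
    """
    if K < 1:
        raise MaskError(f"K must be >= 1, got {K}")
    if mask.is_empty():
        raise MaskError("cannot build shells from an empty mask")
    struct = structuring_element(connectivity)
    for other, what in ((brain, "brain mask"), (exclude, "exclusion mask")):
        if other is not None:
            mask.grid.require_same(other.grid, what)

    shells: list[BinaryMask] = []
    prev = mask.data
    for _k in range(1, K + 1):
        dil = binary_dilation(prev, structure=struct)
        ring = dil & ~prev
        prev = dil
        if brain is not None:
            ring &= brain.data
        if exclude is not None:
            ring &= ~exclude.data
        shells.append(BinaryMask(mask.grid, ring))
    for k, sh in enumerate(shells, start=1):
        if sh.is_empty():
            warnings.warn(
                f"perivascular shell at distance {k} is empty after clipping",
                stacklevel=2,
            )
    return ShellSet(source=mask, shells=shells, connectivity=int(connectivity))
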