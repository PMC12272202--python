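"""Macrovascular occupancy of resting-state networks.

For each RSN z-map, the network mask is ``z > z_thresh`` (default 3) and the
macrovascular mask is the set of frequency-map voxels at or above its
``pct_thresh``-th percentile (default 90, computed over the nonzero voxels;
ties at the percentile value are kept).  Occupancy is the percentage of the
network mask covered by the macrovascular mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["OccupancyRow", "occupancy", "occupancy_table", "vascular_mask_from_frequency"]

DEFAULT_Z_THRESH = 3.0
DEFAULT_PCT_THRESH = 90.0


@dataclass(frozen=True)
class OccupancyRow:
    rsn_name: str
    rsn_voxels: int
    overlap_voxels: int
    percent: float


def vascular_mask_from_frequency(
    freq_map: np.ndarray, pct_thresh: float = DEFAULT_PCT_THRESH
) -> np.ndarray:
    """Threshold a macrovascular frequency map at its percentile.

    The percentile is computed over the nonzero voxels (the map's support);
    voxels equal to the percentile value are included.  A constant nonzero
    map therefore yields all of its nonzero voxels.
    """
    if not (0.0 < pct_thresh < 100.0):
        raise ValueError(f"pct_thresh must lie in (0, 100), got {pct_thresh}")
    freq = np.asarray(freq_map, dtype=float)
    support = freq != 0
    if not support.any():
        raise ValueError("frequency map has no nonzero voxels")
    cut = np.percentile(freq[support], pct_thresh)
    return support & (freq >= cut)


def occupancy(
    rsn_zmap: np.ndarray,
    freq_map: np.ndarray,
    z_thresh: float = DEFAULT_Z_THRESH,
    pct_thresh: float = DEFAULT_PCT_THRESH,
    rsn_name: str = "RSN",
) -> OccupancyRow:
    """Percentage of one RSN (z > z_thresh) occupied by macrovasculature."""
    zmap = np.asarray(rsn_zmap, dtype=float)
    freq = np.asarray(freq_map, dtype=float)
    if zmap.shape != freq.shape:
        raise ValueError(
            f"RSN map shape {zmap.shape} differs from frequency map {freq.shape}"
        )
    rsn_mask = zmap > z_thresh
    n_rsn = int(rsn_mask.sum())
    if n_rsn == 0:
        raise ValueError(f"RSN {rsn_name!r}: empty mask at z > {z_thresh}")
    vasc = vascular_mask_from_frequency(freq, pct_thresh)
    n_overlap = int((rsn_mask & vasc).sum())
    return OccupancyRow(
        rsn_name=rsn_name,
        rsn_voxels=n_rsn,
        overlap_voxels=n_overlap,
        percent=100.0 * n_overlap / n_rsn,
    )


def occupancy_table(
    rsn_zmaps: dict[str, np.ndarray],
    freq_map: np.ndarray,
    z_thresh: float = DEFAULT_Z_THRESH,
    pct_thresh: float = DEFAULT_PCT_THRESH,
) -> pd.DataFrame:
    """Occupancy for a set of RSNs, sorted descending by percentage."""
    rows = [
        occupancy(zmap, freq_map, z_thresh, pct_thresh, rsn_name=name)
        for name, zmap in rsn_zmaps.items()
    ]
    df = pd.DataFrame([r.__dict__ for r in rows])
    return df.sort_values("percent", ascending=False, kind="mergesort").reset_index(
        drop=True
    )
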