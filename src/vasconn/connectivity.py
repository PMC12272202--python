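"""Seed-target correlation structure of the macrovasculature.

For each of the four vascular seed/target categories (venous-venous VV,
arterial-arterial AA, arterial-venous AV, venous-arterial VA) plus the
gray-matter references (V_GM, A_GM, GM_GM), this module computes per-seed

* degree of connectivity ``D``: number of target voxels whose Pearson
  correlation with the seed exceeds a threshold (default 0.15), either in
  absolute value (default) or positively;
* strength of connectivity ``S``: spatial mean of the correlations, split by
  sign (``S_pos``/``S_neg``) and overall (``S_all``);
* variance of connectivity ``var``: spatial (population) variance of the
  correlations, same splits.

Correlations are streamed in seed blocks so the working set is bounded by
``block_size x n_targets`` correlation rows, never the full seed-by-target
matrix.  Self-pairs are flagged and excluded from all statistics, and
zero-variance voxels are dropped from the target set (shrinking
``n_targets_valid``) and yield undefined rows as seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pandas as pd

from .grid import BinaryMask, Bold4D, VolumeGrid

__all__ = [
    "PerSeedRow",
    "ConnectivityMaps",
    "RatioMaps",
    "GroupSummary",
    "seed_target_correlations",
    "degree_map",
    "strength_variance_maps",
    "connectivity_maps",
    "category_metrics",
    "ratio_maps",
    "group_summarize",
    "CATEGORY_DEFS",
]

DEFAULT_THRESHOLD = 0.15  # degree threshold on the correlation coefficient

#: category name -> (seed set, target set) in terms of the three input masks
CATEGORY_DEFS = {
    "VV": ("venous", "venous"),
    "AA": ("arterial", "arterial"),
    "AV": ("arterial", "venous"),
    "VA": ("venous", "arterial"),
    "V_GM": ("venous", "gm"),
    "A_GM": ("arterial", "gm"),
    "GM_GM": ("gm", "gm"),
}

CONNECTIVITY_METRICS = ("D", "S_pos", "S_neg", "S_all", "var_pos", "var_neg", "var_all")
RATIO_METRICS = ("D_ratio", "var_ratio_pos", "var_ratio_neg", "var_ratio_all")


class PerSeedRow(NamedTuple):
    """One seed's correlations with all valid targets (self excluded)."""

    seed_flat: int  # flat C-order voxel index of the seed
    r: np.ndarray | None  # None when the seed has zero variance
    n_targets_valid: int  # valid targets for this seed (self excluded)


def _standardized(ts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows standardized so that Z @ Z.T gives Pearson r; returns (Z, valid)."""
    ts = ts - ts.mean(axis=1, keepdims=True)
    sd = ts.std(axis=1)
    valid = sd > 0
    Z = np.zeros_like(ts)
    if valid.any():
        Z[valid] = ts[valid] / (sd[valid, None] * np.sqrt(ts.shape[1]))
    return Z, valid


def seed_target_correlations(
    bold: Bold4D,
    seeds: BinaryMask,
    targets: BinaryMask,
    block_size: int = 256,
) -> Iterator[PerSeedRow]:
    """Stream Pearson correlations of every seed voxel with every target voxel.

    Yields one :class:`PerSeedRow` per seed voxel (in flat-index order) with
    the self-pair removed and zero-variance targets dropped.  Raises if the
    seed set is empty or entirely zero-variance.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    bold.grid.require_same(seeds.grid, "seed mask")
    bold.grid.require_same(targets.grid, "target mask")
    if seeds.is_empty():
        raise ValueError("seed mask is empty")
    if targets.is_empty():
        raise ValueError("target mask is empty")

    n_t = bold.n_volumes
    Y = bold.data.reshape(-1, n_t)
    seed_flat = seeds.flat_indices()
    target_flat = targets.flat_indices()

    Zt_all, t_valid = _standardized(Y[target_flat])
    valid_target_flat = target_flat[t_valid]
    Zt = Zt_all[t_valid]
    n_valid_targets = int(t_valid.sum())

    seed_sd = Y[seed_flat].std(axis=1)
    if not (seed_sd > 0).any():
        raise ValueError("every seed voxel has zero variance")

    for start in range(0, seed_flat.size, block_size):
        block = seed_flat[start : start + block_size]
        Zs, s_valid = _standardized(Y[block])
        r_block = Zs @ Zt.T  # (block, n_valid_targets)
        # column of each seed's own voxel in the valid-target list, if present
        cols = np.searchsorted(valid_target_flat, block)
        for i, sf in enumerate(block):
            self_col = -1
            if cols[i] < n_valid_targets and valid_target_flat[cols[i]] == sf:
                self_col = int(cols[i])
            n_valid = n_valid_targets - (1 if self_col >= 0 else 0)
            if not s_valid[i]:
                yield PerSeedRow(int(sf), None, n_valid)
                continue
            row = r_block[i]
            if self_col >= 0:
                row = np.delete(row, self_col)
            np.clip(row, -1.0, 1.0, out=row)
            yield PerSeedRow(int(sf), row, n_valid)


def degree_map(
    rows: Iterable[PerSeedRow],
    threshold: float = DEFAULT_THRESHOLD,
    mode: str = "absolute",
) -> np.ndarray:
    """Degree of connectivity per seed: count of suprathreshold correlations.

    ``mode='absolute'`` counts ``|r| > threshold`` (captures the arterial-
    venous anti-correlations); ``mode='positive'`` counts ``r > threshold``.
    Undefined (zero-variance) seeds yield NaN.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    if mode not in ("absolute", "positive"):
        raise ValueError(f"mode must be 'absolute' or 'positive', got {mode!r}")
    out = []
    for row in rows:
        if row.r is None:
            out.append(np.nan)
        elif mode == "absolute":
            out.append(float(np.count_nonzero(np.abs(row.r) > threshold)))
        else:
            out.append(float(np.count_nonzero(row.r > threshold)))
    return np.asarray(out)


def strength_variance_maps(rows: Iterable[PerSeedRow]) -> dict[str, np.ndarray]:
    """Signed strength and spatial variance of correlations per seed.

    ``S_pos``/``var_pos`` are the mean and population variance over the
    positive correlations only (NaN when the sign class is empty), likewise
    for negatives; ``S_all``/``var_all`` use every correlation.  ``n_pos`` /
    ``n_neg`` report the sign-class sizes.
    """
    acc: dict[str, list[float]] = {
        k: [] for k in ("S_pos", "S_neg", "S_all", "var_pos", "var_neg", "var_all", "n_pos", "n_neg")
    }
    for row in rows:
        if row.r is None or row.r.size == 0:
            for k in ("S_pos", "S_neg", "S_all", "var_pos", "var_neg", "var_all"):
                acc[k].append(np.nan)
            acc["n_pos"].append(0.0)
            acc["n_neg"].append(0.0)
            continue
        r = row.r
        pos = r[r > 0]
        neg = r[r < 0]
        acc["n_pos"].append(float(pos.size))
        acc["n_neg"].append(float(neg.size))
        acc["S_pos"].append(float(pos.mean()) if pos.size else np.nan)
        acc["var_pos"].append(float(pos.var()) if pos.size else np.nan)
        acc["S_neg"].append(float(neg.mean()) if neg.size else np.nan)
        acc["var_neg"].append(float(neg.var()) if neg.size else np.nan)
        acc["S_all"].append(float(r.mean()))
        acc["var_all"].append(float(r.var()))
    return {k: np.asarray(v) for k, v in acc.items()}


@dataclass
class ConnectivityMaps:
    """Per-seed connectivity metrics for one seed/target category."""

    category: str
    grid: VolumeGrid
    seed_flat: np.ndarray
    threshold: float
    mode: str
    D: np.ndarray
    S_pos: np.ndarray
    S_neg: np.ndarray
    S_all: np.ndarray
    var_pos: np.ndarray
    var_neg: np.ndarray
    var_all: np.ndarray
    n_pos: np.ndarray
    n_neg: np.ndarray
    n_targets_valid: np.ndarray

    def metric(self, name: str) -> np.ndarray:
        if name not in CONNECTIVITY_METRICS:
            raise KeyError(f"unknown metric {name!r}")
        return getattr(self, name)

    def spatial_mean(self, name: str) -> float:
        """Mean over defined seed voxels (undefined sentinels excluded)."""
        vals = self.metric(name)
        if np.isnan(vals).all():
            return float("nan")
        return float(np.nanmean(vals))

    def n_defined(self, name: str) -> int:
        return int(np.count_nonzero(~np.isnan(self.metric(name))))

    def to_volume(self, name: str, background: float = np.nan) -> np.ndarray:
        vol = np.full(self.grid.n_voxels, background)
        vol[self.seed_flat] = self.metric(name)
        return vol.reshape(self.grid.shape)


def connectivity_maps(
    bold: Bold4D,
    seeds: BinaryMask,
    targets: BinaryMask,
    threshold: float = DEFAULT_THRESHOLD,
    mode: str = "absolute",
    block_size: int = 256,
    category: str = "",
) -> ConnectivityMaps:
    """Single-pass computation of D, S+-, and variance maps for one category."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    if mode not in ("absolute", "positive"):
        raise ValueError(f"mode must be 'absolute' or 'positive', got {mode!r}")
    D: list[float] = []
    nt: list[int] = []
    sv_rows: list[PerSeedRow] = []

    acc = {
        k: []
        for k in ("S_pos", "S_neg", "S_all", "var_pos", "var_neg", "var_all", "n_pos", "n_neg")
    }
    for row in seed_target_correlations(bold, seeds, targets, block_size):
        nt.append(row.n_targets_valid)
        if row.r is None:
            D.append(np.nan)
        elif mode == "absolute":
            D.append(float(np.count_nonzero(np.abs(row.r) > threshold)))
        else:
            D.append(float(np.count_nonzero(row.r > threshold)))
        sv = strength_variance_maps([row])
        for k in acc:
            acc[k].append(float(sv[k][0]))

    return ConnectivityMaps(
        category=category,
        grid=bold.grid,
        seed_flat=seeds.flat_indices(),
        threshold=float(threshold),
        mode=mode,
        D=np.asarray(D),
        S_pos=np.asarray(acc["S_pos"]),
        S_neg=np.asarray(acc["S_neg"]),
        S_all=np.asarray(acc["S_all"]),
        var_pos=np.asarray(acc["var_pos"]),
        var_neg=np.asarray(acc["var_neg"]),
        var_all=np.asarray(acc["var_all"]),
        n_pos=np.asarray(acc["n_pos"]),
        n_neg=np.asarray(acc["n_neg"]),
        n_targets_valid=np.asarray(nt),
    )


def category_metrics(
    bold: Bold4D,
    arterial: BinaryMask,
    venous: BinaryMask,
    gm: BinaryMask,
    threshold: float = DEFAULT_THRESHOLD,
    mode: str = "absolute",
    block_size: int = 256,
    categories: Iterable[str] | None = None,
) -> dict[str, ConnectivityMaps]:
    """Connectivity maps for the four vascular categories plus GM references.

    Seeds are excluded from their own target sets voxelwise (self-pairs),
    so VV/AA/GM_GM behave as "each voxel against each *other* voxel".
    """
    if not arterial.intersect(venous).is_empty():
        raise ValueError("arterial and venous masks overlap")
    mask_by_role = {"arterial": arterial, "venous": venous, "gm": gm}
    wanted = list(categories) if categories is not None else list(CATEGORY_DEFS)
    unknown = set(wanted) - set(CATEGORY_DEFS)
    if unknown:
        raise ValueError(f"unknown categories {sorted(unknown)}")
    out: dict[str, ConnectivityMaps] = {}
    for name in wanted:
        seed_role, target_role = CATEGORY_DEFS[name]
        out[name] = connectivity_maps(
            bold,
            mask_by_role[seed_role],
            mask_by_role[target_role],
            threshold=threshold,
            mode=mode,
            block_size=block_size,
            category=name,
        )
    return out


@dataclass
class RatioMaps:
    """Voxelwise macrovascular-to-GM metric ratios for one seed set."""

    category: str  # e.g. "VV:V_GM"
    grid: VolumeGrid
    seed_flat: np.ndarray
    threshold: float
    D_ratio: np.ndarray
    var_ratio_pos: np.ndarray
    var_ratio_neg: np.ndarray
    var_ratio_all: np.ndarray

    def metric(self, name: str) -> np.ndarray:
        if name not in RATIO_METRICS:
            raise KeyError(f"unknown ratio metric {name!r}")
        return getattr(self, name)

    def spatial_mean(self, name: str) -> float:
        vals = self.metric(name)
        if np.isnan(vals).all():
            return float("nan")
        return float(np.nanmean(vals))

    def n_defined(self, name: str) -> int:
        return int(np.count_nonzero(~np.isnan(self.metric(name))))

    def to_volume(self, name: str, background: float = np.nan) -> np.ndarray:
        vol = np.full(self.grid.n_voxels, background)
        vol[self.seed_flat] = self.metric(name)
        return vol.reshape(self.grid.shape)


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(num.shape, np.nan)
    ok = ~np.isnan(num) & ~np.isnan(den) & (den != 0)
    out[ok] = num[ok] / den[ok]
    return out


def ratio_maps(numerator: ConnectivityMaps, denominator: ConnectivityMaps) -> RatioMaps:
    """Voxelwise ratios of two connectivity maps sharing one seed set.

    ``D_ratio = D_num / D_den`` (NaN where the denominator is zero or
    undefined); variance ratios analogously per sign class.
    """
    if numerator.seed_flat.shape != denominator.seed_flat.shape or not np.array_equal(
        numerator.seed_flat, denominator.seed_flat
    ):
        raise ValueError("numerator and denominator use different seed masks")
    if numerator.threshold != denominator.threshold or numerator.mode != denominator.mode:
        raise ValueError("numerator and denominator use different threshold/mode")
    return RatioMaps(
        category=f"{numerator.category}:{denominator.category}",
        grid=numerator.grid,
        seed_flat=numerator.seed_flat.copy(),
        threshold=numerator.threshold,
        D_ratio=_safe_ratio(numerator.D, denominator.D),
        var_ratio_pos=_safe_ratio(numerator.var_pos, denominator.var_pos),
        var_ratio_neg=_safe_ratio(numerator.var_neg, denominator.var_neg),
        var_ratio_all=_safe_ratio(numerator.var_all, denominator.var_all),
    )


@dataclass
class GroupSummary:
    """Session-level spatial means and their group statistics.

    ``per_session``: one row per (session, category, metric) with the spatial
    mean over defined seed voxels and the defined-voxel count.
    ``group``: mean, median, quartiles (linear interpolation) and extremes of
    the session values per (category, metric).
    """

    per_session: pd.DataFrame
    group: pd.DataFrame


def _session_rows(session: int, maps: dict) -> list[dict]:
    rows = []
    for cat, m in maps.items():
        metrics = CONNECTIVITY_METRICS if isinstance(m, ConnectivityMaps) else RATIO_METRICS
        for metric in metrics:
            rows.append(
                {
                    "session": session,
                    "category": cat,
                    "metric": metric,
                    "value": m.spatial_mean(metric),
                    "n_defined": m.n_defined(metric),
                }
            )
    return rows


def group_summarize(sessions: list[dict]) -> GroupSummary:
    """Summarize per-session connectivity/ratio maps across sessions.

    Each element of ``sessions`` is a mapping category -> ConnectivityMaps or
    RatioMaps.  A metric undefined in every session stays NaN (never coerced
    to zero); NaN session values are excluded from group statistics with the
    inclusion count reported.
    """
    if not sessions:
        raise ValueError("need at least one session")
    rows: list[dict] = []
    for i, maps in enumerate(sessions):
        rows.extend(_session_rows(i, maps))
    per_session = pd.DataFrame(rows)

    def _stats(g: pd.Series) -> pd.Series:
        vals = g.dropna().to_numpy()
        if vals.size == 0:
            return pd.Series(
                {"mean": np.nan, "median": np.nan, "q1": np.nan, "q3": np.nan,
                 "min": np.nan, "max": np.nan, "n_sessions": 0}
            )
        return pd.Series(
            {
                "mean": vals.mean(),
                "median": float(np.median(vals)),
                "q1": float(np.percentile(vals, 25)),
                "q3": float(np.percentile(vals, 75)),
                "min": vals.min(),
                "max": vals.max(),
                "n_sessions": vals.size,
            }
        )

    group = (
        per_session.groupby(["category", "metric"])["value"].apply(_stats).unstack()
    ).reset_index()
    return GroupSummary(per_session=per_session, group=group)
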