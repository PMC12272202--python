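"""Seeded 4D vascular sLFO phantoms with ground truth.

The phantom emulates the data structure the connectivity analysis assumes: a
coarse fMRI grid carrying thin tubular arteries and veins that share one
band-limited (0.01-0.1 Hz) systemic low-frequency oscillation (sLFO) with
opposite signs, extravascular coupling that decays with Chebyshev distance
from the vessels, a gray-matter background that carries an attenuated copy of
the same global signal, and additive noise.  Every voxel time series is

    x(t) = g_type * s(t - lag_type) * c(d)  +  background(t)  +  noise(t)

where ``s`` is the unit-variance sLFO, ``g_type`` the venous or arterial
gain, ``d`` the Chebyshev distance to the nearest vessel voxel and
``c(d) = c0 * exp(-d / lambda)`` for perivascular voxels (``c(0) = 1`` inside
a vessel, 0 beyond the truncation radius ``4 * lambda``).

All randomness derives from one integer seed through fixed per-compartment
sub-streams, so identical specs give bit-identical phantoms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import distance_transform_cdt

from .grid import (
    ARTERY_LABEL,
    VEIN_LABEL,
    BinaryMask,
    Bold4D,
    VesselLabelMap,
    VolumeGrid,
)

__all__ = [
    "PhantomSpecError",
    "PhantomSpec",
    "PhantomTruth",
    "Phantom",
    "make_slfo",
    "lay_vessels",
    "make_phantom",
    "straight_tube",
    "vessels_from_voxels",
    "brain_compartments",
]

# sub-stream ids appended to the user seed; fixed forever for reproducibility
_STREAM_SLFO = 0
_STREAM_GM = 1
_STREAM_WM = 2
_STREAM_CSF = 3
_STREAM_WHITE = 4


class PhantomSpecError(ValueError):
    """Invalid phantom specification."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic run.

    Defaults are the desk-scale test profile (24 x 24 x 16 voxels at 4 mm,
    200 volumes).  ``msc_like`` gives the full-scale profile of the study
    data (64 x 64 x 36 at 4 mm, TR 2.2 s, 818 volumes ~ 30 min).
    """

    grid_dims: tuple[int, int, int] = (24, 24, 16)
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    tr_s: float = 2.2
    n_volumes: int = 200
    band_lo_hz: float = 0.01
    band_hi_hz: float = 0.1
    venous_gain: float = 1.0
    arterial_gain: float = -0.5
    venous_lag_s: float = 0.0
    arterial_lag_s: float = 0.0
    gm_lag_s: float = 3.0
    wm_lag_s: float = 4.0
    csf_lag_s: float = 6.0
    coupling_c0: float = 0.5
    coupling_lambda_vox: float = 2.0
    gm_global_gain: float = 0.3
    gm_noise_sd: float = 2.0
    noise_sd: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid_dims", tuple(int(d) for d in self.grid_dims))
        object.__setattr__(
            self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm)
        )
        self.validate()

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_s)

    def validate(self) -> None:
        if len(self.grid_dims) != 3 or any(d <= 0 for d in self.grid_dims):
            raise PhantomSpecError(f"grid_dims must be positive triple: {self.grid_dims}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise PhantomSpecError("voxel_size_mm must be positive")
        if self.tr_s <= 0:
            raise PhantomSpecError("tr_s must be positive")
        if self.n_volumes < 32:
            raise PhantomSpecError(f"n_volumes must be >= 32, got {self.n_volumes}")
        if not (0.0 < self.band_lo_hz < self.band_hi_hz < self.nyquist_hz):
            raise PhantomSpecError(
                f"band [{self.band_lo_hz}, {self.band_hi_hz}] Hz must satisfy "
                f"0 < lo < hi < Nyquist = {self.nyquist_hz:.4g} Hz"
            )
        for name in (
            "venous_gain", "arterial_gain", "venous_lag_s", "arterial_lag_s",
            "gm_lag_s", "wm_lag_s", "csf_lag_s",
        ):
            if not np.isfinite(getattr(self, name)):
                raise PhantomSpecError(f"{name} must be finite")
        if not (0.0 <= self.coupling_c0 <= 1.0):
            raise PhantomSpecError("coupling_c0 must lie in [0, 1]")
        if self.coupling_lambda_vox <= 0:
            raise PhantomSpecError("coupling_lambda_vox must be positive")
        if not (0.0 <= self.gm_global_gain < 1.0):
            raise PhantomSpecError("gm_global_gain must lie in [0, 1)")
        if self.noise_sd < 0:
            raise PhantomSpecError("noise_sd must be nonnegative")
        if self.gm_noise_sd < 0:
            raise PhantomSpecError("gm_noise_sd must be nonnegative")

    @classmethod
    def msc_like(cls, rng_seed: int = 0, **overrides) -> "PhantomSpec":
        """Full-scale profile mirroring the study acquisition (36 slices,
        TR 2.2 s, 818 volumes ~ 30 min, 4 mm isotropic)."""
        params = dict(
            grid_dims=(64, 64, 36),
            n_volumes=818,
            rng_seed=rng_seed,
        )
        params.update(overrides)
        return cls(**params)

    def grid(self) -> VolumeGrid:
        return VolumeGrid.from_spacing(self.grid_dims, self.voxel_size_mm)

    def replace(self, **kw) -> "PhantomSpec":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PhantomTruth:
    """Ground truth for parameter-recovery tests."""

    vessel_distance_map: np.ndarray  # Chebyshev distance to nearest vessel voxel
    vessel_type_map: np.ndarray  # 0 none (or beyond truncation), 1 artery, 2 vein
    coupling_gain: np.ndarray  # c(d); zero beyond the truncation radius
    slfo_timecourse: np.ndarray


@dataclass
class Phantom:
    """One generated phantom: BOLD, vessel labels, tissue masks, truth."""

    spec: PhantomSpec
    bold: Bold4D
    labels: VesselLabelMap
    gm: BinaryMask
    wm: BinaryMask
    csf: BinaryMask
    brain: BinaryMask
    truth: PhantomTruth

    def save(self, out_dir) -> None:
        """Write NIfTI volumes plus a JSON sidecar (spec echo, label codes)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.bold.save(out / "bold.nii")
        self.labels.save(out / "vessel_labels.nii")
        for name in ("gm", "wm", "csf", "brain"):
            getattr(self, name).save(out / f"{name}.nii")
        import nibabel as nib

        aff = self.bold.grid.affine
        nib.save(
            nib.Nifti1Image(self.truth.vessel_distance_map.astype(np.int16), aff),
            str(out / "truth_distance.nii"),
        )
        nib.save(
            nib.Nifti1Image(self.truth.vessel_type_map.astype(np.int16), aff),
            str(out / "truth_type.nii"),
        )
        nib.save(
            nib.Nifti1Image(self.truth.coupling_gain.astype(np.float32), aff),
            str(out / "truth_coupling.nii"),
        )
        sidecar = {
            "spec": self.spec.to_dict(),
            "labels": {"background": 0, "artery": ARTERY_LABEL, "vein": VEIN_LABEL},
            "slfo_timecourse": [float(v) for v in self.truth.slfo_timecourse],
        }
        (out / "phantom.json").write_text(json.dumps(sidecar, indent=2))


def _rng(spec: PhantomSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(spec.rng_seed), int(stream)])


def _band_mask(n: int, tr_s: float, lo: float, hi: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, d=tr_s)
    keep = (freqs >= lo) & (freqs <= hi)
    keep[0] = False  # never keep DC
    return keep


def make_slfo(spec: PhantomSpec) -> np.ndarray:
    """Unit-variance, zero-mean signal with power confined to the sLFO band.

    White Gaussian noise is hard band-limited in the frequency domain and
    standardized, so the spectral support matches the analysis band exactly.
    """
    spec.validate()
    keep = _band_mask(spec.n_volumes, spec.tr_s, spec.band_lo_hz, spec.band_hi_hz)
    if not keep.any():
        raise PhantomSpecError(
            f"band [{spec.band_lo_hz}, {spec.band_hi_hz}] Hz contains no frequency "
            f"bin at n={spec.n_volumes}, TR={spec.tr_s}s"
        )
    rng = _rng(spec, _STREAM_SLFO)
    white = rng.standard_normal(spec.n_volumes)
    spectrum = np.fft.rfft(white)
    spectrum[~keep] = 0.0
    s = np.fft.irfft(spectrum, n=spec.n_volumes)
    s -= s.mean()
    sd = s.std()
    if sd == 0:  # pragma: no cover - requires pathological band
        raise PhantomSpecError("degenerate sLFO: zero variance after band-limiting")
    return s / sd


def _lag_signal(s: np.ndarray, lag_s: float, tr_s: float) -> np.ndarray:
    """Circularly delay a band-limited signal by ``lag_s`` seconds (FFT phase
    ramp; exact for the periodic extension of a band-limited series)."""
    if lag_s == 0.0:
        return s
    n = s.size
    freqs = np.fft.rfftfreq(n, d=tr_s)
    shifted = np.fft.irfft(np.fft.rfft(s) * np.exp(-2j * np.pi * freqs * lag_s), n=n)
    return shifted


def straight_tube(
    start: tuple[int, int, int], axis: int, length: int
) -> np.ndarray:
    """Voxel indices (length, 3) of an axis-aligned 1-voxel-thick tube."""
    if length < 1:
        raise ValueError("tube length must be >= 1")
    idx = np.repeat(np.asarray(start, dtype=int)[None, :], length, axis=0)
    idx[:, axis] += np.arange(length)
    return idx


def vessels_from_voxels(
    grid_dims: tuple[int, int, int],
    artery_voxels: np.ndarray,
    vein_voxels: np.ndarray,
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0),
) -> VesselLabelMap:
    """Build a label map from explicit artery/vein voxel index arrays."""
    grid = VolumeGrid.from_spacing(grid_dims, voxel_size_mm)
    data = np.zeros(grid_dims, dtype=np.int16)
    a = np.atleast_2d(np.asarray(artery_voxels, dtype=int))
    v = np.atleast_2d(np.asarray(vein_voxels, dtype=int))
    if a.size and v.size:
        overlap = {tuple(r) for r in a} & {tuple(r) for r in v}
        if overlap:
            raise ValueError(f"artery and vein voxel sets overlap at {sorted(overlap)[:5]}")
    for idx, label in ((a, ARTERY_LABEL), (v, VEIN_LABEL)):
        if idx.size == 0:
            continue
        if (idx < 0).any() or (idx >= np.asarray(grid_dims)).any():
            raise ValueError("vessel voxel index outside the grid")
        data[idx[:, 0], idx[:, 1], idx[:, 2]] = label
    return VesselLabelMap(grid, data)


def _default_tube_geometry(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    nx, ny, nz = spec.grid_dims
    if nx < 10 or ny < 12 or nz < 9:
        raise PhantomSpecError(
            f"grid {spec.grid_dims} too small for the default vessel layout "
            "(need >= 10 x 12 x 9 to fit two tubes of length >= 5 inside GM)"
        )
    y0, y1 = 3, ny - 4  # inclusive; keeps tube ends >= 3 voxels from the edge
    length = y1 - y0 + 1
    artery = straight_tube((3, y0, nz // 2), axis=1, length=length)
    vein = straight_tube((nx - 4, y0, nz // 2), axis=1, length=length)
    return artery, vein


def lay_vessels(spec: PhantomSpec) -> VesselLabelMap:
    """Place the default vascular geometry: two parallel straight tubes
    (one artery, one vein), 1 voxel thick, running through the GM band on
    opposite sides of the volume."""
    artery, vein = _default_tube_geometry(spec)
    return vessels_from_voxels(
        spec.grid_dims, artery, vein, voxel_size_mm=spec.voxel_size_mm
    )


def brain_compartments(grid: VolumeGrid) -> dict[str, BinaryMask]:
    """Partition the volume into background / CSF / GM / WM by Chebyshev
    depth from the volume edge (nested boxes).

    Depth 1 is background (outside the head), depth 2 the CSF layer, depths
    3 .. (dmax - 2) the GM band and anything deeper WM, where dmax is the
    largest depth the grid supports.  Crude but sufficient: straight vessel
    tubes placed at depth 4 always lie inside GM.
    """
    nx, ny, nz = grid.shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    depth = np.minimum.reduce(
        [ii + 1, nx - ii, jj + 1, ny - jj, kk + 1, nz - kk]
    )
    dmax = int(depth.max())
    if dmax < 5:
        raise PhantomSpecError(
            f"grid {grid.shape} too thin for compartments (max edge depth {dmax} < 5)"
        )
    gm_hi = max(4, dmax - 2)  # keep default tubes (depth 4) inside the GM band
    masks = {
        "csf": depth == 2,
        "gm": (depth >= 3) & (depth <= gm_hi),
        "wm": depth > gm_hi,
        "brain": depth >= 2,
    }
    return {k: BinaryMask(grid, v) for k, v in masks.items()}


def _bandlimited_noise(
    rng: np.random.Generator, n_vox: int, spec: PhantomSpec
) -> np.ndarray:
    """(n_vox, T) independent per-voxel unit-variance band-limited series."""
    if n_vox == 0:
        return np.zeros((0, spec.n_volumes))
    keep = _band_mask(spec.n_volumes, spec.tr_s, spec.band_lo_hz, spec.band_hi_hz)
    white = rng.standard_normal((n_vox, spec.n_volumes))
    spectrum = np.fft.rfft(white, axis=1)
    spectrum[:, ~keep] = 0.0
    x = np.fft.irfft(spectrum, n=spec.n_volumes, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def make_phantom(
    spec: PhantomSpec, labels: VesselLabelMap | None = None
) -> Phantom:
    """Generate a complete phantom from a spec (and optionally a custom
    vessel label map on the same grid)."""
    spec.validate()
    grid = spec.grid()
    if labels is None:
        labels = lay_vessels(spec)
    else:
        grid.require_same(labels.grid, "vessel label map")

    comps = brain_compartments(grid)
    artery = labels.data == ARTERY_LABEL
    vein = labels.data == VEIN_LABEL
    cores = artery | vein

    # Chebyshev distances to each vessel class (0 inside the class)
    d_a = (
        distance_transform_cdt(~artery, metric="chessboard")
        if artery.any()
        else np.full(grid.shape, np.iinfo(np.int32).max, dtype=np.int64)
    )
    d_v = (
        distance_transform_cdt(~vein, metric="chessboard")
        if vein.any()
        else np.full(grid.shape, np.iinfo(np.int32).max, dtype=np.int64)
    )
    d_a = np.asarray(d_a, dtype=np.int64)
    d_v = np.asarray(d_v, dtype=np.int64)
    d = np.minimum(d_a, d_v)
    # equidistant voxels couple to the vein (dominant macrovascular signal)
    nearest_is_vein = d_v <= d_a

    trunc = 4.0 * spec.coupling_lambda_vox
    coupled = d <= trunc
    c = np.zeros(grid.shape)
    peri = coupled & (d >= 1)
    c[peri] = spec.coupling_c0 * np.exp(-d[peri] / spec.coupling_lambda_vox)
    c[cores] = 1.0

    type_map = np.zeros(grid.shape, dtype=np.int16)
    type_map[coupled & nearest_is_vein] = VEIN_LABEL
    type_map[coupled & ~nearest_is_vein] = ARTERY_LABEL

    s = make_slfo(spec)
    s_by_type = {
        ARTERY_LABEL: spec.arterial_gain
        * _lag_signal(s, spec.arterial_lag_s, spec.tr_s),
        VEIN_LABEL: spec.venous_gain * _lag_signal(s, spec.venous_lag_s, spec.tr_s),
    }

    n_t = spec.n_volumes
    data = np.zeros((*grid.shape, n_t))

    # vascular component: g_type * s(t - lag) * c(d)
    for label, sig in s_by_type.items():
        sel = (type_map == label) & (c > 0)
        if sel.any():
            data[sel] += c[sel, None] * sig[None, :]

    # compartment backgrounds: shared global signal (at the compartment's
    # transit lag, sLFOs being a traveling signal) + per-voxel band-limited
    # noise; vessel cores carry only the vascular signal (plus white noise).
    # The lags keep the WM/CSF mean regressors only partially correlated with
    # the vascular signal, so nuisance regression has a real partial effect.
    bg_specs = (
        ("gm", spec.gm_global_gain, spec.gm_lag_s, _STREAM_GM),
        ("wm", spec.gm_global_gain / 2.0, spec.wm_lag_s, _STREAM_WM),
        ("csf", spec.gm_global_gain / 2.0, spec.csf_lag_s, _STREAM_CSF),
    )
    for name, gain, lag_s, stream in bg_specs:
        sel = comps[name].data & ~cores
        n_vox = int(sel.sum())
        if n_vox == 0:
            continue
        bg = gain * _lag_signal(s, lag_s, spec.tr_s)[None, :] + (
            spec.gm_noise_sd * _bandlimited_noise(_rng(spec, stream), n_vox, spec)
        )
        data[sel] += bg

    if spec.noise_sd > 0:
        brain = comps["brain"].data
        n_brain = int(brain.sum())
        data[brain] += spec.noise_sd * _rng(spec, _STREAM_WHITE).standard_normal(
            (n_brain, n_t)
        )

    bold = Bold4D(grid, data, spec.tr_s)
    truth = PhantomTruth(
        vessel_distance_map=d,
        vessel_type_map=type_map,
        coupling_gain=c,
        slfo_timecourse=s,
    )
    return Phantom(
        spec=spec,
        bold=bold,
        labels=labels,
        gm=comps["gm"],
        wm=comps["wm"],
        csf=comps["csf"],
        brain=comps["brain"],
        truth=truth,
    )
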