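"""Minimal rs-fMRI preprocessing: nuisance regression, bandpass, smoothing.

Only the stages downstream of motion correction / coregistration are
implemented (inputs are assumed already realigned): (e) regression of the
mean WM and CSF signals, (f) 0.01-0.1 Hz temporal bandpass, (g) 6 mm FWHM
Gaussian spatial smoothing, applied in that order.  All three stages are
linear operators on the time series.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import detrend as _linear_detrend

from .grid import BinaryMask, Bold4D

__all__ = ["regress_nuisance", "bandpass", "smooth", "preprocess_bold", "fwhm_to_sigma"]

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Gaussian sigma for a given FWHM: sigma = FWHM / sqrt(8 ln 2)."""
    return fwhm_mm * FWHM_TO_SIGMA


def regress_nuisance(bold: Bold4D, region_masks: list[BinaryMask]) -> Bold4D:
    """Regress the mean signal of each region (plus an intercept) out of
    every voxel time series.

    Residuals are orthogonal to each retained regressor.  A regressor that is
    (numerically) collinear with the ones before it is dropped with a
    warning rather than silently inflating the fit.
    """
    n_t = bold.n_volumes
    columns = [np.ones(n_t)]
    for i, m in enumerate(region_masks):
        bold.grid.require_same(m.grid, f"region mask #{i}")
        if m.is_empty():
            raise ValueError(f"region mask #{i} is empty; cannot form a mean regressor")
        columns.append(bold.timeseries(m).mean(axis=0))

    design = [columns[0]]
    for i, col in enumerate(columns[1:]):
        trial = np.column_stack(design + [col])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            design.append(col)
        else:
            warnings.warn(
                f"nuisance regressor #{i} is collinear with earlier regressors; dropped",
                stacklevel=2,
            )
    X = np.column_stack(design)  # (T, p)

    Y = bold.data.reshape(-1, n_t).T  # (T, n_vox)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return bold.with_data(resid.T.reshape(bold.data.shape))


def bandpass(bold: Bold4D, f_lo: float = 0.01, f_hi: float = 0.1) -> Bold4D:
    """Frequency-domain ideal bandpass after linear detrending.

    Retains DFT bins with ``f_lo <= f <= f_hi``; the DC bin is always
    removed, so the output is zero-mean per voxel.  An ideal (bin-selection)
    filter has an exactly bounded passband and no phase distortion, mirroring
    the behavior of the standard fMRI bandpass tools.
    """
    nyq = bold.nyquist_hz
    if not (0.0 <= f_lo < f_hi):
        raise ValueError(f"need 0 <= f_lo < f_hi, got [{f_lo}, {f_hi}]")
    if f_hi > nyq + 1e-12:
        raise ValueError(
            f"f_hi = {f_hi} Hz exceeds the Nyquist frequency {nyq:.6g} Hz "
            f"for TR = {bold.tr_s} s"
        )
    if bold.n_volumes < 16:
        raise ValueError("need at least 16 volumes to bandpass")

    n_t = bold.n_volumes
    Y = bold.data.reshape(-1, n_t)
    Y = _linear_detrend(Y, axis=1, type="linear")
    freqs = np.fft.rfftfreq(n_t, d=bold.tr_s)
    keep = (freqs >= f_lo) & (freqs <= f_hi)
    keep[0] = False
    spectrum = np.fft.rfft(Y, axis=1)
    spectrum[:, ~keep] = 0.0
    out = np.fft.irfft(spectrum, n=n_t, axis=1)
    # remove the in-band component of the trend direction so the whole
    # operation is an orthogonal projection (output in band and orthogonal to
    # {1, t}); this makes the filter exactly idempotent
    t = np.arange(n_t) - (n_t - 1) / 2.0
    g_spec = np.fft.rfft(t)
    g_spec[~keep] = 0.0
    g = np.fft.irfft(g_spec, n=n_t)
    gg = float(g @ g)
    if gg > 1e-12:
        out -= np.outer(out @ g, g) / gg
    return bold.with_data(out.reshape(bold.data.shape))


def smooth(
    bold: Bold4D,
    fwhm_mm: float = 6.0,
    renormalize_mask: BinaryMask | None = None,
) -> Bold4D:
    """Per-volume 3D Gaussian smoothing.

    Anisotropic voxels are handled through per-axis sigmas in voxel units;
    the kernel is truncated at 4 sigma with zero-padded borders (plain
    Gaussian behavior).  With ``renormalize_mask``, smoothing is restricted
    to the mask and renormalized by the smoothed mask so border voxels are
    not dimmed.  FWHM below half the smallest voxel edge is treated as the
    identity.
    """
    if fwhm_mm <= 0:
        raise ValueError(f"fwhm_mm must be positive, got {fwhm_mm}")
    vox = bold.grid.voxel_size_mm
    if fwhm_mm < 0.5 * float(vox.min()):
        return bold.with_data(bold.data.copy())
    sigma_vox = fwhm_to_sigma(fwhm_mm) / vox

    def _smooth3(vol: np.ndarray) -> np.ndarray:
        return gaussian_filter(vol, sigma=sigma_vox, mode="constant", cval=0.0, truncate=4.0)

    out = np.empty_like(bold.data)
    if renormalize_mask is None:
        for t in range(bold.n_volumes):
            out[..., t] = _smooth3(bold.data[..., t])
    else:
        bold.grid.require_same(renormalize_mask.grid, "renormalization mask")
        m = renormalize_mask.data.astype(float)
        sm = _smooth3(m)
        inside = renormalize_mask.data
        with np.errstate(invalid="ignore", divide="ignore"):
            for t in range(bold.n_volumes):
                vol = _smooth3(bold.data[..., t] * m)
                vol = np.where(inside, vol / sm, 0.0)
                out[..., t] = vol
    return bold.with_data(out)


def preprocess_bold(
    bold: Bold4D,
    wm: BinaryMask,
    csf: BinaryMask,
    band: tuple[float, float] = (0.01, 0.1),
    fwhm_mm: float | None = 6.0,
    renormalize_mask: BinaryMask | None = None,
) -> tuple[Bold4D, dict]:
    """Run the three stages in the fixed order regress -> bandpass -> smooth.

    ``fwhm_mm=None`` (or 0) skips smoothing.  Returns the processed series
    and a provenance record of the applied stages and parameters.
    """
    provenance: dict = {
        "assumes": "inputs motion-corrected, slice-time corrected, coregistered",
        "order": [],
    }
    out = regress_nuisance(bold, [wm, csf])
    provenance["order"].append({"stage": "regress_nuisance", "regions": ["wm", "csf"]})
    out = bandpass(out, *band)
    provenance["order"].append(
        {"stage": "bandpass", "f_lo_hz": band[0], "f_hi_hz": band[1]}
    )
    if fwhm_mm:
        out = smooth(out, fwhm_mm, renormalize_mask=renormalize_mask)
        provenance["order"].append(
            {
                "stage": "smooth",
                "fwhm_mm": fwhm_mm,
                "renormalized": renormalize_mask is not None,
            }
        )
    return out, provenance
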