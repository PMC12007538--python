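"""Power Doppler preprocessing pipeline.

The stages, in order, are:

1. slice-timing correction (STC): every slice's time series is linearly
   interpolated onto the first motor position's sample grid;
2. voxelwise degree-3 polynomial detrending;
3. calm-period detection on the global signal (GS): the GS baseline is a
   linear regression over the whole scan, and volumes whose rolling GS
   standard deviation stays below 5% of the local baseline for at least
   60 s form calm segments.  Scans with less than 10 min of calm data are
   flagged excluded;
4. per-segment voxelwise standardization followed by a zero-phase
   Butterworth band-pass (0.01-0.1 Hz), then temporal concatenation of the
   filtered segments;
5. global-signal regression (GSR), used for awake resting-state data only.

Stages 3-5 are specific to awake resting-state scans; task-evoked data
from anesthetized animals stop after detrending.
"""

from __future__ import annotations

import numpy as np
from scipy import signal, stats

from .volume import CalmSegments, PDVolume

__all__ = [
    "slice_timing_correct",
    "detrend",
    "detect_calm_periods",
    "design_bandpass",
    "bandpass_filter",
    "bandpass_standardize_concat",
    "global_signal_regress",
    "preprocess_resting",
    "CALM_THRESHOLD_RATIO",
    "CALM_MIN_DURATION_S",
    "CALM_WINDOW_S",
    "MIN_CALM_TOTAL_S",
    "RESTING_BAND_HZ",
]

CALM_THRESHOLD_RATIO = 0.05
CALM_MIN_DURATION_S = 60.0
CALM_WINDOW_S = 24.0
MIN_CALM_TOTAL_S = 600.0
RESTING_BAND_HZ = (0.01, 0.1)


def slice_timing_correct(vol: PDVolume) -> PDVolume:
    """Resample every slice onto the first position's time base.

    Linear interpolation; the reference grid is the earliest slice onset.
    Endpoints beyond a slice's sampled range are edge-held.
    """
    if vol.n_volumes < 2:
        raise ValueError("slice timing correction needs at least two volumes")
    onsets = vol.slice_onsets_s
    ref = float(np.min(onsets))
    out = vol.data.copy()
    n = vol.n_volumes
    for iz in range(vol.data.shape[2]):
        shift = (onsets[iz] - ref) / vol.tr_s
        if shift == 0:
            continue
        # target time v*tr falls at fractional sample index v - shift
        idx = np.clip(np.arange(n) - shift, 0.0, n - 1.0)
        i0 = np.floor(idx).astype(int)
        i1 = np.minimum(i0 + 1, n - 1)
        w = idx - i0
        sl = vol.data[:, :, iz, :]
        out[:, :, iz, :] = sl[..., i0] * (1.0 - w) + sl[..., i1] * w
    return vol.with_data(out, slice_onsets_s=np.full_like(onsets, ref))


def _poly_design(n: int, degree: int) -> np.ndarray:
    t = np.linspace(-1.0, 1.0, n)
    return np.vander(t, degree + 1, increasing=True)


def detrend(vol: PDVolume, degree: int = 3) -> PDVolume:
    """Subtract a voxelwise least-squares polynomial (degree 3 by default)."""
    n = vol.n_volumes
    if n <= degree + 1:
        raise ValueError("not enough time points for the requested degree")
    X = _poly_design(n, degree)
    Y = vol.data.reshape(-1, n).T  # time x voxels
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = (Y - X @ coef).T.reshape(vol.data.shape)
    return vol.with_data(resid)


def rolling_std(x: np.ndarray, window: int) -> np.ndarray:
    """Centred rolling sample standard deviation, window truncated at edges."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        seg = x[lo:hi]
        out[i] = seg.std(ddof=1) if len(seg) > 1 else 0.0
    return out


def detect_calm_periods(
    gs: np.ndarray,
    tr_s: float,
    threshold_ratio: float = CALM_THRESHOLD_RATIO,
    min_duration_s: float = CALM_MIN_DURATION_S,
    window_s: float = CALM_WINDOW_S,
) -> CalmSegments:
    """Find calm resting periods from the global-signal profile.

    The GS baseline is a linear regression over the full scan; a volume is
    calm when the rolling GS standard deviation (centred window,
    ``window_s`` wide) is below ``threshold_ratio`` times the local
    baseline value.  Maximal calm runs of at least ``min_duration_s`` are
    kept.  The result is invariant to affine rescaling of the GS.
    """
    gs = np.asarray(gs, dtype=float)
    n = len(gs)
    if n * tr_s < min_duration_s:
        return CalmSegments([], tr_s)
    t = np.arange(n) * tr_s
    slope, intercept, *_ = stats.linregress(t, gs)
    baseline = intercept + slope * t

    window = max(3, int(round(window_s / tr_s)))
    if window % 2 == 0:
        window += 1
    rstd = rolling_std(gs, window)
    calm = rstd < threshold_ratio * np.abs(baseline)

    min_len = int(np.ceil(min_duration_s / tr_s))
    segments: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if calm[i]:
            j = i
            while j < n and calm[j]:
                j += 1
            if j - i >= min_len:
                segments.append((i, j))
            i = j
        else:
            i += 1
    return CalmSegments(segments, tr_s)


def design_bandpass(band_hz: tuple[float, float], fs_hz: float, order: int = 4) -> np.ndarray:
    """Butterworth band-pass in second-order sections (applied zero-phase)."""
    lo, hi = band_hz
    nyq = fs_hz / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band {band_hz} infeasible at fs={fs_hz}")
    return signal.butter(order, [lo, hi], btype="bandpass", fs=fs_hz, output="sos")


def bandpass_filter(x: np.ndarray, band_hz: tuple[float, float], fs_hz: float, axis: int = -1) -> np.ndarray:
    """Zero-phase (forward-backward) band-pass along ``axis``."""
    sos = design_bandpass(band_hz, fs_hz)
    n = x.shape[axis]
    padlen = min(3 * (2 * sos.shape[0] + 1), n - 1)
    return signal.sosfiltfilt(sos, x, axis=axis, padlen=padlen)


def bandpass_standardize_concat(
    vol: PDVolume,
    segments: CalmSegments,
    band_hz: tuple[float, float] = RESTING_BAND_HZ,
) -> PDVolume:
    """Standardize then band-pass each calm segment; concatenate in time.

    Each voxel is z-scored within the segment before filtering (constant
    voxels map to zero), then band-passed with the zero-phase Butterworth
    design, and segments are joined along the time axis.
    """
    if not segments.segments:
        raise ValueError("no calm segments: scan excluded from resting-state analysis")
    fs = 1.0 / vol.tr_s
    pieces = []
    for start, end in segments.segments:
        seg = vol.data[..., start:end]
        mu = seg.mean(axis=-1, keepdims=True)
        sd = seg.std(axis=-1, keepdims=True)
        z = np.divide(seg - mu, sd, out=np.zeros_like(seg), where=sd > 0)
        pieces.append(bandpass_filter(z, band_hz, fs))
    out = np.concatenate(pieces, axis=-1)
    return PDVolume(out, tr_s=vol.tr_s, slice_onsets_s=np.zeros(vol.data.shape[2]), affine=vol.affine)


def global_signal_regress(vol: PDVolume, mask: np.ndarray | None = None) -> PDVolume:
    """Regress the brain-mean time course (plus intercept) out of every voxel."""
    gs = vol.global_signal(mask)
    n = vol.n_volumes
    X = np.column_stack([np.ones(n), gs])
    Y = vol.data.reshape(-1, n).T
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = (Y - X @ coef).T.reshape(vol.data.shape)
    return vol.with_data(resid)


def preprocess_resting(
    vol: PDVolume,
    band_hz: tuple[float, float] = RESTING_BAND_HZ,
    threshold_ratio: float = CALM_THRESHOLD_RATIO,
    min_duration_s: float = CALM_MIN_DURATION_S,
    window_s: float = CALM_WINDOW_S,
    min_calm_total_s: float = MIN_CALM_TOTAL_S,
    gsr: bool = True,
    detrend_degree: int = 3,
    mask: np.ndarray | None = None,
) -> tuple[PDVolume | None, CalmSegments, bool]:
    """Full awake resting-state pipeline.

    Returns ``(preprocessed volume or None, calm segments, excluded flag)``.
    The volume is None when the calm score falls below
    ``min_calm_total_s`` (scan excluded).
    """
    v = slice_timing_correct(vol)
    # calm detection uses the undetrended GS: its linear-regression baseline
    # is an independent estimate, and the 5% threshold is relative to it
    gs_raw = v.global_signal(mask)
    v = detrend(v, degree=detrend_degree)
    segments = detect_calm_periods(
        gs_raw,
        v.tr_s,
        threshold_ratio=threshold_ratio,
        min_duration_s=min_duration_s,
        window_s=window_s,
    )
    if segments.excluded(min_calm_total_s):
        return None, segments, True
    v = bandpass_standardize_concat(v, segments, band_hz)
    if gsr:
        v = global_signal_regress(v, mask)
    return v, segments, False
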