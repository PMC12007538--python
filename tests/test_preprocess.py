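"""Preprocessing: slice timing, detrending, calm detection, band-pass, GSR."""

import numpy as np
import pytest

from smsfus import PDVolume
from smsfus.preprocess import (
    bandpass_filter,
    bandpass_standardize_concat,
    detect_calm_periods,
    detrend,
    global_signal_regress,
    preprocess_resting,
    rolling_std,
    slice_timing_correct,
)
from smsfus.volume import CalmSegments

TR = 2.4


def volume_from_series(series_by_slice, onsets=None):
    """Build a (1,1,nz,nt) volume from per-slice 1D series."""
    arr = np.stack(series_by_slice)[None, None, :, :]
    return PDVolume(arr, tr_s=TR, slice_onsets_s=onsets)


# --- slice timing correction ------------------------------------------------


def test_stc_zero_offset_slice_unchanged():
    rng = np.random.default_rng(0)
    s0, s1 = rng.normal(size=(2, 50)) + 100
    vol = volume_from_series([s0, s1], onsets=[0.0, 1.2])
    out = slice_timing_correct(vol)
    assert np.array_equal(out.data[0, 0, 0], s0)
    assert not np.array_equal(out.data[0, 0, 1], s1)
    assert np.all(out.slice_onsets_s == 0.0)


def test_stc_exact_on_linear_signals():
    n = 40
    offsets = [0.0, 0.6, 1.2, 1.8]
    slope, intercept = 0.37, 5.0
    series = [intercept + slope * (np.arange(n) * TR + o) for o in offsets]
    out = slice_timing_correct(volume_from_series(series, onsets=offsets))
    target = intercept + slope * np.arange(n) * TR
    for iz in range(4):
        # interior samples are exact; the first sample is edge-held because
        # the reference grid starts before the slice's first acquisition
        assert np.allclose(out.data[0, 0, iz, 1:], target[1:], atol=1e-10)


def test_stc_reduces_phase_error_on_sinusoid():
    n = 200
    offset = 1.2
    t_ref = np.arange(n) * TR
    latent = np.sin(2 * np.pi * 0.05 * t_ref)
    shifted = np.sin(2 * np.pi * 0.05 * (t_ref + offset))
    out = slice_timing_correct(volume_from_series([latent, shifted], onsets=[0.0, offset]))
    err_before = np.abs(shifted - latent).mean()
    err_after = np.abs(out.data[0, 0, 1] - latent).mean()
    assert err_after < 0.2 * err_before


def test_stc_rejects_single_volume():
    vol = PDVolume(np.ones((2, 2, 2, 1)), tr_s=TR)
    with pytest.raises(ValueError):
        slice_timing_correct(vol)


# --- detrending ---------------------------------------------------------------


def test_detrend_annihilates_cubic():
    n = 200
    t = np.linspace(-1, 1, n)
    cubic = 3.0 + 2.0 * t - 1.5 * t**2 + 0.8 * t**3
    vol = volume_from_series([cubic])
    out = detrend(vol, degree=3)
    assert np.abs(out.data).max() / np.abs(cubic).max() < 1e-8


def test_detrend_constant_and_insufficient_samples():
    out = detrend(volume_from_series([np.full(20, 7.0)]), degree=3)
    assert np.allclose(out.data, 0.0, atol=1e-10)
    with pytest.raises(ValueError):
        detrend(volume_from_series([np.ones(4)]), degree=3)


def test_detrend_preserves_slow_sinusoid():
    n = 500  # 1200 s at TR 2.4
    t = np.arange(n) * TR
    sinus = np.sin(2 * np.pi * 0.05 * t)
    drift = 1e-3 * t + 1e-6 * t**2
    out = detrend(volume_from_series([sinus + drift]), degree=3)
    resid = out.data[0, 0, 0]
    amp = (resid * sinus).sum() / (sinus * sinus).sum()  # projection onto the sinusoid
    assert amp > 0.95


# --- calm-period detection ----------------------------------------------------


def oracle_segments(gs, tr, ratio=0.05, min_s=60.0, window_s=24.0):
    """Independent re-derivation: explicit rolling std + run-length scan."""
    n = len(gs)
    t = np.arange(n) * tr
    A = np.vstack([np.ones(n), t]).T
    coef, *_ = np.linalg.lstsq(A, gs, rcond=None)
    base = A @ coef
    w = max(3, int(round(window_s / tr)))
    if w % 2 == 0:
        w += 1
    half = w // 2
    calm = np.zeros(n, dtype=bool)
    for i in range(n):
        seg = gs[max(0, i - half) : min(n, i + half + 1)]
        sd = seg.std(ddof=1) if len(seg) > 1 else 0.0
        calm[i] = sd < ratio * abs(base[i])
    segs, i = [], 0
    min_len = int(np.ceil(min_s / tr))
    while i < n:
        if calm[i]:
            j = i
            while j < n and calm[j]:
                j += 1
            if j - i >= min_len:
                segs.append((i, j))
            i = j
        else:
            i += 1
    return segs


def test_constant_gs_is_one_full_segment():
    n = 300
    segs = detect_calm_periods(np.full(n, 100.0), TR)
    assert segs.segments == [(0, n)]
    assert segs.calm_score_s == pytest.approx(n * TR)


def test_constructed_quiet_noisy_quiet_matches_oracle():
    rng = np.random.default_rng(3)
    n = int(720 / TR)
    gs = 100.0 + rng.normal(0, 1.0, n)
    t = np.arange(n) * TR
    noisy = (t >= 300) & (t < 420)
    gs[noisy] += 10.0 * np.sign(rng.normal(size=noisy.sum()))
    segs = detect_calm_periods(gs, TR)
    assert len(segs.segments) == 2
    assert segs.segments == oracle_segments(gs, TR)
    # the noisy middle is excluded along with window-edge erosion
    assert segs.calm_score_s < 600.0


def test_everywhere_noisy_gs_has_no_calm():
    rng = np.random.default_rng(4)
    gs = 100.0 + rng.normal(0, 20.0, 400)
    segs = detect_calm_periods(gs, TR)
    assert segs.segments == []
    assert segs.calm_score_s == 0.0


def test_calm_detection_scale_invariant():
    rng = np.random.default_rng(5)
    n = 500
    gs = 100.0 + rng.normal(0, 1.0, n)
    gs[100:150] += 15.0 * np.sign(rng.normal(size=50))
    a = detect_calm_periods(gs, TR)
    b = detect_calm_periods(3.7 * gs, TR)
    assert a.segments == b.segments


def test_short_scan_has_no_segments():
    segs = detect_calm_periods(np.full(10, 100.0), TR)
    assert segs.segments == []


def test_rolling_std_matches_numpy_windows():
    rng = np.random.default_rng(6)
    x = rng.normal(size=50)
    out = rolling_std(x, 11)
    for i in (0, 7, 25, 49):
        lo, hi = max(0, i - 5), min(50, i + 6)
        assert out[i] == pytest.approx(x[lo:hi].std(ddof=1))


# --- band-pass / standardize / concatenate ------------------------------------


def test_bandpass_gain_in_band_and_rejection():
    fs = 2.0
    t = np.arange(0, 1200, 1 / fs)
    inband = np.sin(2 * np.pi * 0.05 * t)
    y = bandpass_filter(inband, (0.01, 0.1), fs)
    gain = y[400:-400].std() / inband[400:-400].std()
    assert 0.9 <= gain <= 1.0
    out = np.sin(2 * np.pi * 0.5 * t)
    y5 = bandpass_filter(out, (0.01, 0.1), fs)
    atten_db = 20 * np.log10(out.std() / y5[400:-400].std())
    assert atten_db >= 20.0


def test_bandpass_is_zero_phase():
    fs = 1 / TR
    t = np.arange(0, 2400, TR)
    x = np.sin(2 * np.pi * 0.05 * t)
    y = bandpass_filter(x, (0.01, 0.1), fs)
    lags = np.arange(-5, 6)
    xc = [np.corrcoef(x[20:-20], np.roll(y, k)[20:-20])[0, 1] for k in lags]
    assert lags[int(np.argmax(xc))] == 0


def test_bandpass_concentrates_white_noise_power():
    rng = np.random.default_rng(7)
    n = 500
    vol = PDVolume(rng.normal(100, 5, size=(2, 2, 2, n)), tr_s=TR)
    segs = CalmSegments([(0, n)], TR)
    out = bandpass_standardize_concat(vol, segs)
    x = out.data[0, 0, 0]
    freqs = np.fft.rfftfreq(n, d=TR)
    power = np.abs(np.fft.rfft(x)) ** 2
    inband = (freqs >= 0.01) & (freqs <= 0.1)
    assert power[inband].sum() / power.sum() > 0.9
    assert abs(x.mean()) < 0.05  # near-zero mean (finite DC attenuation)


def test_concat_joins_segments_and_rejects_empty():
    rng = np.random.default_rng(8)
    vol = PDVolume(rng.normal(100, 5, size=(1, 1, 1, 200)), tr_s=TR)
    segs = CalmSegments([(0, 60), (100, 180)], TR)
    out = bandpass_standardize_concat(vol, segs)
    assert out.n_volumes == 60 + 80
    with pytest.raises(ValueError):
        bandpass_standardize_concat(vol, CalmSegments([], TR))


# --- global signal regression --------------------------------------------------


def test_gsr_removes_common_signal_entirely():
    rng = np.random.default_rng(9)
    common = rng.normal(size=100)
    vol = PDVolume(np.tile(common, (2, 2, 2, 1)), tr_s=TR)
    out = global_signal_regress(vol)
    assert np.abs(out.data).max() < 1e-8


def test_gsr_leaves_orthogonal_signal():
    n = 200
    t = np.arange(n)
    gs_like = np.sin(2 * np.pi * t / 50)
    ortho = np.cos(2 * np.pi * t / 50)  # orthogonal over full periods
    data = np.zeros((2, 1, 1, n))
    data[0, 0, 0] = gs_like + ortho
    data[1, 0, 0] = gs_like - ortho
    out = global_signal_regress(PDVolume(data, tr_s=TR))
    assert np.allclose(out.data[0, 0, 0], ortho, atol=1e-8)
    assert np.abs(out.global_signal()).max() < 1e-8


def test_gsr_introduces_negative_correlation():
    """Removing a shared global component drives group correlations negative."""
    rng = np.random.default_rng(10)
    n = 400
    g = rng.normal(size=n)
    a = rng.normal(size=n)
    b = rng.normal(size=n)
    data = np.zeros((2, 1, 1, n))
    data[0, 0, 0] = g + 0.7 * a
    data[1, 0, 0] = g + 0.7 * b
    vol = PDVolume(data, tr_s=TR)
    pre = np.corrcoef(data[0, 0, 0], data[1, 0, 0])[0, 1]
    out = global_signal_regress(vol)
    post = np.corrcoef(out.data[0, 0, 0], out.data[1, 0, 0])[0, 1]
    assert post < pre
    assert post < 0


# --- pipeline wiring -----------------------------------------------------------


def test_preprocess_resting_excludes_motion_heavy_scan(atlas):
    from smsfus import SimulationSpec, simulate_pd_series

    labels, _ = atlas
    episodes = [(60.0 + k * 120.0, 80.0, 1.5) for k in range(9)]
    spec = SimulationSpec(
        labels=labels, n_volumes=480, latent_std_pct=1.0, noise_sigma_pct=0.3,
        motion_episodes=episodes, seed=13,
    )
    vol = simulate_pd_series(spec)
    out, segments, excluded = preprocess_resting(vol)
    assert excluded
    assert out is None
    assert segments.calm_score_s < 600.0


def test_preprocess_resting_keeps_calm_scan(atlas):
    from smsfus import SimulationSpec, simulate_pd_series

    labels, _ = atlas
    spec = SimulationSpec(labels=labels, n_volumes=300, latent_std_pct=1.0, noise_sigma_pct=0.3, seed=14)
    vol = simulate_pd_series(spec)
    out, segments, excluded = preprocess_resting(vol)
    assert not excluded
    assert out is not None
    assert segments.calm_score_s >= 600.0
    # GSR leaves a (numerically) zero global signal
    assert np.abs(out.global_signal()).max() < 1e-6
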