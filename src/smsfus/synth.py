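"""Synthetic data generation for every stage of the pipeline.

Two families of generators are provided, both seed-deterministic:

* IQ phantoms emulating a clutter-filtering scenario: a few high-energy
  low-rank tissue patterns with slow phase modulation, Doppler-shifted
  decorrelating blood scatterers confined to a vessel mask, and circular
  white complex noise.  Point-scatterer channel data for the beamformer
  are generated from the analytic two-way travel-time model.

* 4D Power Doppler series emulating a resting-state or task scan: each
  atlas region follows a latent band-limited (0.01-0.1 Hz) Gaussian
  process drawn from a network covariance, stimulus responses are added as
  HRF-convolved boxcars scaled in % of baseline, and voxels add white
  noise plus a degree-3 polynomial drift.  Motion episodes multiply the
  global level by a noisy excursion factor.  Slices sample the latent
  process at their true within-TR onsets so slice-timing correction is
  testable.  The band-limiting filter is the same Butterworth design used
  by the preprocessing band-pass, so the generative and analysis bands
  match by construction.

Baseline Power Doppler is 100 arbitrary units, making % rCBV directly
readable from the raw signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .activation import HRFModel, build_regressor
from .beamforming import ChannelData, SPEED_OF_SOUND_M_S
from .clutter import IQBlock
from .geometry import ScanSchedule
from .preprocess import bandpass_filter
from .volume import PDVolume

__all__ = [
    "PhantomSpec",
    "SimulationSpec",
    "make_iq_phantom",
    "make_stimulus",
    "make_atlas",
    "simulate_pd_series",
    "point_scatterer_channels",
    "DEFAULT_PAIR_ACRONYMS",
]

BASELINE_PD = 100.0
DEFAULT_PAIR_ACRONYMS = ("SSp-ul", "ACA", "V1", "LGN", "SC", "RS")


@dataclass
class PhantomSpec:
    """Specification of an IQ clutter phantom.

    Amplitudes are arbitrary units; 40 dB tissue/blood separation is
    ``tissue_amplitude / blood_amplitude = 100``.  The Doppler shift of
    blood must stay below the Nyquist rate of the frame stack.
    """

    shape: tuple[int, int] = (48, 48)
    n_frames: int = 200
    frame_rate_hz: float = 500.0
    tissue_amplitude: float = 100.0
    blood_amplitude: float = 1.0
    noise_sigma: float = 0.1
    tissue_rank: int = 3
    tissue_motion_freq_hz: float = 1.0
    blood_doppler_freq_hz: float = 100.0
    blood_decorrelation_s: float = 0.005
    vessel_mask: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.tissue_amplitude, self.blood_amplitude, self.noise_sigma) < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.blood_doppler_freq_hz >= self.frame_rate_hz / 2:
            raise ValueError("blood Doppler frequency must be below Nyquist")
        if not 1 <= self.tissue_rank <= 3:
            raise ValueError("tissue_rank must be 1..3")
        if self.vessel_mask is None:
            nx, nz = self.shape
            m = np.zeros(self.shape, dtype=bool)
            w = max(nz // 6, 1)  # vessel stripe ~1/6 of the field
            m[:, nz // 2 - w // 2 : nz // 2 - w // 2 + w] = True
            self.vessel_mask = m


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float = 4.0) -> np.ndarray:
    """Smooth positive random spatial pattern (unit RMS)."""
    from scipy import ndimage

    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    f = f - f.min() + 0.5
    return f / np.sqrt(np.mean(f**2))


def make_iq_phantom(spec: PhantomSpec) -> IQBlock:
    """Generate a tissue + blood + noise IQ block (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    nx, nz = spec.shape
    nt = spec.n_frames
    t = np.arange(nt) / spec.frame_rate_hz
    data = np.zeros((nx, nz, nt), dtype=complex)

    # tissue: low-rank smooth patterns x slowly phase-modulated time courses
    for r in range(spec.tissue_rank):
        pattern = _smooth_field(rng, spec.shape)
        f = spec.tissue_motion_freq_hz * (r + 1) / spec.tissue_rank
        phase = 0.2 * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        amp = 1.0 + 0.02 * np.sin(2 * np.pi * f * t / 2 + rng.uniform(0, 2 * np.pi))
        tc = amp * np.exp(1j * phase)
        data += (spec.tissue_amplitude / spec.tissue_rank) * pattern[:, :, None] * tc[None, None, :]

    # blood: decorrelating scatterers in the vessel advancing at the Doppler rate
    if spec.blood_amplitude > 0:
        n_ves = int(spec.vessel_mask.sum())
        white = (rng.standard_normal((n_ves, nt)) + 1j * rng.standard_normal((n_ves, nt))) / np.sqrt(2)
        tau = max(spec.blood_decorrelation_s * spec.frame_rate_hz, 1.0)
        k = np.exp(-np.arange(int(4 * tau) + 1) / tau)
        g = np.apply_along_axis(lambda row: np.convolve(row, k)[:nt], 1, white.real) + 1j * np.apply_along_axis(
            lambda row: np.convolve(row, k)[:nt], 1, white.imag
        )
        g /= np.sqrt(np.mean(np.abs(g) ** 2))
        carrier = np.exp(2j * np.pi * spec.blood_doppler_freq_hz * t)
        data[spec.vessel_mask] += spec.blood_amplitude * g * carrier[None, :]

    if spec.noise_sigma > 0:
        data += spec.noise_sigma * (
            rng.standard_normal((nx, nz, nt)) + 1j * rng.standard_normal((nx, nz, nt))
        ) / np.sqrt(2)

    return IQBlock(data, frame_rate_hz=spec.frame_rate_hz)


def make_stimulus(
    baseline_s: float,
    n_stimuli: int,
    on_duration_s: float,
    period_s: float,
    tr_s: float,
) -> np.ndarray:
    """0/1 stimulus timeline at the volume TR.

    The protocol is ``baseline_s`` of rest followed by ``n_stimuli``
    ON blocks of ``on_duration_s`` repeated every ``period_s`` (total
    duration ``baseline_s + n_stimuli * period_s``).  A volume is ON when
    its start time falls inside an ON interval; the number of volumes is
    ``floor(total / tr)``.
    """
    if on_duration_s > period_s:
        raise ValueError("on_duration must not exceed the period")
    total = baseline_s + n_stimuli * period_s
    n_vol = int(np.floor(total / tr_s + 1e-9))
    t = np.arange(n_vol) * tr_s
    stim = np.zeros(n_vol)
    for k in range(n_stimuli):
        onset = baseline_s + k * period_s
        stim[(t >= onset) & (t < onset + on_duration_s)] = 1.0
    return stim


def stimulus_total_duration_s(baseline_s: float, n_stimuli: int, period_s: float) -> float:
    """Total protocol duration in seconds."""
    return baseline_s + n_stimuli * period_s


def make_atlas(
    shape: tuple[int, int, int] = (16, 4, 8),
    pair_acronyms: tuple[str, ...] = DEFAULT_PAIR_ACRONYMS,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Toy bilateral label volume standing in for the Allen segmentation.

    The x axis is split into left/right hemispheres; the (y, z) plane is
    partitioned into one block per region pair, mirrored across the
    midline.  Synthetic stand-in for an atlas segmentation: region ids are
    2i+1 (left) and 2i+2 (right) for pair i.  Returns the integer label
    volume and a region table (id, acronym, hemisphere, mirror_id).
    """
    nx, ny, nz = shape
    n_pairs = len(pair_acronyms)
    labels = np.zeros(shape, dtype=int)
    blocks = np.array_split(np.arange(ny * nz), n_pairs)
    yz = np.arange(ny * nz).reshape(ny, nz)
    half = nx // 2
    rows = []
    for i, acr in enumerate(pair_acronyms):
        in_block = np.isin(yz, blocks[i])
        left_id, right_id = 2 * i + 1, 2 * i + 2
        labels[:half, in_block] = left_id
        labels[half:, in_block] = right_id
        rows.append({"id": left_id, "acronym": f"{acr}_L", "hemisphere": "L", "mirror_id": right_id})
        rows.append({"id": right_id, "acronym": f"{acr}_R", "hemisphere": "R", "mirror_id": left_id})
    return labels, pd.DataFrame(rows)


@dataclass
class SimulationSpec:
    """Specification of a synthetic 4D Power Doppler scan.

    ``network_corr`` is the latent region correlation matrix (symmetric
    PSD); latents are band-limited to ``band_hz`` and scaled to
    ``latent_std_pct`` percent of baseline.  ``response_pct`` plants
    HRF-convolved stimulus responses (in % of baseline) in the listed
    region ids.  ``motion_episodes`` are (onset_s, duration_s, amplitude
    ratio) multiplicative global excursions.
    """

    labels: np.ndarray
    n_volumes: int
    tr_s: float = 2.4
    network_corr: np.ndarray | None = None
    latent_std_pct: float = 2.0
    band_hz: tuple[float, float] = (0.01, 0.1)
    response_pct: dict[int, float] = field(default_factory=dict)
    hrf: HRFModel = field(default_factory=HRFModel)
    drift_amp_pct: float = 1.0
    drift_degree: int = 3
    motion_episodes: list[tuple[float, float, float]] = field(default_factory=list)
    noise_sigma_pct: float = 0.5
    baseline: float = BASELINE_PD
    slice_onsets_s: np.ndarray | None = None
    schedule: ScanSchedule | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D integer volume")
        ids = np.unique(self.labels)
        self.region_ids = ids[ids > 0]
        n_r = len(self.region_ids)
        if self.network_corr is None:
            self.network_corr = np.eye(n_r)
        else:
            self.network_corr = np.asarray(self.network_corr, dtype=float)
            if self.network_corr.shape != (n_r, n_r):
                raise ValueError("network_corr dimension must match the region count")
            if not np.allclose(self.network_corr, self.network_corr.T):
                raise ValueError("network_corr must be symmetric")
            if np.min(np.linalg.eigvalsh(self.network_corr)) < -1e-10:
                raise ValueError("network_corr must be positive semi-definite")
        if any(v < 0 for v in self.response_pct.values()):
            raise ValueError("effect sizes must be >= 0")
        for rid in self.response_pct:
            if rid not in self.region_ids:
                raise ValueError(f"response region {rid} absent from labels")
        if any(amp <= 0 for *_, amp in self.motion_episodes):
            raise ValueError("motion amplitude ratio must be positive")
        if self.schedule is not None and self.slice_onsets_s is None:
            onsets = np.asarray(self.schedule.slice_onset_s)
            nz = self.labels.shape[2]
            if len(onsets) != nz:
                raise ValueError("schedule slice count must match the label grid")
            self.slice_onsets_s = onsets

    def provenance(self) -> dict:
        """JSON-serializable echo of the generating parameters."""
        return {
            "seed": self.seed,
            "n_volumes": self.n_volumes,
            "tr_s": self.tr_s,
            "latent_std_pct": self.latent_std_pct,
            "band_hz": list(self.band_hz),
            "response_pct": {int(k): float(v) for k, v in self.response_pct.items()},
            "drift_amp_pct": self.drift_amp_pct,
            "motion_episodes": [list(e) for e in self.motion_episodes],
            "noise_sigma_pct": self.noise_sigma_pct,
            "baseline": self.baseline,
            "shape": list(self.labels.shape),
        }


def _chol_psd(corr: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(corr)
        return v @ np.diag(np.sqrt(np.clip(w, 0, None)))


def simulate_pd_series(spec: SimulationSpec, stimulus: np.ndarray | None = None) -> PDVolume:
    """Simulate a 4D Power Doppler scan from a simulation specification.

    Latent region signals are white noise band-passed with the analysis
    filter, standardized, mixed with the Cholesky factor of
    ``network_corr`` and scaled to ``latent_std_pct``.  Latents (and the
    stimulus regressor) live on a fine time grid so each slice samples the
    process at its true within-TR onset.  The voxel signal is

        baseline * (1 + (latent + response + drift) / 100) * motion + noise.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.labels.shape
    n_vol = spec.n_volumes
    n_r = len(spec.region_ids)

    onsets = spec.slice_onsets_s
    if onsets is None:
        onsets = np.zeros(nz)
    distinct = np.unique(np.round(onsets / spec.tr_s, 9))
    os_factor = max(len(distinct), 1)
    fs_fine = os_factor / spec.tr_s
    n_fine = n_vol * os_factor + os_factor

    # latent band-limited network processes (% of baseline); the filtered
    # noise is empirically whitened before mixing so the realized latent
    # correlation matrix equals network_corr exactly at any scan length
    latents = np.zeros((n_r, n_fine))
    if spec.latent_std_pct > 0 and n_r > 0:
        white = rng.standard_normal((n_r, n_fine))
        filt = bandpass_filter(white, spec.band_hz, fs_fine)
        filt -= filt.mean(axis=1, keepdims=True)
        cov = filt @ filt.T / n_fine
        w, v = np.linalg.eigh(cov)
        whitened = (v @ np.diag(1.0 / np.sqrt(np.clip(w, 1e-30, None))) @ v.T) @ filt
        latents = spec.latent_std_pct * (_chol_psd(spec.network_corr) @ whitened)

    # stimulus response on the fine grid (% of baseline, plateau = effect size)
    resp_fine = None
    if stimulus is not None and spec.response_pct:
        stim_fine = np.repeat(np.asarray(stimulus, dtype=float), os_factor)
        stim_fine = np.pad(stim_fine, (0, max(0, n_fine - len(stim_fine))))[:n_fine]
        resp_fine = build_regressor(stim_fine, spec.hrf, spec.tr_s / os_factor)

    # per-voxel degree-3 drift (raw units), zero-mean basis over the scan
    tnorm = np.linspace(-1.0, 1.0, n_vol)
    drift_basis = np.vstack([tnorm**d for d in range(1, spec.drift_degree + 1)])
    n_vox = nx * ny * nz
    drift_coef = rng.uniform(-1.0, 1.0, size=(n_vox, spec.drift_degree))
    drift = (spec.drift_amp_pct / 100.0 * spec.baseline) * (drift_coef @ drift_basis)

    # multiplicative motion excursions on the global level
    motion = np.ones(n_vol)
    tv = np.arange(n_vol) * spec.tr_s
    for onset_s, dur_s, amp in spec.motion_episodes:
        m = (tv >= onset_s) & (tv < onset_s + dur_s)
        motion[m] = 1.0 + (amp - 1.0) * np.abs(rng.standard_normal(int(m.sum())))

    fine_offset = np.round(onsets / spec.tr_s * os_factor).astype(int)
    base_idx = np.arange(n_vol) * os_factor

    # percent signal per region (row 0 = background) on the fine grid
    pct_arr = np.zeros((n_r + 1, n_fine))
    for i, rid in enumerate(spec.region_ids):
        pct_arr[i + 1] = latents[i]
        if resp_fine is not None and int(rid) in spec.response_pct:
            pct_arr[i + 1] += spec.response_pct[int(rid)] * resp_fine
    region_index = np.zeros_like(spec.labels)
    for i, rid in enumerate(spec.region_ids):
        region_index[spec.labels == rid] = i + 1

    data = np.empty((nx, ny, nz, n_vol))
    for iz in range(nz):
        idx = np.clip(base_idx + fine_offset[iz], 0, n_fine - 1)
        pct_v = pct_arr[region_index[:, :, iz]][..., idx]
        data[:, :, iz, :] = spec.baseline * (1.0 + pct_v / 100.0)
    data = data.reshape(n_vox, n_vol)
    data += drift
    data *= motion[None, :]
    if spec.noise_sigma_pct > 0:
        data += (spec.noise_sigma_pct / 100.0 * spec.baseline) * rng.standard_normal((n_vox, n_vol))

    affine = np.diag([0.1, 0.1, 0.525, 1.0])
    vol = PDVolume(
        data.reshape(nx, ny, nz, n_vol),
        tr_s=spec.tr_s,
        slice_onsets_s=onsets,
        affine=affine,
    )
    vol.provenance = spec.provenance()  # type: ignore[attr-defined]
    return vol


def point_scatterer_channels(
    element_x_mm: np.ndarray,
    angle_deg: float,
    scatterers: list[tuple[float, float, float]],
    sample_rate_hz: float,
    n_samples: int,
    carrier_hz: float = 15e6,
    pulse_sigma_s: float | None = None,
    c_m_s: float = SPEED_OF_SOUND_M_S,
) -> ChannelData:
    """Analytic echo model for point scatterers (the beamforming oracle input).

    Each scatterer (x_mm, z_mm, amplitude) produces, on every element, a
    Gaussian-enveloped complex pulse centred at the two-way travel time of
    the tilted plane wave.  Emitted directly as complex baseband-style
    analytic samples.
    """
    from .beamforming import travel_time_s

    element_x_mm = np.asarray(element_x_mm, dtype=float)
    if pulse_sigma_s is None:
        pulse_sigma_s = 2.0 / carrier_hz
    t = np.arange(n_samples) / sample_rate_hz
    samples = np.zeros((len(element_x_mm), n_samples), dtype=complex)
    for x0, z0, amp in scatterers:
        tau = travel_time_s(np.array([x0]), np.array([z0]), element_x_mm, angle_deg, c_m_s)[0]
        dtau = t[None, :] - tau[:, None]
        samples += amp * np.exp(-(dtau**2) / (2 * pulse_sigma_s**2)) * np.exp(2j * np.pi * carrier_hz * dtau)
    return ChannelData(samples=samples, element_x_mm=element_x_mm, sample_rate_hz=sample_rate_hz)
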