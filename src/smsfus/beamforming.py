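"""Plane-wave delay-and-sum beamforming on a trapezoidal grid.

Each linear array transmits tilted plane waves (eight angles evenly spaced
between +-12 degrees by default) and the backscattered echoes are
beamformed by delay-and-sum onto a grid whose lateral extent widens with
depth at the maximum steering angle.  This trapezoidal grid recovers
lateral regions beyond the physical aperture, compensating the limited
64-element width of each compact array.  Images from the different angles
are averaged coherently (compounding).

Channel data are complex baseband samples; the travel time from a plane
wave tilted by ``theta`` to a voxel (x, z) and back to element ``x_e`` is

    tau = (z cos(theta) + x sin(theta)) / c + sqrt(z^2 + (x - x_e)^2) / c.

Samples are linearly interpolated at ``tau``; delays beyond the recorded
window contribute zero.  Receive apodization is rectangular over elements
within a configurable f-number acceptance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PlaneWaveSet",
    "TrapezoidalGrid",
    "ChannelData",
    "default_angles",
    "das_beamform",
    "compound",
]

SPEED_OF_SOUND_M_S = 1540.0


def default_angles(n_angles: int = 8, theta_max_deg: float = 12.0) -> np.ndarray:
    """Evenly spaced steering angles, symmetric about zero (degrees)."""
    return np.linspace(-theta_max_deg, theta_max_deg, n_angles)


@dataclass(frozen=True)
class PlaneWaveSet:
    """Tilted plane-wave transmission set."""

    angles_deg: tuple[float, ...] = tuple(default_angles())
    prf_hz: float = 4000.0
    speed_of_sound_m_s: float = SPEED_OF_SOUND_M_S

    def __post_init__(self) -> None:
        if self.prf_hz <= 0:
            raise ValueError("prf must be positive")
        if len(self.angles_deg) < 1:
            raise ValueError("need at least one angle")

    @property
    def theta_max_deg(self) -> float:
        return float(np.max(np.abs(self.angles_deg)))

    @property
    def compound_rate_hz(self) -> float:
        return self.prf_hz / len(self.angles_deg)


@dataclass(frozen=True)
class TrapezoidalGrid:
    """Beamforming grid widening linearly with depth at tan(theta_max).

    ``x_mm``/``z_mm`` are voxel-centre coordinates of the enclosing
    rectangle; voxels outside the trapezoid (mask False) are not computed.
    ``aperture_mm`` is the (min, max) lateral extent of the element centres.
    """

    x_mm: np.ndarray
    z_mm: np.ndarray
    aperture_mm: tuple[float, float]
    theta_max_deg: float = 12.0

    @classmethod
    def from_aperture(
        cls,
        element_x_mm: np.ndarray,
        z_min_mm: float,
        z_max_mm: float,
        dx_mm: float = 0.1,
        dz_mm: float = 0.1,
        theta_max_deg: float = 12.0,
    ) -> "TrapezoidalGrid":
        element_x_mm = np.asarray(element_x_mm, dtype=float)
        ap = (float(element_x_mm.min()), float(element_x_mm.max()))
        halfwidth = z_max_mm * np.tan(np.deg2rad(theta_max_deg))
        x0, x1 = ap[0] - halfwidth, ap[1] + halfwidth
        nx = int(np.floor((x1 - x0) / dx_mm + 1e-9)) + 1
        nz = int(np.floor((z_max_mm - z_min_mm) / dz_mm + 1e-9)) + 1
        return cls(
            x_mm=x0 + np.arange(nx) * dx_mm,
            z_mm=z_min_mm + np.arange(nz) * dz_mm,
            aperture_mm=ap,
            theta_max_deg=theta_max_deg,
        )

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.x_mm), len(self.z_mm))

    def mask(self) -> np.ndarray:
        """Boolean (nx, nz) mask of voxels inside the trapezoid."""
        slope = np.tan(np.deg2rad(self.theta_max_deg))
        x = self.x_mm[:, None]
        z = self.z_mm[None, :]
        lo = self.aperture_mm[0] - z * slope
        hi = self.aperture_mm[1] + z * slope
        return (x >= lo - 1e-9) & (x <= hi + 1e-9)

    def width_mm(self, z: float) -> float:
        """Lateral trapezoid width at depth z."""
        slope = np.tan(np.deg2rad(self.theta_max_deg))
        return (self.aperture_mm[1] - self.aperture_mm[0]) + 2.0 * z * slope


@dataclass(frozen=True)
class ChannelData:
    """Complex baseband channel samples for one transmit event.

    ``samples`` is (n_elements, n_samples); ``element_x_mm`` gives lateral
    element-centre positions; ``t0_s`` the time of the first sample.
    """

    samples: np.ndarray
    element_x_mm: np.ndarray
    sample_rate_hz: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        if self.samples.ndim != 2:
            raise ValueError("samples must be (n_elements, n_samples)")
        if len(self.element_x_mm) != self.samples.shape[0]:
            raise ValueError("element count mismatch")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("channel samples must be finite")


def travel_time_s(
    x_mm: np.ndarray,
    z_mm: np.ndarray,
    element_x_mm: np.ndarray,
    angle_deg: float,
    c_m_s: float = SPEED_OF_SOUND_M_S,
) -> np.ndarray:
    """Two-way plane-wave travel time, broadcast over voxels x elements.

    Returns an array of shape ``broadcast(x, z) x n_elements`` in seconds.
    """
    th = np.deg2rad(angle_deg)
    x = np.asarray(x_mm, dtype=float) * 1e-3
    z = np.asarray(z_mm, dtype=float) * 1e-3
    xe = np.asarray(element_x_mm, dtype=float) * 1e-3
    tx = z * np.cos(th) + x * np.sin(th)
    rx = np.sqrt(z[..., None] ** 2 + (x[..., None] - xe) ** 2)
    return (tx[..., None] + rx) / c_m_s


def das_beamform(
    channels: ChannelData,
    angle_deg: float,
    grid: TrapezoidalGrid,
    f_number: float = 1.0,
    c_m_s: float = SPEED_OF_SOUND_M_S,
) -> np.ndarray:
    """Delay-and-sum one plane-wave transmit onto the trapezoidal grid.

    Returns a complex (nx, nz) image; voxels outside the trapezoid are zero.
    Elements contribute only if within the f-number acceptance cone
    (|x - x_e| <= z / (2 f#)); ``f_number <= 0`` accepts every element.
    Delays falling outside the recorded samples contribute zero.
    """
    if abs(angle_deg) > grid.theta_max_deg + 1e-9:
        raise ValueError("steering angle exceeds grid theta_max")
    nx, nz = grid.shape
    mask = grid.mask()
    xv, zv = np.meshgrid(grid.x_mm, grid.z_mm, indexing="ij")
    xf = xv[mask]
    zf = zv[mask]

    tau = travel_time_s(xf, zf, channels.element_x_mm, angle_deg, c_m_s)
    idx = (tau - channels.t0_s) * channels.sample_rate_hz
    n_samp = channels.samples.shape[1]

    i0 = np.floor(idx).astype(int)
    frac = idx - i0
    valid = (i0 >= 0) & (i0 < n_samp - 1)
    if f_number > 0:
        accept = np.abs(xf[:, None] - channels.element_x_mm[None, :]) <= (
            zf[:, None] / (2.0 * f_number) + 1e-12
        )
        valid &= accept
    i0c = np.clip(i0, 0, n_samp - 2)

    elem_idx = np.broadcast_to(np.arange(len(channels.element_x_mm)), i0c.shape)
    s0 = channels.samples[elem_idx, i0c]
    s1 = channels.samples[elem_idx, i0c + 1]
    contrib = np.where(valid, s0 * (1.0 - frac) + s1 * frac, 0.0)

    image = np.zeros((nx, nz), dtype=complex)
    image[mask] = contrib.sum(axis=1)
    return image


def compound(images: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Coherent mean of per-angle complex images (identical grids required)."""
    images = [np.asarray(im) for im in images]
    if not images:
        raise ValueError("no images to compound")
    shape = images[0].shape
    if any(im.shape != shape for im in images):
        raise ValueError("images must share the same grid")
    return np.mean(np.stack(images, axis=0), axis=0)
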