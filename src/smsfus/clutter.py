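"""SVD clutter filtering of IQ blocks and Power Doppler image formation.

An integration block of beamformed complex frames (200 frames at 500 Hz by
default, i.e. 0.4 s) is reshaped to a Casorati matrix (space x time) and
decomposed by SVD,

    Mc = U S V*.

The first ``n_cut`` spatiotemporal modes carry the high-energy, spatially
coherent tissue echoes; the blood signal is the remainder,

    S_blood = sum_{i > n_cut} U_i lambda_i V_i*.

For motion-free (anesthetized) data a fixed ``n_cut = 60`` is used; for
awake data with episodic motion the cut is set adaptively per block from a
cumulative energy threshold on the singular spectrum.  The Power Doppler
image is the per-voxel temporal mean of |filtered signal|^2, proportional
to cerebral blood volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IQBlock",
    "SVDDecomposition",
    "FIXED_NCUT_ANESTHETIZED",
    "casorati",
    "uncasorati",
    "svd_decompose",
    "svd_filter",
    "adaptive_ncut",
    "power_doppler",
]

# fixed tissue-mode cut for motion-free acquisitions
FIXED_NCUT_ANESTHETIZED = 60


@dataclass
class IQBlock:
    """Complex frame stack (x, z, t) for one slice over one integration window."""

    data: np.ndarray
    frame_rate_hz: float = 500.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("IQBlock data must be (x, z, t)")
        if self.data.shape[-1] < 2:
            raise ValueError("need at least two frames")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("IQ data must be finite")

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz


@dataclass
class SVDDecomposition:
    """Economy SVD of a Casorati matrix: spatial modes, singular values, temporal modes."""

    u: np.ndarray  # (n_vox, k) spatial singular vectors
    s: np.ndarray  # (k,) non-increasing singular values
    vh: np.ndarray  # (k, n_t) conjugate-transposed temporal vectors

    @property
    def energies(self) -> np.ndarray:
        """Per-mode energy lambda_i^2."""
        return self.s**2


def casorati(block: IQBlock) -> np.ndarray:
    """Reshape an (x, z, t) block to a (space x time) Casorati matrix.

    Raster convention: voxel (ix, iz) maps to row ``ix * Nz + iz``
    (row-major over the spatial axes).
    """
    nx, nz, nt = block.data.shape
    return block.data.reshape(nx * nz, nt)


def uncasorati(mat: np.ndarray, shape: tuple[int, int], frame_rate_hz: float = 500.0) -> IQBlock:
    """Inverse of :func:`casorati` for a known (nx, nz) spatial shape."""
    nx, nz = shape
    return IQBlock(mat.reshape(nx, nz, -1), frame_rate_hz=frame_rate_hz)


def svd_decompose(block: IQBlock) -> SVDDecomposition:
    """Economy SVD of the block's Casorati matrix (raw, no mean removal)."""
    u, s, vh = np.linalg.svd(casorati(block), full_matrices=False)
    return SVDDecomposition(u=u, s=s, vh=vh)


def svd_filter(block: IQBlock, n_cut: int) -> IQBlock:
    """Remove the first ``n_cut`` spatiotemporal (tissue) modes.

    ``n_cut = 0`` returns the input unchanged up to numerical round-off;
    ``n_cut >= n_frames`` is an error (nothing would remain).
    """
    nt = block.n_frames
    if not 0 <= n_cut < nt:
        raise ValueError(f"n_cut must satisfy 0 <= n_cut < n_frames ({nt})")
    if n_cut == 0:
        return IQBlock(block.data.copy(), frame_rate_hz=block.frame_rate_hz)
    dec = svd_decompose(block)
    blood = dec.u[:, n_cut:] @ (dec.s[n_cut:, None] * dec.vh[n_cut:])
    return uncasorati(blood, block.data.shape[:2], block.frame_rate_hz)


def adaptive_ncut(decomp: SVDDecomposition, energy_fraction: float = 0.95) -> int:
    """Smallest n with cumulative mode energy >= ``energy_fraction`` of total.

    Energy is lambda^2 (not amplitude).  At least one mode is always
    removed for any positive fraction.
    """
    if not 0.0 < energy_fraction < 1.0:
        raise ValueError("energy_fraction must lie in (0, 1)")
    e = decomp.energies
    cum = np.cumsum(e) / e.sum()
    return int(np.searchsorted(cum, energy_fraction - 1e-12) + 1)


def power_doppler(block: IQBlock) -> np.ndarray:
    """Power Doppler image: per-voxel temporal mean of |signal|^2."""
    return np.mean(np.abs(block.data) ** 2, axis=-1)
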