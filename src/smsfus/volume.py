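"""4D Power Doppler volume container, the common currency of the pipeline.

Axis convention: ``data[x, y, z, t]`` with x lateral, y dorsoventral
(depth), z anteroposterior (one entry per coronal slice), t volumes.  The
affine maps voxel indices to Bregma-relative millimetres.  ``slice_onsets_s``
records each slice's acquisition onset within the TR, as produced by the
motorized scan schedule, and drives slice-timing correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["PDVolume", "CalmSegments"]


@dataclass
class PDVolume:
    """4D Power Doppler series (x, y, z, t) with timing metadata."""

    data: np.ndarray
    tr_s: float
    slice_onsets_s: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("PDVolume data must be 4D (x, y, z, t)")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.slice_onsets_s is None:
            self.slice_onsets_s = np.zeros(self.data.shape[2])
        else:
            self.slice_onsets_s = np.asarray(self.slice_onsets_s, dtype=float)
        if len(self.slice_onsets_s) != self.data.shape[2]:
            raise ValueError("need one slice onset per z slice")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def times_s(self) -> np.ndarray:
        """Nominal volume start times."""
        return np.arange(self.n_volumes) * self.tr_s

    def global_signal(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Brain-mean time course (over ``mask`` voxels if given)."""
        if mask is None:
            return self.data.reshape(-1, self.n_volumes).mean(axis=0)
        return self.data[mask].mean(axis=0)

    def with_data(self, data: np.ndarray, slice_onsets_s: np.ndarray | None = None) -> "PDVolume":
        out = replace(self, data=np.asarray(data, dtype=float))
        if slice_onsets_s is not None:
            out.slice_onsets_s = np.asarray(slice_onsets_s, dtype=float)
        return out


@dataclass
class CalmSegments:
    """Motion-free ("calm") intervals of a scan, as half-open volume indices."""

    segments: list[tuple[int, int]]
    tr_s: float

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.segments:
            if end <= start:
                raise ValueError("segments must be non-empty half-open intervals")
            if start <= prev_end:
                raise ValueError("segments must be disjoint and ordered")
            prev_end = end - 1

    @property
    def calm_score_s(self) -> float:
        """Total useful (calm) duration in seconds."""
        return sum(end - start for start, end in self.segments) * self.tr_s

    @property
    def n_volumes(self) -> int:
        return sum(end - start for start, end in self.segments)

    def excluded(self, min_total_s: float = 600.0) -> bool:
        """True when the scan has too little calm data for resting-state use."""
        return self.calm_score_s < min_total_s
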