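"""Multi-array probe geometry and motorized scan scheduling.

The probe is a row of compact linear arrays (four by default, 64 elements
each at 110 um pitch) whose acoustic lenses focus each array onto a thin
coronal slice.  Translating the probe through ``n_positions`` motor
positions, with a step of ``inter_array_mm / n_positions``, tiles the
elevation (anteroposterior) axis with ``n_arrays * n_positions`` contiguous
slices.  One full volume takes

    TR = n_positions * (T_integration + T_translation)

seconds, e.g. 4 * (0.4 + 0.2) = 2.4 s for the default whole-brain sequence.
Positions are visited in an interleaved order (1-3-4-2 for four positions)
so that no single motor move, including the wrap-around back to the first
position, exceeds two steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProbeGeometry",
    "ScanSchedule",
    "repetition_time",
    "interleaved_order",
    "build_schedule",
    "max_cyclic_displacement",
    "compound_frame_rate",
]


@dataclass(frozen=True)
class ProbeGeometry:
    """Geometry of the multi-array probe.

    Lengths are millimetres; ``center_frequency_mhz`` is informational (the
    emission frequency sets the in-plane resolution, not the schedule).
    """

    n_arrays: int = 4
    elements_per_array: int = 64
    pitch_mm: float = 0.110
    inter_array_mm: float = 2.1
    elevation_fwhm_mm: float = 0.5
    center_frequency_mhz: float = 15.0

    def __post_init__(self) -> None:
        if self.n_arrays < 1:
            raise ValueError("n_arrays must be >= 1")
        if self.elements_per_array < 1:
            raise ValueError("elements_per_array must be >= 1")
        if self.inter_array_mm <= 0:
            raise ValueError("inter_array_mm must be positive")
        if self.pitch_mm <= 0:
            raise ValueError("pitch_mm must be positive")

    @property
    def n_channels(self) -> int:
        """Total addressable element count (n_arrays x elements_per_array)."""
        return self.n_arrays * self.elements_per_array

    @property
    def aperture_mm(self) -> float:
        """Lateral extent of one array's element centres."""
        return (self.elements_per_array - 1) * self.pitch_mm

    def element_positions_mm(self) -> np.ndarray:
        """Lateral element-centre positions of one array, centred on zero."""
        n = self.elements_per_array
        return (np.arange(n) - (n - 1) / 2.0) * self.pitch_mm


def repetition_time(n_positions: int, t_integration: float, t_translation: float) -> float:
    """Volume repetition time: ``n_positions * (t_integration + t_translation)``.

    All arguments must be positive; times are seconds.
    """
    if n_positions <= 0:
        raise ValueError("n_positions must be positive")
    if t_integration <= 0 or t_translation <= 0:
        raise ValueError("t_integration and t_translation must be positive")
    return n_positions * (t_integration + t_translation)


def interleaved_order(n_positions: int) -> tuple[int, ...]:
    """Interleaved position visiting order limiting motor moves to two steps.

    Odd-numbered positions are visited in ascending order, then even-numbered
    positions in descending order.  For four positions this yields 1-3-4-2;
    for any ``n >= 2`` every consecutive move, including the cyclic wrap from
    the last position back to the first, is at most two steps.
    """
    if n_positions < 1:
        raise ValueError("n_positions must be >= 1")
    odds = list(range(1, n_positions + 1, 2))
    evens = list(range(2, n_positions + 1, 2))[::-1]
    return tuple(odds + evens)


@dataclass(frozen=True)
class ScanSchedule:
    """Timed, interleaved motor schedule producing contiguous slices.

    ``slice_*`` tuples are indexed by slice number, slice 0 being the most
    anterior; elevations are Bregma-relative millimetres (anterior positive).
    ``slice_onset_s`` is the acquisition onset of each slice within one TR.
    """

    n_positions: int
    step_mm: float
    order: tuple[int, ...]
    t_integration_s: float
    t_translation_s: float
    slice_elevations_mm: tuple[float, ...]
    slice_onset_s: tuple[float, ...]
    slice_position: tuple[int, ...] = field(repr=False, default=())
    slice_array: tuple[int, ...] = field(repr=False, default=())

    def __post_init__(self) -> None:
        if len(self.order) != self.n_positions:
            raise ValueError("order must be a permutation of 1..n_positions")
        if sorted(self.order) != list(range(1, self.n_positions + 1)):
            raise ValueError("order must be a permutation of 1..n_positions")
        tr = self.tr_s
        if any(t < 0 or t >= tr for t in self.slice_onset_s):
            raise ValueError("slice onset times must lie in [0, TR)")

    @property
    def tr_s(self) -> float:
        return repetition_time(self.n_positions, self.t_integration_s, self.t_translation_s)

    @property
    def n_slices(self) -> int:
        return len(self.slice_elevations_mm)

    def to_frame(self) -> pd.DataFrame:
        """Schedule as a table (slice_index, elevation_mm, position, array, onset_s)."""
        return pd.DataFrame(
            {
                "slice_index": np.arange(self.n_slices),
                "elevation_mm": self.slice_elevations_mm,
                "position": self.slice_position,
                "array": self.slice_array,
                "onset_s": self.slice_onset_s,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_schedule(
    geometry: ProbeGeometry,
    n_positions: int,
    t_integration: float = 0.4,
    t_translation: float = 0.2,
    start_elevation_mm: float = 3.0,
) -> ScanSchedule:
    """Build the interleaved scan schedule for a probe geometry.

    The motor step is ``inter_array_mm / n_positions`` so that the
    ``n_arrays * n_positions`` slices tile the elevation axis without gaps.
    Slice elevations run from ``start_elevation_mm`` (slice 0, most anterior)
    downward in uniform steps; slice onset within the TR is the rank of its
    motor position in the visiting order times (T_integration + T_translation).
    """
    if n_positions < 1:
        raise ValueError("n_positions must be >= 1")
    step = geometry.inter_array_mm / n_positions
    order = interleaved_order(n_positions)
    rank = {pos: i for i, pos in enumerate(order)}
    dwell = t_integration + t_translation

    elevations: list[float] = []
    onsets: list[float] = []
    positions: list[int] = []
    arrays: list[int] = []
    for a in range(geometry.n_arrays):
        for p in range(1, n_positions + 1):
            k = a * n_positions + (p - 1)
            elevations.append(start_elevation_mm - k * step)
            onsets.append(rank[p] * dwell)
            positions.append(p)
            arrays.append(a)

    return ScanSchedule(
        n_positions=n_positions,
        step_mm=step,
        order=order,
        t_integration_s=t_integration,
        t_translation_s=t_translation,
        slice_elevations_mm=tuple(elevations),
        slice_onset_s=tuple(onsets),
        slice_position=tuple(positions),
        slice_array=tuple(arrays),
    )


def max_cyclic_displacement(schedule: ScanSchedule) -> float:
    """Largest motor move (mm) over the cyclic visiting order.

    Includes the wrap-around move from the last visited position back to the
    first (the move made before each new volume starts).
    """
    order = schedule.order
    if len(order) < 2:
        return 0.0
    arr = np.asarray(order)
    diffs = np.abs(np.diff(np.concatenate([arr, arr[:1]])))
    return float(diffs.max()) * schedule.step_mm


def compound_frame_rate(prf: float, n_angles: int) -> float:
    """Compounded frame rate: pulse repetition frequency / number of angles."""
    if prf <= 0:
        raise ValueError("prf must be positive")
    if n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    return prf / n_angles
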