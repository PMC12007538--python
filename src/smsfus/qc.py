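"""Quality-control metrics: CNR, matching score, calm score reporting."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

__all__ = ["QCReport", "cnr", "matching_score", "intensity_profile"]


@dataclass
class QCReport:
    """Per-session quality metrics with a parameter echo for provenance."""

    cnr_db: float | None = None
    matching_score: float | None = None
    calm_score_s: float | None = None
    excluded: bool = False
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.matching_score is not None and not -1.0 <= self.matching_score <= 1.0:
            raise ValueError("matching_score must lie in [-1, 1]")
        if self.calm_score_s is not None and self.calm_score_s < 0:
            raise ValueError("calm_score_s must be >= 0")

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


def cnr(image: np.ndarray, vessel_roi: np.ndarray, background_roi: np.ndarray) -> float:
    """Contrast-to-noise ratio between a vessel ROI and a background ROI.

    ``20 * log10(|mean(vessel) - mean(background)| / std(background))`` in
    dB.  ROIs are boolean masks and must be non-empty and disjoint; zero
    contrast returns ``-inf``.
    """
    vessel_roi = np.asarray(vessel_roi, dtype=bool)
    background_roi = np.asarray(background_roi, dtype=bool)
    if not vessel_roi.any() or not background_roi.any():
        raise ValueError("ROIs must be non-empty")
    if (vessel_roi & background_roi).any():
        raise ValueError("ROIs must be disjoint")
    bg = image[background_roi]
    sd = bg.std()
    if sd == 0:
        raise ValueError("background ROI has zero variance")
    contrast = abs(float(image[vessel_roi].mean()) - float(bg.mean()))
    if contrast == 0:
        return float("-inf")
    return 20.0 * np.log10(contrast / sd)


def matching_score(scan: np.ndarray, template: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Pearson correlation between a registered scan and the template.

    Computed over in-brain voxels when ``mask`` is given; grids must match.
    """
    scan = np.asarray(scan, dtype=float)
    template = np.asarray(template, dtype=float)
    if scan.shape != template.shape:
        raise ValueError("scan and template must share the same grid")
    if mask is not None:
        scan = scan[mask]
        template = template[mask]
    return float(np.corrcoef(scan.ravel(), template.ravel())[0, 1])


def intensity_profile(image: np.ndarray, start: tuple[float, float], end: tuple[float, float], n: int = 100) -> np.ndarray:
    """Image intensity sampled along a voxel line (linear interpolation)."""
    coords = np.stack([np.linspace(s, e, n) for s, e in zip(start, end)])
    return ndimage.map_coordinates(np.asarray(image, dtype=float), coords, order=1)
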