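"""Resting-state functional connectivity analysis.

Region time series are the voxel-mean preprocessed Power Doppler signals
within an atlas label volume.  Seed-based maps reuse the voxelwise GLM
with the seed region's mean time course as the regressor.  The FC matrix
is the pairwise Pearson correlation between region series; group matrices
are Fisher-z transformed, averaged across subjects and transformed back.
Significance of the average coefficients is assessed with a one-sample
t-test on the Fisher-z values, Benjamini-Hochberg FDR corrected over the
unique (upper-triangle) entries.  A specificity quality-control metric
contrasts the homotopic somatosensory correlation (specific) with the
somatosensory-to-cingulate correlation (unspecific).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .activation import GLMResult, StatMap, glm_fit
from .volume import PDVolume

__all__ = [
    "RegionTimeSeries",
    "FCMatrix",
    "extract_regions",
    "seed_map",
    "fc_matrix",
    "fisher_z",
    "group_average_fc",
    "fc_significance",
    "fc_specificity",
]


@dataclass
class RegionTimeSeries:
    """Region x time matrix with an aligned region table.

    ``table`` carries at least columns (id, acronym); optional columns
    hemisphere and mirror_id support homotopic analyses.  Regions absent
    from the label volume are dropped (flagged in ``missing_ids``), never
    zero-filled.
    """

    data: np.ndarray  # (n_regions, n_t)
    table: pd.DataFrame
    missing_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.table):
            raise ValueError("region table must align with the series rows")

    def series(self, acronym: str) -> np.ndarray:
        sel = self.table.index[self.table["acronym"] == acronym]
        if len(sel) == 0:
            raise KeyError(f"region {acronym!r} not present")
        return self.data[sel[0]]


def extract_regions(vol: PDVolume, labels: np.ndarray, table: pd.DataFrame | None = None) -> RegionTimeSeries:
    """Voxel-mean time course per labelled region.

    ``labels`` must share the volume's spatial grid; label 0 is background.
    Regions listed in ``table`` but empty in the label volume are dropped
    and reported in ``missing_ids``.
    """
    labels = np.asarray(labels)
    if labels.shape != vol.data.shape[:3]:
        raise ValueError("label volume grid does not match the data")
    present = np.unique(labels)
    present = present[present > 0]
    if table is None:
        table = pd.DataFrame({"id": present, "acronym": [f"R{int(r)}" for r in present]})
    wanted = table["id"].to_numpy()
    missing = tuple(int(i) for i in wanted if i not in present)
    keep = [i for i in wanted if i in present]
    data = np.stack([vol.data[labels == rid].mean(axis=0) for rid in keep])
    tbl = table[table["id"].isin(keep)].reset_index(drop=True)
    return RegionTimeSeries(data=data, table=tbl, missing_ids=missing)


def seed_map(vol: PDVolume, seed_series: np.ndarray) -> GLMResult:
    """Voxelwise GLM with the seed mean time course as regressor."""
    seed_series = np.asarray(seed_series, dtype=float)
    if np.allclose(seed_series, seed_series[0]):
        raise ValueError("seed series is constant")
    n = vol.n_volumes
    X = np.column_stack([np.ones(n), seed_series])
    Y = vol.data.reshape(-1, n).T
    return glm_fit(Y, X)


@dataclass
class FCMatrix:
    """Symmetric Pearson correlation matrix with optional inference fields."""

    r: np.ndarray
    region_ids: np.ndarray
    valid: np.ndarray | None = None  # False where a series was constant
    t: np.ndarray | None = None
    sig: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.r.shape[0] != self.r.shape[1]:
            raise ValueError("FC matrix must be square")
        if self.valid is None:
            self.valid = np.ones_like(self.r, dtype=bool)


def fc_matrix(ts: RegionTimeSeries) -> FCMatrix:
    """Pairwise Pearson correlations; exact symmetry, unit diagonal.

    Entries involving a constant region series are undefined: they are set
    to NaN and masked out via ``valid``.
    """
    X = ts.data
    if X.shape[1] < 3:
        raise ValueError("need at least three time points")
    sd = X.std(axis=1)
    const = sd <= 1e-12 * np.maximum(np.abs(X).max(axis=1), 1e-300)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    valid = ~(const[:, None] | const[None, :])
    r = np.where(valid, r, np.nan)
    np.fill_diagonal(r, 1.0)
    ids = ts.table["id"].to_numpy()
    return FCMatrix(r=np.clip(r, -1.0, 1.0), region_ids=ids, valid=valid)


def _zero_diag(r: np.ndarray) -> np.ndarray:
    """Copy with a zeroed diagonal (the self-correlation is not averaged)."""
    out = np.array(r, dtype=float, copy=True)
    np.fill_diagonal(out, 0.0)
    return out


def fisher_z(r: np.ndarray, clip: float = 1.0 - 1e-7) -> np.ndarray:
    """Variance-stabilizing Fisher transform atanh(r), with |r|=1 clipped."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > clip):
        warnings.warn("correlations at +-1 clipped before Fisher transform", stacklevel=2)
    return np.arctanh(np.clip(r, -clip, clip))


def group_average_fc(matrices: list[FCMatrix]) -> FCMatrix:
    """Fisher-z average across subjects, transformed back to correlations."""
    if not matrices:
        raise ValueError("no matrices to average")
    ids = matrices[0].region_ids
    for m in matrices:
        if not np.array_equal(m.region_ids, ids):
            raise ValueError("matrices must share the same region set")
    z = np.stack([fisher_z(_zero_diag(m.r)) for m in matrices])
    r = np.tanh(np.nanmean(z, axis=0))
    np.fill_diagonal(r, 1.0)
    valid = np.all(np.stack([m.valid for m in matrices]), axis=0)
    return FCMatrix(r=r, region_ids=ids, valid=valid)


def fc_significance(matrices: list[FCMatrix], alpha: float = 0.05) -> np.ndarray:
    """One-sample t on Fisher-z across subjects, BH-FDR over unique pairs.

    Returns a boolean matrix (symmetric, False diagonal) marking entries
    whose group-average coefficient differs from zero at FDR ``alpha``.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two subjects")
    z = np.stack([fisher_z(_zero_diag(m.r)) for m in matrices])  # (n_sub, R, R)
    n_r = z.shape[1]
    iu = np.triu_indices(n_r, k=1)
    zp = z[:, iu[0], iu[1]]
    tstat, pvals = stats.ttest_1samp(zp, 0.0, axis=0)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    reject, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    sig = np.zeros((n_r, n_r), dtype=bool)
    sig[iu] = reject
    return sig | sig.T


def fc_specificity(
    ts: RegionTimeSeries,
    ss_left: str = "SSp-ul_L",
    ss_right: str = "SSp-ul_R",
    aca: str = "ACA_L",
) -> tuple[float, float]:
    """Specific vs unspecific FC quality-control pair.

    ``r_specific`` is the homotopic somatosensory correlation (left/right
    SSp); ``r_unspecific`` correlates the somatosensory cortex with the
    anterior cingulate.  A motion- or GS-dominated session inflates both.
    """
    a = ts.series(ss_left)
    b = ts.series(ss_right)
    c = ts.series(aca)
    r_specific = float(np.corrcoef(a, b)[0, 1])
    r_unspecific = float(np.corrcoef(a, c)[0, 1])
    return r_specific, r_unspecific
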