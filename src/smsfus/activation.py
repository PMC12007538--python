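"""Task-activation statistics: HRF, GLM, Bonferroni, rCBV, TFCE permutation.

The stimulus-evoked hemodynamic response is modeled by convolving the 0/1
stimulus timeline with a canonical hemodynamic response function built
from four half-cosine segments (onset delay, rise, fall, undershoot
recovery).  The regressor is rescaled to be 0 at rest and 1 during a
sustained stimulus, so the GLM intercept is directly the CBV baseline and
the stimulus beta reads in the same units as the signal.

Voxelwise inference uses ordinary least squares with a Student t per
voxel.  Subject-level maps are corrected with Bonferroni (FWER alpha
0.05); group-level maps use a one-sample t-test across subjects combined
with threshold-free cluster enhancement (TFCE) and max-statistic sign-flip
permutation testing.  Relative CBV is 100 * (y - baseline) / baseline.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "HRFModel",
    "StatMap",
    "GLMResult",
    "RasterExtract",
    "build_regressor",
    "glm_fit",
    "bonferroni_mask",
    "rcbv",
    "rcbv_raster",
    "percent_activated",
    "trial_average",
    "tfce",
    "one_sample_t",
    "group_permutation_test",
]


@dataclass(frozen=True)
class HRFModel:
    """Four half-cosine canonical hemodynamic response function.

    Segments (seconds): a flat onset delay, a half-cosine rise from 0 to
    the peak, a half-cosine fall from the peak to ``-undershoot_depth``,
    and a half-cosine recovery back to 0.  The kernel starts and ends at
    zero and is normalized to unit peak.  Defaults give a ~8 s kernel with
    the undershoot disabled.
    """

    onset_s: float = 0.5
    rise_s: float = 1.0
    fall_s: float = 5.0
    recovery_s: float = 1.5
    undershoot_depth: float = 0.0

    def __post_init__(self) -> None:
        if min(self.onset_s, self.rise_s, self.fall_s, self.recovery_s) <= 0:
            raise ValueError("segment durations must be positive")
        if self.undershoot_depth < 0:
            raise ValueError("undershoot_depth must be >= 0")

    @property
    def duration_s(self) -> float:
        return self.onset_s + self.rise_s + self.fall_s + self.recovery_s

    def kernel(self, dt_s: float) -> np.ndarray:
        """Sample the kernel at resolution ``dt_s`` (unit peak)."""
        t = np.arange(0.0, self.duration_s + dt_s / 2, dt_s)
        h = np.zeros_like(t)
        t1 = self.onset_s
        t2 = t1 + self.rise_s
        t3 = t2 + self.fall_s
        t4 = t3 + self.recovery_s
        u = self.undershoot_depth
        m = (t >= t1) & (t < t2)
        h[m] = 0.5 * (1 - np.cos(np.pi * (t[m] - t1) / self.rise_s))
        m = (t >= t2) & (t < t3)
        h[m] = -u + (1 + u) * 0.5 * (1 + np.cos(np.pi * (t[m] - t2) / self.fall_s))
        # recovery rises from -u back to 0
        m = (t >= t3) & (t <= t4)
        h[m] = -u + u * 0.5 * (1 - np.cos(np.pi * (t[m] - t3) / self.recovery_s))
        return h


def build_regressor(stimulus: np.ndarray, hrf: HRFModel, tr_s: float) -> np.ndarray:
    """Convolve a 0/1 stimulus timeline with the HRF; rescale to [0, 1].

    The kernel is normalized to unit sum so a sustained stimulus drives the
    regressor to exactly 1 while rest periods sit at 0.  The convolution is
    causal and truncated to the stimulus length.
    """
    stimulus = np.asarray(stimulus, dtype=float)
    k = hrf.kernel(tr_s)
    ksum = k.sum()
    if ksum <= 0:
        raise ValueError("HRF kernel has non-positive area")
    k = k / ksum
    return np.convolve(stimulus, k)[: len(stimulus)]


@dataclass
class GLMResult:
    """Voxelwise OLS fit: betas, contrast t, two-sided p, dof and baseline."""

    beta: np.ndarray  # (p, n_vox)
    t: np.ndarray  # (n_vox,)
    p: np.ndarray  # (n_vox,)
    dof: int
    contrast: np.ndarray

    @property
    def intercept(self) -> np.ndarray:
        """Baseline (intercept) estimate per voxel."""
        return self.beta[0]


def glm_fit(y: np.ndarray, X: np.ndarray, contrast: np.ndarray | None = None) -> GLMResult:
    """OLS GLM with a t-statistic for one contrast.

    ``y`` is (n_t,) or (n_t, n_vox); ``X`` is (n_t, p) and must include the
    intercept as its first column.  The default contrast selects the second
    column (the stimulus or seed regressor).  Voxels with zero residual
    variance get ``t = inf`` (p = 0) when the contrast estimate is nonzero.
    """
    y = np.asarray(y, dtype=float)
    squeeze = y.ndim == 1
    Y = y[:, None] if squeeze else y
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more time points than regressors")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    if contrast is None:
        c = np.zeros(p)
        c[1 if p > 1 else 0] = 1.0
    else:
        c = np.asarray(contrast, dtype=float)

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = n - p
    sigma2 = np.sum(resid**2, axis=0) / dof
    cvar = float(c @ xtx_inv @ c)
    # an (essentially) exact fit has no residual error: flag t as infinite
    perfect = sigma2 <= np.finfo(float).eps ** 1.5 * np.maximum(np.mean(Y**2, axis=0), 1e-300)
    se = np.sqrt(sigma2 * cvar)
    cb = c @ beta
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, cb / np.where(se > 0, se, 1.0), np.where(cb != 0, np.inf * np.sign(cb), 0.0))
    t = np.where(perfect & (cb != 0), np.inf * np.sign(cb), t)
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    pvals = np.where(np.isinf(t), 0.0, pvals)
    if squeeze:
        return GLMResult(beta[:, 0][:, None], float(t[0]) * np.ones(1), pvals[:1], dof, c)
    return GLMResult(beta, t, pvals, dof, c)


@dataclass
class StatMap:
    """Per-voxel statistic, p-value and significance mask."""

    stat: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    method: str
    dof: int


@dataclass
class RasterExtract:
    """Region x time rCBV matrix (%) with per-region activation coverage."""

    rcbv_pct: np.ndarray  # (n_regions, n_t)
    region_ids: np.ndarray
    pct_activated: np.ndarray | None = None  # (n_regions,) in [0, 100]


def bonferroni_mask(p: np.ndarray, alpha: float = 0.05, mask: np.ndarray | None = None) -> np.ndarray:
    """Voxelwise Bonferroni FWER control: significant iff p < alpha / n."""
    p = np.asarray(p)
    if mask is None:
        n = p.size
        return p < alpha / n
    n = int(mask.sum())
    return (p < alpha / n) & mask


def rcbv(series: np.ndarray, baseline: float | np.ndarray) -> np.ndarray:
    """Relative CBV change in percent: ``100 * (y - baseline) / baseline``."""
    baseline = np.asarray(baseline, dtype=float)
    if np.any(baseline <= 0):
        raise ValueError("baseline must be positive")
    return 100.0 * (np.asarray(series, dtype=float) - baseline) / baseline


def rcbv_raster(
    vol_data: np.ndarray,
    labels: np.ndarray,
    baseline: np.ndarray,
    sig_mask: np.ndarray | None = None,
) -> RasterExtract:
    """Region-mean rCBV time courses from a 4D series and a label volume.

    ``baseline`` is a per-voxel baseline map (e.g. the GLM intercept); the
    region series is the voxel-mean rCBV.  When ``sig_mask`` is given, the
    percentage of significantly activated voxels per region is attached.
    """
    ids = np.unique(labels)
    ids = ids[ids > 0]
    n_t = vol_data.shape[-1]
    out = np.zeros((len(ids), n_t))
    pct = np.zeros(len(ids)) if sig_mask is not None else None
    for i, rid in enumerate(ids):
        m = labels == rid
        out[i] = rcbv(vol_data[m], baseline[m][:, None]).mean(axis=0)
        if sig_mask is not None:
            pct[i] = 100.0 * sig_mask[m].mean()
    return RasterExtract(out, ids, pct)


def percent_activated(sig_mask: np.ndarray, labels: np.ndarray) -> dict[int, float]:
    """Percentage of significant voxels in each labelled region."""
    ids = np.unique(labels)
    return {int(r): 100.0 * float(sig_mask[labels == r].mean()) for r in ids if r > 0}


def trial_average(raster: RasterExtract, trial_onsets: np.ndarray, window: int) -> RasterExtract:
    """Average equal-length trial windows of a raster (inter-trial mean)."""
    n_t = raster.rcbv_pct.shape[1]
    trial_onsets = np.asarray(trial_onsets, dtype=int)
    if np.any(trial_onsets + window > n_t) or np.any(trial_onsets < 0):
        raise ValueError("trial window exceeds the scan")
    trials = np.stack([raster.rcbv_pct[:, o : o + window] for o in trial_onsets], axis=0)
    return RasterExtract(trials.mean(axis=0), raster.region_ids, raster.pct_activated)


def _tfce_one_tail(a: np.ndarray, E: float, H: float, dh: float | None, n_steps: int, structure: np.ndarray) -> np.ndarray:
    out = np.zeros_like(a, dtype=float)
    amax = float(a.max(initial=0.0))
    if amax <= 0:
        return out
    step = dh if dh is not None else amax / n_steps
    n = int(math.floor(amax / step + 1e-9))
    for k in range(1, n + 1):
        h = k * step
        sup = a >= h - 1e-12
        lab, nlab = ndimage.label(sup, structure=structure)
        if nlab == 0:
            continue
        sizes = np.bincount(lab.ravel())
        out[sup] += (sizes[lab[sup]] ** E) * (h**H) * step
    return out


def tfce(
    statmap: np.ndarray,
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
    n_steps: int = 100,
    connectivity: int = 1,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a statistic map.

    For each voxel the enhanced value is ``sum_h e(h)^E h^H dh`` over
    thresholds ``h`` from 0 up to the voxel's height, where ``e(h)`` is the
    extent of the cluster supporting the voxel at height ``h``.  Positive
    and negative tails are enhanced separately and recombined with sign.
    Default 6-connectivity in 3D (``connectivity=1`` faces only); ``dh``
    defaults to max/``n_steps`` per tail.
    """
    a = np.asarray(statmap, dtype=float)
    structure = ndimage.generate_binary_structure(a.ndim, connectivity)
    pos = _tfce_one_tail(np.maximum(a, 0.0), E, H, dh, n_steps, structure)
    neg = _tfce_one_tail(np.maximum(-a, 0.0), E, H, dh, n_steps, structure)
    return pos - neg


def one_sample_t(maps: np.ndarray) -> np.ndarray:
    """One-sample t across the first axis (subjects), dof = n - 1."""
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t


def group_permutation_test(
    subject_maps: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    tail: str = "two",
    seed: int | None = 0,
    tfce_kwargs: dict | None = None,
    brain_mask: np.ndarray | None = None,
) -> StatMap:
    """Group one-sample test with TFCE and max-statistic sign-flip permutation.

    ``subject_maps`` is (n_subjects, *spatial).  The observed group t map
    is TFCE-enhanced; the null distribution is the image-wise maximum of
    the enhanced map under random sign flips of whole subjects (exhaustive
    2^n flips when n <= 12).  A voxel is significant when its enhanced
    statistic reaches the (1 - alpha) quantile of the max-null.  ``tail``
    is "two" (|enhanced|) or "one" (positive tail).
    """
    maps = np.asarray(subject_maps, dtype=float)
    n_sub = maps.shape[0]
    if n_sub < 2:
        raise ValueError("need at least two subjects")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse null distribution", stacklevel=2)
    tkw = tfce_kwargs or {}

    def stat_of(m: np.ndarray) -> np.ndarray:
        e = tfce(one_sample_t(m), **tkw)
        s = np.abs(e) if tail == "two" else e
        if brain_mask is not None:
            s = np.where(brain_mask, s, 0.0)
        return s

    obs = stat_of(maps)

    if n_sub <= 12:
        flips = np.array(list(itertools.product([1.0, -1.0], repeat=n_sub)))
    else:
        rng = np.random.default_rng(seed)
        flips = rng.choice([1.0, -1.0], size=(n_perm, n_sub))
    null_max = np.empty(len(flips))
    for i, f in enumerate(flips):
        null_max[i] = stat_of(maps * f.reshape(-1, *([1] * (maps.ndim - 1)))).max()

    exhaustive = n_sub <= 12
    if exhaustive:
        p = (null_max[None] >= obs[..., None] - 1e-12).mean(axis=-1)
    else:
        p = (1.0 + (null_max[None] >= obs[..., None] - 1e-12).sum(axis=-1)) / (len(flips) + 1.0)
    sig = p <= alpha
    return StatMap(stat=obs, p=p, mask=sig, method="tfce_permutation", dof=n_sub - 1)
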