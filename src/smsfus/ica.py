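"""Group spatial ICA with icasso-style stabilization.

Spatial ICA treats voxels as samples and time points as features: the data
matrix (voxels x time) is whitened by PCA to the requested dimensionality
and unmixed by fixed-point ICA with a log-cosh non-Gaussianity contrast,
so each component is a spatial map with an associated time course.

Stabilization follows the icasso recipe: ICA is re-run many times from
random initial conditions, all estimated components are pooled, and their
pairwise similarity (absolute Pearson correlation of the spatial maps,
sign-invariant) drives average-linkage agglomerative clustering into as
many clusters as components.  Each cluster is summarized by its centrotype
(the member most similar to the rest of its cluster) and a stability index

    Iq = mean intra-cluster similarity - mean extra-cluster similarity,

close to 1 for reproducible components.  For display, spatial maps are
scaled to Z-scores and thresholded at |Z| > 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "ICARun",
    "StabilizedComponent",
    "run_ica",
    "icasso",
    "icasso_cluster",
    "zscale_threshold",
    "region_overlap",
]

DEFAULT_N_RUNS = 100
CANDIDATE_DIMENSIONALITIES = (15, 25, 35)
Z_THRESHOLD = 3.0


@dataclass
class ICARun:
    """One randomized ICA estimate: spatial maps, mixing, convergence flag."""

    maps: np.ndarray  # (n_vox, n_components)
    mixing: np.ndarray  # (n_t, n_components)
    converged: bool
    seed: int


@dataclass
class StabilizedComponent:
    """An icasso cluster: centrotype map, stability, thresholded Z map."""

    map: np.ndarray  # centrotype spatial map (n_vox,)
    iq: float
    n_members: int
    zmap: np.ndarray | None = None
    mask: np.ndarray | None = None


def run_ica(
    data: np.ndarray,
    n_components: int,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-4,
) -> ICARun:
    """Fixed-point spatial ICA (PCA whitening, log-cosh contrast).

    ``data`` is (n_voxels, n_time).  Deterministic given ``seed``.  A run
    that does not converge within ``max_iter`` is flagged and should be
    excluded from clustering.
    """
    data = np.asarray(data, dtype=float)
    if min(data.shape) < n_components:
        raise ValueError("data dimensionality below n_components")
    ica = FastICA(
        n_components=n_components,
        whiten="unit-variance",
        fun="logcosh",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        maps = ica.fit_transform(data)
    converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    return ICARun(maps=maps, mixing=ica.mixing_, converged=converged, seed=seed)


def icasso_cluster(runs: list[ICARun], n_components: int) -> list[StabilizedComponent]:
    """Cluster pooled components from repeated runs; pick centrotypes.

    Similarity between components is the absolute Pearson correlation of
    their spatial maps (invariant to the ICA sign ambiguity).  Clusters
    come from average-linkage agglomeration at distance 1 - |r|, cut at
    ``n_components`` clusters, and are returned sorted by decreasing Iq.
    """
    good = [r for r in runs if r.converged]
    if len(good) < 2:
        failed = [r.seed for r in runs if not r.converged]
        raise ValueError(f"need >= 2 converged runs; non-converged seeds: {failed}")
    pool = np.concatenate([r.maps for r in good], axis=1)  # (n_vox, total)
    total = pool.shape[1]
    sim = np.abs(np.corrcoef(pool.T))
    np.fill_diagonal(sim, 1.0)
    dist = np.clip(1.0 - sim, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    assign = fcluster(Z, t=n_components, criterion="maxclust")

    comps: list[StabilizedComponent] = []
    for c in np.unique(assign):
        members = np.where(assign == c)[0]
        outside = np.where(assign != c)[0]
        sub = sim[np.ix_(members, members)]
        if len(members) > 1:
            intra = (sub.sum() - len(members)) / (len(members) * (len(members) - 1))
            # centrotype: member with maximal total intra-cluster similarity
            centro = members[np.argmax(sub.sum(axis=1))]
        else:
            intra = 1.0
            centro = members[0]
        extra = sim[np.ix_(members, outside)].mean() if len(outside) else 0.0
        iq = float(np.clip(intra - extra, 0.0, 1.0))
        comps.append(StabilizedComponent(map=pool[:, centro].copy(), iq=iq, n_members=len(members)))
    comps.sort(key=lambda comp: comp.iq, reverse=True)
    return comps


def icasso(
    data: np.ndarray,
    n_components: int,
    n_runs: int = DEFAULT_N_RUNS,
    seed: int = 0,
    z_thresh: float = Z_THRESHOLD,
    **ica_kwargs,
) -> list[StabilizedComponent]:
    """Repeated randomized ICA + clustering + Z-thresholded maps."""
    runs = [run_ica(data, n_components, seed=seed + i, **ica_kwargs) for i in range(n_runs)]
    comps = icasso_cluster(runs, n_components)
    for comp in comps:
        comp.zmap, comp.mask = zscale_threshold(comp.map, z_thresh)
    return comps


def zscale_threshold(m: np.ndarray, z_thresh: float = Z_THRESHOLD) -> tuple[np.ndarray, np.ndarray]:
    """Scale a spatial map to Z-scores and threshold at |Z| > ``z_thresh``.

    Idempotent on maps that are already Z-scaled; a constant map is an
    error.  For a standard-normal map the expected masked fraction is
    ``2 * Phi(-z_thresh)`` (~0.27% at the default threshold of 3).
    """
    m = np.asarray(m, dtype=float)
    sd = m.std()
    if sd == 0:
        raise ValueError("cannot Z-scale a constant map")
    z = (m - m.mean()) / sd
    return z, np.abs(z) > z_thresh


def region_overlap(mask: np.ndarray, labels: np.ndarray, table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-region overlap of a component mask with an atlas label volume.

    Supports manual classification of components into named networks; the
    classification itself stays with the analyst.
    """
    ids = np.unique(labels)
    ids = ids[ids > 0]
    rows = []
    for rid in ids:
        reg = labels == rid
        inter = int((mask & reg).sum())
        rows.append(
            {
                "id": int(rid),
                "n_voxels": int(reg.sum()),
                "n_overlap": inter,
                "fraction": inter / max(int(reg.sum()), 1),
            }
        )
    out = pd.DataFrame(rows)
    if table is not None:
        out = out.merge(table[["id", "acronym"]], on="id", how="left")
    return out.sort_values("fraction", ascending=False, ignore_index=True)
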