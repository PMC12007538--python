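"""Connectivity: region extraction, seed maps, FC matrices, Fisher averaging."""

import numpy as np
import pandas as pd
import pytest

from smsfus import (
    PDVolume,
    SimulationSpec,
    extract_regions,
    fc_matrix,
    fc_significance,
    fc_specificity,
    fisher_z,
    group_average_fc,
    seed_map,
    simulate_pd_series,
)
from smsfus.connectivity import FCMatrix, RegionTimeSeries

TR = 2.4


def small_ts(data, acronyms=None):
    n = data.shape[0]
    if acronyms is None:
        acronyms = [f"R{i}" for i in range(n)]
    table = pd.DataFrame({"id": np.arange(1, n + 1), "acronym": acronyms})
    return RegionTimeSeries(np.asarray(data, dtype=float), table)


# --- extraction ----------------------------------------------------------------


def test_extract_single_voxel_region_exact(rng):
    data = rng.normal(100, 5, size=(2, 2, 2, 30))
    labels = np.zeros((2, 2, 2), dtype=int)
    labels[0, 0, 0] = 1
    labels[1, :, :] = 2
    vol = PDVolume(data, tr_s=TR)
    table = pd.DataFrame({"id": [1, 2, 3], "acronym": ["a", "b", "missing"]})
    ts = extract_regions(vol, labels, table)
    assert np.array_equal(ts.series("a"), data[0, 0, 0])
    assert np.allclose(ts.series("b"), data[1].reshape(-1, 30).mean(axis=0))
    assert ts.missing_ids == (3,)
    assert list(ts.table["acronym"]) == ["a", "b"]


def test_extract_rejects_grid_mismatch(rng):
    vol = PDVolume(rng.normal(size=(2, 2, 2, 10)), tr_s=TR)
    with pytest.raises(ValueError):
        extract_regions(vol, np.zeros((3, 2, 2), dtype=int))


def test_extract_planted_region_means(atlas):
    labels, table = atlas
    spec = SimulationSpec(labels=labels, n_volumes=60, noise_sigma_pct=0.0, drift_amp_pct=0.0, seed=21)
    vol = simulate_pd_series(spec)
    ts = extract_regions(vol, labels, table)
    # within a region every voxel carries the identical latent signal
    rid = int(table["id"].iloc[0])
    voxels = vol.data[labels == rid]
    assert np.allclose(ts.data[0], voxels[0])


# --- seed maps -------------------------------------------------------------------


def test_seed_map_self_voxel_is_maximal(rng):
    data = rng.normal(size=(3, 3, 1, 80))
    vol = PDVolume(data + 100, tr_s=TR)
    seed = vol.data[1, 1, 0]
    res = seed_map(vol, seed)
    assert np.nanargmax(res.t) == np.ravel_multi_index((1, 1, 0), (3, 3, 1))


def test_seed_map_orthogonal_voxel_is_null():
    n = 120
    t = np.arange(n)
    seed = np.sin(2 * np.pi * t / 30)
    ortho = np.cos(2 * np.pi * t / 30)
    data = np.zeros((2, 1, 1, n))
    data[0, 0, 0] = seed
    data[1, 0, 0] = ortho
    res = seed_map(PDVolume(data + 100, tr_s=TR), seed)
    assert abs(res.beta[1, 1]) < 1e-8
    with pytest.raises(ValueError):
        seed_map(PDVolume(data + 100, tr_s=TR), np.ones(n))


def test_group_seed_map_finds_contralateral_homolog(atlas):
    """Bilateral planted network: the mirror region is significant at group level."""
    from smsfus import group_permutation_test

    labels, table = atlas
    n_r = len(table)
    corr = np.eye(n_r)
    corr[0, 1] = corr[1, 0] = 0.85  # SSp-ul left/right
    tmaps = []
    for s in range(6):
        spec = SimulationSpec(
            labels=labels, n_volumes=200, network_corr=corr, noise_sigma_pct=1.0,
            drift_amp_pct=0.0, seed=100 + s,
        )
        vol = simulate_pd_series(spec)
        ts = extract_regions(vol, labels, table)
        res = seed_map(vol, ts.series("SSp-ul_L"))
        tmaps.append(np.where(np.isfinite(res.t), res.t, 0.0).reshape(labels.shape))
    sm = group_permutation_test(np.stack(tmaps), tail="one", tfce_kwargs={"n_steps": 25})
    homolog = labels == int(table.loc[table["acronym"] == "SSp-ul_R", "id"].iloc[0])
    far = labels == int(table.loc[table["acronym"] == "RS_L", "id"].iloc[0])
    assert sm.mask[homolog].mean() > 0.9
    assert sm.mask[far].mean() < 0.1


# --- FC matrix -------------------------------------------------------------------


def test_fc_matrix_identities(rng):
    base = rng.normal(size=60)
    ts = small_ts(np.stack([base, base, -base]))
    fc = fc_matrix(ts)
    assert fc.r[0, 1] == pytest.approx(1.0)
    assert fc.r[0, 2] == pytest.approx(-1.0)
    assert np.array_equal(fc.r, fc.r.T)
    assert np.all(np.diag(fc.r) == 1.0)


def test_fc_matrix_matches_bruteforce_pearson(rng):
    X = rng.normal(size=(10, 100))
    fc = fc_matrix(small_ts(X))
    for i in range(10):
        for j in range(10):
            num = ((X[i] - X[i].mean()) * (X[j] - X[j].mean())).sum()
            den = np.sqrt(((X[i] - X[i].mean()) ** 2).sum() * ((X[j] - X[j].mean()) ** 2).sum())
            assert fc.r[i, j] == pytest.approx(num / den, abs=1e-12)


def test_fc_matrix_masks_constant_series(rng):
    X = rng.normal(size=(3, 50))
    X[1] = 4.2
    fc = fc_matrix(small_ts(X))
    assert not fc.valid[0, 1]
    assert np.isnan(fc.r[0, 1])
    assert fc.r[1, 1] == 1.0


def test_fc_matrix_needs_three_points():
    with pytest.raises(ValueError):
        fc_matrix(small_ts(np.zeros((2, 2))))


# --- Fisher averaging -------------------------------------------------------------


def make_fc(r_val, n=3):
    r = np.eye(n)
    r[0, 1] = r[1, 0] = r_val
    return FCMatrix(r=r, region_ids=np.arange(1, n + 1))


def test_group_average_identities():
    m = make_fc(0.42)
    avg = group_average_fc([m, m, m])
    assert np.allclose(avg.r, m.r)
    single = group_average_fc([m])
    assert np.allclose(single.r, m.r)


def test_group_average_fisher_worked_examples():
    avg = group_average_fc([make_fc(0.5), make_fc(-0.5)])
    assert avg.r[0, 1] == pytest.approx(0.0, abs=1e-12)
    avg2 = group_average_fc([make_fc(0.3), make_fc(0.9)])
    expected = np.tanh((np.arctanh(0.3) + np.arctanh(0.9)) / 2)
    assert avg2.r[0, 1] == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(0.712, abs=0.001)  # != arithmetic mean 0.6


def test_group_average_clips_perfect_correlation():
    with pytest.warns(UserWarning):
        avg = group_average_fc([make_fc(1.0), make_fc(0.5)])
    assert -1.0 < avg.r[0, 1] < 1.0
    assert np.all(np.abs(avg.r[~np.eye(3, dtype=bool)]) < 1.0)


def test_fisher_z_is_atanh():
    r = np.array([0.0, 0.5, -0.8])
    assert np.allclose(fisher_z(r), np.arctanh(r))


# --- FC significance ---------------------------------------------------------------


def test_fc_significance_null_and_planted(rng):
    n_sub, n_r = 6, 8
    zeros = [make_fc(0.0, n_r) for _ in range(n_sub)]
    assert not fc_significance(zeros).any()

    mats = []
    for s in range(n_sub):
        r = np.eye(n_r)
        noise = 0.05 * rng.normal(size=(n_r, n_r))
        noise = (noise + noise.T) / 2
        r = np.clip(r + noise - np.diag(np.diag(noise)), -0.99, 0.99)
        np.fill_diagonal(r, 1.0)
        r[0, 1] = r[1, 0] = np.clip(0.7 + 0.05 * rng.normal(), -0.99, 0.99)
        mats.append(FCMatrix(r=r, region_ids=np.arange(n_r)))
    sig = fc_significance(mats)
    assert sig[0, 1] and sig[1, 0]
    assert not np.diag(sig).any()
    with pytest.raises(ValueError):
        fc_significance(mats[:1])


# --- specificity QC -----------------------------------------------------------------


def test_specificity_planted_bilateral_network(rng):
    n = 400
    shared = rng.normal(size=n)
    ss_l = shared + 0.3 * rng.normal(size=n)
    ss_r = shared + 0.3 * rng.normal(size=n)
    aca = rng.normal(size=n)
    ts = small_ts(np.stack([ss_l, ss_r, aca]), ["SSp-ul_L", "SSp-ul_R", "ACA_L"])
    r_spec, r_unspec = fc_specificity(ts)
    assert r_spec > 0.8
    assert abs(r_unspec) < 0.15


def test_specificity_flags_global_signal(rng):
    n = 400
    g = rng.normal(size=n)
    ts = small_ts(np.stack([g, g + 0.01 * rng.normal(size=n), g + 0.01 * rng.normal(size=n)]),
                  ["SSp-ul_L", "SSp-ul_R", "ACA_L"])
    r_spec, r_unspec = fc_specificity(ts)
    assert r_spec > 0.95 and r_unspec > 0.95


def test_specificity_independent_noise(rng):
    ts = small_ts(rng.normal(size=(3, 2000)), ["SSp-ul_L", "SSp-ul_R", "ACA_L"])
    r_spec, r_unspec = fc_specificity(ts)
    assert abs(r_spec) < 0.1 and abs(r_unspec) < 0.1
    with pytest.raises(KeyError):
        fc_specificity(ts, ss_left="nope")


# --- seed/FC consistency --------------------------------------------------------------


def test_seed_map_consistent_with_fc_column(atlas):
    """With region-pure voxels, seed-map t ordering tracks the FC row."""
    labels, table = atlas
    n_r = len(table)
    rng = np.random.default_rng(31)
    w = rng.standard_normal((n_r, 2 * n_r))
    corr = np.corrcoef(w)
    spec = SimulationSpec(
        labels=labels, n_volumes=300, network_corr=corr, noise_sigma_pct=0.0, drift_amp_pct=0.0, seed=33
    )
    vol = simulate_pd_series(spec)
    ts = extract_regions(vol, labels, table)
    fc = fc_matrix(ts)
    res = seed_map(vol, ts.data[0])
    tmap = res.t.reshape(labels.shape)
    per_region_t = np.array([np.mean(tmap[labels == rid]) for rid in ts.table["id"]])
    finite = np.isfinite(per_region_t)
    finite[0] = False  # the seed region itself is an exact fit
    assert np.array_equal(np.argsort(per_region_t[finite]), np.argsort(fc.r[0][finite]))
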