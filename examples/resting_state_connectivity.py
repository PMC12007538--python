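"""Resting-state preprocessing and functional connectivity on synthetic scans.

Six synthetic "subjects" carry a bilateral somatosensory network (latent
correlation 0.8 between SSp-ul left/right).  Each scan passes the full
awake pipeline (slice timing, detrend, calm detection, standardize +
band-pass 0.01-0.1 Hz, global-signal regression); region series give a
Pearson FC matrix per subject, Fisher-averaged across the group, and a
specificity QC contrasting homotopic SS correlation with SS-to-ACA.
"""

import numpy as np

from smsfus import (
    SimulationSpec,
    extract_regions,
    fc_matrix,
    fc_significance,
    fc_specificity,
    group_average_fc,
    make_atlas,
    preprocess_resting,
    simulate_pd_series,
)

labels, table = make_atlas((16, 4, 16))
n_r = len(table)
corr = np.eye(n_r)
corr[0, 1] = corr[1, 0] = 0.8  # SSp-ul left <-> right

matrices = []
for subject in range(6):
    spec = SimulationSpec(
        labels=labels, n_volumes=400, network_corr=corr,
        latent_std_pct=2.0, noise_sigma_pct=0.5, seed=subject,
    )
    vol = simulate_pd_series(spec)
    clean, segments, excluded = preprocess_resting(vol)
    ts = extract_regions(clean, labels, table)
    matrices.append(fc_matrix(ts))
    r_spec, r_unspec = fc_specificity(ts)
    print(f"subject {subject}: calm {segments.calm_score_s:5.0f} s, "
          f"r(SS-L, SS-R) = {r_spec:+.2f}, r(SS, ACA) = {r_unspec:+.2f}")

group = group_average_fc(matrices)
sig = fc_significance(matrices, alpha=0.05)
i, j = 0, 1  # SSp-ul_L, SSp-ul_R rows
print(f"\ngroup Fisher-averaged r(SSp-ul L/R): {group.r[i, j]:.3f} "
      f"({'significant' if sig[i, j] else 'not significant'} at FDR 0.05)")
print(f"significant FC pairs: {sig.sum() // 2} of {n_r * (n_r - 1) // 2}")
off = group.r[~np.eye(n_r, dtype=bool)]
print(f"median off-diagonal r: {np.median(off):+.3f}")
print("(the homotopic pair dominates in magnitude; GSR leaves small but consistent")
print(" negative correlations everywhere else, which a one-sample test duly flags)")
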