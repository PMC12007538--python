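# Methods

This note records the models, parameter choices and numerical conventions
behind `smsfus`, and what the synthetic generators do and do not emulate.

## Acquisition geometry and scheduling

The probe model is four linear arrays of 64 elements (110 µm pitch,
2.1 mm inter-array spacing, ~0.5 mm elevation FWHM from the acoustic
lens, 15 MHz). A motorized sweep through `n` positions with step
`2.1 / n` mm tiles `4n` contiguous slices; volume timing follows
`TR = n (T_int + T_trans)` with defaults `T_int = 0.4 s` (200 frames at
the 500 Hz compound rate) and `T_trans = 0.2 s`. `T_trans` is modeled as
a constant dead time independent of move distance: it is an upper bound
on the motor settle time (the two-step bound keeps the true time well
below it), and a constant keeps slice onsets strictly periodic.

Interleaving rule: odd positions ascending, then even positions
*descending* (1-3-4-2 for n = 4). The descending-even branch is a
deliberate design choice: it makes the wrap-around move small for every
`n`, so the maximum cyclic displacement is at most two steps for all
`n ≥ 2`, not just the four-position case.

Slice elevations are Bregma-relative millimetres, anterior positive,
slice 0 most anterior, default origin +3.0 mm; 16 slices at 0.525 mm then
span +3.0 → −4.875 mm. We report exact arithmetic (7.875 mm span) rather
than rounding to a nominal field of view.

## Beamforming

Delay-and-sum with two-way travel time
`τ = (z cosθ + x sinθ)/c + √(z² + (x − x_e)²)/c`, `c = 1540 m/s`.
Unspecified details are set to the simplest defensible defaults and are
all configurable: linear-in-time interpolation, rectangular receive
apodization inside an f-number = 1 acceptance cone, no transmit
apodization. Delays outside the recorded samples contribute zero. Each
array is beamformed independently on its own grid; there is no
cross-array coherent summation. Channel data are complex analytic
(baseband-style) samples; an RF→IQ converter is out of scope, and the
synthetic scatterer model emits analytic samples directly. The
trapezoidal grid widens at tan(θmax = 12°) on both sides; voxels outside
the trapezoid are not computed. Compounding is the coherent mean over
angles (default 8 angles evenly spaced in ±12°).

## Clutter filter

SVD is taken on the raw Casorati matrix without mean removal — the
temporal mean is captured by the first mode anyway, and keeping the raw
decomposition makes the energy bookkeeping exact (Parseval split between
tissue and blood parts, verified to 1e-10 in the tests). Raster
convention: voxel (ix, iz) ↦ row `ix·Nz + iz`. The spatial support is
the whole slice (no sub-block tiling).

The adaptive threshold for awake data is the smallest `n` whose
cumulative **energy** (λ², not amplitude) reaches a fixed fraction of the
total, default 0.95. This is the simplest rule consistent with a fixed
energy threshold and is monotone in block energy; the λ²-vs-λ choice is
flagged here because either reading is defensible. At least one mode is
always removed for any positive fraction. Note its intended regime: it
adapts the cut to *motion* (which inflates the number of high-energy
tissue modes); on a phantom whose tissue is concentrated in one dominant
mode it returns 1, which is correct under the rule. The fixed
motion-free default is `Ncut = 60`.

## Synthetic data

The generators are the package's study conditions, not conveniences:

* **IQ phantom** — ≤ 3 low-rank smooth tissue patterns with slow phase
  modulation (each exactly rank 1 in the Casorati sense), blood
  scatterers confined to a vessel stripe (~1/6 of the field) with a
  100 Hz Doppler carrier and 5 ms amplitude decorrelation, and circular
  white complex noise. Defaults put tissue 40 dB above blood and blood
  20 dB above noise on a 48×48 grid — sized so the blood subspace spans
  far more than 60 modes, as it does in real frames, making the fixed
  cut meaningful.
* **PD time series** — per-region latent signals band-limited to
  0.01–0.1 Hz using the *same* Butterworth design as the preprocessing
  band-pass (shared code path, so the generative and analysis bands
  match by construction). The filtered latents are empirically whitened
  before mixing with the Cholesky factor of the network correlation, so
  the realized latent correlation equals the target exactly at any scan
  length; this makes closed-loop correlation recovery a sharp test
  rather than one smeared by the ~2BT effective dof of band-limited
  series at TR 2.4 s. Stimulus responses are HRF-convolved boxcars in %
  of a 100-unit baseline (so rCBV is directly readable); drift is a
  zero-mean random cubic per voxel (default ±1% amplitude budget);
  motion episodes multiply the global level by a noisy excursion factor
  (the calm detector watches GS variance; spatial displacement and
  registration are out of scope); slices sample the latent process at
  their true within-TR onsets so slice-timing correction is testable.

Not emulated: realistic vasculature, biophysical neurovascular coupling,
skull aberration, spatially structured noise, cardiac/respiratory
physiology. Passing closed-loop tests therefore demonstrates the
correctness and calibration of the *algorithms* under the stated signal
model, not performance on real tissue.

## Preprocessing

Stage order: slice-timing correction → detrend → calm detection →
per-segment standardize + band-pass → concatenate → GSR (awake only;
task data from anesthetized sessions stop after detrending). Details:

* STC resamples onto the first position's grid by linear interpolation;
  samples requested before a slice's first acquisition are edge-held.
* Calm detection uses the **undetrended** global signal: its baseline is
  an independent linear regression over the scan, and "below 5%" is
  relative to the local regression value, not the scan mean (both
  configurable). The rolling-SD window is 24 s (an odd number of
  volumes, truncated at the edges) — long enough to estimate variance,
  short against the 60 s minimum duration. Scans with < 600 s total calm
  are flagged excluded.
* Standardize-then-filter (in that order) per segment, then temporal
  concatenation; the band-pass is a 4th-order Butterworth applied
  forward-backward (zero phase), the standard choice in the
  resting-state literature. GSR projects out the brain-mean course plus
  intercept; the note that GSR induces small consistent negative
  correlations is demonstrated in the tests and examples.

## Activation statistics

The canonical HRF is four half-cosine segments — onset delay 0.5 s, rise
1 s (0→1), fall 5 s (1→−u), recovery 1.5 s (−u→0) — peak-normalized,
undershoot `u = 0` by default, total 8 s. The exact segment durations
are configuration, not doctrine: the 0/1 regressor rescaling constrains
amplitude, not shape. The regressor normalizes the kernel to unit sum so
a sustained stimulus drives it to exactly 1 and the GLM intercept is the
CBV baseline.

GLM is OLS with a Student t per voxel (dof n − p); an exact fit is
flagged with t = ∞, p = 0. Serial autocorrelation is **not** modeled
(no prewhitening); the Monte-Carlo calibration tests quantify the type-I
error under white noise, where it is exact — on strongly autocorrelated
data the nominal level would be optimistic, a known limitation.
Subject-level correction is Bonferroni at FWER α = 0.05 (the procedure
named; we treat "false discovery rate" wording for it as a slip).
Group-level inference is a one-sample t across subjects, TFCE-enhanced
(E = 0.5, H = 2, dh = max/100, 6-connectivity — the standard published
defaults) with max-statistic sign-flip permutation; flips are exhaustive
(2^n) for n ≤ 12 subjects, giving p-values in multiples of 2^-n.
Positive and negative TFCE tails are enhanced separately and recombined
with sign; two-tailed tests use |enhanced|.

## Connectivity and ICA

FC matrices are pairwise Pearson correlations with exact symmetry and
unit diagonal; constant series yield masked (NaN) entries, never
imputed. Group averaging is tanh(mean(atanh r)) with |r| clipped at
1 − 1e-7 (warned); inference is a one-sample t on Fisher-z across
subjects with Benjamini–Hochberg FDR over the upper triangle only. The
specificity QC defaults to SSp-ul left/right (specific) vs SSp→ACA
(unspecific); region names are configurable since toy label sets differ.

Spatial ICA whitens voxels × time data by PCA to the requested
dimensionality and runs fixed-point ICA with the log-cosh contrast
(deterministic per seed; non-convergent runs are flagged and excluded).
Icasso stabilization pools components from repeated runs, clusters by
average linkage on 1 − |Pearson r| between spatial maps (sign
invariant), fixes the cluster count to the dimensionality (icasso
convention), and reports the centrotype and
`Iq = mean intra-cluster − mean extra-cluster similarity`, clipped to
[0, 1]. Candidate dimensionalities 15/25/35 and 100 replications are the
full-scale defaults; desk-scale tests use ~20 runs. |Z| > 3 thresholding
of Z-scaled maps keeps 2Φ(−3) ≈ 0.27% of a Gaussian map (the often-cited
"p < 0.001" equivalence is approximate — the exact two-sided tail is
0.0027); a constant map is an error. Component-to-network classification
is left to the analyst; the package provides ranked components with
region-overlap tables.

## Problem sizes and numerical conventions

Monte-Carlo calibrations use 500 replicates (FWER/FDR standard errors
≈ 1%), permutation nulls the exhaustive 64 sign flips of six subjects,
TFCE 20–100 threshold steps, and simulations of 8×3×8 to 16×4×16 voxel
volumes over 150–500 TRs — sizes chosen so the whole suite runs in a few
minutes on one CPU while keeping every estimate's sampling error well
inside the asserted tolerances. Ties and degenerate inputs: empty
calm-segment lists are an upstream exclusion error; rank-deficient GLM
designs and constant seeds/maps raise; TFCE threshold membership uses
`value ≥ h − 1e-12` so printed heights are included exactly.

## Known limitations

No prewhitening for serial autocorrelation; no image-registration motion
correction (calm-period exclusion only); no RF stage in the beamformer;
single-slice (not volumetric) clutter filtering; FC and ICA results on
GSR'd data inherit the GSR negative-correlation artifact; the adaptive
clutter cut is a cumulative-energy rule standing in for an unspecified
prior-work criterion.
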