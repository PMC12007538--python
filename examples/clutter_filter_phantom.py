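"""SVD clutter filtering of a synthetic IQ phantom.

The phantom holds slowly moving tissue 40 dB above Doppler-shifted blood
confined to a vessel stripe, plus white noise.  Unfiltered Power Doppler
shows no vessel (ratio near 1); discarding the first 60 spatiotemporal
modes reveals it with a vessel/background ratio well above 10.
"""

import numpy as np

from smsfus import adaptive_ncut, cnr, make_iq_phantom, power_doppler, svd_decompose, svd_filter
from smsfus.synth import PhantomSpec

spec = PhantomSpec(seed=1)
block = make_iq_phantom(spec)
vessel = spec.vessel_mask

pd_raw = power_doppler(block)
pd_filt = power_doppler(svd_filter(block, n_cut=60))

ratio = lambda img: img[vessel].mean() / img[~vessel].mean()
print(f"vessel/background PD ratio, unfiltered : {ratio(pd_raw):6.2f}")
print(f"vessel/background PD ratio, n_cut = 60 : {ratio(pd_filt):6.2f}")
print(f"CNR after filtering                    : {cnr(pd_filt, vessel, ~vessel):6.2f} dB")

# the adaptive cut (cumulative 95% energy) tracks the dominant tissue mode
n_adapt = adaptive_ncut(svd_decompose(block), energy_fraction=0.95)
print(f"adaptive n_cut at 95% energy           : {n_adapt}")
print("(fixed n_cut = 60 is the motion-free default; the adaptive rule serves awake data)")
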