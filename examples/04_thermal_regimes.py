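"""Characterize thermal regimes from monthly sea-surface temperatures.

Synthesizes a 70-year monthly SST series for each study region with a
prescribed power-law spectrum plus annual cycle, then summarizes each
regime with its mean, coefficient of variation and spectral exponent
(the slope of log spectral density on log frequency; more negative =
variance concentrated in slow, "reddened" fluctuations).
"""

from coralipm import preset_sst, simulate_sst
from coralipm.environment import spectral_exponent, sst_summary
from coralipm.synthetic import PRESET_REGIONS

print(f"{'region':8s} {'mean':>6s} {'cv':>7s} {'beta':>7s} {'target':>7s}")
for region in PRESET_REGIONS:
    params = preset_sst(region, n_months=840, seed=1)
    series = simulate_sst(params)
    mean, cv = sst_summary(series)
    beta = spectral_exponent(series)
    print(f"{region:8s} {mean:6.2f} {cv:7.3f} {beta:7.2f} {params.beta:7.2f}")
print("\nSubtropical regions (AS, JS) run cooler and more variable than the")
print("tropical ones; the estimated exponent tracks the synthesis target")
print("(the annual cycle biases it slightly toward white).")
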