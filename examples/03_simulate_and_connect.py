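"""Simulate coupled-oscillator EEG and measure band connectivity.

Generates one recording at several theta coupling strengths and shows that
the epoch-mean PLI tracks the programmed coupling knob, while zero-lag
mixing (volume conduction) does not move it.
"""

import numpy as np

from eegmst import SimulationParams, band_mean_pli, bandpass, generate_recording, get_band

theta = get_band("theta")

for c in (0.0, 0.3, 0.6, 0.9):
    params = SimulationParams(
        n_channels=16, fs=256.0, n_epochs=6, bands=(theta,),
        amplitudes={"theta": 3.0}, coupling={"theta": c},
        noise_amplitude=2.0, seed=7,
    )
    rec = generate_recording(params)
    print(f"coupling c={c:.1f}: mean theta PLI = {band_mean_pli(bandpass(rec, theta)):.3f}")

print()
for v in (0.0, 0.4):
    params = SimulationParams(
        n_channels=16, fs=256.0, n_epochs=6, bands=(theta,),
        amplitudes={"theta": 3.0}, coupling={"theta": 0.0},
        noise_amplitude=1.0, mixing=v, seed=7,
    )
    rec = generate_recording(params)
    print(f"zero-lag mixing v={v:.1f} (no coupling): mean theta PLI = "
          f"{band_mean_pli(bandpass(rec, theta)):.3f}")
# PLI rises with the coupling knob but stays at its chance floor when only
# instantaneous mixing is added: the measure discounts volume conduction.
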