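"""Measure the magnitude response of the preprocessing filter chain.

The zero-phase high-pass (passband 0.1 Hz, stopband 0.05 Hz) composed with
the Savitzky-Golay smoother (order 20, frame 999) should suppress DC and
slow baseline drift by at least 60 dB while passing the cardiac band
around 1 Hz essentially unchanged.
"""

import numpy as np

from ppginv import composite_frequency_response

freqs = np.array([0.01, 0.05, 0.1, 0.5, 1.0, 2.0, 5.0, 10.0])
gains = composite_frequency_response(freqs, sampling_rate=800.0)

print("frequency [Hz]   gain [dB]")
for f, g in zip(freqs, gains):
    print(f"{f:12.2f} {20 * np.log10(max(g, 1e-12)):11.2f}")

# Below 0.05 Hz the chain attenuates by >= 60 dB (baseline wander and DC
# are removed); 0.5-2 Hz (resting heart rates) passes within a fraction of
# a dB; above ~5 Hz the Savitzky-Golay smoother rolls off sharp noise.
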