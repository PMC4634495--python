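"""Condition a synthetic breath recording and inspect the effect.

Renders one two-channel recording with wheeze, heart thumps and ambient
interference, applies DC removal, the 100-2000 Hz equiripple band-pass
and RLS adaptive noise suppression, and prints power figures before and
after each stage.
"""

import numpy as np

from aecopd import SoundParams, synth_breath, preprocess_recording
from aecopd.preprocess import remove_dc, bandpass

rec = synth_breath(
    SoundParams(duration_s=8.0, wheeze_intensity=0.5, crackle_rate=1.0,
                heart_level=0.6, ambient_level=0.4, seed=42)
)

raw = remove_dc(rec.main)
filtered = bandpass(raw, rate=rec.rate)
clean = preprocess_recording(rec)


def band_power(x, lo, hi, rate=8000):
    spec = np.abs(np.fft.rfft(x)) ** 2
    f = np.fft.rfftfreq(len(x), 1 / rate)
    return spec[(f >= lo) & (f < hi)].sum() / len(x) ** 2


print(f"sub-50 Hz band power   raw: {band_power(raw, 0, 50):.2e}   "
      f"band-passed: {band_power(filtered, 0, 50):.2e}")
print(f"total power  band-passed: {np.mean(filtered**2):.5f}   "
      f"after RLS: {np.mean(clean.main**2):.5f}")
# The band-pass crushes the heart-sound band (the stop band below
# 50 Hz drops by orders of magnitude); RLS then strips the residual
# ambient component correlated with the reference microphone, which
# shows as a further drop in total power.
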