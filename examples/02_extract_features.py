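"""Extract the 112-feature bank from a quiet and a wheezy recording.

Wheezes are tonal components in the few-hundred-Hz range; they raise the
relative power in the 200-800 Hz octaves and sharpen the spectrum
(higher crest factor, lower spectral entropy).
"""

from dataclasses import replace

from aecopd import SoundParams, synth_breath, extract_all, preprocess_recording

base = SoundParams(duration_s=6.0, wheeze_intensity=0.0, heart_level=0.2,
                   ambient_level=0.1, seed=7)

quiet = extract_all(preprocess_recording(synth_breath(base)))
wheezy = extract_all(preprocess_recording(
    synth_breath(replace(base, wheeze_intensity=0.8))
))

idx = {name: i for i, name in enumerate(quiet.names)}
print(f"{'feature':28s} {'quiet':>10s} {'wheezy':>10s}")
for name in ("stft_rp_200_400_mean", "stft_rp_400_800_mean",
             "stft_crest_mean", "stft_shannon_mean", "mfcc1_mean",
             "hht_if1_mean"):
    i = idx[name]
    print(f"{name:28s} {quiet.values[i]:10.3f} {wheezy.values[i]:10.3f}")
# The wheeze tones concentrate spectral mass: the crest factor rises
# and the Shannon entropy falls.  The octave relative powers move less
# here because the default wheeze frequencies (400/620 Hz) sit where
# normal breath noise already peaks; the first IMF's instantaneous
# frequency also shifts toward the tonal components.
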