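"""Independent brute-force oracles shared by the test modules.

Every function here re-derives a quantity loop-by-loop from its defining
formula, deliberately avoiding the package's vectorised implementations.
"""

import math

import numpy as np
from scipy import signal as ssig


def oracle_stft_params(p, f, alpha=2.0, q=2.0):
    """Loop-wise evaluation of the 13 spectral parameters."""
    mean_f = sum(fi * pi for fi, pi in zip(f, p))
    cum = 0.0
    median_f = f[-1]
    for fi, pi in zip(f, p):
        cum += pi
        if cum >= 0.5 - 1e-12:
            median_f = fi
            break
    crest = max(p) / (sum(p) / len(p))
    shannon = -sum(pi * math.log2(pi) for pi in p if pi > 0)
    renyi = math.log2(sum(pi**alpha for pi in p if pi > 0)) / (1 - alpha)
    tsallis = (1 - sum(pi**q for pi in p if pi > 0)) / (q - 1)
    bands = [(100, 200), (200, 400), (400, 800), (800, 2000)]
    rp = [sum(pi for fi, pi in zip(f, p) if lo <= fi < hi) for lo, hi in bands]
    m2 = sum((fi - mean_f) ** 2 * pi for fi, pi in zip(f, p))
    if m2 > 0:
        skew = sum((fi - mean_f) ** 3 * pi for fi, pi in zip(f, p)) / m2**1.5
        kurt = sum((fi - mean_f) ** 4 * pi for fi, pi in zip(f, p)) / m2**2
    else:
        skew = kurt = 0.0
    return np.array([mean_f, median_f, crest, shannon, renyi, tsallis,
                     *rp, m2, skew, kurt])


def oracle_mfcc_frame(frame, rate, n_filters=26, n_mfcc=13, floor=1e-10):
    """Independent mel filterbank + DCT evaluation for one raw frame."""
    n = len(frame)
    win = ssig.get_window("hamming", n, fftbins=True)
    mag = np.abs(np.fft.rfft(frame * win))
    freqs = np.fft.rfftfreq(n, 1 / rate)
    mel = lambda x: 2595.0 * np.log10(1 + x / 700.0)
    imel = lambda m: 700.0 * (10 ** (m / 2595.0) - 1)
    edges = imel(np.linspace(mel(0.0), mel(rate / 2), n_filters + 2))
    energies = np.zeros(n_filters)
    for i in range(n_filters):
        lo, cen, hi = edges[i], edges[i + 1], edges[i + 2]
        for fj, mj in zip(freqs, mag):
            if lo < fj < hi:
                wgt = (fj - lo) / (cen - lo) if fj <= cen else (hi - fj) / (hi - cen)
                energies[i] += wgt * mj
    loge = np.log(np.maximum(energies, floor))
    coefs = np.zeros(n_mfcc)
    for k in range(1, n_mfcc + 1):
        s = sum(
            loge[m] * math.cos(math.pi * k * (m + 0.5) / n_filters)
            for m in range(n_filters)
        )
        coefs[k - 1] = s * math.sqrt(2.0 / n_filters)
    return coefs


def oracle_subband_stats(c):
    """(mean|c|, mean power, SD, skewness, kurtosis), degenerate -> 0."""
    c = np.asarray(c, float)
    absmean = np.mean(np.abs(c))
    power = np.mean(c**2)
    sd = np.sqrt(np.mean((c - np.mean(c)) ** 2))
    if sd > 0:
        skew = np.mean(((c - np.mean(c)) / sd) ** 3)
        kurt = np.mean(((c - np.mean(c)) / sd) ** 4)
    else:
        skew = kurt = 0.0
    return absmean, power, sd, skew, kurt


def oracle_smooth(days, values, window=14):
    """Trailing calendar-window mean over available days."""
    out = {}
    for d in days:
        sel = [v for t, v in zip(days, values) if d - (window - 1) <= t <= d]
        out[d] = np.mean(sel, axis=0)
    return out


def oracle_labels(n_days, onsets, prodrome=7, recovery=14):
    """Enumerated labelling/masking rule with non-recovered-event drop."""
    kept = []
    for d in sorted(onsets):
        if not kept or d > kept[-1] + recovery:
            kept.append(d)
    label = [0] * n_days
    valid = [True] * n_days
    for d in kept:
        for t in range(max(0, d - prodrome), d + 1):
            label[t] = 1
        for t in range(d + 1, min(n_days, d + recovery + 1)):
            valid[t] = False
    for t in range(n_days):
        if not valid[t]:
            label[t] = 0
    return np.array(label), np.array(valid)
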