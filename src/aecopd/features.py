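"""The 112-dimensional respiratory-sound feature bank.

Each preprocessed recording is summarised by four feature families:

- 26 STFT features: 13 per-frame spectral parameters (characteristic
  frequencies, crest factor, Shannon/Rényi/Tsallis entropies, octave-band
  relative powers, spectral moments), mean and SD across frames.
- 26 MFCC features: the first 13 mel-frequency cepstral coefficients,
  mean and SD across frames.
- 36 DWT features: 6 statistics on each of the A1/A2/D2 subbands of a
  2-level decomposition, for the Daubechies-8 and Biorthogonal-1.5
  wavelets.
- 24 HHT features: mean and SD of the instantaneous frequencies of the
  first 12 intrinsic mode functions from empirical mode decomposition.

Wheezes raise tonal energy in the 100–1000 Hz octaves and sharpen the
spectrum (higher crest, lower entropy); the bank is designed so such
changes move many features at once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import fft as sfft
from scipy import signal as sig
from scipy.interpolate import CubicSpline

logger = logging.getLogger(__name__)

__all__ = [
    "FrameSpec",
    "FeatureConfig",
    "FeatureVector",
    "feature_names",
    "frame_signal",
    "frame_psd",
    "stft_frame_parameters",
    "stft_features",
    "mfcc_features",
    "dwt_features",
    "emd",
    "instantaneous_frequency",
    "hht_features",
    "extract_all",
    "STFT_PARAM_NAMES",
]

OCTAVE_BANDS: tuple[tuple[float, float], ...] = (
    (100.0, 200.0),
    (200.0, 400.0),
    (400.0, 800.0),
    (800.0, 2000.0),
)

STFT_PARAM_NAMES = (
    "mean_freq",
    "median_freq",
    "crest",
    "shannon",
    "renyi",
    "tsallis",
    "rp_100_200",
    "rp_200_400",
    "rp_400_800",
    "rp_800_2000",
    "moment2",
    "skewness",
    "kurtosis",
)


@dataclass
class FrameSpec:
    """Short-time framing: 64 ms Hamming frames with 25% overlap."""

    frame_ms: float = 64.0
    overlap_fraction: float = 0.25
    window: str = "hamming"

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError("overlap_fraction must be in [0, 1)")

    def frame_samples(self, rate: float) -> int:
        n = int(round(self.frame_ms * rate / 1000.0))
        if n < 2:
            raise ValueError("frame length must be >= 2 samples")
        return n

    def hop_samples(self, rate: float) -> int:
        n = self.frame_samples(rate)
        return max(1, int(round(n * (1 - self.overlap_fraction))))


@dataclass
class FeatureConfig:
    """Feature-bank configuration.

    ``renyi_order``/``tsallis_order`` default to 2, the quadratic-entropy
    convention in lung-sound work.  Counts of MFCCs (13) and IMFs (12)
    and the wavelet pair are fixed by the feature-vector layout.
    """

    renyi_order: float = 2.0
    tsallis_order: float = 2.0
    n_mel_filters: int = 26
    n_mfcc: int = 13
    wavelets: tuple[str, str] = ("db8", "bior1.5")
    n_imf: int = 12
    band_low: float = 100.0
    band_high: float = 2000.0
    octave_bands: tuple[tuple[float, float], ...] = OCTAVE_BANDS
    log_floor: float = 1e-10
    restrict_band: bool = True

    def __post_init__(self) -> None:
        for a in (self.renyi_order, self.tsallis_order):
            if a <= 0 or a == 1:
                raise ValueError("entropy orders must be > 0 and != 1")
        if self.n_mfcc != 13 or self.n_imf != 12:
            raise ValueError("feature layout fixes n_mfcc=13 and n_imf=12")


@dataclass
class FeatureVector:
    """The 112 named features of one recording, in canonical order."""

    values: np.ndarray
    names: tuple[str, ...]
    patient_id: str = ""
    day_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != 112 or len(self.names) != 112:
            raise ValueError("a feature vector has exactly 112 entries")
        if len(set(self.names)) != 112:
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")


def feature_names(config: FeatureConfig | None = None) -> tuple[str, ...]:
    """Canonical 112 feature names, in extraction order."""
    config = config or FeatureConfig()
    names: list[str] = []
    names += [f"stft_{p}_mean" for p in STFT_PARAM_NAMES]
    names += [f"stft_{p}_sd" for p in STFT_PARAM_NAMES]
    names += [f"mfcc{i}_mean" for i in range(1, 14)]
    names += [f"mfcc{i}_sd" for i in range(1, 14)]
    stats = ("absmean", "power", "sd", "ratio", "skew", "kurt")
    for wav in config.wavelets:
        tag = wav.replace(".", "")
        for band in ("a1", "a2", "d2"):
            names += [f"dwt_{tag}_{band}_{s}" for s in stats]
    names += [f"hht_if{i}_mean" for i in range(1, 13)]
    names += [f"hht_if{i}_sd" for i in range(1, 13)]
    return tuple(names)


# ---------------------------------------------------------------------------
# STFT family


def frame_signal(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    """Slice a signal into overlapping frames (n_frames, frame_len)."""
    x = np.asarray(x, dtype=float)
    if x.size < frame_len:
        raise ValueError(
            f"signal of {x.size} samples shorter than one {frame_len}-sample frame"
        )
    n_frames = (x.size - frame_len) // hop + 1
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def frame_psd(
    x: np.ndarray,
    frame_spec: FrameSpec | None = None,
    rate: float = 8000,
    config: FeatureConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame normalized power spectra on the analysis band.

    Returns ``(psd, freqs)`` where ``psd[i]`` is frame *i*'s power
    spectrum restricted to the 100–2000 Hz band and renormalized to unit
    total power.  Zero-energy frames are dropped.
    """
    frame_spec = frame_spec or FrameSpec()
    config = config or FeatureConfig()
    n = frame_spec.frame_samples(rate)
    frames = frame_signal(x, n, frame_spec.hop_samples(rate))
    win = sig.get_window(frame_spec.window, n, fftbins=True)
    spec = np.abs(np.fft.rfft(frames * win, axis=1)) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    if config.restrict_band:
        keep = (freqs >= config.band_low) & (freqs <= config.band_high)
        spec, freqs = spec[:, keep], freqs[keep]
    tot = spec.sum(axis=1)
    nz = tot > 0
    if not np.all(nz):
        logger.warning("dropping %d zero-energy frames", int((~nz).sum()))
    spec = spec[nz]
    if spec.shape[0] == 0:
        raise ValueError("no non-degenerate frames in signal")
    return spec / spec.sum(axis=1, keepdims=True), freqs


def stft_frame_parameters(
    psd: np.ndarray, freqs: np.ndarray, config: FeatureConfig | None = None
) -> np.ndarray:
    """The 13 spectral parameters of one normalized power spectrum.

    Order: mean/median frequency, crest factor, Shannon/Rényi/Tsallis
    entropies (bits; orders α=q=2 by default), relative power in the four
    octave bands, second central spectral moment, spectral skewness and
    kurtosis (standardized moments about the mean frequency).
    """
    config = config or FeatureConfig()
    p = np.asarray(psd, dtype=float)
    f = np.asarray(freqs, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("psd must be nonnegative and sum to 1")
    mean_f = float(np.dot(f, p))
    cum = np.cumsum(p)
    median_f = float(f[np.searchsorted(cum, 0.5 - 1e-12)])
    crest = float(p.max() / p.mean())
    pos = p[p > 0]
    shannon = float(-np.sum(pos * np.log2(pos)))
    a, q = config.renyi_order, config.tsallis_order
    renyi = float(np.log2(np.sum(pos**a)) / (1 - a))
    tsallis = float((1 - np.sum(pos**q)) / (q - 1))
    rp = [float(p[(f >= lo) & (f < hi)].sum()) for lo, hi in config.octave_bands]
    d = f - mean_f
    m2 = float(np.dot(d**2, p))
    if m2 > 0:
        skew = float(np.dot(d**3, p) / m2**1.5)
        kurt = float(np.dot(d**4, p) / m2**2)
    else:
        skew = kurt = 0.0
    return np.array(
        [mean_f, median_f, crest, shannon, renyi, tsallis, *rp, m2, skew, kurt]
    )


def stft_features(
    x: np.ndarray,
    frame_spec: FrameSpec | None = None,
    config: FeatureConfig | None = None,
    rate: float = 8000,
) -> np.ndarray:
    """Mean and SD across frames of the 13 spectral parameters (26 values)."""
    psd, freqs = frame_psd(x, frame_spec, rate, config)
    if psd.shape[0] < 2:
        raise ValueError("need >= 2 non-degenerate frames for SDs")
    params = np.array([stft_frame_parameters(p, freqs, config) for p in psd])
    return np.concatenate([params.mean(axis=0), params.std(axis=0, ddof=1)])


# ---------------------------------------------------------------------------
# MFCC family


def mel_filterbank(
    n_filters: int, n_fft: int, rate: float, f_low: float = 0.0, f_high: float | None = None
) -> np.ndarray:
    """Triangular mel filterbank (n_filters, n_fft//2 + 1)."""
    f_high = f_high if f_high is not None else rate / 2
    mel = lambda f: 2595.0 * np.log10(1.0 + f / 700.0)
    imel = lambda m: 700.0 * (10.0 ** (m / 2595.0) - 1.0)
    pts = imel(np.linspace(mel(f_low), mel(f_high), n_filters + 2))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    bank = np.zeros((n_filters, freqs.size))
    for i in range(n_filters):
        lo, cen, hi = pts[i], pts[i + 1], pts[i + 2]
        up = (freqs - lo) / (cen - lo)
        down = (hi - freqs) / (hi - cen)
        bank[i] = np.maximum(0.0, np.minimum(up, down))
    return bank


def mfcc_features(
    x: np.ndarray,
    frame_spec: FrameSpec | None = None,
    config: FeatureConfig | None = None,
    rate: float = 8000,
) -> np.ndarray:
    """Mean and SD of MFCC 1..13 across frames (26 values).

    Per frame: magnitude spectrum → triangular mel filterbank energies →
    log with floor → orthonormal DCT-II; coefficients 1–13 (the 0th,
    overall-energy coefficient is excluded).  Zero-energy frames are
    dropped from the aggregation.
    """
    frame_spec = frame_spec or FrameSpec()
    config = config or FeatureConfig()
    n = frame_spec.frame_samples(rate)
    frames = frame_signal(x, n, frame_spec.hop_samples(rate))
    win = sig.get_window(frame_spec.window, n, fftbins=True)
    mag = np.abs(np.fft.rfft(frames * win, axis=1))
    energetic = mag.sum(axis=1) > 0
    if energetic.sum() < 2:
        # a silent recording still yields finite features via the log floor
        energetic = np.ones(mag.shape[0], dtype=bool)
    mag = mag[energetic]
    bank = mel_filterbank(config.n_mel_filters, n, rate)
    logeng = np.log(np.maximum(bank @ mag.T, config.log_floor))  # (n_filt, n_frames)
    coefs = sfft.dct(logeng, type=2, axis=0, norm="ortho")
    cc = coefs[1 : config.n_mfcc + 1].T  # (n_frames, 13)
    return np.concatenate([cc.mean(axis=0), cc.std(axis=0, ddof=1)])


# ---------------------------------------------------------------------------
# DWT family


def _moment_stats(c: np.ndarray) -> tuple[float, float, float, float, float]:
    """(mean|c|, mean power, SD, skewness, kurtosis) with degenerate→0."""
    c = np.asarray(c, dtype=float)
    absmean = float(np.abs(c).mean())
    power = float(np.mean(c**2))
    sd = float(c.std(ddof=0))
    if sd > 0:
        z = (c - c.mean()) / sd
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4))
    else:
        skew = kurt = 0.0
    return absmean, power, sd, skew, kurt


def dwt_subbands(
    x: np.ndarray, wavelet: str, mode: str = "periodization"
) -> dict[str, np.ndarray]:
    """A1 (0–2000 Hz), A2 (0–1000 Hz) and D2 (1000–2000 Hz) coefficients
    of a 2-level discrete wavelet decomposition at 8000 Hz sampling."""
    x = np.asarray(x, dtype=float)
    w = pywt.Wavelet(wavelet)
    if x.size < 2 * w.dec_len:
        raise ValueError(
            f"signal of {x.size} samples too short for 2-level {wavelet} DWT"
        )
    a1, _d1 = pywt.dwt(x, w, mode=mode)
    a2, d2 = pywt.dwt(a1, w, mode=mode)
    return {"a1": a1, "a2": a2, "d2": d2}


def dwt_features(
    x: np.ndarray, config: FeatureConfig | None = None
) -> np.ndarray:
    """36 wavelet subband statistics (18 per wavelet).

    For each wavelet and each subband A1/A2/D2: mean absolute value,
    average power, SD, ratio of adjacent-subband absolute means
    (A1/A2, A2/D2, D2/A2; zero denominator → 0), skewness and kurtosis.
    """
    config = config or FeatureConfig()
    out: list[float] = []
    for wav in config.wavelets:
        sub = dwt_subbands(x, wav)
        absmeans = {k: float(np.abs(v).mean()) for k, v in sub.items()}
        ratio = {
            "a1": _safe_div(absmeans["a1"], absmeans["a2"]),
            "a2": _safe_div(absmeans["a2"], absmeans["d2"]),
            "d2": _safe_div(absmeans["d2"], absmeans["a2"]),
        }
        for band in ("a1", "a2", "d2"):
            absmean, power, sd, skew, kurt = _moment_stats(sub[band])
            out += [absmean, power, sd, ratio[band], skew, kurt]
    return np.array(out)


def _safe_div(a: float, b: float) -> float:
    return a / b if b != 0 else 0.0


# ---------------------------------------------------------------------------
# HHT family (empirical mode decomposition, implemented here)


def _extrema_indices(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    dx = np.diff(x)
    # collapse plateaus so flat-topped extrema are found once
    nz = np.nonzero(dx)[0]
    maxima, minima = [], []
    for i in range(len(nz) - 1):
        a, b = nz[i], nz[i + 1]
        if dx[a] > 0 and dx[b] < 0:
            maxima.append((a + 1 + b) // 2)
        elif dx[a] < 0 and dx[b] > 0:
            minima.append((a + 1 + b) // 2)
    return np.array(maxima, dtype=int), np.array(minima, dtype=int)


def _envelope(x: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    """Cubic-spline envelope through the extrema, mirror-extended at the
    edges to tame spline overshoot."""
    t = idx.astype(float)
    v = x[idx]
    # mirror the two nearest extrema across each boundary
    k = min(2, len(idx))
    t_pre = -t[:k][::-1]
    v_pre = v[:k][::-1]
    t_post = 2 * (n - 1) - t[-k:][::-1]
    v_post = v[-k:][::-1]
    tt = np.concatenate([t_pre, t, t_post])
    vv = np.concatenate([v_pre, v, v_post])
    tt, order = np.unique(tt, return_index=True)
    return CubicSpline(tt, vv[order])(np.arange(n))


def emd(
    x: np.ndarray,
    max_imfs: int = 12,
    sd_threshold: float = 0.2,
    max_sifts: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical mode decomposition.

    Repeatedly sifts the residual: upper/lower cubic-spline envelopes
    through the local extrema, subtract their mean, stop a sift pass once
    the normalized squared change (Cauchy SD criterion) drops below
    ``sd_threshold`` or after ``max_sifts`` passes.  Extraction stops when
    the residual has fewer than two extrema of either kind (monotonic
    trend) or ``max_imfs`` IMFs are out.

    Returns ``(imfs, residual)`` with ``imfs`` of shape (n_imfs, n).  The
    identity ``imfs.sum(axis=0) + residual == x`` holds to round-off by
    construction.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("empty signal")
    residual = x.copy()
    imfs: list[np.ndarray] = []
    for _ in range(max_imfs):
        maxima, minima = _extrema_indices(residual)
        if len(maxima) < 2 or len(minima) < 2:
            break
        h = residual
        for _sift in range(max_sifts):
            maxima, minima = _extrema_indices(h)
            if len(maxima) < 2 or len(minima) < 2:
                break
            upper = _envelope(h, maxima, n)
            lower = _envelope(h, minima, n)
            mean_env = 0.5 * (upper + lower)
            h_new = h - mean_env
            denom = np.sum(h**2)
            if denom > 0 and np.sum(mean_env**2) / denom < sd_threshold:
                h = h_new
                break
            h = h_new
        imfs.append(h)
        residual = residual - h
    return np.array(imfs).reshape(len(imfs), n), residual


def instantaneous_frequency(imf: np.ndarray, rate: float) -> np.ndarray:
    """IF of one IMF: derivative of the unwrapped analytic-signal phase / 2π."""
    analytic = sig.hilbert(np.asarray(imf, dtype=float))
    phase = np.unwrap(np.angle(analytic))
    return np.gradient(phase) * rate / (2 * np.pi)


def hht_features(
    x: np.ndarray, rate: float = 8000, config: FeatureConfig | None = None
) -> np.ndarray:
    """24 Hilbert–Huang features: mean and SD of 12 IMF instantaneous
    frequencies.

    The first and last 5% of each IF trace are trimmed before aggregation
    to suppress Hilbert end effects.  Missing IMF slots (signals with
    fewer than 12 modes) are zero-filled.
    """
    config = config or FeatureConfig()
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    imfs, _res = emd(x, max_imfs=config.n_imf)
    if imfs.shape[0] == 0:
        logger.warning("no IMFs extracted (constant or trivial signal)")
        return np.zeros(2 * config.n_imf)
    means = np.zeros(config.n_imf)
    sds = np.zeros(config.n_imf)
    trim = max(1, int(0.05 * x.size))
    for i, imf in enumerate(imfs):
        f_inst = instantaneous_frequency(imf, rate)
        core = f_inst[trim:-trim] if x.size > 2 * trim else f_inst
        means[i] = core.mean()
        sds[i] = core.std(ddof=1) if core.size > 1 else 0.0
    if imfs.shape[0] < config.n_imf:
        logger.warning(
            "only %d of %d IMFs extracted; remaining slots zero-filled",
            imfs.shape[0], config.n_imf,
        )
    return np.concatenate([means, sds])


# ---------------------------------------------------------------------------


def extract_all(
    recording,
    frame_spec: FrameSpec | None = None,
    config: FeatureConfig | None = None,
) -> FeatureVector:
    """Extract the full 112-feature vector from a preprocessed recording.

    Concatenation order: 13 STFT means, 13 STFT SDs, 13 MFCC means,
    13 MFCC SDs, 18 db8 DWT, 18 bior1.5 DWT, 12 IF means, 12 IF SDs.
    Deterministic given the recording and configuration.
    """
    frame_spec = frame_spec or FrameSpec()
    config = config or FeatureConfig()
    x = np.asarray(recording.main, dtype=float)
    rate = recording.rate
    values = np.concatenate(
        [
            stft_features(x, frame_spec, config, rate),
            mfcc_features(x, frame_spec, config, rate),
            dwt_features(x, config),
            hht_features(x, rate, config),
        ]
    )
    return FeatureVector(
        values,
        feature_names(config),
        patient_id=recording.patient_id,
        day_index=recording.day_index,
    )
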