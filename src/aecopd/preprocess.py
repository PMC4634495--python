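"""Signal conditioning for two-channel respiratory-sound recordings.

A daily recording carries the tracheal (main) channel and an environmental
reference channel, sampled at 8000 Hz.  Conditioning follows three steps:

1. DC removal (mean subtraction).
2. Equiripple band-pass FIR, 100–2000 Hz, ≥ 80 dB stop-band attenuation —
   the band where lung-sound energy lives; the filter also suppresses
   heart and muscle sounds below 100 Hz.
3. RLS adaptive noise suppression using the environmental reference and,
   optionally, a surrogate heart-sound reference (the main channel
   low-pass filtered below 100 Hz: heart sounds dominate that band).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sig
from scipy.io import wavfile

logger = logging.getLogger(__name__)

__all__ = [
    "AudioRecording",
    "FilterSpec",
    "read_wav",
    "write_wav",
    "remove_dc",
    "design_bandpass",
    "bandpass",
    "rls_denoise",
    "estimate_heart_reference",
    "preprocess_recording",
]


@dataclass
class AudioRecording:
    """One day's two-channel sound sample buffer at a fixed rate.

    ``main`` holds the tracheal-microphone samples, ``reference`` the
    environmental-microphone samples; both are dimensionless amplitudes
    in [-1, 1] of equal length.
    """

    patient_id: str
    day_index: int
    main: np.ndarray
    reference: np.ndarray
    rate: int = 8000

    def __post_init__(self) -> None:
        self.main = np.asarray(self.main, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if self.main.size == 0:
            raise ValueError("main channel is empty")
        if self.main.shape != self.reference.shape:
            raise ValueError(
                f"main ({self.main.shape}) and reference "
                f"({self.reference.shape}) must have equal length"
            )
        if self.rate <= 2 * 2000:
            raise ValueError(
                f"rate {self.rate} violates Nyquist for the 100-2000 Hz band"
            )


@dataclass
class FilterSpec:
    """Band-pass FIR design parameters.

    ``transition_hz`` is the width of each transition band flanking the
    pass band; ``ripple_db`` the allowed peak-to-peak pass-band deviation.
    """

    band_low: float = 100.0
    band_high: float = 2000.0
    stop_atten_db: float = 80.0
    transition_hz: float = 50.0
    ripple_db: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.band_low < self.band_high):
            raise ValueError("require 0 < band_low < band_high")
        if self.stop_atten_db <= 0:
            raise ValueError("stop_atten_db must be positive")


def read_wav(path, patient_id: str = "", day_index: int = 0) -> AudioRecording:
    """Read a 1- or 2-channel PCM WAV file into an :class:`AudioRecording`.

    Channel 0 maps to the main (tracheal) channel and channel 1 to the
    environmental reference.  Samples are rescaled to [-1, 1].  A
    single-channel file yields an all-zero reference and logs a warning.
    """
    rate, data = wavfile.read(path)
    if data.dtype.kind == "i":
        scale = float(np.iinfo(data.dtype).max) + 1.0
        data = data.astype(float) / scale
    elif data.dtype.kind == "u":  # 8-bit WAV is unsigned
        info = np.iinfo(data.dtype)
        data = (data.astype(float) - (info.max + 1) / 2.0) / ((info.max + 1) / 2.0)
    else:
        data = data.astype(float)
    if data.ndim == 1:
        logger.warning("%s: single-channel file, reference set to zeros", path)
        main, ref = data, np.zeros_like(data)
    elif data.shape[1] >= 2:
        main, ref = data[:, 0], data[:, 1]
    else:
        main, ref = data[:, 0], np.zeros_like(data[:, 0])
        logger.warning("%s: single-channel file, reference set to zeros", path)
    return AudioRecording(patient_id, day_index, main, ref, rate=int(rate))


def write_wav(path, recording: AudioRecording) -> None:
    """Write a recording as 2-channel 16-bit PCM WAV (main, reference)."""
    stacked = np.stack([recording.main, recording.reference], axis=1)
    clipped = np.clip(stacked, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(path, recording.rate, pcm)


def remove_dc(signal_in: np.ndarray) -> np.ndarray:
    """Subtract the arithmetic mean (DC component) from a signal."""
    x = np.asarray(signal_in, dtype=float)
    if x.size == 0:
        raise ValueError("cannot remove DC from an empty signal")
    return x - x.mean()


def _estimate_numtaps(spec: FilterSpec, rate: float) -> int:
    # Bellanger's estimate for an equiripple design; the tighter of the
    # two transition bands governs the order.
    dp = (10 ** (spec.ripple_db / 40.0) - 1) / (10 ** (spec.ripple_db / 40.0) + 1)
    ds = 10 ** (-spec.stop_atten_db / 20.0)
    dfrac = spec.transition_hz / rate
    n = int(np.ceil((-20 * np.log10(np.sqrt(dp * ds)) - 13) / (14.6 * dfrac)))
    return max(n, 8)


def design_bandpass(spec: FilterSpec, rate: float) -> np.ndarray:
    """Design the equiripple band-pass FIR and verify it on a dense grid.

    Parks–McClellan (``scipy.signal.remez``) with the order estimated by
    Bellanger's formula, increased until the evaluated frequency response
    meets the stop-band attenuation and pass-band ripple; falls back to a
    Kaiser-window design if the exchange algorithm fails to converge.
    """
    if spec.band_high >= rate / 2:
        raise ValueError(f"band_high {spec.band_high} >= Nyquist {rate / 2}")
    dp = (10 ** (spec.ripple_db / 40.0) - 1) / (10 ** (spec.ripple_db / 40.0) + 1)
    ds = 10 ** (-spec.stop_atten_db / 20.0)
    lo, hi, tw = spec.band_low, spec.band_high, spec.transition_hz
    bands = [0, lo - tw, lo, hi, hi + tw, rate / 2]
    numtaps = _estimate_numtaps(spec, rate)
    for attempt in range(6):
        n = int(numtaps * (1.15 ** attempt))
        n += (n % 2 == 0)  # type-I (odd length) for a band-pass
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                taps = sig.remez(
                    n, bands, [0, 1, 0], weight=[dp / ds, 1, dp / ds],
                    fs=rate, grid_density=32,
                )
        except Exception:  # pragma: no cover - remez convergence failure
            taps = None
        if taps is not None and np.all(np.isfinite(taps)) and _meets_spec(
            taps, spec, rate
        ):
            return taps
    # Kaiser fallback: guaranteed-by-construction attenuation.
    atten = spec.stop_atten_db + 5
    n, beta = sig.kaiserord(atten, tw / (rate / 2))
    n += (n % 2 == 0)
    taps = sig.firwin(
        n, [lo - tw / 2, hi + tw / 2], window=("kaiser", beta),
        pass_zero=False, fs=rate,
    )
    return taps


def _meets_spec(taps: np.ndarray, spec: FilterSpec, rate: float) -> bool:
    w, h = sig.freqz(taps, worN=8192, fs=rate)
    mag = np.abs(h)
    ds = 10 ** (-spec.stop_atten_db / 20.0)
    stop = (w <= spec.band_low - spec.transition_hz) | (
        w >= spec.band_high + spec.transition_hz
    )
    pas = (w >= spec.band_low) & (w <= spec.band_high)
    ripple_ok = np.all(
        np.abs(20 * np.log10(np.maximum(mag[pas], 1e-300))) <= spec.ripple_db
    )
    return bool(np.all(mag[stop] <= ds) and ripple_ok)


def bandpass(
    signal_in: np.ndarray,
    spec: FilterSpec | None = None,
    rate: float = 8000,
    taps: np.ndarray | None = None,
) -> np.ndarray:
    """Apply the band-pass FIR with group-delay compensation.

    The linear-phase filter delays by (numtaps-1)/2 samples; the output is
    shifted back so features stay aligned with the raw timeline.  Output
    length equals input length.
    """
    x = np.asarray(signal_in, dtype=float)
    if taps is None:
        taps = design_bandpass(spec or FilterSpec(), rate)
    if x.size <= taps.size:
        raise ValueError(
            f"signal length {x.size} must exceed filter length {taps.size}"
        )
    full = sig.fftconvolve(x, taps, mode="full")
    delay = (taps.size - 1) // 2
    return full[delay : delay + x.size]


def rls_denoise(
    primary: np.ndarray,
    reference: np.ndarray,
    forgetting: float = 0.995,
    order: int = 16,
    delta: float = 100.0,
    p_max: float = 1e4,
) -> np.ndarray:
    """Recursive-least-squares adaptive noise cancellation.

    Predicts the interference in ``primary`` from a tapped delay line of
    ``reference`` (or several references stacked column-wise) and returns
    the prediction error, i.e. the cleaned signal.  ``delta`` scales the
    initial inverse-correlation matrix P(0) = delta·I.

    With forgetting < 1 and a narrowband reference (e.g. a low-passed
    heart surrogate) the inverse-correlation matrix grows without bound
    along unexcited directions and the filter diverges; P is therefore
    symmetrized each step and its trace bounded at ``p_max`` per tap,
    which leaves well-excited problems untouched.
    """
    d = np.asarray(primary, dtype=float)
    refs = np.asarray(reference, dtype=float)
    if refs.ndim == 1:
        refs = refs[:, None]
    if refs.shape[0] != d.size:
        raise ValueError("primary and reference must have equal length")
    if not (0 < forgetting <= 1):
        raise ValueError("forgetting factor must be in (0, 1]")
    if order < 1:
        raise ValueError("order must be >= 1")
    if not np.any(refs):
        logger.warning("all-zero reference: RLS denoising skipped")
        return d.copy()

    n, n_ref = refs.shape
    m = order * n_ref
    w = np.zeros(m)
    P = np.eye(m) * delta
    trace_cap = m * max(p_max, delta)
    out = np.empty(n)
    lam_inv = 1.0 / forgetting
    buf = np.zeros((order, n_ref))
    for t in range(n):
        buf[1:] = buf[:-1]
        buf[0] = refs[t]
        u = buf.ravel()
        Pu = P @ u
        k = Pu * lam_inv / (1.0 + lam_inv * (u @ Pu))
        e = d[t] - w @ u
        w = w + k * e
        P = lam_inv * (P - np.outer(k, Pu))
        if forgetting < 1.0:
            P = 0.5 * (P + P.T)
            tr = np.trace(P)
            if tr > trace_cap:
                P *= trace_cap / tr
        out[t] = e
    return out


def estimate_heart_reference(
    main: np.ndarray, rate: float = 8000, cutoff_hz: float = 100.0
) -> np.ndarray:
    """Surrogate heart-sound reference: main channel low-passed below 100 Hz.

    Heart sounds dominate the sub-100 Hz band at the suprasternal notch, so
    the low-passed tracheal signal serves as an adaptive-filter reference
    when no dedicated heart estimate is available.
    """
    nyq = rate / 2
    sos = sig.butter(4, cutoff_hz / nyq, btype="low", output="sos")
    return sig.sosfiltfilt(sos, np.asarray(main, dtype=float))


def preprocess_recording(
    rec: AudioRecording,
    spec: FilterSpec | None = None,
    rls_order: int = 16,
    rls_forgetting: float = 0.995,
    enable_heart_reference: bool = True,
    taps: np.ndarray | None = None,
) -> AudioRecording:
    """Full conditioning chain: DC removal → band-pass → RLS denoising.

    Returns a new recording whose main channel is cleaned; the reference
    channel is passed through unchanged.
    """
    spec = spec or FilterSpec()
    raw = remove_dc(rec.main)
    filtered = bandpass(raw, spec, rec.rate, taps=taps)
    refs = [np.asarray(rec.reference, dtype=float)]
    if enable_heart_reference:
        refs.append(estimate_heart_reference(raw, rec.rate, spec.band_low))
    ref_mat = np.stack(refs, axis=1)
    if np.any(ref_mat):
        cleaned = rls_denoise(
            filtered, ref_mat, forgetting=rls_forgetting, order=rls_order
        )
    else:
        cleaned = filtered
    return AudioRecording(
        rec.patient_id, rec.day_index, cleaned, rec.reference, rate=rec.rate
    )
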