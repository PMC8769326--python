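"""Cough-part segmentation and the 34-dimensional acoustic feature vector.

Each detected event is split into an explosive first part, a turbulent
second part and — when a periodicity score exceeds 0.45 — a voiced third
part. Twelve feature types are extracted: the part-1 energy-peak index,
12 MFCCs per part averaged over frames, two autocorrelation voicing
scores (50-255 Hz and 10-100 Hz lag bands), the cross-frame variance of
8 LPC coefficients, the part-1/part-2 energy-peak ratio, mean ZCR,
kurtosis, skewness, sample-amplitude entropy and the spectral centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import rfft
from scipy.fftpack import dct
from scipy.stats import kurtosis as _kurtosis, skew as _skew

from .detect import SoundEvent

PART1_WINDOW_S = 0.079      # first part searched within [0, 0.079] s
VOICED_THRESHOLD = 0.45     # part-3 onset criterion on the Voiced_H track
VOICED_H_BAND = (50.0, 255.0)   # Hz, vocal-cord pitch range
VOICED_L_BAND = (10.0, 100.0)   # Hz, low-frequency snore periodicity
VOICED_H_WIN_S = 0.064      # analysis window holds the longest 50-255 Hz lag
VOICED_L_WIN_S = 0.128      # holds the longest 10-100 Hz lag (100 ms)
FRAME_S = 0.020
HOP_S = 0.010
N_MFCC = 12
N_MEL_FILTERS = 26
N_LPC = 8
ENTROPY_BINS = 100

#: Column order of the 34-dimensional feature vector.
FEATURE_NAMES: tuple[str, ...] = (
    ("energy_index",)
    + tuple(f"mfcc1_{i}" for i in range(1, 13))
    + tuple(f"mfcc2_{i}" for i in range(1, 13))
    + ("voiced_h", "voiced_l", "lpc_variance", "energy_ratio", "zcr",
       "kurtosis", "skewness", "entropy", "spectral_centroid")
)

__all__ = [
    "CoughPartition", "FeatureVector", "FEATURE_NAMES",
    "partition_event", "voiced_value", "lpc_variance", "extract_features",
    "frame_signal", "mfcc",
]


@dataclass
class CoughPartition:
    """Two/three-part segmentation of an event, in 20 ms / 10 ms-hop frames."""

    peak_frame: int            # frame of E_p within the first 0.079 s
    peak_energy: float         # E_p
    onset2: int                # frame index of the first local energy minimum
    onset3: int | None         # first frame with Voiced_H > 0.45, or None
    voiced_track: np.ndarray   # framewise Voiced_H from onset2 onward
    frame_energies: np.ndarray
    degenerate: bool = False   # no local minimum found before the event end

    @property
    def voiced(self) -> bool:
        return self.onset3 is not None


@dataclass
class FeatureVector:
    """The 34 named acoustic features of one event (order = FEATURE_NAMES)."""

    energy_index: float
    mfcc1: np.ndarray   # 12 coefficients, part 1
    mfcc2: np.ndarray   # 12 coefficients, part 2
    voiced_h: float
    voiced_l: float
    lpc_variance: float
    energy_ratio: float
    zcr: float
    kurtosis: float
    skewness: float
    entropy: float
    spectral_centroid: float

    def as_array(self) -> np.ndarray:
        out = np.concatenate([
            [self.energy_index], self.mfcc1, self.mfcc2,
            [self.voiced_h, self.voiced_l, self.lpc_variance,
             self.energy_ratio, self.zcr, self.kurtosis, self.skewness,
             self.entropy, self.spectral_centroid]])
        assert out.shape == (len(FEATURE_NAMES),)
        return out


def frame_signal(x: np.ndarray, sr: int, frame_s: float = FRAME_S,
                 hop_s: float = HOP_S) -> np.ndarray:
    """Slice ``x`` into overlapping frames (rows); pads to one frame if short."""
    n_frame = int(round(frame_s * sr))
    hop = int(round(hop_s * sr))
    if len(x) < n_frame:
        x = np.pad(x, (0, n_frame - len(x)))
    return sliding_window_view(x, n_frame)[::hop]


def voiced_value(frame: np.ndarray, f_low: float, f_high: float, sr: int) -> float:
    """Peak of the lag-0-normalized autocorrelation over lags [sr/f_high, sr/f_low].

    High values indicate periodicity with a fundamental inside the band.
    """
    lo = int(np.ceil(sr / f_high))
    hi = int(np.floor(sr / f_low))
    if len(frame) <= lo:
        raise ValueError(
            f"frame of {len(frame)} samples cannot resolve a lag of {lo}; "
            "use the extended analysis window")
    x = frame - frame.mean()
    e0 = float(np.dot(x, x))
    if e0 == 0.0:
        return 0.0
    n = len(x)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(spec * np.conj(spec), nfft)[:n]
    hi = min(hi, n - 1)
    lags = np.arange(lo, hi + 1)
    # unbiased estimate: a perfectly periodic signal then scores ~1 at its lag
    unbiased = ac[lo:hi + 1] * n / (n - lags)
    return float(unbiased.max() / e0)


def _voiced_track(x: np.ndarray, sr: int, band: tuple[float, float],
                  win_s: float, hop_s: float = HOP_S) -> np.ndarray:
    """Framewise voicing scores, one extended window centered per hop.

    The signal is zero-padded by half a window on each side so that score
    k reflects the neighbourhood of sample ``k * hop`` (batch FFT).
    """
    win = int(round(win_s * sr))
    hop = int(round(hop_s * sr))
    if len(x) < win:  # extended-frame path: single window spanning the event
        windows = x[None, :]
        win = len(x)
    else:
        padded = np.pad(x, win // 2)
        windows = sliding_window_view(padded, win)[::hop]
        windows = windows[:max(1, int(np.ceil(len(x) / hop)))]
    f_low, f_high = band
    lo = int(np.ceil(sr / f_high))
    hi = min(int(np.floor(sr / f_low)), win - 1)
    if lo >= win:
        return np.zeros(len(windows))
    w = windows - windows.mean(axis=1, keepdims=True)
    e0 = np.einsum("ij,ij->i", w, w)
    nfft = 1 << int(np.ceil(np.log2(2 * win)))
    spec = np.fft.rfft(w, nfft, axis=1)
    ac = np.fft.irfft(spec * np.conj(spec), nfft, axis=1)[:, :win]
    lags = np.arange(lo, hi + 1)
    peak = (ac[:, lo:hi + 1] * win / (win - lags)).max(axis=1)
    out = np.zeros(len(windows))
    nz = e0 > 0
    out[nz] = peak[nz] / e0[nz]
    return out


def partition_event(ev: SoundEvent) -> CoughPartition:
    """Locate the part boundaries of a detected event.

    E_p is the maximum 20 ms-frame energy within the first 0.079 s; the
    second part starts at the first local energy minimum after the E_p
    frame; the third part starts at the first frame (from onset2 on) whose
    Voiced_H score exceeds 0.45, if any.
    """
    x = ev.samples
    sr = ev.sample_rate
    frames = frame_signal(x, sr)
    E = np.einsum("ij,ij->i", frames, frames)

    hop = int(round(HOP_S * sr))
    n_first = max(1, int(PART1_WINDOW_S * sr) // hop)
    peak_frame = int(np.argmax(E[:n_first]))
    peak_energy = float(E[peak_frame])

    onset2 = None
    for k in range(peak_frame + 1, len(E) - 1):
        if E[k] <= E[k - 1] and E[k] <= E[k + 1]:
            onset2 = k
            break
    degenerate = onset2 is None
    if onset2 is None:
        onset2 = min(peak_frame + 1, len(E) - 1)

    tail = x[onset2 * hop:]
    track = _voiced_track(tail, sr, VOICED_H_BAND, VOICED_H_WIN_S)
    above = np.nonzero(track > VOICED_THRESHOLD)[0]
    onset3 = onset2 + int(above[0]) if len(above) else None

    return CoughPartition(
        peak_frame=peak_frame, peak_energy=peak_energy, onset2=onset2,
        onset3=onset3, voiced_track=track, frame_energies=E,
        degenerate=degenerate)


# ---------------------------------------------------------------------------
# MFCC


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def _mel_filterbank(sr: int, n_fft: int, n_filters: int = N_MEL_FILTERS,
                    f_min: float = 0.0, f_max: float | None = None) -> np.ndarray:
    f_max = f_max or sr / 2.0
    pts = _mel_to_hz(np.linspace(_hz_to_mel(f_min), _hz_to_mel(f_max), n_filters + 2))
    bins = np.floor((n_fft + 1) * pts / sr).astype(int)
    fb = np.zeros((n_filters, n_fft // 2 + 1))
    for i in range(n_filters):
        a, b, c = bins[i], bins[i + 1], bins[i + 2]
        if b > a:
            fb[i, a:b] = (np.arange(a, b) - a) / (b - a)
        if c > b:
            fb[i, b:c] = (c - np.arange(b, c)) / (c - b)
    return fb


def mfcc(frames: np.ndarray, sr: int, n_coeffs: int = N_MFCC) -> np.ndarray:
    """MFCCs c1..c12 per frame (rows); 26-filter mel bank, Hamming window.

    c0 is excluded: it tracks overall log-energy, which the dedicated
    energy features already capture, and dropping it makes the
    coefficients invariant to amplitude scaling.
    """
    n_frame = frames.shape[1]
    n_fft = 1 << int(np.ceil(np.log2(n_frame)))
    win = np.hamming(n_frame)
    spec = np.abs(rfft(frames * win, n_fft, axis=1)) ** 2
    fb = _mel_filterbank(sr, n_fft)
    energies = spec @ fb.T
    logmel = np.log(np.maximum(energies, 1e-12))
    cc = dct(logmel, type=2, norm="ortho", axis=1)
    return cc[:, 1:n_coeffs + 1]


# ---------------------------------------------------------------------------
# LPC


def _levinson(r: np.ndarray, order: int) -> np.ndarray:
    """Levinson-Durbin recursion; returns AR coefficients a[1..order]."""
    a = np.zeros(order)
    err = r[0]
    if err <= 0:
        raise np.linalg.LinAlgError("non-positive zero-lag autocorrelation")
    for i in range(order):
        acc = r[i + 1] - np.dot(a[:i], r[i:0:-1])
        k = acc / err
        a_new = a.copy()
        a_new[i] = k
        a_new[:i] = a[:i] - k * a[:i][::-1]
        a = a_new
        err *= (1.0 - k * k)
        if err <= 0:
            raise np.linalg.LinAlgError("singular prediction error")
    return a


def lpc_frames(frames: np.ndarray, order: int = N_LPC) -> np.ndarray:
    """Autocorrelation-method LPC per frame; silent/unstable frames give zeros."""
    n = frames.shape[1]
    win = np.hamming(n)
    w = frames * win
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(w, nfft, axis=1)
    ac = np.fft.irfft(spec * np.conj(spec), nfft, axis=1)[:, :order + 1]
    out = np.zeros((len(frames), order))
    for i, r in enumerate(ac):
        try:
            out[i] = _levinson(r, order)
        except np.linalg.LinAlgError:
            pass  # leave zeros for degenerate frames
    return out


def lpc_variance(ev: SoundEvent, order: int = N_LPC) -> float:
    """Mean over coefficients of the cross-frame variance of 8 LPCs.

    ``(1/M) * sum_m (1/(K-1)) * sum_k (a_m(k) - mean_m)^2`` over the K
    frames of the event — a non-stationarity measure.
    """
    frames = frame_signal(ev.samples, ev.sample_rate)
    if len(frames) < 2:
        raise ValueError("LPC variance needs at least 2 frames")
    coeffs = lpc_frames(frames, order)
    return float(np.mean(coeffs.var(axis=0, ddof=1)))


# ---------------------------------------------------------------------------
# scalar features


def _zcr(frames: np.ndarray) -> float:
    s = np.where(frames >= 0, 1.0, -1.0)
    return float(np.abs(np.diff(s, axis=1)).sum(axis=1).mean() / 2.0)


def _entropy(x: np.ndarray, n_bins: int = ENTROPY_BINS) -> float:
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / len(x)
    return float(-(p * np.log2(p)).sum())


def _spectral_centroid(x: np.ndarray, sr: int) -> float:
    # power weighting keeps window sidelobes from dragging the centroid
    n_fft = 1 << int(np.ceil(np.log2(len(x))))
    power = np.abs(rfft(x * np.hamming(len(x)), n_fft)) ** 2
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sr)
    total = power.sum()
    if total == 0:
        return 0.0
    return float((freqs * power).sum() / total)


def extract_features(ev: SoundEvent, part: CoughPartition | None = None) -> FeatureVector:
    """Extract the full 34-dimensional feature vector from one event."""
    if part is None:
        part = partition_event(ev)
    x = ev.samples
    sr = ev.sample_rate
    frames = frame_signal(x, sr)
    E = part.frame_energies

    onset2 = part.onset2
    end2 = part.onset3 if part.onset3 is not None else len(frames)
    part1 = frames[:max(onset2, 1)]
    part2 = frames[onset2:max(end2, onset2 + 1)]
    if len(part2) == 0:
        part2 = frames[onset2:] if onset2 < len(frames) else frames[-1:]

    mfcc1 = mfcc(part1, sr).mean(axis=0)
    mfcc2 = mfcc(part2, sr).mean(axis=0)

    vh = float(_voiced_track(x, sr, VOICED_H_BAND, VOICED_H_WIN_S).max())
    vl = float(_voiced_track(x, sr, VOICED_L_BAND, VOICED_L_WIN_S).max())

    # part-2 energy peak; degenerate partitions fall back to the post-onset2 peak
    e2_span = E[onset2:end2]
    if len(e2_span) == 0:
        e2_span = E[onset2:] if onset2 < len(E) else E[-1:]
    e2_peak = float(e2_span.max())
    energy_ratio = part.peak_energy / e2_peak if e2_peak > 0 else np.inf

    return FeatureVector(
        energy_index=float(part.peak_frame),
        mfcc1=mfcc1,
        mfcc2=mfcc2,
        voiced_h=vh,
        voiced_l=vl,
        lpc_variance=lpc_variance(ev) if len(frames) >= 2 else 0.0,
        energy_ratio=float(energy_ratio),
        zcr=_zcr(frames),
        kurtosis=float(_kurtosis(x, fisher=False)) if x.std() > 0 else 0.0,
        skewness=float(_skew(x)) if x.std() > 0 else 0.0,
        entropy=_entropy(x),
        spectral_centroid=_spectral_centroid(x, sr),
    )
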