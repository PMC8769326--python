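"""Synthetic nocturnal-recording generator with ground-truth annotations.

Produces whole-night-style waveforms containing three event classes —
coughs (explosive onset, turbulent second phase, optional voiced tail
with a 2:3 voiced:unvoiced default ratio), semi-periodic low-frequency
snores and broadband transient noises — over a pink-noise background,
plus a 5-stage Markov-chain hypnogram at 30 s epochs. Everything is
driven by one seeded random generator so nights are bit-reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

STAGES = ("W", "REM", "N1", "N2", "N3")
EPOCH_S = 30.0

#: Default 30 s-epoch stage-transition matrix (rows/cols ordered as STAGES).
#: Chosen so the stationary occupancy is dominated by N2 (~44%), with
#: plausible dwell times; not fitted to any particular cohort.
DEFAULT_TRANSITIONS = np.array([
    [0.80, 0.02, 0.15, 0.03, 0.00],   # W
    [0.03, 0.85, 0.05, 0.07, 0.00],   # REM
    [0.05, 0.05, 0.60, 0.30, 0.00],   # N1
    [0.02, 0.04, 0.03, 0.85, 0.06],   # N2
    [0.01, 0.02, 0.00, 0.12, 0.85],   # N3
])

__all__ = [
    "SynthConfig", "EventAnnotation", "SyntheticNight", "Hypnogram",
    "generate_event", "generate_hypnogram", "generate_night",
    "snore_wave", "cough_wave", "noise_wave", "pink_noise",
    "stage_dependent_cough_times",
    "write_wav", "write_annotations_csv", "write_hypnogram_tsv",
    "DEFAULT_TRANSITIONS", "STAGES",
]


@dataclass
class Hypnogram:
    """Sleep-stage labels, one per 30 s epoch."""

    stages: list[str]
    epoch_length: float = EPOCH_S
    start_time: float = 0.0

    def __post_init__(self) -> None:
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        if self.epoch_length != EPOCH_S:
            raise ValueError("epoch_length must be 30 s")

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def span(self) -> float:
        return self.start_time + len(self.stages) * self.epoch_length

    def stage_at(self, t: float) -> str:
        """Stage of the half-open epoch [t0, t0+30) containing time ``t``."""
        idx = int((t - self.start_time) // self.epoch_length)
        if not (0 <= idx < len(self.stages)):
            raise ValueError(f"time {t} s outside hypnogram span")
        return self.stages[idx]


@dataclass
class SynthConfig:
    """Knobs of the synthetic night generator."""

    sample_rate: int = 16_000
    night_duration: float = 600.0
    events_per_hour: dict = field(
        default_factory=lambda: {"cough": 20.0, "snore": 60.0, "noise": 60.0})
    voiced_cough_fraction: float = 0.4      # voiced:unvoiced = 2:3
    cough_duration_range: tuple[float, float] = (0.3, 1.0)
    snore_f0_range: tuple[float, float] = (30.0, 80.0)
    voiced_f0_range: tuple[float, float] = (80.0, 250.0)
    event_to_background_snr: float = 46.0   # dB, event peak over background RMS
    amplitude_range: tuple[float, float] = (0.4, 0.9)
    min_event_gap: float = 0.25             # s of background between events
    rng_seed: int = 0
    transition_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITIONS.copy())

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.events_per_hour.values()):
            raise ValueError("event rates must be >= 0")
        if not (0 <= self.voiced_cough_fraction <= 1):
            raise ValueError("voiced_cough_fraction must be in [0, 1]")
        lo, hi = self.cough_duration_range
        if not (0 < lo <= hi < self.night_duration):
            raise ValueError("cough_duration_range must lie in (0, night_duration)")
        if not (10 <= self.snore_f0_range[0] <= self.snore_f0_range[1] <= 100):
            raise ValueError("snore_f0_range must lie within [10, 100] Hz")
        if not (50 <= self.voiced_f0_range[0] <= self.voiced_f0_range[1] <= 255):
            raise ValueError("voiced_f0_range must lie within [50, 255] Hz")


@dataclass
class EventAnnotation:
    onset_s: float
    offset_s: float
    label: str                 # cough | snore | noise
    voiced: bool = False

    @property
    def duration(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class SyntheticNight:
    samples: np.ndarray
    sample_rate: int
    annotations: list[EventAnnotation]
    hypnogram: Hypnogram


# ---------------------------------------------------------------------------
# waveform builders


def _fade(n_samples: int, n_fade: int) -> np.ndarray:
    """Unity envelope with raised-cosine edges of ``n_fade`` samples."""
    env = np.ones(n_samples)
    n_fade = min(n_fade, n_samples // 2)
    if n_fade > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_fade) / n_fade))
        env[:n_fade] = ramp
        env[-n_fade:] = ramp[::-1]
    return env


def cough_wave(duration: float, voiced: bool, sr: int, rng: np.random.Generator,
               voiced_f0: float = 150.0, amplitude: float = 1.0) -> np.ndarray:
    """Two/three-phase cough: explosive burst, turbulent decay, voiced tail.

    Phase 1 is 30-80 ms of white noise under a fast-attack/exponential-decay
    envelope; phase 2 is turbulence 6-14 dB below the phase-1 peak; the
    voiced tail (iff ``voiced``) is a harmonic series at ``voiced_f0``.
    Ends with a 10 ms raised-cosine fade so the offset stays sharp.
    """
    n = int(round(duration * sr))
    t = np.arange(n) / sr

    # one continuous envelope: 2 ms attack to 1, explosive decay to the
    # phase-2 level over 30-80 ms, then slow turbulent decay to the end
    n1 = int(rng.uniform(0.030, 0.080) * sr)
    attack = int(0.002 * sr)
    level2 = 10.0 ** (-rng.uniform(10.0, 16.0) / 20.0)
    env = np.empty(n)
    env[:attack] = np.linspace(0, 1, attack, endpoint=False)
    k1 = np.arange(n1 - attack)
    env[attack:n1] = np.exp(np.log(level2) * k1 / max(1, n1 - attack - 1))
    k2 = np.arange(n - n1)
    env[n1:] = level2 * np.exp(-0.7 * k2 / max(1, n - n1))
    x = env * rng.standard_normal(n)

    if voiced:
        n2_end = max(n1, int(n * rng.uniform(0.45, 0.65)))
        tail = np.zeros(n)
        tt = t[n2_end:]
        for h in range(1, 9):
            if h * voiced_f0 < 2000:
                tail[n2_end:] += np.sin(2 * np.pi * h * voiced_f0 * tt
                                        + rng.uniform(0, 2 * np.pi)) / h
        if tail.any():
            tail /= np.abs(tail).max()
        x[n2_end:] *= 0.3          # turbulence fades as the voiced tail enters
        x += 2.5 * level2 * tail   # harmonic tail at the phase-2 scale

    x *= _fade(n, int(0.010 * sr))
    peak = np.abs(x).max()
    if peak > 0:
        x = x / peak * amplitude
    return x


def snore_wave(f0: float, duration: float, sr: int, rng: np.random.Generator,
               amplitude: float = 1.0) -> np.ndarray:
    """Semi-periodic snore: resonant wavelet train at ``f0`` under an AM arc.

    The dominant autocorrelation lag equals ``round(sr / f0)``.
    """
    n = int(round(duration * sr))
    period = int(round(sr / f0))
    tw = np.arange(int(0.020 * sr)) / sr
    wavelet = np.exp(-tw * 120.0) * np.sin(2 * np.pi * 180.0 * tw)
    pulses = np.zeros(n)
    for k in range(0, n, period):
        pulses[k] = 1.0 + 0.1 * rng.standard_normal()
    x = np.convolve(pulses, wavelet)[:n]
    x += 0.02 * rng.standard_normal(n)
    x *= 0.55 + 0.45 * np.hanning(n)   # shallow AM arc keeps the edges energetic
    x *= _fade(n, int(0.010 * sr))
    peak = np.abs(x).max()
    if peak > 0:
        x = x / peak * amplitude
    return x


def noise_wave(duration: float, sr: int, rng: np.random.Generator,
               amplitude: float = 1.0) -> np.ndarray:
    """Transient ambient noise (not cough-like): one of three subtypes.

    Low-frequency rumble (e.g. bed movement), a repeated click pair
    (device manipulation) or a slow-attack broadband hiss. None has the
    cough's explosive onset followed by decaying turbulence.
    """
    from scipy.signal import sosfilt, butter

    n = int(round(duration * sr))
    kind = rng.integers(0, 3)
    if kind == 0:      # rumble: band-passed noise, low spectral centroid
        f_hi = rng.uniform(300.0, 900.0)
        sos = butter(4, f_hi, btype="lowpass", fs=sr, output="sos")
        x = sosfilt(sos, rng.standard_normal(n))
        x *= 0.6 + 0.4 * np.hanning(n)
    elif kind == 1:    # click pair: two short broadband taps over a bed of noise
        x = 0.35 * rng.standard_normal(n)
        for pos in (int(0.1 * n), int(rng.uniform(0.5, 0.8) * n)):
            w = int(0.015 * sr)
            x[pos:pos + w] += rng.standard_normal(min(w, n - pos)) * \
                np.exp(-np.arange(min(w, n - pos)) / (0.3 * w))
    else:              # hiss: slow rise then sustain
        rise = int(0.4 * n)
        env = np.concatenate([np.linspace(0.45, 1.0, rise), np.ones(n - rise)])
        x = env * rng.standard_normal(n)
    x *= _fade(n, int(0.010 * sr))
    peak = np.abs(x).max()
    if peak > 0:
        x = x / peak * amplitude
    return x


def pink_noise(n: int, rng: np.random.Generator,
               sr: int = 16_000, corner_hz: float = 40.0) -> np.ndarray:
    """1/f-shaped noise via spectral shaping, unit RMS.

    The 1/f slope is applied only above ``corner_hz`` (flat below): infra-
    sonic energy would make 20 ms frame energies strongly correlated
    across frames, which no event detector can distinguish from events.
    """
    chunk = 1 << 19   # power-of-2 FFTs; whole-night lengths factor badly
    parts = []
    remaining = n
    while remaining > 0:
        m = min(chunk, remaining) if remaining >= 256 else remaining
        m_fft = m if m == chunk else (1 << max(8, int(np.ceil(np.log2(m)))))
        white = rng.standard_normal(m_fft)
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(m_fft, d=1.0 / sr)
        spec /= np.sqrt(np.maximum(f, corner_hz))
        parts.append(np.fft.irfft(spec, m_fft)[:m])
        remaining -= m
    x = np.concatenate(parts)
    return x / x.std()


def generate_event(kind: str, voiced: bool, config: SynthConfig,
                   rng: np.random.Generator, amplitude: float | None = None
                   ) -> np.ndarray:
    """Generate one event waveform of the given kind; peak amplitude <= 1."""
    sr = config.sample_rate
    if amplitude is None:
        amplitude = rng.uniform(*config.amplitude_range)
    if kind == "cough":
        duration = rng.uniform(*config.cough_duration_range)
        f0 = rng.uniform(*config.voiced_f0_range)
        return cough_wave(duration, voiced, sr, rng, voiced_f0=f0,
                          amplitude=amplitude)
    if kind == "snore":
        duration = rng.uniform(0.2, 1.0)
        f0 = rng.uniform(*config.snore_f0_range)
        return snore_wave(f0, duration, sr, rng, amplitude=amplitude)
    if kind == "noise":
        duration = rng.uniform(0.2, 1.0)
        return noise_wave(duration, sr, rng, amplitude=amplitude)
    raise ValueError(f"unknown event kind: {kind!r}")


# ---------------------------------------------------------------------------
# hypnogram


def generate_hypnogram(night_duration: float, rng: np.random.Generator,
                       transition_matrix: np.ndarray | None = None,
                       start_stage: str = "W") -> Hypnogram:
    """Sample a 5-state Markov-chain hypnogram, one stage per 30 s epoch."""
    if night_duration < EPOCH_S:
        raise ValueError("night_duration must cover at least one 30 s epoch")
    P = DEFAULT_TRANSITIONS if transition_matrix is None else np.asarray(transition_matrix)
    if P.shape != (5, 5) or not np.allclose(P.sum(axis=1), 1.0):
        raise ValueError("transition matrix must be 5x5 row-stochastic")
    n_epochs = int(night_duration // EPOCH_S)
    cum = np.cumsum(P, axis=1)
    state = STAGES.index(start_stage)
    out = [STAGES[state]]
    for _ in range(n_epochs - 1):
        state = int(np.searchsorted(cum[state], rng.random(), side="right"))
        state = min(state, 4)
        out.append(STAGES[state])
    return Hypnogram(stages=out)


# ---------------------------------------------------------------------------
# night assembly


def _poisson_counts(config: SynthConfig, rng: np.random.Generator) -> dict[str, int]:
    hours = config.night_duration / 3600.0
    return {k: int(rng.poisson(rate * hours))
            for k, rate in config.events_per_hour.items()}


def generate_night(config: SynthConfig,
                   rng: np.random.Generator | None = None) -> SyntheticNight:
    """Assemble a full annotated night.

    Event counts are Poisson draws per class; events are placed uniformly
    with overlap rejection (up to 100 retries each) over a pink-noise
    background whose RMS sits ``event_to_background_snr`` dB below the
    nominal peak event amplitude.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    sr = config.sample_rate
    n_total = int(round(config.night_duration * sr))

    bg_rms = 10.0 ** (-config.event_to_background_snr / 20.0)
    samples = bg_rms * pink_noise(n_total, rng, sr=sr)

    hyp = generate_hypnogram(max(config.night_duration, EPOCH_S), rng,
                             config.transition_matrix)

    counts = _poisson_counts(config, rng)
    plan: list[tuple[str, bool]] = []
    for kind, cnt in counts.items():
        for _ in range(cnt):
            voiced = kind == "cough" and rng.random() < config.voiced_cough_fraction
            plan.append((kind, voiced))
    order = rng.permutation(len(plan))

    gap = int(config.min_event_gap * sr)
    placed: list[tuple[int, int]] = []
    annotations: list[EventAnnotation] = []
    for idx in order:
        kind, voiced = plan[idx]
        wave = generate_event(kind, voiced, config, rng)
        n = len(wave)
        ok = False
        for _ in range(100):
            start = int(rng.integers(0, n_total - n))
            if all(start >= e + gap or start + n <= s - gap for s, e in placed):
                ok = True
                break
        if not ok:
            raise RuntimeError(
                "could not place event without overlap after 100 retries; "
                "reduce event rates or lengthen the night")
        samples[start:start + n] += wave
        placed.append((start, start + n))
        annotations.append(EventAnnotation(
            onset_s=start / sr, offset_s=(start + n) / sr,
            label=kind, voiced=voiced))

    annotations.sort(key=lambda a: a.onset_s)
    peak = np.abs(samples).max()
    if peak > 1.0:
        samples /= peak
    return SyntheticNight(samples=samples, sample_rate=sr,
                          annotations=annotations, hypnogram=hyp)


def stage_dependent_cough_times(hyp: Hypnogram, rates_per_hour: dict[str, float],
                                rng: np.random.Generator) -> list[float]:
    """Cough onset times from a stage-modulated Poisson process.

    Each epoch contributes Poisson(rate[stage] / 3600 * 30) coughs placed
    uniformly within it. Used to plant stage-rate effects for analysis
    tests without synthesizing audio.
    """
    times: list[float] = []
    for i, stage in enumerate(hyp.stages):
        lam = rates_per_hour.get(stage, 0.0) * hyp.epoch_length / 3600.0
        k = rng.poisson(lam)
        t0 = hyp.start_time + i * hyp.epoch_length
        times.extend(sorted(t0 + rng.random(k) * hyp.epoch_length))
    return times


# ---------------------------------------------------------------------------
# writers


def write_wav(night: SyntheticNight, path: str | Path) -> None:
    """Write the waveform as 16-bit PCM WAV."""
    x = np.clip(night.samples, -1.0, 1.0)
    wavfile.write(path, night.sample_rate, (x * 32767).astype(np.int16))


def write_annotations_csv(annotations: list[EventAnnotation],
                          path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["onset_s", "offset_s", "label", "voiced"])
        for a in annotations:
            w.writerow([f"{a.onset_s:.6f}", f"{a.offset_s:.6f}", a.label,
                        int(a.voiced)])


def read_annotations_csv(path: str | Path) -> list[EventAnnotation]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(EventAnnotation(
                onset_s=float(row["onset_s"]), offset_s=float(row["offset_s"]),
                label=row["label"], voiced=bool(int(row["voiced"]))))
    return out


def write_hypnogram_tsv(hyp: Hypnogram, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("epoch_index\tstage\n")
        for i, s in enumerate(hyp.stages):
            fh.write(f"{i}\t{s}\n")
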