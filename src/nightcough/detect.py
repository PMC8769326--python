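"""Energy-based sound-event detection with recording-adaptive thresholds.

Per-frame energies (20 ms frames, 50% overlap, rectangular window) are
histogrammed in dB over the whole recording. Three linear-energy
thresholds are derived from the histogram: ``th1`` triggers an event,
``th2`` locates its onset scanning left, ``th3`` its offset scanning
right. Events outside the 0.15-1.1 s duration band are dropped.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .preprocess import Recording

DEFAULT_FRAME_S = 0.020
DEFAULT_OVERLAP = 0.5
DEFAULT_MIN_DUR = 0.15
DEFAULT_MAX_DUR = 1.1
# empirically set on the synthetic training split so that the background
# tail < th1 < weakest event peak AND the 0.01*th1 offset floor clears the
# background's upper percentiles (+23 dB on linear energy)
DEFAULT_A = 200.0
DEFAULT_B = 0.08
DEFAULT_N_BINS = 100
_DB_EPS = 1e-12

__all__ = [
    "EnergySeries",
    "EnergyHistogram",
    "EnergyThresholds",
    "SoundEvent",
    "frame_energy",
    "build_histogram",
    "compute_thresholds",
    "detect_events",
    "write_events_csv",
    "write_label_track",
]


@dataclass
class EnergySeries:
    """Per-frame energies E(j) = sum of squared samples in frame j.

    Frame j covers samples ``[j*hop, j*hop + frame_samples)``.
    """

    E: np.ndarray
    frame_length: float
    overlap: float
    sample_rate: int

    @property
    def frame_samples(self) -> int:
        return int(round(self.frame_length * self.sample_rate))

    @property
    def hop_samples(self) -> int:
        return int(round(self.frame_samples * (1.0 - self.overlap)))

    @property
    def hop_s(self) -> float:
        return self.hop_samples / self.sample_rate

    def frame_start_sample(self, j: int) -> int:
        return j * self.hop_samples


@dataclass
class EnergyHistogram:
    """Histogram of per-frame energy in dB (10*log10(E + eps))."""

    bin_edges: np.ndarray  # dB, len n_bins + 1
    counts: np.ndarray

    @property
    def modal_bin(self) -> int:
        return int(np.argmax(self.counts))

    @property
    def bin_centers_db(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def bin_energy(self, j: int) -> float:
        """Linear energy at the centre of bin ``j``."""
        return float(10.0 ** (self.bin_centers_db[j] / 10.0))


@dataclass
class EnergyThresholds:
    """Recording-adaptive detection thresholds in linear energy units."""

    th1: float
    th2: float
    th3: float
    A: float = DEFAULT_A
    B: float = DEFAULT_B

    def __post_init__(self) -> None:
        if not (self.th3 <= self.th2 <= self.th1):
            raise ValueError(
                f"threshold ordering violated: th3={self.th3} th2={self.th2} th1={self.th1}"
            )


@dataclass
class SoundEvent:
    """A detected energetic segment, half-open sample interval [start, end)."""

    start_sample: int
    end_sample: int
    sample_rate: int
    samples: np.ndarray = field(repr=False)
    peak_energy: float = 0.0
    subject_id: str = ""

    @property
    def start_s(self) -> float:
        return self.start_sample / self.sample_rate

    @property
    def end_s(self) -> float:
        return self.end_sample / self.sample_rate

    @property
    def duration(self) -> float:
        return (self.end_sample - self.start_sample) / self.sample_rate


def frame_energy(
    rec: Recording,
    frame_length: float = DEFAULT_FRAME_S,
    overlap: float = DEFAULT_OVERLAP,
) -> EnergySeries:
    """Compute per-frame energy with a rectangular window.

    ``E(j) = sum_i x(i)**2`` over frame j of ``frame_length`` seconds with
    fractional ``overlap`` between consecutive frames.
    """
    if frame_length <= 0:
        raise ValueError("frame_length must be positive")
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    n_frame = int(round(frame_length * rec.sample_rate))
    hop = int(round(n_frame * (1.0 - overlap)))
    if len(rec.samples) < n_frame:
        raise ValueError(
            f"recording of {len(rec.samples)} samples is shorter than one "
            f"frame ({n_frame} samples)"
        )
    frames = sliding_window_view(rec.samples, n_frame)[::hop]
    E = np.einsum("ij,ij->i", frames, frames)
    return EnergySeries(E=E, frame_length=frame_length, overlap=overlap,
                        sample_rate=rec.sample_rate)


def build_histogram(es: EnergySeries, n_bins: int = DEFAULT_N_BINS) -> EnergyHistogram:
    """Histogram the frame energies in dB; counts conserve the frame count."""
    if len(es.E) == 0:
        raise ValueError("empty energy series")
    db = 10.0 * np.log10(es.E + _DB_EPS)
    lo, hi = float(db.min()), float(db.max())
    if hi == lo:
        hi = lo + 1e-9
    counts, edges = np.histogram(db, bins=n_bins, range=(lo, hi))
    return EnergyHistogram(bin_edges=edges, counts=counts)


def compute_thresholds(
    hist: EnergyHistogram, A: float = DEFAULT_A, B: float = DEFAULT_B
) -> EnergyThresholds:
    """Derive th1 >= th2 >= th3 from the energy histogram.

    th1 = A times the energy of the highest-energy bin (right of the modal
    bin) whose count still reaches B times the modal count — i.e. the level
    where the background's right tail dies off, pushed up by the factor A.
    th2 and th3 floor at the modal (background) energy.
    """
    if A <= 0 or not (0 < B <= 1):
        raise ValueError("require A > 0 and 0 < B <= 1")
    mode = hist.modal_bin
    modal_energy = hist.bin_energy(mode)
    max_count = hist.counts[mode]

    # walk right from the mode while the main peak's tail holds >= B*max:
    # the last bin of that contiguous run is where the background tail
    # falls to B of the modal count (bins further right belong to events)
    tail_bin = mode
    while tail_bin + 1 < len(hist.counts) and \
            hist.counts[tail_bin + 1] >= B * max_count:
        tail_bin += 1
    if tail_bin == mode:
        warnings.warn(
            "no bin right of the mode meets the count criterion; "
            "falling back to the modal energy", RuntimeWarning, stacklevel=2)
    tail_energy = hist.bin_energy(tail_bin)

    th1 = A * tail_energy
    if th1 <= modal_energy:
        raise ValueError(
            f"th1={th1:.3g} does not exceed the modal (background) energy "
            f"{modal_energy:.3g}; increase A"
        )
    th2 = max(0.15 * th1, modal_energy)
    th3 = max(0.01 * th1, modal_energy)
    th2 = max(th2, th3)  # ordering guard when floors engage
    return EnergyThresholds(th1=th1, th2=th2, th3=th3, A=A, B=B)


def detect_events(
    es: EnergySeries,
    th: EnergyThresholds,
    min_dur: float = DEFAULT_MIN_DUR,
    max_dur: float = DEFAULT_MAX_DUR,
    *,
    recording: Recording | None = None,
    merge_gap_frames: int = 0,
) -> list[SoundEvent]:
    """Detect duration-filtered events from an energy series.

    An event triggers where E crosses th1; the onset is the frame after
    the last preceding frame with E < th2, the offset the frame before the
    first following frame with E < th3. Events closer than
    ``merge_gap_frames`` frames are merged before duration filtering.
    """
    E = es.E
    n = len(E)
    hop = es.hop_samples
    n_frame = es.frame_samples
    spans: list[tuple[int, int]] = []  # inclusive frame spans
    j = 0
    while j < n:
        if E[j] >= th.th1:
            a = j
            while a > 0 and E[a - 1] >= th.th2:
                a -= 1
            b = j
            while b + 1 < n and E[b + 1] >= th.th3:
                b += 1
            if spans and a <= spans[-1][1] + 1 + merge_gap_frames:
                spans[-1] = (spans[-1][0], max(spans[-1][1], b))
            else:
                spans.append((a, b))
            j = b + 1
        else:
            j += 1

    samples = recording.samples if recording is not None else None
    subject = recording.subject_id if recording is not None else ""
    events: list[SoundEvent] = []
    for a, b in spans:
        start = a * hop
        end = b * hop + n_frame
        dur = (end - start) / es.sample_rate
        if not (min_dur <= dur <= max_dur):
            continue
        if events and start < events[-1].end_sample:
            start = events[-1].end_sample
        sl = samples[start:end] if samples is not None else np.empty(0)
        events.append(SoundEvent(
            start_sample=start, end_sample=end, sample_rate=es.sample_rate,
            samples=sl, peak_energy=float(E[a:b + 1].max()), subject_id=subject))
    return events


def write_events_csv(events: list[SoundEvent], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "start_s", "end_s", "peak_energy"])
        for ev in events:
            w.writerow([ev.subject_id, f"{ev.start_s:.6f}", f"{ev.end_s:.6f}",
                        f"{ev.peak_energy:.8g}"])


def write_label_track(events: list[SoundEvent], path: str | Path,
                      label: str = "event") -> None:
    """Audacity-style tab-separated label track for listening checks."""
    with open(path, "w") as fh:
        for ev in events:
            fh.write(f"{ev.start_s:.6f}\t{ev.end_s:.6f}\t{label}\n")
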