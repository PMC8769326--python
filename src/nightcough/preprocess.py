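"""Audio loading and pre-processing (DC removal, down-sampling to 16 kHz)."""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, resample_poly, sosfiltfilt

TARGET_RATE = 16_000

__all__ = ["Recording", "load_audio", "preprocess", "TARGET_RATE"]


@dataclass
class Recording:
    """A mono audio recording with samples normalized to [-1, 1].

    Parameters
    ----------
    samples : np.ndarray
        1-D float array of dimensionless amplitudes, ``|x| <= 1``.
    sample_rate : int
        Sampling rate in Hz.
    subject_id : str
        Identifier of the recorded subject.
    lights_off, lights_on : float or None
        Optional markers (seconds from recording start) delimiting the
        analysis window.
    """

    samples: np.ndarray
    sample_rate: int
    subject_id: str = ""
    lights_off: float | None = None
    lights_on: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Recording samples must be 1-D (mono)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.lights_off is not None and self.lights_on is not None:
            if not (0 <= self.lights_off < self.lights_on <= self.duration):
                raise ValueError("require 0 <= lights_off < lights_on <= duration")

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return len(self.samples) / self.sample_rate


def load_audio(path: str | Path, subject_id: str | None = None) -> Recording:
    """Read a WAV file into a :class:`Recording`.

    Integer PCM is scaled to [-1, 1]; stereo files are down-mixed by
    channel averaging. The sample rate is preserved.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except (FileNotFoundError, ValueError) as exc:
        raise IOError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise IOError(f"empty WAV file: {path}")

    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        scale = float(max(abs(info.min), info.max))
        x = data.astype(np.float64) / scale
    else:
        x = data.astype(np.float64)
    if x.ndim == 2:
        x = x.mean(axis=1)
    return Recording(x, int(rate), subject_id=subject_id or path.stem)


def preprocess(
    rec: Recording,
    target_rate: int = TARGET_RATE,
    highpass_hz: float | None = None,
) -> Recording:
    """Remove DC and down-sample to ``target_rate`` (default 16 kHz).

    DC removal subtracts the global mean; pass ``highpass_hz`` (e.g. 10.0)
    to use a zero-phase Butterworth high-pass instead. Resampling is
    polyphase with a Kaiser-windowed filter. Up-sampling is refused.
    """
    if len(rec.samples) == 0:
        raise ValueError("empty recording")
    if rec.sample_rate < target_rate:
        raise ValueError(
            f"sample rate {rec.sample_rate} Hz is below target {target_rate} Hz; "
            "up-sampling is not supported"
        )

    x = rec.samples
    if highpass_hz is not None:
        sos = butter(2, highpass_hz, btype="highpass", fs=rec.sample_rate, output="sos")
        x = sosfiltfilt(sos, x)
    x = x - x.mean()

    if rec.sample_rate != target_rate:
        ratio = Fraction(target_rate, rec.sample_rate)
        x = resample_poly(x, ratio.numerator, ratio.denominator, window=("kaiser", 5.0))
        x = x - x.mean()

    return replace(rec, samples=x, sample_rate=target_rate)
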