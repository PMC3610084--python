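"""Audio ingestion and preparation.

Recordings are handled as mono float waveforms in [-1, 1]. Per-participant
material may arrive as several WAV files with annotated stretches of adult
speech or environmental sound to remove; :func:`excise_and_concatenate`
excises those intervals and joins the remainders into the single sample the
feature extraction operates on. The working sample rate is 22 050 Hz.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from .errors import FormatError, PreconditionError

#: minimum combined duration (s) considered adequate for feature extraction
MIN_USABLE_DURATION_S = 120.0

#: duration (s) of the raised-cosine fade applied at every cut boundary, to
#: avoid inserting click transients into the 50-100 Hz modulation band
EDGE_FADE_S = 0.005


@dataclass(frozen=True)
class AudioSample:
    """Mono waveform with its sample rate."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim != 1:
            raise PreconditionError("AudioSample must be mono (1-D)")
        if self.sample_rate <= 0:
            raise PreconditionError("sample_rate must be positive")
        object.__setattr__(self, "samples", arr)

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return len(self.samples) / self.sample_rate

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class ExclusionAnnotation:
    """Half-open intervals [start, end) in seconds to excise from a sample."""

    intervals: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        norm = []
        for start, end in self.intervals:
            if end < start:
                raise PreconditionError(f"interval end {end} < start {start}")
            if start < 0:
                raise PreconditionError("interval start must be >= 0")
            if end > start:
                norm.append((float(start), float(end)))
        norm.sort()
        merged: list[tuple[float, float]] = []
        for start, end in norm:
            if merged and start <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], end))
            else:
                merged.append((start, end))
        object.__setattr__(self, "intervals", tuple(merged))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExclusionAnnotation":
        """Read a 2-column CSV of start/end seconds (header optional)."""
        intervals = []
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row:
                    continue
                try:
                    start, end = float(row[0]), float(row[1])
                except ValueError:
                    continue  # header or comment line
                intervals.append((start, end))
        return cls(tuple(intervals))


def read_wav(path: str | Path) -> AudioSample:
    """Read a PCM WAV file as a mono float sample in [-1, 1].

    Stereo files are averaged across channels; the original rate is kept.
    """
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # noqa: BLE001 - wrap any parse failure
        raise FormatError(f"cannot read WAV file {path}: {exc}") from exc
    dtype = data.dtype
    if data.ndim == 2:
        if data.shape[1] > 2:
            raise FormatError(f"{path}: more than 2 channels unsupported")
        data = data.astype(np.float64).mean(axis=1)
    if dtype == np.int16:
        samples = data / 32768.0
    elif dtype == np.int32:
        samples = data / 2147483648.0
    elif dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:  # float WAV
        samples = np.asarray(data, dtype=np.float64)
    return AudioSample(samples, int(rate))


def write_wav(path: str | Path, sample: AudioSample) -> None:
    """Write a sample as 16-bit PCM WAV."""
    clipped = np.clip(sample.samples, -1.0, 1.0)
    data = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(path, sample.sample_rate, data)


def resample(sample: AudioSample, target_rate: int = 22050) -> AudioSample:
    """Band-limited resampling to *target_rate* (identity if already there)."""
    if target_rate <= 0:
        raise PreconditionError("target_rate must be positive")
    if sample.sample_rate == target_rate:
        return sample
    ratio = Fraction(target_rate, sample.sample_rate)
    out = resample_poly(sample.samples, ratio.numerator, ratio.denominator)
    expected = int(round(len(sample) * target_rate / sample.sample_rate))
    if len(out) > expected:
        out = out[:expected]
    elif len(out) < expected:
        out = np.pad(out, (0, expected - len(out)))
    return AudioSample(out, target_rate)


def _keep_slices(n: int, rate: int, annotation: ExclusionAnnotation | None):
    if annotation is None or not annotation.intervals:
        return [(0, n)]
    keep = []
    pos = 0
    for start, end in annotation.intervals:
        i0 = min(n, int(round(start * rate)))
        i1 = min(n, int(round(end * rate)))
        if i0 > pos:
            keep.append((pos, i0))
        pos = max(pos, i1)
    if pos < n:
        keep.append((pos, n))
    return keep


def excise_and_concatenate(
    samples: list[AudioSample],
    annotations: list[ExclusionAnnotation | None] | None = None,
    edge_fade_s: float = EDGE_FADE_S,
) -> AudioSample:
    """Remove annotated intervals and join the remainders in order.

    Cut boundaries receive a short raised-cosine fade (in place, so the
    output length is exactly the retained length) to keep editing clicks out
    of the fast modulation band. Unedited stretches are passed through
    bit-exactly. An empty or sub-2-minute result triggers a warning.
    """
    if not samples:
        raise PreconditionError("need at least one input sample")
    rate = samples[0].sample_rate
    if any(s.sample_rate != rate for s in samples):
        raise PreconditionError("mixed sample rates: resample inputs first")
    if annotations is None:
        annotations = [None] * len(samples)
    if len(annotations) != len(samples):
        raise PreconditionError("one annotation (or None) per input sample")

    fade_n = int(round(edge_fade_s * rate))
    pieces: list[np.ndarray] = []
    for sample, ann in zip(samples, annotations):
        n = len(sample)
        slices = _keep_slices(n, rate, ann)
        edited = len(slices) != 1 or slices[0] != (0, n)
        for i0, i1 in slices:
            piece = sample.samples[i0:i1]
            if edited and fade_n > 0 and len(piece) > 2 * fade_n:
                piece = piece.copy()
                ramp = 0.5 - 0.5 * np.cos(
                    np.pi * np.arange(fade_n) / fade_n
                )
                if i0 != 0:
                    piece[:fade_n] *= ramp
                if i1 != n:
                    piece[-fade_n:] *= ramp[::-1]
            pieces.append(piece)

    out = np.concatenate(pieces) if pieces else np.empty(0)
    result = AudioSample(out, rate)
    if len(result) == 0:
        warnings.warn("excision removed all audio: result is empty", stacklevel=2)
    elif result.duration < MIN_USABLE_DURATION_S:
        warnings.warn(
            f"combined duration {result.duration:.1f}s is below the "
            f"{MIN_USABLE_DURATION_S:.0f}s recommended minimum",
            stacklevel=2,
        )
    return result
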