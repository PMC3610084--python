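"""Vocalization detection and counting.

A vocalization is a continuous run of vocal sound containing no internal
silent pause longer than 300 ms. Detection is energy-based: short frames
are classified active when their RMS level exceeds an adaptive noise floor
by a margin, active runs separated by gaps of at most the pause threshold
are merged, and the count is normalized to vocalizations per minute of
recording. Two detector parameter sets can stand in for two independent
raters, with the mean count reported.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .audio import AudioSample
from .errors import DegenerateInputError, PreconditionError

_EPS = 1e-10
#: the adaptive floor never rises above this level (dBFS), so sustained
#: loud input is not mistaken for background noise
_FLOOR_CEILING_DB = -60.0


@dataclass(frozen=True)
class VocalSegment:
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise PreconditionError("segment end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class VocalizationResult:
    segments: tuple[VocalSegment, ...]
    count: int
    rate: float  # vocalizations per minute
    duration: float  # analyzed duration, s


def frame_activity(
    sample: AudioSample, frame_ms: float = 10.0, threshold_db: float = 15.0
) -> np.ndarray:
    """Boolean per-frame activity track.

    A frame is active when its RMS (dBFS) exceeds the noise floor by
    *threshold_db*; the floor is the 5th percentile of the frame levels,
    capped at -60 dBFS so recordings that are loud throughout stay active.
    """
    if frame_ms <= 0:
        raise PreconditionError("frame_ms must be > 0")
    frame_n = max(1, int(round(frame_ms * sample.sample_rate / 1000.0)))
    n_frames = len(sample) // frame_n
    if n_frames == 0:
        return np.zeros(0, dtype=bool)
    x = sample.samples[: n_frames * frame_n].reshape(n_frames, frame_n)
    rms = np.sqrt((x**2).mean(axis=1))
    level_db = 20.0 * np.log10(rms + _EPS)
    floor = min(float(np.percentile(level_db, 5)), _FLOOR_CEILING_DB)
    return level_db > floor + threshold_db


def detect_vocalizations(
    sample: AudioSample,
    pause_ms: float = 300.0,
    frame_ms: float = 10.0,
    threshold_db: float = 15.0,
) -> VocalizationResult:
    """Segment *sample* into vocalizations under the pause rule.

    Active runs separated by an inactive gap of at most *pause_ms* belong to
    the same vocalization ("no pause greater than" the threshold: a gap of
    exactly *pause_ms* merges, one frame longer splits). The rate is the
    count divided by the recording duration in minutes.
    """
    if len(sample) == 0:
        raise DegenerateInputError("empty audio sample")
    active = frame_activity(sample, frame_ms=frame_ms, threshold_db=threshold_db)
    frame_s = frame_ms / 1000.0

    runs: list[tuple[int, int]] = []  # [start_frame, end_frame) of activity
    in_run = False
    start = 0
    for i, flag in enumerate(active):
        if flag and not in_run:
            in_run, start = True, i
        elif not flag and in_run:
            runs.append((start, i))
            in_run = False
    if in_run:
        runs.append((start, len(active)))

    merged: list[tuple[int, int]] = []
    max_gap_frames = pause_ms / frame_ms + 1e-9
    for s, e in runs:
        if merged and (s - merged[-1][1]) <= max_gap_frames:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))

    segments = tuple(
        VocalSegment(s * frame_s, e * frame_s) for s, e in merged
    )
    minutes = sample.duration / 60.0
    rate = len(segments) / minutes if minutes > 0 else 0.0
    return VocalizationResult(
        segments=segments, count=len(segments), rate=rate,
        duration=sample.duration,
    )


def mean_vocalization_result(
    sample: AudioSample, param_sets: list[dict]
) -> tuple[float, float]:
    """Mean (count, rate) over several detector parameterizations.

    Emulates averaging counts from independent raters.
    """
    if not param_sets:
        raise PreconditionError("need at least one parameter set")
    results = [detect_vocalizations(sample, **p) for p in param_sets]
    return (
        float(np.mean([r.count for r in results])),
        float(np.mean([r.rate for r in results])),
    )


def segments_to_csv(result: VocalizationResult, path: str | Path) -> None:
    """Write segments as a 2-column CSV of start/end seconds."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["start_s", "end_s"])
        for seg in result.segments:
            writer.writerow([f"{seg.start:.3f}", f"{seg.end:.3f}"])


def segments_to_textgrid(result: VocalizationResult) -> str:
    """Render segments as a minimal Praat TextGrid interval tier."""
    parts = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {result.duration:.6f}",
        "tiers? <exists>",
        "size = 1",
        "item []:",
        "    item [1]:",
        '        class = "IntervalTier"',
        '        name = "vocalizations"',
        "        xmin = 0",
        f"        xmax = {result.duration:.6f}",
    ]
    intervals: list[tuple[float, float, str]] = []
    cursor = 0.0
    for seg in result.segments:
        if seg.start > cursor:
            intervals.append((cursor, seg.start, ""))
        intervals.append((seg.start, seg.end, "voc"))
        cursor = seg.end
    if cursor < result.duration:
        intervals.append((cursor, result.duration, ""))
    parts.append(f"        intervals: size = {len(intervals)}")
    for i, (x0, x1, text) in enumerate(intervals, 1):
        parts += [
            f"        intervals [{i}]:",
            f"            xmin = {x0:.6f}",
            f"            xmax = {x1:.6f}",
            f'            text = "{text}"',
        ]
    return "\n".join(parts) + "\n"
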