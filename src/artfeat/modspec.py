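"""Spectrogram and speech modulation spectrum.

The modulation spectrum is the 2-D Fourier decomposition of a spectrogram:
it redistributes spectro-temporal energy over temporal modulation frequency
omega_t (Hz, fluctuation rate of energy over time at a fixed acoustic
frequency) and spectral modulation frequency omega_f (cycles/kHz, density of
energy fluctuation across the frequency axis at a fixed time). Slow syllabic
rhythm, formant transitions and rapid plosive-like events occupy
progressively higher omega_t; downstream feature extraction quantifies how
much of this plane a speaker's vocalizations occupy.

To make bin-count features comparable across recordings of different
lengths, the transform is computed on fixed-duration spectrogram chunks
(default 1 s, 50% overlap) and the chunk power spectra are averaged, so the
omega_t resolution (~1 Hz) and the bin grid are identical for every
participant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import fft, fftfreq, fftshift, rfft, rfft2
from scipy.signal.windows import gaussian, get_window

from .audio import AudioSample
from .errors import ConfigError, PreconditionError


@dataclass(frozen=True)
class SpectrogramConfig:
    """Short-time analysis parameters.

    The defaults (25 ms Gaussian window, 2 ms hop, log amplitude with a
    60 dB floor, 8 kHz ceiling) give a temporal-modulation Nyquist of
    250 Hz — comfortably above the 100 Hz upper edge of the fastest
    articulatory band — and a spectral-modulation range beyond 40 cycles/kHz.
    """

    window_length_ms: float = 25.0
    hop_ms: float = 2.0
    window_shape: str = "gaussian"
    amplitude_scale: str = "log"  # "log" (dB above floor) or "linear"
    log_floor_db: float = 60.0
    max_frequency: float = 8000.0
    nfft: int | None = None  # default: next pow2 covering ~11 Hz bin spacing

    def validate(self) -> list[str]:
        problems = []
        if self.window_length_ms <= 0:
            problems.append("window_length_ms must be > 0")
        if self.hop_ms <= 0:
            problems.append("hop_ms must be > 0")
        elif self.hop_ms > self.window_length_ms:
            problems.append("hop_ms must not exceed window_length_ms")
        if self.hop_ms > 0 and 1000.0 / (2 * self.hop_ms) < 100.0:
            problems.append(
                "hop_ms too large: temporal-modulation Nyquist 1/(2*hop) "
                "must reach 100 Hz (hop <= 5 ms)"
            )
        if self.amplitude_scale not in ("log", "linear"):
            problems.append("amplitude_scale must be 'log' or 'linear'")
        if self.log_floor_db <= 0:
            problems.append("log_floor_db must be > 0")
        if self.max_frequency <= 0:
            problems.append("max_frequency must be > 0")
        return problems

    def __post_init__(self) -> None:
        problems = self.validate()
        if problems:
            raise ConfigError("; ".join(problems))


@dataclass(frozen=True)
class Spectrogram:
    """Magnitude time-frequency representation.

    ``magnitude`` has shape (n_freq, n_frames) and is non-negative: linear
    magnitude, or dB above the per-file floor when the log scale is used
    (values in [0, log_floor_db]).
    """

    magnitude: np.ndarray
    freq_step: float
    time_step: float
    scale: str = "log"

    @property
    def freqs(self) -> np.ndarray:
        return np.arange(self.magnitude.shape[0]) * self.freq_step

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.magnitude.shape[1]) * self.time_step


@dataclass(frozen=True)
class ModulationSpectrum:
    """2-D modulation power distribution.

    ``power`` has shape (n_wf, n_wt) on the fftshifted grid given by ``wf``
    (cycles/kHz) and ``wt`` (Hz) and, when ``total_power`` > 0, is normalized
    to sum to 1 (a probability distribution over spectro-temporal
    modulations). ``total_power`` retains the raw (Parseval) energy of the
    mean-removed spectrogram chunks.
    """

    power: np.ndarray
    wf: np.ndarray
    wt: np.ndarray
    total_power: float

    @property
    def wf_step(self) -> float:
        return float(self.wf[1] - self.wf[0])

    @property
    def wt_step(self) -> float:
        return float(self.wt[1] - self.wt[0])

    def save_npz(self, path) -> None:
        np.savez(
            path, power=self.power, wf=self.wf, wt=self.wt,
            total_power=self.total_power,
        )

    @classmethod
    def load_npz(cls, path) -> "ModulationSpectrum":
        with np.load(path) as data:
            return cls(
                data["power"], data["wf"], data["wt"],
                float(data["total_power"]),
            )


def _analysis_window(config: SpectrogramConfig, nperseg: int) -> np.ndarray:
    if config.window_shape == "gaussian":
        # std = nperseg/6 keeps the taper effectively confined to the window
        return gaussian(nperseg, std=nperseg / 6.0, sym=True)
    return get_window(config.window_shape, nperseg)


def compute_spectrogram(
    sample: AudioSample, config: SpectrogramConfig | None = None
) -> Spectrogram:
    """Short-time Fourier magnitude of *sample* under *config*.

    With the log scale, magnitudes are expressed in dB above a floor set
    ``log_floor_db`` below the per-file maximum (clipped there), so silence
    maps to 0 everywhere.
    """
    config = config or SpectrogramConfig()
    fs = sample.sample_rate
    nperseg = max(2, int(round(config.window_length_ms * fs / 1000.0)))
    hop = max(1, int(round(config.hop_ms * fs / 1000.0)))
    if sample.duration * 1000.0 < 2 * config.window_length_ms:
        raise PreconditionError(
            "sample shorter than two analysis windows"
        )
    if config.nfft is not None:
        nfft = config.nfft
    else:
        # bin spacing <= ~11 Hz so omega_f reaches past 40 cycles/kHz
        nfft = 1
        while nfft < max(nperseg, fs / 11.0):
            nfft *= 2
    win = _analysis_window(config, nperseg)
    freq_step = fs / nfft
    n_keep = min(nfft // 2 + 1, int(np.floor(config.max_frequency / freq_step)) + 1)

    # batched framing + rfft (blocked to bound memory on long recordings)
    pad = nperseg // 2
    x = np.pad(sample.samples, (pad, pad))
    view = np.lib.stride_tricks.sliding_window_view(x, nperseg)[::hop]
    n_frames = view.shape[0]
    mag = np.empty((n_keep, n_frames))
    block = 4096
    for b0 in range(0, n_frames, block):
        frames = view[b0 : b0 + block] * win
        mag[:, b0 : b0 + block] = np.abs(
            rfft(frames, n=nfft, axis=1)[:, :n_keep]
        ).T

    if config.amplitude_scale == "log":
        ref = mag.max()
        if ref <= 0:
            out = np.zeros_like(mag)
        else:
            floor = ref * 10 ** (-config.log_floor_db / 20.0)
            out = 20.0 * np.log10(np.maximum(mag, floor) / ref) + config.log_floor_db
    else:
        out = mag
    return Spectrogram(out, freq_step=freq_step, time_step=hop / fs,
                       scale=config.amplitude_scale)


def compute_modulation_spectrum(
    spec: Spectrogram,
    chunk_duration: float = 1.0,
    chunk_overlap: float = 0.5,
    taper: str | None = "hann",
) -> ModulationSpectrum:
    """Chunked 2-D Fourier transform of the spectrogram, power-averaged.

    Each chunk has its scalar mean removed before the transform, so the
    (0, 0) bin carries no overall-level term; the omega_t = 0 column still
    holds genuinely stationary spectral structure. By default each chunk is
    Hann-tapered along the time axis: without it, sidelobe leakage from
    strong slow-modulation lines that are not bin-aligned would swamp the
    genuinely fast tail of the distribution (the taper's sidelobes fall
    ~18 dB/octave, far below the contour threshold). Pass ``taper=None``
    for the plain transform, under which per-chunk output power equals the
    mean-removed chunk energy exactly (orthonormal FFT, Parseval); with a
    taper the conserved quantity is the tapered chunk's energy. The
    averaged power map is normalized to sum to 1.
    """
    if not 0 <= chunk_overlap < 1:
        raise PreconditionError("chunk_overlap must be in [0, 1)")
    if taper not in (None, "hann"):
        raise PreconditionError("taper must be 'hann' or None")
    n_freq, n_frames = spec.magnitude.shape
    n_chunk = int(round(chunk_duration / spec.time_step))
    if n_chunk < 2:
        raise PreconditionError("chunk_duration too short for the frame rate")
    if n_frames < n_chunk:
        raise PreconditionError(
            f"spectrogram ({n_frames} frames) shorter than one "
            f"{n_chunk}-frame chunk"
        )
    step = max(1, int(round(n_chunk * (1 - chunk_overlap))))

    win = np.hanning(n_chunk)[None, :]
    win_power = float((win**2).mean())
    # real input: compute the half-spectrum and mirror by Hermitian symmetry
    n_half = n_chunk // 2 + 1
    neg_rows = np.concatenate(([0], np.arange(n_freq - 1, 0, -1)))
    neg_cols = np.arange(n_chunk - 1, n_half - 1, -1)

    def _power2d(M: np.ndarray) -> np.ndarray:
        Ph = np.abs(rfft2(M, norm="ortho")) ** 2
        P = np.empty((n_freq, n_chunk))
        P[:, :n_half] = Ph
        P[:, neg_cols] = Ph[neg_rows, 1 : n_chunk - n_half + 1]
        return P

    acc = np.zeros((n_freq, n_chunk))
    count = 0
    for start in range(0, n_frames - n_chunk + 1, step):
        chunk = spec.magnitude[:, start : start + n_chunk]
        if taper is None:
            acc += _power2d(chunk - chunk.mean())
        else:
            # The stationary structure goes into the omega_t = 0 column
            # exactly (no taper, so its large power cannot leak into the
            # +-1 Hz bins); only the temporally varying remainder is
            # tapered, with its power renormalized for the taper loss.
            row_means = chunk.mean(axis=1)
            P = _power2d((chunk - row_means[:, None]) * win)
            P /= win_power
            dc = np.abs(fft(row_means - row_means.mean(), norm="ortho")) ** 2
            P[:, 0] = n_chunk * dc
            acc += P
        count += 1
    power = fftshift(acc / count)
    total = float(power.sum())
    if total > 0:
        power = power / total
    wt = fftshift(fftfreq(n_chunk, d=spec.time_step))
    wf = fftshift(fftfreq(n_freq, d=spec.freq_step)) * 1000.0  # cycles/kHz
    return ModulationSpectrum(power=power, wf=wf, wt=wt, total_power=total)


def wt_marginal(ms: ModulationSpectrum) -> tuple[np.ndarray, np.ndarray]:
    """Marginal power over temporal modulation frequency.

    Returns ``(wt, marginal)`` with ``marginal.sum()`` preserving the total
    of the 2-D map.
    """
    return ms.wt, ms.power.sum(axis=0)
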