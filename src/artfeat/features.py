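"""Articulatory features: 99.9%-energy contour and timescale band areas.

A speaker's modulation spectrum is summarized by the *contour area*: the
number of modulation-plane bins in the minimal set that captures a fixed
fraction (default 99.9%) of the total modulation power. Partitioning the
temporal-modulation axis into syllabic rhythm (SR, 0-10 Hz), formant
transition (FT, 10-50 Hz) and place of articulation (POA, 50-100 Hz) bands
splits that count into per-timescale areas; the presence flag marks whether
a speaker shows any contour bins in a band at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audio import AudioSample
from .errors import ConfigError, DegenerateInputError, PreconditionError
from .modspec import (
    ModulationSpectrum,
    SpectrogramConfig,
    compute_modulation_spectrum,
    compute_spectrogram,
)


@dataclass(frozen=True)
class BandDefinition:
    """Temporal-modulation band [wt_low, wt_high) Hz (last band closed)."""

    name: str
    wt_low: float
    wt_high: float

    def __post_init__(self) -> None:
        if not 0 <= self.wt_low < self.wt_high:
            raise ConfigError(
                f"band {self.name}: need 0 <= wt_low < wt_high"
            )


#: operational partition of (0, 100] Hz into the three articulatory bands
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("SR", 0.0, 10.0),
    BandDefinition("FT", 10.0, 50.0),
    BandDefinition("POA", 50.0, 100.0),
)


def validate_bands(bands: tuple[BandDefinition, ...]) -> list[str]:
    """Check that bands form a contiguous non-overlapping partition."""
    problems = []
    if not bands:
        return ["no bands defined"]
    ordered = sorted(bands, key=lambda b: b.wt_low)
    if ordered[0].wt_low != 0:
        problems.append("first band must start at 0 Hz")
    for lo, hi in zip(ordered[:-1], ordered[1:]):
        if lo.wt_high != hi.wt_low:
            problems.append(
                f"bands {lo.name}/{hi.name} must be contiguous "
                f"({lo.wt_high} != {hi.wt_low})"
            )
    return problems


@dataclass(frozen=True)
class ContourMask:
    """Minimal bin set covering the requested energy fraction.

    ``inside`` is a boolean array aligned with the modulation spectrum's
    power grid (True only within the analysis region).
    """

    inside: np.ndarray
    energy_fraction_covered: float
    total_area: int


@dataclass(frozen=True)
class ArticulatoryFeatures:
    """Contour bin counts per timescale band, plus presence flags."""

    sr_area: int
    ft_area: int
    poa_area: int
    total_area: int
    presence: dict[str, bool] = field(default_factory=dict)

    def area(self, band: str) -> int:
        return {"SR": self.sr_area, "FT": self.ft_area, "POA": self.poa_area}[band]


@dataclass(frozen=True)
class FeatureConfig:
    """End-to-end extraction parameters."""

    spectrogram: SpectrogramConfig = field(default_factory=SpectrogramConfig)
    chunk_duration: float = 1.0
    chunk_overlap: float = 0.5
    energy_fraction: float = 0.999
    wf_max: float = 40.0  # cycles/kHz; covers harmonic/formant structure
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
    min_presence_area: int = 0

    def validate(self) -> list[str]:
        problems = list(self.spectrogram.validate())
        if not 0 < self.energy_fraction < 1:
            problems.append("energy_fraction must be in (0, 1)")
        if self.wf_max <= 0:
            problems.append("wf_max must be > 0")
        if self.chunk_duration <= 0:
            problems.append("chunk_duration must be > 0")
        if not 0 <= self.chunk_overlap < 1:
            problems.append("chunk_overlap must be in [0, 1)")
        problems += validate_bands(self.bands)
        return problems


def _region_mask(
    ms: ModulationSpectrum, wt_max: float, wf_max: float
) -> np.ndarray:
    wf = ms.wf[:, None]
    wt = ms.wt[None, :]
    # small tolerance so grid values landing exactly on an edge are kept
    tol = 1e-9
    region = (wt >= -tol) & (wt <= wt_max + tol) & (np.abs(wf) <= wf_max + tol)
    region &= ~((np.abs(wt) <= tol) & (np.abs(wf) <= tol))  # drop DC bin
    return region


def extract_contour(
    ms: ModulationSpectrum,
    energy_fraction: float = 0.999,
    wt_max: float = 100.0,
    wf_max: float = 40.0,
) -> ContourMask:
    """Minimal-count bin set covering *energy_fraction* of region power.

    The analysis region is the omega_t in [0, wt_max] half-plane clipped to
    |omega_f| <= wf_max, with the DC (0, 0) bin excluded. Bins are ranked by
    power (descending), ties broken by lower |omega_t| then lower |omega_f|,
    and included until the cumulative power reaches the requested fraction
    of the region total.
    """
    if not 0 < energy_fraction < 1:
        raise PreconditionError("energy_fraction must be in (0, 1)")
    region = _region_mask(ms, wt_max, wf_max)
    p = ms.power[region]
    total = p.sum()
    if total <= 0:
        raise DegenerateInputError(
            "modulation spectrum carries no power in the analysis region"
        )
    wf_idx, wt_idx = np.nonzero(region)
    abs_wt = np.abs(ms.wt[wt_idx])
    abs_wf = np.abs(ms.wf[wf_idx])
    order = np.lexsort((abs_wf, abs_wt, -p))
    csum = np.cumsum(p[order])
    k = int(np.searchsorted(csum, energy_fraction * total)) + 1
    k = min(k, len(p))
    chosen = order[:k]
    inside = np.zeros_like(ms.power, dtype=bool)
    inside[wf_idx[chosen], wt_idx[chosen]] = True
    return ContourMask(
        inside=inside,
        energy_fraction_covered=float(csum[k - 1] / total),
        total_area=int(k),
    )


def band_areas(
    mask: ContourMask,
    ms: ModulationSpectrum,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    min_presence_area: int = 0,
) -> ArticulatoryFeatures:
    """Split the contour area across the timescale bands.

    A contour bin is assigned to the band whose [wt_low, wt_high) interval
    contains its |omega_t| (the topmost band is closed at its upper edge),
    so the band areas always sum to the total contour area.
    """
    problems = validate_bands(bands)
    if problems:
        raise ConfigError("; ".join(problems))
    ordered = sorted(bands, key=lambda b: b.wt_low)
    wf_idx, wt_idx = np.nonzero(mask.inside)
    abs_wt = np.abs(ms.wt[wt_idx])
    tol = 1e-9
    areas: dict[str, int] = {}
    for i, band in enumerate(ordered):
        if i == len(ordered) - 1:
            sel = (abs_wt >= band.wt_low - tol) & (abs_wt <= band.wt_high + tol)
        else:
            sel = (abs_wt >= band.wt_low - tol) & (abs_wt < band.wt_high - tol)
        areas[band.name] = int(sel.sum())
    presence = {n: a > min_presence_area for n, a in areas.items()}
    return ArticulatoryFeatures(
        sr_area=areas.get("SR", 0),
        ft_area=areas.get("FT", 0),
        poa_area=areas.get("POA", 0),
        total_area=int(mask.total_area),
        presence=presence,
    )


def extract_features(
    sample: AudioSample, config: FeatureConfig | None = None
) -> ArticulatoryFeatures:
    """Full extraction: spectrogram -> modulation spectrum -> band areas."""
    config = config or FeatureConfig()
    problems = config.validate()
    if problems:
        raise ConfigError("; ".join(problems))
    spec = compute_spectrogram(sample, config.spectrogram)
    ms = compute_modulation_spectrum(
        spec, chunk_duration=config.chunk_duration,
        chunk_overlap=config.chunk_overlap,
    )
    wt_max = max(b.wt_high for b in config.bands)
    mask = extract_contour(
        ms, energy_fraction=config.energy_fraction,
        wt_max=wt_max, wf_max=config.wf_max,
    )
    return band_areas(mask, ms, config.bands, config.min_presence_area)
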