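"""Synthetic toddler-vocalization cohorts.

Real toddler recordings of the kind this pipeline targets are not publicly
distributable, so every downstream stage is exercised on synthetic cohorts
whose modulation content is controllable at the three articulatory
timescales. Each participant's audio is a train of utterances: a harmonic
carrier (f0 ~ 300 Hz, child-like) shaped by three formant resonances,
amplitude-modulated at the syllable rate (2-10 Hz -> SR band), with linear
formant sweeps at syllable onsets (-> FT band) and short plosive-like noise
bursts (5-15 ms -> POA band). The burst energy multiplier
``fast_modulation_gain`` is the generator's handle on fast-timescale
content; ASD-like profiles draw it from a long-tailed lognormal to mimic
the high heterogeneity of that group, optionally anti-correlated with the
verbal-ability latent so that low-VIQ participants carry the elevation.

Behavioral scores are drawn from per-group Gaussian profiles clipped to the
legal scale ranges; the default profiles encode the study conditions of a
39/26/20 ASD/TD/DD toddler cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .audio import AudioSample
from .errors import ParameterError
from .records import GROUPS, ParticipantRecord, get_value

# ---------------------------------------------------------------------------
# specifications


@dataclass(frozen=True)
class SyllableTrainSpec:
    """Acoustic recipe for one participant's utterance train.

    ``mod_depth`` < 1 keeps voicing continuous between syllable peaks; full
    on/off syllabic gating would spray broadband energy across the
    modulation plane once the spectrogram is log-compressed, masking the
    burst-driven fast-timescale content the generator is meant to control.
    """

    utterance_durations_ms: tuple[float, ...]
    pause_durations_ms: tuple[float, ...]
    syllable_rate: float = 4.0  # Hz
    vowel_duration_ms: float = 180.0
    mod_depth: float = 0.8
    attack_ms: float = 50.0
    formant_sweep: tuple[float, float, float] | None = (1800.0, 2300.0, 150.0)
    burst_rate: float = 3.0  # Hz; ignored when burst_gain == 0
    burst_duration_ms: float = 10.0
    burst_gain: float = 0.0
    carrier_f0: float = 300.0
    noise_snr_db: float | None = None
    total_duration_ms: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.syllable_rate <= 100:
            raise ParameterError("syllable_rate must be in (0, 100] Hz")
        if any(d <= 0 for d in self.utterance_durations_ms):
            raise ParameterError("utterance durations must be > 0")
        if any(p <= 0 for p in self.pause_durations_ms):
            raise ParameterError("pause durations must be > 0")
        n_utt = len(self.utterance_durations_ms)
        if len(self.pause_durations_ms) != max(0, n_utt - 1):
            raise ParameterError(
                "need exactly one pause between consecutive utterances"
            )
        if not 0 < self.mod_depth <= 1:
            raise ParameterError("mod_depth must be in (0, 1]")
        if self.vowel_duration_ms <= 0 or self.burst_duration_ms <= 0:
            raise ParameterError("durations must be > 0")
        if self.carrier_f0 <= 0:
            raise ParameterError("carrier_f0 must be > 0")
        if self.burst_gain < 0:
            raise ParameterError("burst_gain must be >= 0")
        if self.formant_sweep is not None and self.formant_sweep[2] <= 0:
            raise ParameterError("formant sweep duration must be > 0")


@dataclass(frozen=True)
class GroupProfile:
    """Generative parameters for one diagnostic group."""

    label: str
    n: int
    fast_modulation_gain: float = 1.0  # median burst-energy multiplier
    gain_sigma: float = 0.4  # lognormal spread of the multiplier
    gain_viq_rho: float = 0.0  # corr(log gain, verbal latent); <0: low VIQ -> high gain
    sweep_prob: float = 0.9  # P(participant produces formant sweeps)
    burst_prob: float = 0.55  # P(participant produces plosive-like bursts)
    score_means: dict[str, float] = field(default_factory=dict)
    score_sds: dict[str, float] = field(default_factory=dict)
    score_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    vocalization_rate_mean: float = 6.0  # utterances / min
    vocalization_rate_sd: float = 1.5
    male_prob: float = 0.75
    # per-participant nuisance ranges; degenerate ranges pin them down in
    # controlled-contrast scenarios
    burst_rate_range: tuple[float, float] = (2.0, 4.0)  # Hz
    burst_duration_range: tuple[float, float] = (5.0, 15.0)  # ms

    def __post_init__(self) -> None:
        if self.label not in GROUPS:
            raise ParameterError(f"unknown group label {self.label!r}")
        if self.n < 2:
            raise ParameterError("profile n must be >= 2")
        if self.fast_modulation_gain < 0:
            raise ParameterError("fast_modulation_gain must be >= 0")
        if any(sd <= 0 for sd in self.score_sds.values()):
            raise ParameterError("score SDs must be > 0")
        if not -1 <= self.gain_viq_rho <= 1:
            raise ParameterError("gain_viq_rho must be in [-1, 1]")


@dataclass(frozen=True)
class CohortSpec:
    profiles: tuple[GroupProfile, ...]
    sample_rate: int = 22050
    recording_duration: float = 120.0  # s; study samples span 2-5 min
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ParameterError("profiles must be non-empty")
        if self.recording_duration <= 0:
            raise ParameterError("recording_duration must be > 0")
        if self.sample_rate <= 0:
            raise ParameterError("sample_rate must be > 0")


# Published per-group behavioral score parameterization: mean, sd, range.
_SCORE_TABLE: dict[str, dict[str, tuple[float, float, tuple[float, float]]]] = {
    "ASD": {
        "age_months": (23.5, 3.8, (18, 30)),
        "mullen_elc": (59.4, 16.0, (24, 95)),
        "mullen_rl": (22.2, 7.2, (20, 56)),
        "mullen_el": (26.9, 9.2, (20, 56)),
        "mullen_fm": (32.1, 11.6, (20, 50)),
        "vabs_abc": (69.2, 6.9, (57, 86)),
        "vabs_rl": (11.1, 3.4, (5, 28)),
        "vabs_el": (5.8, 2.3, (2, 12)),
    },
    "TD": {
        "age_months": (23.1, 3.0, (18, 29)),
        "mullen_elc": (105.2, 7.7, (94, 127)),
        "mullen_rl": (57.4, 6.8, (40, 78)),
        "mullen_el": (48.1, 8.7, (30, 68)),
        "mullen_fm": (49.8, 6.4, (39, 64)),
        "vabs_abc": (95.2, 8.3, (81, 115)),
        "vabs_rl": (14.6, 0.9, (13, 16)),
        "vabs_el": (11.6, 1.8, (8, 15)),
    },
    "DD": {
        "age_months": (22.1, 3.5, (18, 30)),
        "mullen_elc": (79.1, 10.7, (57, 108)),
        "mullen_rl": (37.2, 13.3, (20, 69)),
        "mullen_el": (32.5, 7.6, (20, 46)),
        "mullen_fm": (35.7, 12.8, (20, 66)),
        "vabs_abc": (78.5, 8.9, (64, 97)),
        "vabs_rl": (13.3, 1.3, (10, 15)),
        "vabs_el": (8.1, 1.4, (6, 11)),
    },
}

#: loading of the Mullen language scales on the shared verbal latent
_LANG_LOADING = 0.8


def _table_profile(label: str, **overrides) -> GroupProfile:
    table = _SCORE_TABLE[label]
    kwargs = dict(
        label=label,
        n={"ASD": 39, "TD": 26, "DD": 20}[label],
        score_means={k: v[0] for k, v in table.items()},
        score_sds={k: v[1] for k, v in table.items()},
        score_ranges={k: v[2] for k, v in table.items()},
    )
    kwargs.update(overrides)
    return GroupProfile(**kwargs)


def default_profiles() -> tuple[GroupProfile, ...]:
    """Study-condition group profiles (39/26/20, published score summaries).

    The ASD profile has an elevated, long-tailed fast-modulation gain whose
    log is anti-correlated with the verbal latent, so fast-timescale content
    concentrates in low-VIQ ASD participants; TD and DD sit at gain 1. ASD
    produces the fewest vocalizations per minute, TD the most.
    """
    return (
        _table_profile(
            "ASD", fast_modulation_gain=2.5, gain_sigma=0.7,
            gain_viq_rho=-0.6, burst_prob=0.7,
            vocalization_rate_mean=4.0, vocalization_rate_sd=1.5,
            male_prob=29 / 39,
        ),
        _table_profile(
            "TD", fast_modulation_gain=1.0, gain_sigma=0.4, burst_prob=0.55,
            vocalization_rate_mean=8.0, vocalization_rate_sd=2.0,
            male_prob=19 / 26,
        ),
        _table_profile(
            "DD", fast_modulation_gain=1.0, gain_sigma=0.4, burst_prob=0.5,
            vocalization_rate_mean=5.0, vocalization_rate_sd=1.5,
            male_prob=17 / 20,
        ),
    )


def null_profiles(ns: tuple[int, int, int] = (39, 26, 20)) -> tuple[GroupProfile, ...]:
    """Three groups with identical generative settings (labels aside).

    Used for type-I-error calibration: any detected group difference is a
    false positive. Bursts are always present so the calibrated feature has
    a continuous distribution.
    """
    common = dict(fast_modulation_gain=1.0, gain_sigma=0.5, gain_viq_rho=0.0,
                  burst_prob=1.0, sweep_prob=0.9,
                  vocalization_rate_mean=6.0, vocalization_rate_sd=1.5)
    return tuple(
        _table_profile(label, n=n, **common)
        for label, n in zip(GROUPS, ns)
    )


def planned_effect_profiles(
    n_asd: int = 12, n_td: int = 10, n_dd: int = 10
) -> tuple[GroupProfile, ...]:
    """Planned-effect scenario for power analyses.

    The ASD profile's burst gain (median 3, lognormal sigma 0.4) is strongly
    anti-correlated with the verbal latent (rho = -0.8), so the low-VIQ ASD
    subgroup carries most of the fast-timescale elevation over TD/DD at
    gain 1. All participants produce bursts and the burst nuisance
    parameters (rate, duration) and vocalization rates are pinned to common
    values, making the contrast purely one of burst energy.
    """
    common = dict(
        burst_prob=1.0, sweep_prob=1.0,
        burst_rate_range=(3.0, 3.0), burst_duration_range=(10.0, 10.0),
        vocalization_rate_mean=10.0, vocalization_rate_sd=0.01,
    )
    return (
        _table_profile(
            "ASD", n=n_asd, fast_modulation_gain=3.0, gain_sigma=0.4,
            gain_viq_rho=-0.8, **common,
        ),
        _table_profile(
            "TD", n=n_td, fast_modulation_gain=1.0, gain_sigma=0.25, **common,
        ),
        _table_profile(
            "DD", n=n_dd, fast_modulation_gain=1.0, gain_sigma=0.25, **common,
        ),
    )


# ---------------------------------------------------------------------------
# waveform synthesis

_FORMANTS = (900.0, 1800.0, 3800.0)  # child-like F1-F3 centers, Hz
_FORMANT_BW = 250.0
_MAX_HARMONIC_FREQ = 8000.0
_BURST_LEVEL = 0.35  # burst peak relative to vocalic peak, before gain


def _syllable_envelope(t: np.ndarray, spec: SyllableTrainSpec) -> np.ndarray:
    period = 1.0 / spec.syllable_rate
    width = min(spec.vowel_duration_ms / 1000.0, period)
    tau = np.mod(t, period)
    # cos^4-type bump: C^3-smooth, so its log-domain harmonics die out well
    # below the fast-modulation band
    bump = np.where(
        tau < width, (0.5 * (1 - np.cos(2 * np.pi * tau / width))) ** 2, 0.0
    )
    return (1.0 - spec.mod_depth) + spec.mod_depth * bump


_EDGE_RANGE_DB = 80.0  # dynamic range the utterance edges traverse


def _edge_ramp(n: int, attack_n: int) -> np.ndarray:
    """Utterance on/offset ramp, smooth in the log-amplitude domain.

    A linear-amplitude fade looks like a near-instantaneous cliff on a dB
    spectrogram and would put broadband energy into the fast-modulation
    band at every utterance boundary; a smoothstep ramp *in dB* keeps the
    edge content at syllable-scale rates.
    """
    ramp = np.ones(n)
    k = min(attack_n, n // 2)
    if k > 0:
        s = np.arange(k) / k
        smooth = s * s * (3 - 2 * s)  # C^1 smoothstep in the dB domain
        rise = 10 ** (-_EDGE_RANGE_DB * (1 - smooth) / 20.0)
        ramp[:k] = rise
        ramp[-k:] = rise[::-1]
    return ramp


def _utterance(
    spec: SyllableTrainSpec, dur_ms: float, fs: int, rng: np.random.Generator
) -> np.ndarray:
    n = int(round(dur_ms * fs / 1000.0))
    t = np.arange(n) / fs
    f0 = spec.carrier_f0 * (1 + 0.03 * rng.standard_normal())

    # formant-shaped harmonic amplitudes; F2 sweeps at each syllable onset
    f2 = np.full(n, _FORMANTS[1])
    if spec.formant_sweep is not None:
        # F2 sweeps up over the sweep duration at each syllable onset and
        # glides back down before the next one (a discontinuous reset would
        # inject spurious fast-modulation energy)
        start, end, sweep_ms = spec.formant_sweep
        sweep_n = max(1, int(round(sweep_ms * fs / 1000.0)))
        period_n = max(2 * sweep_n, int(round(fs / spec.syllable_rate)))
        pos = np.mod(np.arange(n), period_n)
        up = np.minimum(pos / sweep_n, 1.0)
        down = np.minimum((period_n - pos) / sweep_n, 1.0)
        f2 = start + (end - start) * np.minimum(up, down)

    wave = np.zeros(n)
    n_harm = int(_MAX_HARMONIC_FREQ // f0)
    for h in range(1, n_harm + 1):
        fh = h * f0
        amp = (
            math.exp(-((fh - _FORMANTS[0]) ** 2) / (2 * _FORMANT_BW**2))
            + math.exp(-((fh - _FORMANTS[2]) ** 2) / (2 * _FORMANT_BW**2))
            + 0.05 / h
        )
        amp = amp + np.exp(-((fh - f2) ** 2) / (2 * _FORMANT_BW**2))
        phase = rng.uniform(0, 2 * np.pi)
        wave += amp * np.sin(2 * np.pi * fh * t + phase)
    wave *= _syllable_envelope(t, spec)
    wave *= _edge_ramp(n, int(round(spec.attack_ms * fs / 1000.0)))
    peak = np.abs(wave).max()
    if peak > 0:
        wave /= peak

    if spec.burst_gain > 0 and spec.burst_rate > 0:
        burst_n = max(2, int(round(spec.burst_duration_ms * fs / 1000.0)))
        window = np.hanning(burst_n)
        step = 1.0 / spec.burst_rate
        k = 0
        while True:
            center = (k + 0.5) * step + rng.uniform(-0.1, 0.1) * step
            i0 = int(center * fs)
            if i0 + burst_n >= n:
                break
            noise = np.diff(rng.standard_normal(burst_n + 1))  # high-tilted
            noise /= max(np.abs(noise).max(), 1e-12)
            wave[i0 : i0 + burst_n] += (
                _BURST_LEVEL * spec.burst_gain * window * noise
            )
            k += 1
    return wave


def generate_vocalization(
    spec: SyllableTrainSpec, sample_rate: int = 22050, seed: int = 0
) -> AudioSample:
    """Synthesize one participant's utterance train.

    Deterministic for a fixed (spec, seed). With no utterances the output is
    silence of ``total_duration_ms`` (or empty).
    """
    rng = np.random.default_rng(seed)
    fs = sample_rate
    pieces: list[np.ndarray] = []
    for i, dur in enumerate(spec.utterance_durations_ms):
        pieces.append(_utterance(spec, dur, fs, rng))
        if i < len(spec.pause_durations_ms):
            pieces.append(np.zeros(int(round(spec.pause_durations_ms[i] * fs / 1000.0))))
    wave = np.concatenate(pieces) if pieces else np.zeros(0)

    if spec.total_duration_ms is not None:
        total_n = int(round(spec.total_duration_ms * fs / 1000.0))
        if len(wave) < total_n:
            wave = np.pad(wave, (0, total_n - len(wave)))
        else:
            wave = wave[:total_n]

    if spec.noise_snr_db is not None and len(wave):
        sig_power = float((wave**2).mean())
        if sig_power > 0:
            noise_power = sig_power * 10 ** (-spec.noise_snr_db / 10.0)
            wave = wave + rng.standard_normal(len(wave)) * math.sqrt(noise_power)

    peak = np.abs(wave).max() if len(wave) else 0.0
    if peak > 0:
        wave = wave * (0.9 / peak)
    return AudioSample(wave, fs)


# ---------------------------------------------------------------------------
# cohort assembly


def _truncnorm(
    rng: np.random.Generator, mean: float, sd: float,
    bounds: tuple[float, float] | None, z: float | None = None,
) -> float:
    value = mean + sd * (z if z is not None else rng.standard_normal())
    if bounds is not None:
        value = min(max(value, bounds[0]), bounds[1])
    return float(value)


def _draw_participant_scores(
    profile: GroupProfile, rng: np.random.Generator
) -> tuple[dict[str, float], float]:
    """Draw one score set; returns (scores, verbal latent z)."""
    z_lang = rng.standard_normal()
    scores: dict[str, float] = {}
    for name, mean in profile.score_means.items():
        sd = profile.score_sds[name]
        bounds = profile.score_ranges.get(name)
        if name in ("mullen_rl", "mullen_el"):
            z = _LANG_LOADING * z_lang + math.sqrt(
                1 - _LANG_LOADING**2
            ) * rng.standard_normal()
            scores[name] = _truncnorm(rng, mean, sd, bounds, z)
        else:
            scores[name] = _truncnorm(rng, mean, sd, bounds)
    return scores, z_lang


def _draw_gain(
    profile: GroupProfile, z_lang: float, rng: np.random.Generator
) -> float:
    rho = profile.gain_viq_rho
    z = rho * z_lang + math.sqrt(1 - rho**2) * rng.standard_normal()
    return profile.fast_modulation_gain * math.exp(profile.gain_sigma * z)


def _utterance_plan(
    profile: GroupProfile, duration_s: float, rng: np.random.Generator
) -> tuple[tuple[float, ...], tuple[float, ...], float]:
    """Durations (ms) of utterances and inter-utterance pauses, plus rate."""
    rate = max(0.5, rng.normal(profile.vocalization_rate_mean,
                               profile.vocalization_rate_sd))
    n_utt = max(1, int(round(rate * duration_s / 60.0)))
    durs = np.exp(rng.normal(math.log(1.2), 0.35, n_utt))
    durs = np.clip(durs, 0.3, 3.0)
    if durs.sum() > 0.6 * duration_s:
        durs *= 0.6 * duration_s / durs.sum()
    silent = duration_s - durs.sum()
    weights = rng.uniform(0.5, 1.5, n_utt + 1)
    gaps = silent * weights / weights.sum()
    # keep inter-utterance pauses clearly above the 300 ms merge threshold
    pauses = np.maximum(gaps[1:-1], 0.4) if n_utt > 1 else np.empty(0)
    return (
        tuple(durs * 1000.0),
        tuple(pauses * 1000.0),
        rate,
    )


def _participant_spec(
    profile: GroupProfile, duration_s: float, rng: np.random.Generator
) -> tuple[SyllableTrainSpec, dict[str, float], dict[str, float]]:
    scores, z_lang = _draw_participant_scores(profile, rng)
    gain = _draw_gain(profile, z_lang, rng)
    has_sweep = rng.random() < profile.sweep_prob
    has_burst = rng.random() < profile.burst_prob
    durs, pauses, rate = _utterance_plan(profile, duration_s, rng)
    spec = SyllableTrainSpec(
        utterance_durations_ms=durs,
        pause_durations_ms=pauses,
        syllable_rate=rng.uniform(2.5, 5.0),
        formant_sweep=(1800.0, 2300.0, 150.0) if has_sweep else None,
        burst_rate=rng.uniform(*profile.burst_rate_range),
        burst_duration_ms=rng.uniform(*profile.burst_duration_range),
        burst_gain=gain if has_burst else 0.0,
        carrier_f0=rng.normal(300.0, 30.0),
        total_duration_ms=duration_s * 1000.0,
    )
    extras = {
        "gain": gain,
        "has_burst": float(has_burst),
        "has_sweep": float(has_sweep),
        "planned_voc_rate": rate,
        "male": float(rng.random() < profile.male_prob),
    }
    return spec, scores, extras


def generate_cohort(
    cohort: CohortSpec,
) -> list[tuple[ParticipantRecord, AudioSample]]:
    """Generate one (record, audio) pair per participant.

    Bit-identical for a fixed :class:`CohortSpec` (including seed).
    """
    out: list[tuple[ParticipantRecord, AudioSample]] = []
    root = np.random.SeedSequence(cohort.seed)
    children = root.spawn(sum(p.n for p in cohort.profiles))
    idx = 0
    for profile in cohort.profiles:
        for i in range(profile.n):
            ss = children[idx]
            idx += 1
            rng = np.random.default_rng(ss)
            spec, scores, extras = _participant_spec(
                profile, cohort.recording_duration, rng
            )
            wav_seed = int(ss.generate_state(1)[0] % (2**31))
            audio = generate_vocalization(spec, cohort.sample_rate, wav_seed)
            rec = ParticipantRecord(
                id=f"{profile.label}-{i + 1:03d}",
                group=profile.label,
                scores=scores,
                extras=extras,
            )
            out.append((rec, audio))
    return out


def draw_scores(
    profile: GroupProfile, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw *n* score sets from a profile (no audio); for sampling checks."""
    rows = [
        _draw_participant_scores(profile, rng)[0] for _ in range(n)
    ]
    return pd.DataFrame(rows)


def simulate_records(
    profiles: tuple[GroupProfile, ...], seed: int = 0
) -> list[ParticipantRecord]:
    """Participant-level statistical surrogate of the extracted features.

    Draws contour-area counts directly from the generative model the audio
    path realises (band-area scale x lognormal participant gain, Poisson
    bin-count noise, Bernoulli burst/sweep presence) without synthesizing
    or analysing audio, and attaches them as synthetic
    :class:`ArticulatoryFeatures`. Used for statistical calibration
    experiments where thousands of cohorts are needed.
    """
    from .features import ArticulatoryFeatures

    rng = np.random.default_rng(seed)
    out = []
    for profile in profiles:
        for i in range(profile.n):
            scores, z_lang = _draw_participant_scores(profile, rng)
            gain = _draw_gain(profile, z_lang, rng)
            has_burst = rng.random() < profile.burst_prob
            has_sweep = rng.random() < profile.sweep_prob
            sr = int(rng.poisson(420))
            ft = int(rng.poisson(140 if has_sweep else 25))
            poa = int(rng.poisson(35 * gain)) if has_burst else 0
            feats = ArticulatoryFeatures(
                sr_area=sr, ft_area=ft, poa_area=poa,
                total_area=sr + ft + poa,
                presence={"SR": sr > 0, "FT": ft > 0, "POA": poa > 0},
            )
            rate = max(0.5, rng.normal(profile.vocalization_rate_mean,
                                       profile.vocalization_rate_sd))
            out.append(ParticipantRecord(
                id=f"{profile.label}-{i + 1:03d}", group=profile.label,
                scores=scores, features=feats, voc_rate=float(rate),
                extras={"gain": gain},
            ))
    return out


def simulate_feature_table(
    profiles: tuple[GroupProfile, ...], seed: int = 0
) -> pd.DataFrame:
    """Tabular view of :func:`simulate_records`."""
    from .records import records_to_frame

    return records_to_frame(simulate_records(profiles, seed))


def inject_correlation(
    records: list[ParticipantRecord],
    feature_name: str,
    score_name: str,
    rho: float,
    seed: int = 0,
) -> list[ParticipantRecord]:
    """Re-draw a score so its population correlation with a feature is rho.

    The score is regenerated as mu + sigma * (rho * z_f + sqrt(1 - rho^2) *
    eps) with z_f the standardized feature, keeping the score's first two
    moments; at |rho| = 1 the map is exactly linear. Returns copies.
    """
    if not -1 <= rho <= 1:
        raise ParameterError("|rho| must be <= 1")
    if not records:
        raise ParameterError("records must be non-empty")
    f = np.array([get_value(r, feature_name) for r in records])
    s = np.array([float(r.scores[score_name]) for r in records])
    f_sd = f.std()
    if f_sd == 0:
        raise ParameterError(f"feature {feature_name!r} is constant")
    z_f = (f - f.mean()) / f_sd
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(len(records))
    new = s.mean() + s.std() * (rho * z_f + math.sqrt(1 - rho**2) * eps)
    out = []
    for rec, value in zip(records, new):
        rec = rec.copy()
        rec.scores[score_name] = float(value)
        out.append(rec)
    return out
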