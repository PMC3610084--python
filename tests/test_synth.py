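import dataclasses

import numpy as np
import pytest
from scipy.fft import rfft, rfftfreq
from scipy.signal import hilbert

from artfeat.errors import ParameterError
from artfeat.records import records_to_frame
from artfeat.synth import (
    CohortSpec,
    GroupProfile,
    SyllableTrainSpec,
    default_profiles,
    draw_scores,
    generate_cohort,
    generate_vocalization,
    inject_correlation,
    null_profiles,
    planned_effect_profiles,
    simulate_records,
)


def envelope_peak_hz(sample, fmax=20.0):
    env = np.abs(hilbert(sample.samples))
    k = int(0.01 * sample.sample_rate)  # 10 ms smoothing
    env = np.convolve(env, np.ones(k) / k, mode="valid")
    env = env - env.mean()
    spec = np.abs(rfft(env))
    freqs = rfftfreq(len(env), 1 / sample.sample_rate)
    sel = (freqs > 0.5) & (freqs <= fmax)
    return freqs[sel][np.argmax(spec[sel])]


class TestVocalizationSynthesis:
    def test_envelope_peak_at_syllable_rate(self):
        spec = SyllableTrainSpec(
            utterance_durations_ms=(4000.0,), pause_durations_ms=(),
            syllable_rate=5.0, burst_gain=0.0, formant_sweep=None,
        )
        audio = generate_vocalization(spec, seed=0)
        assert envelope_peak_hz(audio) == pytest.approx(5.0, abs=0.3)

    def test_zero_utterances_is_silence_of_requested_duration(self):
        spec = SyllableTrainSpec(
            utterance_durations_ms=(), pause_durations_ms=(),
            total_duration_ms=1500.0,
        )
        audio = generate_vocalization(spec, sample_rate=22050, seed=1)
        assert len(audio) == int(1.5 * 22050)
        assert not audio.samples.any()

    def test_deterministic_per_seed(self):
        spec = SyllableTrainSpec(
            utterance_durations_ms=(800.0, 900.0), pause_durations_ms=(400.0,),
            burst_gain=1.5,
        )
        a = generate_vocalization(spec, seed=42)
        b = generate_vocalization(spec, seed=42)
        assert np.array_equal(a.samples, b.samples)
        c = generate_vocalization(spec, seed=43)
        assert not np.array_equal(a.samples, c.samples)

    def test_bursts_present_iff_gain_positive(self):
        base = dict(
            utterance_durations_ms=(1000.0,), pause_durations_ms=(),
            formant_sweep=None,
        )
        quiet = generate_vocalization(
            SyllableTrainSpec(burst_gain=0.0, **base), seed=5
        )
        bursty = generate_vocalization(
            SyllableTrainSpec(burst_gain=2.0, **base), seed=5
        )
        # bursts add broadband high-frequency energy
        def hf_energy(s):
            spec = np.abs(rfft(s.samples))
            freqs = rfftfreq(len(s), 1 / s.sample_rate)
            return spec[freqs > 5000].sum() / spec.sum()

        assert hf_energy(bursty) > 2 * hf_energy(quiet)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(utterance_durations_ms=(0.0,), pause_durations_ms=()),
            dict(utterance_durations_ms=(500.0, 500.0), pause_durations_ms=()),
            dict(utterance_durations_ms=(500.0,), pause_durations_ms=(),
                 syllable_rate=0.0),
            dict(utterance_durations_ms=(500.0,), pause_durations_ms=(),
                 mod_depth=1.5),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            SyllableTrainSpec(**kwargs)


class TestCohort:
    def test_group_sizes(self):
        profiles = default_profiles()
        assert [p.n for p in profiles] == [39, 26, 20]
        cohort = CohortSpec(profiles=profiles, recording_duration=2.0, seed=0)
        pairs = generate_cohort(cohort)
        assert len(pairs) == 85
        frame = records_to_frame([r for r, _ in pairs])
        assert frame.group.value_counts().to_dict() == {
            "ASD": 39, "TD": 26, "DD": 20
        }

    def test_cohort_bit_identical_under_seed(self):
        profiles = tuple(
            dataclasses.replace(p, n=2) for p in default_profiles()
        )
        spec = CohortSpec(profiles=profiles, recording_duration=3.0, seed=9)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        for (ra, wa), (rb, wb) in zip(a, b):
            assert ra.scores == rb.scores
            assert np.array_equal(wa.samples, wb.samples)

    def test_score_sampling_matches_profile(self):
        td = default_profiles()[1]
        rng = np.random.default_rng(0)
        frame = draw_scores(td, 1000, rng)
        se = 8.7 / np.sqrt(1000)
        assert abs(frame.mullen_el.mean() - 48.1) <= 3 * se
        assert frame.mullen_el.min() >= 30 and frame.mullen_el.max() <= 68

    def test_scores_respect_scale_ranges(self):
        asd = default_profiles()[0]
        rng = np.random.default_rng(1)
        frame = draw_scores(asd, 500, rng)
        assert frame.mullen_rl.min() >= 20
        assert frame.vabs_el.between(2, 12).all()

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ParameterError):
            GroupProfile(label="XX", n=5)
        with pytest.raises(ParameterError):
            GroupProfile(label="TD", n=1)
        with pytest.raises(ParameterError):
            GroupProfile(label="TD", n=5, score_sds={"mullen_el": 0.0})

    def test_viq_is_mean_of_language_scales(self):
        recs = simulate_records(null_profiles((5, 5, 5)), seed=2)
        for r in recs:
            assert r.viq == pytest.approx(
                (r.scores["mullen_rl"] + r.scores["mullen_el"]) / 2
            )

    def test_effect_profiles_elevate_low_viq_gain(self):
        recs = simulate_records(planned_effect_profiles(200, 5, 5), seed=3)
        asd = [r for r in recs if r.group == "ASD"]
        viqs = np.array([r.viq for r in asd])
        gains = np.array([r.extras["gain"] for r in asd])
        low = gains[viqs <= np.mean(viqs)].mean()
        high = gains[viqs > np.mean(viqs)].mean()
        assert low > high


class TestInjectCorrelation:
    @pytest.fixture
    def asd_records(self):
        profiles = (
            dataclasses.replace(null_profiles()[0], n=1000),
            null_profiles()[1],
            null_profiles()[2],
        )
        return [r for r in simulate_records(profiles, seed=0) if r.group == "ASD"]

    def _r(self, records, feat, score):
        f = np.array([getattr(r.features, feat) for r in records])
        s = np.array([r.scores[score] for r in records])
        return np.corrcoef(f, s)[0, 1]

    def test_rho_zero_gives_small_r(self, asd_records):
        out = inject_correlation(asd_records, "poa_area", "vabs_rl", 0.0, seed=1)
        assert abs(self._r(out, "poa_area", "vabs_rl")) <= 0.1

    def test_rho_one_gives_exact_r(self, asd_records):
        out = inject_correlation(asd_records, "poa_area", "vabs_rl", 1.0, seed=1)
        assert self._r(out, "poa_area", "vabs_rl") == pytest.approx(1.0, abs=1e-12)

    def test_rho_half_recovered_within_fisher_ci(self, asd_records):
        out = inject_correlation(
            asd_records[:500], "poa_area", "vabs_rl", 0.5, seed=2
        )
        r = self._r(out, "poa_area", "vabs_rl")
        z = np.arctanh(r)
        lo, hi = np.tanh(z - 1.96 / np.sqrt(497)), np.tanh(z + 1.96 / np.sqrt(497))
        assert lo <= 0.5 <= hi

    def test_unknown_names_raise(self, asd_records):
        with pytest.raises(KeyError):
            inject_correlation(asd_records, "nope_area", "vabs_rl", 0.5)
        with pytest.raises(KeyError):
            inject_correlation(asd_records, "poa_area", "nope_score", 0.5)

    def test_rho_out_of_range_rejected(self, asd_records):
        with pytest.raises(ParameterError):
            inject_correlation(asd_records, "poa_area", "vabs_rl", 1.5)
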