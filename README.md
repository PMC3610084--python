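# artfeat

Articulatory-feature analysis of child vocalization audio.

`artfeat` is for researchers studying early speech-motor development —
particularly group comparisons between toddlers with autism spectrum
disorder (ASD), developmental delay (DD) and typical development (TD) —
who want an automated, reproducible version of the *speech modulation
spectrum* analysis of naturalistic vocalization recordings, together with
the cohort statistics that typically accompany it.

## The measure

Given a mono recording (22 050 Hz target rate), the pipeline computes a
log-magnitude spectrogram and takes its 2-D Fourier transform, yielding
the modulation power distribution P(ω_f, ω_t) over spectral modulation
ω_f (cycles/kHz) and temporal modulation ω_t (Hz). The speaker's
**contour area** is |C|, where C is the minimal set of modulation-plane
bins with

&nbsp;&nbsp;&nbsp;&nbsp;Σ<sub>(ω_f, ω_t) ∈ C</sub> P(ω_f, ω_t) ≥ 0.999,

and the per-timescale **articulatory features** split that count over
temporal-modulation bands:

| band | ω_t range | articulatory correlate |
|------|-----------|------------------------|
| SR   | 0–10 Hz   | syllabic rhythm (vowel-scale amplitude modulation) |
| FT   | 10–50 Hz  | formant transitions, consonant blends |
| POA  | 50–100 Hz | place-of-articulation cues, plosive-like transients |

A **vocalization** is a run of detected vocal sound with no internal
pause longer than 300 ms; counts are normalized to per-minute rates.
The statistics battery covers one-way ANOVA (raw or reconstructed from
printed group mean/SD/n summaries), Kruskal–Wallis, Tukey and Fisher-LSD
post-hocs, per-group Pearson correlation tables, a verbal-IQ split of the
ASD group (VIQ = mean of the Mullen receptive and expressive language
T-scores), descriptives with a normality flag, and band-presence
percentages.

Because clinical audio of this kind cannot be redistributed, the package
includes a first-class synthetic cohort generator (`artfeat.synth`) whose
defaults encode a 39/26/20 ASD/TD/DD toddler cohort: harmonic, formant-
shaped utterance trains with controllable modulation content at the three
timescales, plus behavioral scores drawn from the published group
distributions. See `docs/methods.md` for the model and its limits.

## Worked example

Generate a planned-effect cohort (low-verbal ASD participants carry
elevated fast-timescale burst energy), extract features, and test the
group effect on the POA contour area:

```python
from artfeat import (CohortSpec, FeatureConfig, SpectrogramConfig,
                     extract_features, planned_effect_profiles, generate_cohort)
from artfeat.stats import one_way_anova, fisher_lsd_posthoc, split_by_viq, group_values

config = FeatureConfig(
    spectrogram=SpectrogramConfig(hop_ms=5.0, nfft=1024, max_frequency=6000.0)
)
cohort = CohortSpec(profiles=planned_effect_profiles(10, 8, 8),
                    recording_duration=10.0, seed=7)
records = []
for rec, audio in generate_cohort(cohort):
    rec.features = extract_features(audio, config)
    records.append(rec)

high, low = split_by_viq(records)
labels = {r.id: "LVIQ-ASD" for r in low}
vals = group_values(records, "poa_area",
                    groups=("LVIQ-ASD", "TD", "DD"), labels=labels)
res = one_way_anova(vals)
for name, v in vals.items():
    print(f"{name:9s} n={len(v):2d}  mean POA area = {v.mean():7.1f} bins")
print(f"one-way ANOVA: F({res.df[0]:.0f}, {res.df[1]:.0f}) = {res.statistic:.2f}, p = {res.p_value:.4f}")
for pr in fisher_lsd_posthoc(vals):
    print(f"  {pr.pair[0]} vs {pr.pair[1]}: t = {pr.statistic:+.2f}, p = {pr.p_value:.4f}"
          + ("  *" if pr.significant else ""))
```

Output:

```
LVIQ-ASD  n= 6  mean POA area =  2158.5 bins
TD        n= 8  mean POA area =  1263.2 bins
DD        n= 8  mean POA area =  1291.4 bins
one-way ANOVA: F(2, 19) = 22.07, p = 0.0000
  LVIQ-ASD vs TD: t = +5.98, p = 0.0000  *
  LVIQ-ASD vs DD: t = +5.79, p = 0.0000  *
  TD vs DD: t = -0.20, p = 0.8414
```

The low-verbal ASD-like subgroup occupies roughly 900 more fast-timescale
modulation bins than either comparison group — the generator's planned
effect — while TD and DD are indistinguishable. The protected-LSD
post-hoc localizes the omnibus effect to the two LVIQ-ASD contrasts.

## Command line

```bash
artfeat simulate --out cohort/ --seed 1 --duration 120   # WAVs + participants.csv
artfeat analyze --manifest cohort/participants.csv --out report/
artfeat analyze --out report/ --bands sr=0:10,ft=10:50,poa=50:100 --pause-ms 300
```

`analyze` writes `features.csv` (one row per participant), `stats.json`
(omnibus tests, post-hocs, descriptives, presence percentages),
`presence.csv`, and a `manifest.json` that records config, versions and
seed for exact re-runs. In `audio-dir` mode it accepts your own WAV files
via a manifest CSV (`id, wav_path[, annotation_path], group, scores...`),
with annotation CSVs listing start/end seconds of adult speech or
environmental sound to excise.

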