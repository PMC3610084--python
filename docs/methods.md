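# Methods

## The measure

`artfeat` quantifies speech-motor content of child vocalization recordings
through the *speech modulation spectrum*: the 2-D Fourier decomposition of
a log-magnitude spectrogram over temporal modulation frequency ω_t (Hz)
and spectral modulation frequency ω_f (cycles/kHz). A speaker's
*contour area* is the number of modulation-plane bins in the minimal set
capturing 99.9% of total modulation power; partitioning ω_t into
syllabic-rhythm (SR, 0–10 Hz), formant-transition (FT, 10–50 Hz) and
place-of-articulation (POA, 50–100 Hz) bands splits that count into
per-timescale areas. Slow amplitude modulation (vowel/syllable structure)
lands in SR, formant glides in FT, and plosive-like transients in POA, so
the band profile acts as a proxy for articulatory-motor maturity. A
complementary measure counts *vocalizations*: runs of vocal sound with no
internal pause longer than 300 ms, normalized to a per-minute rate.

"Contour area" is implemented literally as a bin count of the minimal
covering set (ties broken by lower |ω_t|, then lower |ω_f|), not as a
geometric isocontour; smoothed closed contours are a visualization device.
Bands are the operational partition of (0, 100] Hz given above, with
half-open intervals [low, high) and the topmost band closed at 100 Hz, so
band areas always sum to the total. The ω_t ≥ 0 half-plane suffices
because the transform of a real spectrogram is point-symmetric. The DC
(0, 0) bin is excluded — it encodes overall level, not articulation — and
the contour is restricted to |ω_f| ≤ 40 cycles/kHz, which covers the
harmonic and formant structure of a child voice.

## Spectrogram and transform parameters

Defaults: 25 ms Gaussian analysis window (σ = window/6), 2 ms hop
(temporal-modulation Nyquist 250 Hz), FFT length chosen so the frequency
step is ≤ 11 Hz (ω_f range beyond ±40 cycles/kHz), 8 kHz ceiling,
log-magnitude scale expressed as dB above a floor set 60 dB below the
per-file maximum. All are configurable.

Two numerical choices matter and are deliberate:

- **60 dB floor.** Spectrogram cells far below the speech peaks (e.g.
  between harmonic lines) carry window-leakage beat products whose *dB*
  fluctuations are independent of their absolute level; with a deep
  (80 dB) floor these cells contribute a broadband power carpet that puts
  spurious energy in the POA band for every speaker and blunts the 99.9%
  contour. At 60 dB they clip to the floor and the POA area responds to
  genuine fast-timescale content only. The floor depth is a config field
  for users who want the deeper convention.
- **Chunked, tapered transform.** The 2-D transform runs on fixed 1 s
  spectrogram chunks (50% overlap), power-averaged, so the ω_t grid
  (~1 Hz) and bin counts are identical across recordings of any length —
  a prerequisite for comparing bin-count areas across participants. Each
  chunk is Hann-tapered along time before the transform; without the
  taper, sidelobe leakage from strong, non-bin-aligned slow-modulation
  lines floods the fast tail of the distribution. The stationary ω_t = 0
  column is computed exactly from the untapered row means so its large
  power cannot leak into the ±1 Hz bins. With `taper=None` the transform
  is plain and satisfies Parseval exactly against the mean-removed chunk
  energy (orthonormal FFT convention); with the taper, the conserved
  quantity is the tapered chunk's energy (power renormalized for the
  taper loss).

## Vocalization detection

The study design this package supports had human listeners count
vocalizations; here a single energy detector stands in. Frames of 10 ms
are active when their RMS exceeds an adaptive noise floor (5th percentile
of frame levels, capped at −60 dBFS so loud-throughout input stays
active) by 15 dB. Active runs separated by gaps of at most 300 ms merge
("no pause greater than" semantics: exactly 300 ms merges, one frame more
splits); the rate is count per minute. A second parameter set can emulate
a second rater, with the mean count reported.

## The synthetic cohort generator

No audio from the target population is distributable, so the package
ships a generator whose defaults encode the study conditions: three
groups (ASD n=39, TD n=26, DD n=20), 2–5 min recordings at 22 050 Hz, and
behavioral scores (Mullen receptive/expressive/fine-motor T-scores and
early-learning composite; Vineland receptive/expressive V-scores and
adaptive composite) drawn from per-group Gaussians with the published
group means and SDs, clipped to the published ranges (T-scores floor at
20, so low-scoring groups pile up at the floor, as real T-scores do). The
verbal-IQ proxy is VIQ = (Mullen RL + Mullen EL)/2, and the ASD group is
split at its sample-mean VIQ into HVIQ/LVIQ subgroups (ties go low, since
"more than the cutoff" defines the high group).

Each participant's audio is an utterance train: a harmonic carrier
(f0 ~ N(300, 30) Hz, ~3% per-utterance jitter) shaped by three formant
resonances (900/1800/3800 Hz, 250 Hz bandwidth), amplitude-modulated at
the syllable rate (U(2.5, 5) Hz) with modulation depth 0.8, with
utterances (lognormal around 1.2 s) separated by pauses ≥ 400 ms.
Optional components per participant: F2 sweeps (1800→2300 Hz over 150 ms
at each syllable onset, gliding back before the next) feeding the FT
band, and plosive-like noise bursts (5–15 ms, 2–4 Hz) feeding the POA
band. The burst amplitude is scaled by `fast_modulation_gain`, drawn
per participant from a lognormal — median 2.5 and σ=0.7 for the ASD-like
profile (long-tailed, mirroring that group's heterogeneity), 1.0 and
σ=0.4 for TD/DD — and the ASD log-gain is anti-correlated (ρ = −0.6) with
the verbal latent that drives the Mullen language scores, so fast-
timescale elevation concentrates in low-VIQ ASD participants. Sweep and
burst presence are Bernoulli per participant (sweeps 0.9 everywhere;
bursts 0.7/0.55/0.5 for ASD/TD/DD), which produces the decreasing
SR → FT → POA presence profile. Planned vocalization rates are
4/8/5 per minute (ASD/TD/DD).

Three generator details protect the log-domain representation from
artifacts: syllable modulation depth < 1 keeps voicing continuous between
peaks (full on/off gating is a square wave in dB whose harmonics blanket
the POA band); utterance on/offsets ramp as smoothsteps *in dB* over
50 ms (a linear-amplitude fade is a near-instantaneous cliff on a dB
spectrogram); and formant sweeps glide up and back down rather than
resetting discontinuously.

What the generator does **not** emulate: real phonetic content, prosody,
background noise and reverberation, adult overlap, or recording-channel
effects. Passing tests therefore demonstrate that the pipeline measures
what the generator controls (modulation-band structure, pause structure,
score distributions), not that it would reproduce any particular clinical
cohort's values.

Two named scenarios besides the default exist for calibration studies:
`null_profiles()` (identical generative settings in all three groups,
bursts always present — any detected group effect is a false positive)
and `planned_effect_profiles()` (ASD burst-gain median 3, σ=0.4,
gain–verbal ρ = −0.8; TD/DD at gain 1; burst nuisance parameters and
vocalization rates pinned to common values so the contrast is purely one
of burst energy).

A statistical surrogate (`simulate_records`) draws contour areas directly
from the participant-level generative model (lognormal gain × Poisson
bin-count noise × Bernoulli presence) without synthesizing audio. It is
used where thousands of cohorts are needed (type-I-error calibration) and
for correlation-injection studies at n=500; the audio path realises the
same model and is exercised directly everywhere else.

`inject_correlation` couples a feature and a score linearly in
standardized space (the score is regenerated as
μ + σ(ρ·z_feature + √(1−ρ²)·ε)), giving population Pearson correlation
exactly ρ and degenerating to an exact linear map at |ρ| = 1. The score's
first two moments are preserved; its marginal shape is only approximately
preserved.

## Statistics

Omnibus comparisons use one-way ANOVA (F = MS_between/MS_within) and
tie-corrected Kruskal–Wallis; `anova_from_summary` reconstructs F from
printed per-group mean/SD/n summaries and equals the raw-data ANOVA on
any dataset having exactly those summaries. Post-hocs are Tukey–Kramer
(studentized range; an explicitly flagged rank-transformed variant is
provided for pairing with a rank-based omnibus) and Fisher's protected
LSD (pooled-MSW pairwise t on N−k df, suppressed when the omnibus is not
significant). Association uses Pearson correlation matrices per group
with two-sided p and significance stars at 0.05/0.01. Descriptives
report mean, SD, SEM, t-based 95% CI half-width, range, and a
Shapiro–Wilk normality flag at α = 0.05. Categorical comparisons use the
Pearson chi-square without continuity correction. All tests are
two-sided at α = 0.05.

## Problem sizes used in tests and the acceptance script

Replicate-based checks scale the cohort and analysis down so the full
suite runs on one CPU in minutes; these sizes are the package's own
choices and are stated here so results are interpretable:

- Simulation analysis config: 5 ms hop (ω_t Nyquist exactly 100 Hz),
  1024-point FFT, 6 kHz ceiling; otherwise defaults.
- Effect recovery: 100 replicates of a `planned_effect_profiles(10, 8, 8)`
  cohort, 10 s recordings; the LVIQ-ASD vs TD vs DD ANOVA on POA area is
  expected significant with the correct mean ordering in ≥ 80% of
  replicates (observed: essentially all).
- Type-I calibration: 1000 replicates of the null scenario via the
  statistical surrogate at full group sizes (39/26/20).
- Presence profile: default-scenario cohorts scaled to 12/10/10
  participants with 30 s recordings.
- Correlation recovery: ρ = 0.5 injected at n = 500 (surrogate), checked
  against the Fisher-z 95% CI.

## Known limitations

- Contour areas grow with estimator noise: short recordings (few
  averaged chunks) inflate areas and their variance, so areas should only
  be compared across recordings analyzed with the same chunk grid and
  broadly similar voiced durations.
- The presence flag uses a strict area > 0 rule; isolated "dust" bins can
  flip it, which makes presence a conservative measure. A minimum-area
  threshold is exposed in `FeatureConfig.min_presence_area` (default 0).
- The energy-based vocalization detector does not distinguish speech from
  non-speech vocal sound, and annotations of adult speech are taken as
  given rather than inferred.
- With ω_t Nyquist at exactly 100 Hz (5 ms hop), content above 100 Hz
  aliases into the analyzed range; the default 2 ms hop avoids this.
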