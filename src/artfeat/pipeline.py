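"""End-to-end orchestration: cohort -> features -> statistics -> report.

``run`` takes a :class:`PipelineConfig`, obtains audio either from the
synthetic cohort generator or from a user-supplied WAV manifest, extracts
articulatory features and vocalization rates per participant, runs the
group-statistics battery, and writes a report bundle (features CSV, stats
JSON, presence percentages, run manifest). Per-participant failures are
logged and skipped, never silently dropped.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import artfeat

from . import stats as cstats
from .audio import AudioSample, ExclusionAnnotation, excise_and_concatenate, read_wav, resample
from .errors import ConfigError
from .features import (
    BandDefinition,
    FeatureConfig,
    SpectrogramConfig,
    extract_features,
    validate_bands,
)
from .records import ParticipantRecord, records_to_frame
from .synth import (
    CohortSpec,
    default_profiles,
    generate_cohort,
    null_profiles,
    planned_effect_profiles,
)
from .vocal import detect_vocalizations

log = logging.getLogger("artfeat.pipeline")

_SCENARIOS = {
    "default": default_profiles,
    "null": null_profiles,
    "effect": planned_effect_profiles,
}


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # or "audio-dir"
    seed: int | None = 0
    outdir: str = "artfeat_out"
    # synthetic mode
    scenario: str = "default"
    recording_duration: float = 120.0
    group_ns: dict[str, int] | None = None  # override per-group sizes
    sample_rate: int = 22050
    # audio-dir mode
    manifest: str | None = None  # CSV: id, wav_path[, annotation_path], group, scores...
    # analysis parameters
    window_length_ms: float = 25.0
    hop_ms: float = 2.0
    amplitude_scale: str = "log"
    log_floor_db: float = 60.0
    max_frequency: float = 8000.0
    chunk_duration: float = 1.0
    energy_fraction: float = 0.999
    wf_max: float = 40.0
    bands: list[tuple[str, float, float]] = field(
        default_factory=lambda: [("SR", 0.0, 10.0), ("FT", 10.0, 50.0), ("POA", 50.0, 100.0)]
    )
    pause_ms: float = 300.0
    frame_ms: float = 10.0
    threshold_db: float = 15.0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "bands" in raw:
            raw["bands"] = [tuple(b) for b in raw["bands"]]
        return cls(**raw)

    def feature_config(self) -> FeatureConfig:
        return FeatureConfig(
            spectrogram=SpectrogramConfig(
                window_length_ms=self.window_length_ms,
                hop_ms=self.hop_ms,
                amplitude_scale=self.amplitude_scale,
                log_floor_db=self.log_floor_db,
                max_frequency=self.max_frequency,
            ),
            chunk_duration=self.chunk_duration,
            energy_fraction=self.energy_fraction,
            wf_max=self.wf_max,
            bands=tuple(BandDefinition(*b) for b in self.bands),
        )


def validate_config(config: PipelineConfig) -> list[str]:
    """Return an empty list iff the config is runnable."""
    problems: list[str] = []
    if config.mode not in ("synthetic", "audio-dir"):
        problems.append(f"mode: unknown mode {config.mode!r}")
    if config.mode == "synthetic":
        if config.seed is None:
            problems.append("seed: mandatory in synthetic mode")
        if config.scenario not in _SCENARIOS:
            problems.append(f"scenario: unknown scenario {config.scenario!r}")
        if config.recording_duration <= 0:
            problems.append("recording_duration: must be > 0")
    else:
        if config.manifest is None:
            problems.append("manifest: required in audio-dir mode")
        elif not Path(config.manifest).exists():
            problems.append(f"manifest: path {config.manifest} does not exist")
    if config.hop_ms > config.window_length_ms:
        problems.append("hop_ms: must not exceed window_length_ms")
    if config.hop_ms > 0 and 1000.0 / (2 * config.hop_ms) < max(
        (b[2] for b in config.bands), default=100.0
    ):
        problems.append("hop_ms: temporal-modulation Nyquist below top band edge")
    if not 0 < config.energy_fraction < 1:
        problems.append("energy_fraction: must be in (0, 1)")
    if config.pause_ms <= 0:
        problems.append("pause_ms: must be > 0")
    try:
        bands = tuple(BandDefinition(*b) for b in config.bands)
        problems += [f"bands: {p}" for p in validate_bands(bands)]
    except (ConfigError, TypeError) as exc:
        problems.append(f"bands: {exc}")
    return problems


@dataclass
class ReportBundle:
    records: list[ParticipantRecord]
    features_frame: pd.DataFrame
    stats: dict
    presence: pd.DataFrame | None
    failures: list[dict]
    outdir: Path | None = None


def _stat_to_dict(res: cstats.StatResult) -> dict:
    return {
        "test": res.test_name,
        "statistic": res.statistic,
        "df": list(res.df),
        "p_value": res.p_value,
        "groups": res.group_summaries,
        "posthoc": [
            {
                "pair": list(pr.pair), "statistic": pr.statistic,
                "p_value": pr.p_value, "significant": pr.significant,
                "note": pr.note,
            }
            for pr in res.posthoc
        ],
        "note": res.note,
    }


def _load_manifest(config: PipelineConfig):
    frame = pd.read_csv(config.manifest)
    required = {"id", "wav_path", "group"}
    missing = required - set(frame.columns)
    if missing:
        raise ConfigError(f"manifest missing columns: {sorted(missing)}")
    base = Path(config.manifest).parent
    items = []
    score_cols = [
        c for c in frame.columns
        if c not in ("id", "wav_path", "annotation_path", "group")
    ]
    for _, row in frame.iterrows():
        def _audio(row=row):
            sample = read_wav(base / str(row["wav_path"]))
            sample = resample(sample, config.sample_rate)
            ann = None
            if "annotation_path" in row and isinstance(row["annotation_path"], str):
                ann = ExclusionAnnotation.from_csv(base / row["annotation_path"])
            import warnings as _warnings
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                return excise_and_concatenate([sample], [ann])

        rec = ParticipantRecord(
            id=str(row["id"]), group=str(row["group"]),
            scores={c: float(row[c]) for c in score_cols if pd.notna(row[c])},
        )
        items.append((rec, _audio))
    return items


def _cohort_items(config: PipelineConfig):
    if config.mode == "synthetic":
        profiles = _SCENARIOS[config.scenario]()
        if config.group_ns:
            profiles = tuple(
                dataclasses.replace(p, n=config.group_ns.get(p.label, p.n))
                for p in profiles
            )
        cohort = CohortSpec(
            profiles=profiles, sample_rate=config.sample_rate,
            recording_duration=config.recording_duration,
            seed=int(config.seed),
        )
        return [(rec, (lambda a=audio: a)) for rec, audio in generate_cohort(cohort)]
    return _load_manifest(config)


def _run_stats(records: list[ParticipantRecord]) -> dict:
    out: dict = {}
    with_features = [r for r in records if r.features is not None]
    if len(with_features) >= 4:
        # timescale effect, collapsed across groups
        areas = {
            band: np.array([r.features.area(band) for r in with_features])
            for band in ("SR", "FT", "POA")
        }
        kw = cstats.kruskal_wallis(areas)
        kw = dataclasses.replace(kw, posthoc=cstats.tukey_posthoc(areas, ranked=True))
        out["timescale_kruskal_wallis"] = _stat_to_dict(kw)

        groups_present = {r.group for r in with_features}
        for band in ("SR", "FT", "POA"):
            try:
                vals = cstats.group_values(with_features, f"{band.lower()}_area")
                if len(vals) >= 2 and all(len(v) >= 2 for v in vals.values()):
                    out[f"{band.lower()}_group_kruskal_wallis"] = _stat_to_dict(
                        cstats.kruskal_wallis(vals)
                    )
            except Exception as exc:  # noqa: BLE001
                log.warning("group test for %s failed: %s", band, exc)

        # low-verbal ASD subgroup comparison on the fastest timescale
        if "ASD" in groups_present and len(groups_present) >= 2:
            try:
                high, low = cstats.split_by_viq(with_features)
                labels = {r.id: "LVIQ-ASD" for r in low}
                labels.update({r.id: "HVIQ-ASD" for r in high})
                for tag, subset in (("lviq", low), ("hviq", high)):
                    vals = cstats.group_values(
                        with_features, "poa_area",
                        groups=(f"{tag.upper()}-ASD", "TD", "DD"),
                        labels=labels,
                    )
                    if len(vals) >= 2 and all(len(v) >= 2 for v in vals.values()):
                        res = cstats.one_way_anova(vals)
                        res = dataclasses.replace(
                            res, posthoc=cstats.fisher_lsd_posthoc(vals)
                        )
                        out[f"poa_{tag}_anova"] = _stat_to_dict(res)
            except Exception as exc:  # noqa: BLE001
                log.warning("VIQ-split analysis failed: %s", exc)

        out["poa_descriptives"] = {
            group: cstats.descriptive_stats(
                [r.features.poa_area for r in with_features if r.group == group]
            )
            for group in sorted(groups_present)
            if sum(r.group == group for r in with_features) >= 2
        }

    with_rate = [r for r in records if r.voc_rate is not None]
    rate_vals = cstats.group_values(with_rate, "voc_rate")
    if len(rate_vals) >= 2 and all(len(v) >= 2 for v in rate_vals.values()):
        res = cstats.one_way_anova(rate_vals)
        res = dataclasses.replace(res, posthoc=cstats.tukey_posthoc(rate_vals))
        out["voc_rate_anova"] = _stat_to_dict(res)
    return out


def run(config: PipelineConfig) -> ReportBundle:
    """Execute the pipeline and write the report bundle to ``config.outdir``."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    problems = validate_config(config)
    if problems:
        raise ConfigError("; ".join(problems))
    feat_config = config.feature_config()

    records: list[ParticipantRecord] = []
    failures: list[dict] = []
    for rec, audio_fn in _cohort_items(config):
        try:
            audio: AudioSample = audio_fn()
            rec.features = extract_features(audio, feat_config)
            rec.voc_rate = detect_vocalizations(
                audio, pause_ms=config.pause_ms, frame_ms=config.frame_ms,
                threshold_db=config.threshold_db,
            ).rate
        except Exception as exc:  # noqa: BLE001 - keep going, log the failure
            failures.append({"id": rec.id, "stage": type(exc).__name__, "error": str(exc)})
            log.warning("participant %s failed: %s", rec.id, exc)
            continue
        records.append(rec)

    frame = records_to_frame(records)
    stats_out = _run_stats(records)
    presence = None
    if any(r.features is not None for r in records):
        presence = cstats.presence_percentages(
            [r for r in records if r.features is not None]
        )
        stats_out["presence_percentages"] = {
            g: {b: float(v) for b, v in row.items()}
            for g, row in presence.iterrows()
        }

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame.to_csv(outdir / "features.csv", index=False)
    with open(outdir / "stats.json", "w") as fh:
        json.dump(stats_out, fh, indent=2, default=float)
    if presence is not None:
        presence.to_csv(outdir / "presence.csv")
    with open(outdir / "failures.json", "w") as fh:
        json.dump(failures, fh, indent=2)
    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "versions": {
            "artfeat": artfeat.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_participants": len(records),
        "n_failures": len(failures),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return ReportBundle(
        records=records, features_frame=frame, stats=stats_out,
        presence=presence, failures=failures, outdir=outdir,
    )
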