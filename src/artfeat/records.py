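"""Participant records: group label, behavioral scores, extracted features."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import PreconditionError
from .features import ArticulatoryFeatures

GROUPS = ("ASD", "TD", "DD")

#: behavioral score columns carried by every record
SCORE_COLUMNS = (
    "age_months",
    "mullen_rl", "mullen_el", "mullen_fm", "mullen_elc",
    "vabs_rl", "vabs_el", "vabs_abc",
)

FEATURE_COLUMNS = ("sr_area", "ft_area", "poa_area", "total_area")


@dataclass
class ParticipantRecord:
    """One participant's metadata, scores and derived measures.

    ``viq`` — the verbal-IQ proxy — is defined as the mean of the Mullen
    receptive and expressive language T-scores.
    """

    id: str
    group: str
    scores: dict[str, float] = field(default_factory=dict)
    features: ArticulatoryFeatures | None = None
    voc_rate: float | None = None
    extras: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise PreconditionError(f"unknown group {self.group!r}")

    @property
    def viq(self) -> float:
        return (self.scores["mullen_rl"] + self.scores["mullen_el"]) / 2.0

    def copy(self) -> "ParticipantRecord":
        return replace(self, scores=dict(self.scores), extras=dict(self.extras))


def records_to_frame(records: list[ParticipantRecord]) -> pd.DataFrame:
    """Flatten records into a participants x columns table."""
    rows = []
    for rec in records:
        row: dict[str, object] = {"id": rec.id, "group": rec.group}
        for col in SCORE_COLUMNS:
            row[col] = rec.scores.get(col, np.nan)
        row["viq"] = rec.viq if {"mullen_rl", "mullen_el"} <= rec.scores.keys() else np.nan
        if rec.features is not None:
            row["sr_area"] = rec.features.sr_area
            row["ft_area"] = rec.features.ft_area
            row["poa_area"] = rec.features.poa_area
            row["total_area"] = rec.features.total_area
            for band, flag in rec.features.presence.items():
                row[f"presence_{band.lower()}"] = bool(flag)
        row["voc_rate"] = rec.voc_rate if rec.voc_rate is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def get_value(rec: ParticipantRecord, name: str) -> float:
    """Look up a feature/score/derived value on a record by column name."""
    if name in rec.scores:
        return float(rec.scores[name])
    if name == "viq":
        return float(rec.viq)
    if name == "voc_rate":
        if rec.voc_rate is None:
            raise KeyError("voc_rate not set on record")
        return float(rec.voc_rate)
    if name in FEATURE_COLUMNS:
        if rec.features is None:
            raise KeyError(f"features not set on record {rec.id}")
        return float(getattr(rec.features, name))
    if name in rec.extras:
        return float(rec.extras[name])
    raise KeyError(f"unknown field {name!r}")
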