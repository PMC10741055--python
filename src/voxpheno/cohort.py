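"""Cohort stratification and the 77-dimensional feature vector.

Analyzing pediatric and adult voices together is unreliable because of
vocal-tract size differences, so subjects are stratified into pediatric
subjects (PS, under 12 years), female adults (FA) and male adults (MA).
Each complete subject-session yields 77 ordered features: the 24 acoustic
parameters for each of /a/, /I/, /u/, followed by the five articulatory
metrics.  The ordering is a published contract and must never change.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from voxpheno.acoustics import PROFILE_FIELDS, AcousticProfile
from voxpheno.articulation import ARTICULATORY_FEATURES, ArticulatoryMetrics
from voxpheno.audio_io import CARDINAL_VOWELS, SubjectMeta
from voxpheno.errors import IncompleteSessionError, VoxPhenoError

PEDIATRIC_AGE_LIMIT = 12.0

GROUP_LABELS = ("PS", "FA", "MA")

#: ordered 77 feature identifiers: 24 per vowel (suffixed _a, _I, _u in the
#: catalog order) then the five articulatory metrics.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{field}_{vowel}" for vowel in CARDINAL_VOWELS for field in PROFILE_FIELDS
) + ARTICULATORY_FEATURES

assert len(FEATURE_NAMES) == 77

METADATA_COLUMNS = ("subject_id", "session_id", "group", "label", "age_years")


def assign_group(meta: SubjectMeta) -> str:
    """PS if under 12 years; otherwise FA/MA by sex."""
    if meta.age_years < PEDIATRIC_AGE_LIMIT:
        return "PS"
    return "FA" if meta.sex == "female" else "MA"


@dataclass(frozen=True)
class FeatureVector:
    """One subject-session row of the feature table."""

    values: np.ndarray  # length 77, order FEATURE_NAMES
    subject_id: str
    session_id: str
    group: str
    label: str
    age_years: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.shape != (len(FEATURE_NAMES),):
            raise ValueError(
                f"feature vector must have length {len(FEATURE_NAMES)}, "
                f"got {values.shape}"
            )
        object.__setattr__(self, "values", values)

    @property
    def names(self) -> tuple[str, ...]:
        return FEATURE_NAMES


def build_feature_vector(
    profiles: dict[str, AcousticProfile],
    art: ArticulatoryMetrics,
    meta: SubjectMeta,
    session_id: str = "s1",
) -> FeatureVector:
    """Assemble the 77 ordered features for one subject-session.

    All three cardinal vowels must be present; sessions missing a vowel
    are excluded from classification rather than imputed.
    """
    missing = set(CARDINAL_VOWELS) - set(profiles)
    if missing:
        raise IncompleteSessionError(
            f"session {meta.subject_id}/{session_id} missing vowels: {sorted(missing)}"
        )
    values = np.concatenate(
        [profiles[v].as_array() for v in CARDINAL_VOWELS]
        + [np.array([getattr(art, name) for name in ARTICULATORY_FEATURES])]
    )
    return FeatureVector(
        values=values,
        subject_id=meta.subject_id,
        session_id=session_id,
        group=assign_group(meta),
        label=meta.label,
        age_years=meta.age_years,
    )


def feature_frame(rows: list[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into the canonical table layout."""
    records = []
    for r in rows:
        rec = {
            "subject_id": r.subject_id,
            "session_id": r.session_id,
            "group": r.group,
            "label": r.label,
            "age_years": r.age_years,
        }
        rec.update(dict(zip(FEATURE_NAMES, r.values)))
        records.append(rec)
    return pd.DataFrame(records, columns=list(METADATA_COLUMNS) + list(FEATURE_NAMES))


def write_feature_table(rows: list[FeatureVector] | pd.DataFrame, path: str | Path) -> None:
    """Write the feature table as UTF-8 CSV with dot decimal separator.

    Floats are written with full precision (repr) so a round trip
    preserves values to better than 1e-12 relative.
    """
    df = rows if isinstance(rows, pd.DataFrame) else feature_frame(rows)
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table, validating the column contract."""
    df = pd.read_csv(path, dtype={"subject_id": str, "session_id": str})
    expected = list(METADATA_COLUMNS) + list(FEATURE_NAMES)
    if list(df.columns) != expected:
        raise VoxPhenoError(
            f"feature table {path} does not match the 77-feature schema"
        )
    return df
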