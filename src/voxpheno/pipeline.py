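"""End-to-end orchestration: analyze -> features -> stats -> train.

Every run is reproducible: all randomness flows from a single root seed,
and each artifact is stamped with the configuration hash, seed and
package version.  Reruns with identical configuration reproduce the
feature table bitwise and the CV reports exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from voxpheno import __version__
from voxpheno.acoustics import analyze_vowel, category_for
from voxpheno.articulation import (
    VowelTriangle,
    articulatory_metrics,
    plot_triangles,
    triangle_plot_data,
)
from voxpheno.audio_io import (
    CARDINAL_VOWELS,
    SubjectMeta,
    load_recording,
    read_manifest,
)
from voxpheno.classify import BUDGETS, run_group_experiment
from voxpheno.cohort import (
    FEATURE_NAMES,
    build_feature_vector,
    feature_frame,
    read_feature_table,
    write_feature_table,
)
from voxpheno.errors import IncompleteSessionError, VoxPhenoError
from voxpheno.stats import ALPHA, group_feature_map, significance_table

logger = logging.getLogger(__name__)

GROUPS = ("PS", "FA", "MA")


@dataclass
class PipelineConfig:
    """All pipeline settings with their defaults (10 folds, alpha 0.05,
    optimizer budgets 30/60/60)."""

    manifest: str = "manifest.csv"
    out_dir: str = "out"
    central_fraction: float = 0.5
    alpha: float = ALPHA
    seed: int = 0
    budgets: dict = field(default_factory=lambda: dict(BUDGETS))
    tuner: str = "surrogate"  # or "random"
    groups: tuple = GROUPS
    families: tuple = ("knn", "svm", "rf")

    def config_hash(self) -> str:
        """Hash of the scientific settings (filesystem paths excluded, so
        the same analysis in a different directory stamps identically)."""
        payload = asdict(self)
        payload.pop("manifest")
        payload.pop("out_dir")
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stamp(config: PipelineConfig) -> dict:
    return {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }


def _mean_profile(profiles: list) -> dict:
    """Average repeated recordings of one vowel within a session."""
    from voxpheno.acoustics import AcousticProfile, PROFILE_FIELDS

    if len(profiles) == 1:
        return profiles[0]
    import numpy as np

    arr = np.mean([p.as_array() for p in profiles], axis=0)
    return AcousticProfile(**dict(zip(PROFILE_FIELDS, arr)))


def analyze_manifest(
    manifest: pd.DataFrame,
    base_dir: str | Path,
    central_fraction: float = 0.5,
) -> pd.DataFrame:
    """Analyze every recording in a manifest into the feature table.

    Repetitions of a vowel within one session are averaged (the count is
    logged); sessions missing one of the three cardinal vowels are
    excluded from the table.  A corrupt recording aborts the stage with a
    message naming the file.
    """
    base_dir = Path(base_dir)
    rows = []
    for (sid, sess), part in manifest.groupby(["subject_id", "session_id"], sort=True):
        first = part.iloc[0]
        meta = SubjectMeta(
            subject_id=str(sid),
            age_years=float(first["age_years"]),
            sex=str(first["sex"]),
            label=str(first["label"]),
        )
        cat = category_for(meta)
        profiles = {}
        for vowel in CARDINAL_VOWELS:
            vowel_rows = part[part["vowel"] == vowel]
            if vowel_rows.empty:
                continue
            reps = []
            for p in vowel_rows["path"]:
                rec = load_recording(base_dir / p, meta, vowel, session_id=str(sess))
                reps.append(analyze_vowel(rec, cat, central_fraction=central_fraction))
            if len(reps) > 1:
                logger.info(
                    "averaged %d repetitions of /%s/ for %s/%s", len(reps), vowel, sid, sess
                )
            profiles[vowel] = _mean_profile(reps)
        try:
            tri = VowelTriangle.from_profiles(profiles)
        except KeyError:
            logger.warning(
                "session %s/%s lacks a cardinal vowel; excluded", sid, sess
            )
            continue
        art = articulatory_metrics(tri)
        rows.append(build_feature_vector(profiles, art, meta, session_id=str(sess)))
    if not rows:
        raise IncompleteSessionError("no complete subject-session in manifest")
    return feature_frame(rows)


def run_stats_stage(
    table: pd.DataFrame, out_dir: Path, alpha: float
) -> dict[str, pd.DataFrame]:
    out = {}
    for group in GROUPS:
        if (table["group"] == group).sum() == 0:
            continue
        fmap = group_feature_map(table, group, FEATURE_NAMES)
        sig = significance_table(fmap, alpha=alpha)
        sig.to_csv(out_dir / f"stats_{group}.csv", index=False)
        out[group] = sig
    return out


def run_train_stage(table: pd.DataFrame, config: PipelineConfig, out_dir: Path) -> dict:
    results = {}
    for group in config.groups:
        sub = table[table["group"] == group]
        if sub.empty or sub["label"].nunique() < 2 or sub["subject_id"].nunique() < 10:
            logger.warning("group %s too small for 10-fold training; skipped", group)
            continue
        res = run_group_experiment(
            table,
            group,
            budgets=config.budgets,
            seed=config.seed,
            method=config.tuner,
            families=config.families,
        )
        payload = {
            "winner": res["winner"],
            "reports": {f: r.to_dict() for f, r in res["reports"].items()},
            **_stamp(config),
        }
        with open(out_dir / f"cv_report_{group}.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        results[group] = payload
    return results


def run_triangle_stage(table: pd.DataFrame, out_dir: Path) -> None:
    for group in GROUPS:
        sub = table[table["group"] == group]
        if sub.empty:
            continue
        triangles = {}
        for label, part in sub.groupby("label"):
            triangles[label] = VowelTriangle(
                F1a=part["f1_mean_a"].mean(),
                F2a=part["f2_mean_a"].mean(),
                F1I=part["f1_mean_I"].mean(),
                F2I=part["f2_mean_I"].mean(),
                F1u=part["f1_mean_u"].mean(),
                F2u=part["f2_mean_u"].mean(),
            )
        data = triangle_plot_data(triangles, include_reference=True)
        plot_triangles(data, str(out_dir / f"triangles_{group}.svg"))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run log (also written to disk).

    Stage order: analyze -> features -> stats -> train (plus triangle
    plots).  Any stage failure raises with a stage-tagged message.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {"stages": [], **_stamp(config)}

    def _stage(name: str, fn):
        try:
            result = fn()
        except Exception as exc:
            raise VoxPhenoError(f"stage '{name}' failed: {exc}") from exc
        log["stages"].append(name)
        return result

    manifest_path = Path(config.manifest)
    manifest = _stage("analyze", lambda: read_manifest(manifest_path))
    table = _stage(
        "features",
        lambda: analyze_manifest(
            manifest, manifest_path.parent, config.central_fraction
        ),
    )
    write_feature_table(table, out_dir / "features.csv")
    _stage("stats", lambda: run_stats_stage(table, out_dir, config.alpha))
    run_triangle_stage(table, out_dir)
    log["train"] = _stage("train", lambda: run_train_stage(table, config, out_dir))
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=str)
    return log
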