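"""Shared fixtures: synthetic vowels and a small analyzed cohort.

All audio is generated at test time; heavier fixtures are session-scoped
so synthesis and analysis run once.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import settings

from voxpheno.audio_io import CLASS_LABELS, read_manifest
from voxpheno.pipeline import analyze_manifest
from voxpheno.synth import (
    SEPARATED_CLASS_EFFECTS,
    CohortSpec,
    VowelSpec,
    generate_cohort,
    synthesize_vowel,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

# formant-quality warnings on deliberately noisy fixtures are expected
warnings.filterwarnings(
    "ignore", message="only .* voiced frames yielded three stable formants"
)


@pytest.fixture(scope="session")
def clean_female_vowel():
    """A clean adult-female /a/-like vowel with known parameters."""
    spec = VowelSpec(
        f0=210.0,
        formants=(800.0, 1300.0, 2800.0),
        jitter_pct=0.0,
        snr_db=60.0,
        duration=3.0,
        rate=22050,
        seed=101,
    )
    return spec, synthesize_vowel(spec)


@pytest.fixture(scope="session")
def male_vowel_25db():
    """An adult-male vowel at a realistic recording SNR."""
    spec = VowelSpec(
        f0=120.0,
        formants=(700.0, 1250.0, 2500.0),
        jitter_pct=1.0,
        snr_db=25.0,
        duration=3.0,
        rate=22050,
        seed=102,
    )
    return spec, synthesize_vowel(spec)


#: scaled-down cohort synthesis settings shared by the end-to-end tests;
#: 16 kHz / 1.5 s keeps the full pipeline fast without touching the
#: generator's class-effect structure.
COHORT_KW = dict(duration=1.5, rate=16000)


@pytest.fixture(scope="session")
def ps_cohort(tmp_path_factory):
    """Synthesized pediatric cohort (4 subjects/class) and its manifest."""
    out = tmp_path_factory.mktemp("ps_cohort")
    spec = CohortSpec(
        group="PS",
        n_subjects={c: 4 for c in CLASS_LABELS},
        class_effects=SEPARATED_CLASS_EFFECTS,
        between_subject_sd_rel=0.02,
        seed=11,
        **COHORT_KW,
    )
    manifest = generate_cohort(spec, out)
    return spec, manifest, out


@pytest.fixture(scope="session")
def ps_feature_table(ps_cohort):
    """Feature table of the pediatric cohort (analyzed once per session)."""
    _, _, out = ps_cohort
    return analyze_manifest(read_manifest(out / "manifest.csv"), out)
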