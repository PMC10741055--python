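"""Source-filter synthesis of sustained cardinal vowels with known truth.

The generator exists so every analysis stage can be validated against
ground truth: a glottal pulse train with controllable cycle-to-cycle
jitter is shaped by a cascade of three two-pole resonators (the formants)
and mixed with white noise at a prescribed SNR.  A cohort generator draws
subject-level parameters around class-specific means and writes WAV files
plus a manifest compatible with :mod:`voxpheno.audio_io`.

Class effect directions (formant centralization for some syndromes,
elevated noise or jitter for others) are test fixtures emulating the
qualitative clinical picture; they are not clinical estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

from voxpheno.audio_io import CARDINAL_VOWELS, CLASS_LABELS, Recording

DEFAULT_RATE = 22050
DEFAULT_DURATION = 3.0  # sustained vowels are held for at least 3 s
DEFAULT_BANDWIDTHS = (80.0, 120.0, 160.0)  # typical adult values, Hz


@dataclass(frozen=True)
class VowelSpec:
    """Ground-truth parameters of one synthetic sustained vowel."""

    f0: float
    formants: tuple[float, float, float]
    bandwidths: tuple[float, float, float] = DEFAULT_BANDWIDTHS
    jitter_pct: float = 0.0
    snr_db: float = 40.0
    duration: float = DEFAULT_DURATION
    rate: int = DEFAULT_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        f1, f2, f3 = self.formants
        if not (0 < self.f0 < f1 < f2 < f3 < self.rate / 2):
            raise ValueError(
                f"require 0 < f0 < F1 < F2 < F3 < rate/2, got f0={self.f0}, "
                f"formants={self.formants}, rate={self.rate}"
            )
        if self.duration < 1.0:
            raise ValueError(f"duration must be >= 1 s, got {self.duration}")
        if self.jitter_pct < 0:
            raise ValueError("jitter_pct must be non-negative")


def _resonator_sos(freq: float, bandwidth: float, rate: int) -> np.ndarray:
    """Two-pole resonator section with unit gain at its center frequency."""
    r = np.exp(-np.pi * bandwidth / rate)
    theta = 2 * np.pi * freq / rate
    a = [1.0, -2.0 * r * np.cos(theta), r * r]
    # normalize so |H(e^{j theta})| = 1
    w, h = signal.freqz([1.0], a, worN=[theta])
    b0 = 1.0 / max(abs(h[0]), 1e-12)
    return np.array([[b0, 0.0, 0.0, *a]])


def synthesize_vowel(spec: VowelSpec) -> Recording:
    """Render a :class:`VowelSpec` to a peak-normalized waveform.

    The source is a pulse train shaped by a double-pole glottal low-pass
    and radiation differentiation (net spectral tilt of roughly
    -6 dB/octave); each glottal period is perturbed independently by
    zero-mean Gaussian noise with relative standard deviation
    ``jitter_pct / 100``.  White noise is added at ``snr_db`` relative to
    the filtered voiced signal power.
    """
    rng = np.random.default_rng(spec.seed)
    rate, f0 = spec.rate, spec.f0
    n_total = int(round(spec.duration * rate))

    # place glottal closure instants with per-cycle period perturbation
    t, instants = 0.0, []
    mean_period = 1.0 / f0
    while t < spec.duration:
        instants.append(t)
        period = mean_period * (1.0 + (spec.jitter_pct / 100.0) * rng.standard_normal())
        t += max(period, 0.2 * mean_period)
    # sub-sample pulse placement (linear split between adjacent samples) so
    # that sample quantization does not inject spurious jitter
    source = np.zeros(n_total + 1)
    pos = np.array(instants) * rate
    pos = pos[pos < n_total - 1]
    base = np.floor(pos).astype(int)
    frac = pos - base
    np.add.at(source, base, 1.0 - frac)
    np.add.at(source, base + 1, frac)
    source = source[:n_total]
    # glottal shaping: double real pole (~ -12 dB/oct above 100 Hz) followed
    # by the radiation differentiation; keeps the fundamental dominant
    a = np.exp(-np.pi * 100.0 / rate)
    glottal = signal.lfilter([1.0], [1.0, -2.0 * a, a * a], source)
    src = np.diff(glottal, prepend=0.0)

    sos = np.vstack(
        [_resonator_sos(f, b, rate) for f, b in zip(spec.formants, spec.bandwidths)]
    )
    voiced = signal.sosfilt(sos, src)

    sig_power = np.mean(voiced**2)
    noise_power = sig_power / (10.0 ** (spec.snr_db / 10.0))
    out = voiced + np.sqrt(noise_power) * rng.standard_normal(n_total)
    out = 0.95 * out / np.max(np.abs(out))
    return Recording(samples=out, rate=rate, subject_id="synth", vowel="a")


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: per voice category: F0 mean and per-vowel (F1, F2, F3) targets, Hz.
#: Values follow the field's standard tables for Italian-style cardinal
#: vowels (/I/ carries an F2 a few hundred Hz below the American /i/).
CATEGORY_VOWEL_TARGETS = {
    "child": {
        "f0": 240.0,
        "a": (1000.0, 1700.0, 3300.0),
        "I": (450.0, 2800.0, 3600.0),
        "u": (480.0, 1100.0, 3100.0),
    },
    "adult_female": {
        "f0": 210.0,
        "a": (850.0, 1450.0, 2850.0),
        "I": (380.0, 2300.0, 2950.0),
        "u": (380.0, 950.0, 2700.0),
    },
    "adult_male": {
        "f0": 120.0,
        "a": (700.0, 1250.0, 2500.0),
        "I": (300.0, 1950.0, 2600.0),
        "u": (320.0, 800.0, 2300.0),
    },
}

#: qualitative class effects used as synthetic fixtures:
#: ``centralization`` moves each vowel's (F1, F2) that fraction of the way
#: toward the vowel-triangle centroid; the remaining entries scale or shift
#: the named source parameters.
DEFAULT_CLASS_EFFECTS = {
    "HS": {},
    "NS": {"centralization": 0.30, "snr_db_shift": -12.0},
    "DS": {"centralization": 0.20, "f0_scale": 1.08},
    "CS": {"jitter_scale": 2.5, "snr_db_shift": -8.0},
    "SMS": {"f0_scale": 1.12, "f1_shift": 60.0},
}


#: fixture for end-to-end recovery checks: every class pair is separated by
#: at least ~5 between-subject SDs (at ``between_subject_sd_rel = 0.02``) in
#: one or more source parameters, so a competent classifier must approach
#: perfect accuracy.  Not a clinical description.
SEPARATED_CLASS_EFFECTS = {
    "HS": {},
    "NS": {"centralization": 0.35, "snr_db_shift": -14.0},
    "DS": {"centralization": 0.15, "f0_scale": 1.15},
    "CS": {"jitter_scale": 4.0, "snr_db_shift": -7.0},
    "SMS": {"f0_scale": 0.85, "f1_shift": 120.0},
}


@dataclass(frozen=True)
class CohortSpec:
    """Sampling plan for a synthetic multi-class cohort.

    ``group`` selects the voice category emulated (PS draws children of
    both sexes, FA adult females, MA adult males).  Between-subject
    variation is Gaussian around class means with the given relative SDs.
    """

    group: str = "PS"  # PS | FA | MA
    n_subjects: dict[str, int] = field(
        default_factory=lambda: {c: 5 for c in CLASS_LABELS}
    )
    sessions_per_subject: int = 1
    class_effects: dict[str, dict] = field(
        default_factory=lambda: DEFAULT_CLASS_EFFECTS
    )
    between_subject_sd_rel: float = 0.04  # relative SD on F0 and formants
    jitter_pct_mean: float = 0.8
    snr_db_mean: float = 30.0
    duration: float = DEFAULT_DURATION
    rate: int = DEFAULT_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in ("PS", "FA", "MA"):
            raise ValueError(f"group must be PS, FA or MA, got {self.group!r}")
        if any(n < 1 for n in self.n_subjects.values()):
            raise ValueError("n_subjects must be >= 1 per class")


def _category_for_group(group: str) -> str:
    return {"PS": "child", "FA": "adult_female", "MA": "adult_male"}[group]


def _apply_class_effects(
    f0: float, formants: dict[str, tuple], effects: dict
) -> tuple[float, dict[str, tuple]]:
    """Shift category targets by one class's qualitative effect map."""
    f0 = f0 * effects.get("f0_scale", 1.0)
    out = {}
    cent = effects.get("centralization", 0.0)
    if cent:
        c1 = np.mean([formants[v][0] for v in CARDINAL_VOWELS])
        c2 = np.mean([formants[v][1] for v in CARDINAL_VOWELS])
    for v in CARDINAL_VOWELS:
        f1, f2, f3 = formants[v]
        if cent:
            f1 = f1 + cent * (c1 - f1)
            f2 = f2 + cent * (c2 - f2)
        f1 += effects.get("f1_shift", 0.0)
        out[v] = (f1, f2, f3)
    return f0, out


def subject_vowel_specs(spec: CohortSpec) -> pd.DataFrame:
    """Draw the per-recording ground-truth table for a cohort.

    One row per (class, subject, session, vowel) holding the sampled
    :class:`VowelSpec` parameters and subject metadata.  Fully determined
    by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    cat = _category_for_group(spec.group)
    targets = CATEGORY_VOWEL_TARGETS[cat]
    base_formants = {v: targets[v] for v in CARDINAL_VOWELS}
    rows = []
    for label in CLASS_LABELS:
        n = spec.n_subjects.get(label, 0)
        eff = spec.class_effects.get(label, {})
        f0_c, formants_c = _apply_class_effects(targets["f0"], base_formants, eff)
        jit_c = spec.jitter_pct_mean * eff.get("jitter_scale", 1.0)
        snr_c = spec.snr_db_mean + eff.get("snr_db_shift", 0.0)
        for i in range(n):
            sid = f"{label}{i + 1:03d}"
            if spec.group == "PS":
                age = float(rng.uniform(5.0, 11.5))
                sex = "female" if rng.random() < 0.5 else "male"
            else:
                age = float(rng.uniform(18.0, 45.0))
                sex = "female" if spec.group == "FA" else "male"
            # subject-level deviations shared across vowels and sessions
            f0_s = f0_c * (1.0 + spec.between_subject_sd_rel * rng.standard_normal())
            fshift = 1.0 + spec.between_subject_sd_rel * rng.standard_normal(3)
            jit_s = max(0.05, jit_c * (1.0 + 0.3 * rng.standard_normal()))
            snr_s = snr_c + 2.0 * rng.standard_normal()
            for s in range(1, spec.sessions_per_subject + 1):
                for v in CARDINAL_VOWELS:
                    f1, f2, f3 = formants_c[v]
                    rows.append(
                        {
                            "subject_id": sid,
                            "session_id": f"s{s}",
                            "age_years": round(age, 2),
                            "sex": sex,
                            "label": label,
                            "vowel": v,
                            "f0": f0_s,
                            "f1": f1 * fshift[0],
                            "f2": f2 * fshift[1],
                            "f3": f3 * fshift[2],
                            "jitter_pct": jit_s,
                            "snr_db": snr_s,
                            "seed": int(rng.integers(0, 2**31 - 1)),
                        }
                    )
    return pd.DataFrame(rows)


def generate_cohort(spec: CohortSpec, out_dir: str | Path) -> pd.DataFrame:
    """Synthesize a cohort to WAV files and return (and write) the manifest.

    The manifest CSV has the :mod:`voxpheno.audio_io` schema and is written
    as ``manifest.csv`` inside ``out_dir``; it is byte-reproducible for a
    fixed :class:`CohortSpec`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = subject_vowel_specs(spec)
    paths = []
    for row in table.itertuples(index=False):
        vspec = VowelSpec(
            f0=row.f0,
            formants=(row.f1, row.f2, row.f3),
            jitter_pct=row.jitter_pct,
            snr_db=row.snr_db,
            duration=spec.duration,
            rate=spec.rate,
            seed=row.seed,
        )
        rec = synthesize_vowel(vspec)
        fname = f"{row.subject_id}_{row.session_id}_{row.vowel}.wav"
        wavfile.write(
            out_dir / fname, spec.rate, (rec.samples * 32767).astype(np.int16)
        )
        paths.append(fname)
    manifest = table[
        ["subject_id", "session_id", "age_years", "sex", "label", "vowel"]
    ].copy()
    manifest["path"] = paths
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
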