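# voxpheno

Acoustic phenotyping of sustained cardinal vowels for the screening of
genetic syndromes.

Several genetic syndromes — Costello (CS), Down (DS), Noonan (NS) and
Smith–Magenis (SMS) — alter the anatomy and neuromotor control of the
phonatory apparatus, and with it the voice. `voxpheno` implements a
standardized analysis chain that turns sustained recordings of the three
cardinal vowels /a/, /I/, /u/ into objective acoustic parameters,
screens them statistically across diagnostic classes, and trains
subject-grouped cross-validated classifiers that separate the four
syndromes from healthy subjects (HS). A source-filter vowel synthesizer
with known ground truth makes every stage testable end to end.

## What it computes

**Per-vowel acoustics** (24 parameters per recording, measured on the
central, steady-state half of the utterance):

- F0 statistics — mean, median, std, min, max of the fundamental
  frequency from the normalized autocorrelation peak, plus the time
  instants T0(F0 min) and T0(F0 max);
- local jitter (%) — mean |T(i+1) − T(i)| / mean T × 100 over a
  cycle-synchronous period track;
- normalized noise energy (NNE, dB ≤ 0) — the non-harmonic fraction of
  spectral energy, 10·log10(E_noise / E_total), via a comb at multiples
  of F0 (±10 % F0 harmonic bands);
- F1–F3 statistics — mean, median, std, min, max of the first three
  formants from LPC root finding with bandwidth and range gating.

Search ranges adapt to the voice category (child, adult female, adult
male), selected from the subject's age and sex.

**Articulation** from the vowel triangle in the (F2, F1) plane:

- VSA = |F1I(F2a − F2u) + F1a(F2u − F2I) + F1u(F2I − F2a)| / 2
- FCR = (F2u + F2a + F1I + F1u) / (F2I + F1a)
- F-ratios F1a/F1I, F1a/F1u (vertical tongue movement) and F2I/F2u
  (horizontal movement).

**Feature vector**: 24 parameters × 3 vowels + 5 articulatory metrics =
77 ordered features per subject-session.

**Statistics**: Shapiro–Wilk / Brown–Forsythe screen, tie-corrected
Kruskal–Wallis across the five classes per feature (α = 0.05), Dunn
post hoc with Bonferroni correction over the 10 class pairs, and the
`*` / `#` marking convention (significant pair involving HS / between
two syndromes).

**Classification**: cohorts are stratified into pediatric subjects
(PS, < 12 y), female adults (FA) and male adults (MA). Per group, KNN,
Gaussian-kernel SVM and random-forest classifiers are tuned by a seeded
sequential model-based optimizer (30 evaluations for KNN, 60 for
SVM/RF) and scored with 10-fold cross-validation in which all
recordings of a subject share one fold, preventing identity leakage.
Reports give per-class precision, recall, specificity, F1 and
one-vs-rest AUC plus global accuracy, each as mean ± std across folds.

## Worked example

```python
from voxpheno.synth import VowelSpec, synthesize_vowel
from voxpheno.acoustics import analyze_vowel, ADULT_FEMALE
from voxpheno.articulation import VowelTriangle, articulatory_metrics

spec = VowelSpec(f0=210, formants=(850, 1450, 2850), jitter_pct=1.0,
                 snr_db=30, duration=3.0, rate=22050, seed=42)
profile = analyze_vowel(synthesize_vowel(spec), ADULT_FEMALE)
print(f"F0  {profile.f0_mean:6.1f} Hz   jitter {profile.jitter_pct:.2f} %   "
      f"NNE {profile.nne_db:6.1f} dB")
print(f"F1  {profile.f1_mean:6.1f} Hz   F2 {profile.f2_mean:6.1f} Hz   "
      f"F3 {profile.f3_mean:6.1f} Hz")

tri = VowelTriangle(F1a=850, F2a=1450, F1I=380, F2I=2300, F1u=380, F2u=950)
m = articulatory_metrics(tri)
print(f"VSA {m.vsa:9.0f} Hz^2   FCR {m.fcr:.3f}")
```

prints

```
F0   210.1 Hz   jitter 1.09 %   NNE  -16.0 dB
F1   841.7 Hz   F2 1466.0 Hz   F3 3118.3 Hz
VSA    317250 Hz^2   FCR 1.003
```

The analyzed F0 (210.1 Hz), F1/F2 (−1 %/+1 %) and jitter (1.09 % for
1 % imposed) sit on their synthesis targets; NNE reflects the 30 dB
SNR. F3 is the least reliable parameter at realistic noise levels —
its harmonics carry little energy. The adult-female triangle gives a
vowel space of ≈ 3.2 × 10⁵ Hz² and an FCR of 1.0; centralized
(dysarthric) articulation shrinks VSA and pushes FCR up toward 2.

A full pipeline run from the shell:

```sh
voxpheno synth cohort/ --group PS --n-subjects 5 --seed 1
voxpheno analyze cohort/manifest.csv --out features.csv
voxpheno stats features.csv --out-dir out/
voxpheno train features.csv --group PS --out report.json
```

## Layout

- `voxpheno.audio_io` — WAV/manifest reading, central-segment
  selection, voiced/unvoiced detection
- `voxpheno.acoustics` — F0, jitter, NNE, formants; the 37-parameter
  catalog
- `voxpheno.articulation` — vowel triangles, VSA/FCR/F-ratios, plots
- `voxpheno.cohort` — PS/FA/MA stratification, the 77-feature table
- `voxpheno.stats` — Kruskal–Wallis, Dunn–Bonferroni, significance
  marking
- `voxpheno.classify` — grouped 10-fold CV, KNN/SVM/RF, Bayesian-style
  tuning
- `voxpheno.synth` — ground-truth vowel and cohort synthesis
- `voxpheno.pipeline` / `voxpheno.cli` — orchestration and the
  `voxpheno` command

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
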