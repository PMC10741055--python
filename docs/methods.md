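# Methods

This note documents the models, numerical choices and defaults behind
`voxpheno`, and what the synthetic validation does and does not show.

## Signal model and preprocessing

A sustained cardinal vowel is treated as a quasi-periodic source-filter
signal: glottal pulses at rate F0 with cycle-to-cycle period
perturbation (jitter), shaped by vocal-tract resonances (formants),
plus additive noise (turbulence, room, sensor). Only the temporally
central fraction of each recording (default 0.5) is analyzed: onset and
offset transients bias pitch and formant statistics, and the center
approximates the steady state. The selected segment must be at least
0.5 s. No denoising is applied anywhere — with genetic syndromes the
noise itself can be diagnostic, and filtering would remove it.

Voicing detection is frame-based (40 ms frames, 10 ms hop; the frame
holds ≥ 2 periods at the lowest adult-male F0 bound). A frame is voiced
iff its energy exceeds 1 % of the maximum frame energy **and** its
normalized autocorrelation peak inside the F0 lag range exceeds 0.45.
These constants are ordinary practice for clean sustained phonation and
are exposed as arguments.

## Voice categories

Search ranges adapt to the speaker (all overridable):

| category | F0 range (Hz) | formant ceiling (Hz) |
|---|---|---|
| child (< 12 y) | 120–600 | 8000 |
| adult female | 120–400 | 5500 |
| adult male | 60–250 | 5000 |

The pediatric/adult boundary at 12 years also defines the PS/FA/MA
analysis groups, so the acoustic search ranges and the cohort
stratification stay consistent.

## F0, jitter, NNE, formants

**F0** per voiced frame is the lag of the maximal normalized
autocorrelation peak within the category range, refined by parabolic
interpolation; a length-5 median filter suppresses octave jumps and
values are clipped to the category range.

**Jitter** is local relative jitter, mean |T(i+1) − T(i)| / mean T ×
100. Frame-wise F0 averages several periods and would systematically
understate cycle-to-cycle perturbation, so jitter is measured on a
cycle-synchronous track: the waveform is low-passed just above the
median F0 (Butterworth order 4 at 1.4 × F0), cycle peaks are marked
with sub-sample parabolic refinement, and each period becomes one track
entry. Gaps longer than 1.5× the median spacing break consecutiveness.
For independent Gaussian per-cycle perturbation the estimator's
expected reading is ≈ 1.13× the imposed SD (the mean absolute
difference of two independent deviates), which the recovery tests
bracket inside [0.5×, 1.5×].

**NNE** splits each voiced frame's spectrum with a comb at multiples of
the frame F0; bins within ±10 % of F0 around each harmonic count as
harmonic energy, the rest as noise, and NNE = 10·log10(E_noise /
E_total) is averaged over frames and clipped to ≤ 0 dB. The analysis
frame is pitch-synchronous — 20 glottal periods with a Hann window — so
the window mainlobe (± 2 bins = ± F0/10) sits exactly inside the
harmonic band; with a fixed-length frame the mainlobe of low-pitched
voices would leak into the noise estimate. Noiseless synthetic vowels
read below −30 dB (the floor is leakage through Hann sidelobes plus
jitter-induced harmonic spreading); equal-power noise reads ≈ −4 dB
(the comb covers ~20 % of the band, so 80 % of the noise is counted:
10·log10(0.8/2)).

**Formants**: audio is resampled to twice the formant ceiling,
pre-emphasized (coefficient 0.97), and per voiced frame a
Hamming-windowed LPC polynomial of order 2 + 2·(ceiling/1000) (Levinson
via Toeplitz solve) is rooted. Roots with bandwidth < 400 Hz and
frequency in (90 Hz, ceiling) are candidates; the lowest three are
F1–F3. Frames with fewer than three candidates are skipped; if more
than half the voiced frames fail, a quality warning is emitted and
statistics cover the available frames.

Known estimator biases, quantified by the recovery suite:

- LPC estimates are attracted to the nearest harmonic; at high F0
  (children, adult females) with a low F1 this can bias F1 by up to
  ~10 % in single cases. Median errors over a mixed batch stay ≈ 3 %
  (F1) and ≈ 1 % (F0, F2).
- F3 carries little energy under a −6 dB/oct source tilt; at SNRs
  below ≈ 30 dB it is frequently unrecoverable and its statistics are
  the least trustworthy of the 24.

**Extremum times** T0(F0 min/max) resolve ties to the first occurrence.
Standard deviations use the n−1 denominator (0 for a single frame).

## Parameter catalog and feature vector

The catalog holds 37 per-recording parameters: the 24 selected ones
above plus 13 time-domain segmentation measures (signal duration,
% voiced, voiced-unit and pause statistics) that are computed on demand
but never enter the classifier. The feature vector is the 24 selected
parameters for /a/, /I/, /u/ in catalog order, then VSA, FCR and the
three F-ratios — 77 features, an ordering pinned by a golden-names
test. Triangles use per-session *mean* formants; repeated recordings of
a vowel within one session are averaged before the triangle is built;
sessions missing a cardinal vowel are excluded rather than imputed
(complete-case policy). Multiple sessions of one subject remain
separate rows and carry the subject id for the grouped split.

## Statistics

Per feature and cohort group, the five classes are compared with the
tie-corrected Kruskal–Wallis test (H on midranks divided by
1 − Σ(t³−t)/(N³−N); p from χ²(k−1)); post hoc, Dunn z tests on pooled
midranks with tie-corrected variance, Bonferroni-multiplied over the
pairs of that feature and capped at 1. The family is the 10 pairwise
comparisons within one feature; no correction is applied across the 77
features, and the output tables record that fact in their metadata.
α = 0.05 throughout. The parametric branch (one-way ANOVA + Tukey HSD)
exists and is selected automatically when every class passes
Shapiro–Wilk; clinical voice features essentially never do, and the
homoscedasticity check uses the median-centered (Brown–Forsythe)
Levene variant for robustness. Monte-Carlo calibration over 2000 null
simulations places the empirical type-I error within [0.03, 0.07].

## Classification

Fold plans assign *subjects* to 10 folds (shuffled by seed within
class, greedily balancing per-fold class counts), so all recordings of
a subject — including longitudinal sessions — share a fold; a leakage
assertion runs on every evaluation. Features are standardized with
training-fold statistics only.

Search spaces follow the common voice-pathology setup: KNN with
k ∈ [2, 27], eleven distance metrics and three weightings; Gaussian
SVM with one-vs-one/one-vs-all coding and box constraint and kernel
scale in [1e−3, 1e3] (log scale); random forest with leaf/split bounds
in [2, 27] and 1–55 sampled variables. Two mappings are worth noting:
the binary distances (hamming, jaccard) operate on the sign pattern of
the standardized features and spearman is correlation distance on
within-row ranks — documented approximations for metrics defined on
continuous inputs; the "twoing" split criterion has no scikit-learn
equivalent, so the forest space maps deviance → cross-entropy and
gdi → Gini and omits twoing.

The tuner is a seeded sequential model-based optimizer: after a random
initial design (~¼ of the budget), a random-forest surrogate ranks 128
candidate draws by expected improvement (mean and spread across trees)
and the best is evaluated; the objective is mean cross-validated global
accuracy under the fold plan, evaluated exactly budget times (30 for
KNN, 60 for SVM/RF). A seeded pure random search with the identical
objective is available via `method="random"`. Multiclass AUC is
one-vs-rest per class from the model's class scores; fold means and
(n−1) standard deviations are reported in percent, with classes absent
from a fold's validation set excluded from that fold's statistics and
the per-class fold counts reported alongside.

## Synthetic ground truth

The synthesizer drives a cascade of three two-pole resonators
(default bandwidths 80/120/160 Hz — typical adult values) with a pulse
train shaped by a double-pole glottal low-pass (~100 Hz corner) and
radiation differentiation, a net ≈ −6 dB/oct source tilt that keeps
the fundamental dominant. Pulses are placed with sub-sample precision
(linear splitting between adjacent samples) so that sampling never
injects spurious jitter; per-cycle periods are perturbed by zero-mean
Gaussian noise of relative SD jitter/100, and white noise is added at
the requested SNR.

The cohort generator draws subject-level F0, formant, jitter and SNR
offsets around class means (4 % relative between-subject SD by
default, jitter 0.8 %, SNR 30 dB, 3 s vowels at 22.05 kHz) and encodes
the qualitative clinical picture as class effects: formant
centralization for NS and DS, elevated jitter and noise for CS, raised
F0 and F1 for SMS. These are test fixtures, not clinical estimates. A
separate `SEPARATED_CLASS_EFFECTS` set spaces every class pair by at
least ~5 between-subject SDs (at 2 % SD) in some source parameter; the
end-to-end recovery checks use it because their premise is a cohort a
competent classifier must solve almost perfectly.

What passing tests show: the analysis chain recovers known F0, F1/F2,
jitter and noise orderings, the statistics are calibrated, the CV
protocol leaks nothing, and the full pipeline is deterministic. What
they do not show: performance on real pathological voices — the
synthesizer produces stationary, single-speaker-model vowels without
breathiness dynamics, diplophonia, nasality, room reverberation or
device coloration, so clinical accuracy claims require clinical data.

## Problem sizes and reproducibility

End-to-end checks run on scaled-down material chosen for quick
iteration: 16 kHz, 1.5 s vowels, 4 subjects per class (20 subjects,
the 10-fold minimum is 10), and reduced tuner budgets (8 per family)
on the separable fixture; the scientific defaults (3 s, 22.05 kHz,
budgets 30/60/60) are unchanged. All randomness flows from a single
root seed; artifacts are stamped with a configuration hash (scientific
settings only, paths excluded), the seed and the package version, and
a repeated run reproduces the feature table bitwise and the CV reports
exactly.

## Known limitations

- Jitter below ≈ 0.3 % imposed is at the estimator floor; shimmer is
  not implemented.
- F3 statistics degrade sharply below ≈ 30 dB SNR (see above).
- The NNE figure depends on the ±10 % harmonic-band convention;
  absolute values are comparable only within this implementation.
- KNN's covariance-based distances (mahalanobis, seuclidean) use a
  pseudo-inverse when training covariance is singular, which is common
  at 77 features and small n.
- The Italian /I/ reference (F2 a few hundred Hz below American /i/)
  affects only the plotted reference triangle, never the metrics.
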