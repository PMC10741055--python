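"""Per-vowel acoustic parameters: F0, jitter, noise level and formants.

This module computes the 24 selected per-recording parameters of the
analysis catalog: five F0 statistics plus the time instants of the F0
extrema, local jitter (%), normalized noise energy (NNE, dB) and
mean/median/std/min/max of the first three formants.  Frequency search
ranges adapt to the voice category (child, adult female, adult male) so
that the same code analyzes pediatric and adult voices without manual
retuning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from typing import Mapping

import numpy as np
from scipy import signal
from scipy.linalg import solve_toeplitz

from voxpheno.audio_io import (
    Recording,
    SubjectMeta,
    VoicedMask,
    detect_voiced,
    frame_signal,
    select_central_segment,
)
from voxpheno.errors import InsufficientVoicingError


@dataclass(frozen=True)
class VoiceCategory:
    """Frequency search ranges for one speaker category."""

    name: str
    f0_range: tuple[float, float]
    formant_ceiling: float

    def __post_init__(self) -> None:
        lo, hi = self.f0_range
        if not lo < hi:
            raise ValueError("f0_range min must be below max")
        if self.formant_ceiling <= hi:
            raise ValueError("formant_ceiling must exceed the F0 search maximum")


#: standard speech-analysis presets; all user-overridable.
CHILD = VoiceCategory("child", (120.0, 600.0), 8000.0)
ADULT_FEMALE = VoiceCategory("adult_female", (120.0, 400.0), 5500.0)
ADULT_MALE = VoiceCategory("adult_male", (60.0, 250.0), 5000.0)

CATEGORIES = {c.name: c for c in (CHILD, ADULT_FEMALE, ADULT_MALE)}

PEDIATRIC_AGE_LIMIT = 12.0


def category_for(meta: SubjectMeta) -> VoiceCategory:
    """Map subject demographics to a voice category."""
    if meta.age_years < PEDIATRIC_AGE_LIMIT:
        return CHILD
    return ADULT_FEMALE if meta.sex == "female" else ADULT_MALE


@dataclass(frozen=True)
class F0Track:
    """Fundamental-frequency estimates over voiced frames (or cycles)."""

    times: np.ndarray  # seconds, strictly increasing
    values: np.ndarray  # Hz

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.float64)
        values = np.asarray(self.values, dtype=np.float64)
        if times.shape != values.shape:
            raise ValueError("times and values must have equal length")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)


# ordered field names of the 24-parameter profile; this order (suffixed by
# vowel) is the feature-table contract.
PROFILE_FIELDS = (
    "f0_mean",
    "f0_median",
    "f0_std",
    "f0_min",
    "t0_f0_min",
    "f0_max",
    "t0_f0_max",
    "jitter_pct",
    "nne_db",
    "f1_mean",
    "f1_median",
    "f1_std",
    "f1_min",
    "f1_max",
    "f2_mean",
    "f2_median",
    "f2_std",
    "f2_min",
    "f2_max",
    "f3_mean",
    "f3_median",
    "f3_std",
    "f3_min",
    "f3_max",
)


@dataclass(frozen=True)
class AcousticProfile:
    """The 24 selected acoustic parameters of one vowel recording."""

    f0_mean: float
    f0_median: float
    f0_std: float
    f0_min: float
    t0_f0_min: float
    f0_max: float
    t0_f0_max: float
    jitter_pct: float
    nne_db: float
    f1_mean: float
    f1_median: float
    f1_std: float
    f1_min: float
    f1_max: float
    f2_mean: float
    f2_median: float
    f2_std: float
    f2_min: float
    f2_max: float
    f3_mean: float
    f3_median: float
    f3_std: float
    f3_min: float
    f3_max: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PROFILE_FIELDS}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PROFILE_FIELDS])


def _check_profile(p: AcousticProfile) -> AcousticProfile:
    assert len(fields(AcousticProfile)) == 24
    if p.nne_db > 0:
        raise ValueError("NNE must be <= 0 dB")
    return p


# ---------------------------------------------------------------------------
# F0
# ---------------------------------------------------------------------------

def estimate_f0_track(
    rec: Recording, mask: VoicedMask, cat: VoiceCategory
) -> F0Track:
    """Frame-wise F0 from the normalized autocorrelation peak.

    Per voiced frame the peak lag is searched within the category's F0
    range, refined by parabolic interpolation, and the resulting track is
    median-filtered (length 5) to suppress octave jumps.  Requires at
    least 5 voiced frames.
    """
    if mask.n_voiced < 5:
        raise InsufficientVoicingError(
            f"need >= 5 voiced frames, got {mask.n_voiced}"
        )
    frames, times = frame_signal(rec.samples, rec.rate, mask.frame_len, mask.hop)
    frames = frames[mask.frame_flags]
    times = times[mask.frame_flags]

    n_frame = frames.shape[1]
    frames = frames - frames.mean(axis=1, keepdims=True)
    nfft = int(2 ** np.ceil(np.log2(2 * n_frame)))
    spec = np.fft.rfft(frames, nfft, axis=1)
    acf = np.fft.irfft(spec * np.conj(spec), nfft, axis=1)[:, :n_frame]
    with np.errstate(invalid="ignore", divide="ignore"):
        acf = np.nan_to_num(acf / acf[:, :1])

    lag_min = max(2, int(np.floor(rec.rate / cat.f0_range[1])))
    lag_max = min(int(np.ceil(rec.rate / cat.f0_range[0])), n_frame - 2)
    window = acf[:, lag_min : lag_max + 1]
    peak_rel = np.argmax(window, axis=1)
    lag = peak_rel + lag_min

    # parabolic refinement around the integer peak
    y0 = acf[np.arange(len(lag)), lag - 1]
    y1 = acf[np.arange(len(lag)), lag]
    y2 = acf[np.arange(len(lag)), lag + 1]
    denom = y0 - 2 * y1 + y2
    delta = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
    delta = np.clip(delta, -0.5, 0.5)
    f0 = rec.rate / (lag + delta)

    f0 = signal.medfilt(f0, kernel_size=5)
    f0 = np.clip(f0, cat.f0_range[0], cat.f0_range[1])
    return F0Track(times=times, values=f0)


def estimate_period_track(
    rec: Recording, track: F0Track, cat: VoiceCategory
) -> F0Track:
    """Cycle-synchronous F0 from glottal-cycle marks.

    Frame-wise F0 averages several periods, which smooths genuine
    cycle-to-cycle perturbation; jitter therefore needs period estimates
    at cycle resolution.  The waveform is low-pass filtered just above the
    median F0, cycle peaks are located with sub-sample parabolic
    refinement, and each period becomes one track entry (value = 1/T).
    """
    f0_med = float(np.median(track.values))
    nyq = rec.rate / 2.0
    cutoff = min(1.4 * f0_med, 0.95 * nyq)
    sos = signal.butter(4, cutoff / nyq, btype="low", output="sos")
    x = signal.sosfiltfilt(sos, rec.samples)

    t0_samp = rec.rate / f0_med
    peaks, _ = signal.find_peaks(x, distance=max(2, int(0.7 * t0_samp)))
    if peaks.size < 4:
        raise InsufficientVoicingError("too few glottal cycles for period marking")
    # sub-sample peak position by parabolic fit
    p = peaks[(peaks > 0) & (peaks < x.size - 1)]
    y0, y1, y2 = x[p - 1], x[p], x[p + 1]
    denom = y0 - 2 * y1 + y2
    delta = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
    marks = (p + np.clip(delta, -0.5, 0.5)) / rec.rate

    periods = np.diff(marks)
    mid = 0.5 * (marks[:-1] + marks[1:])
    ok = (periods > 0.7 / f0_med) & (periods < 1.3 / f0_med)
    if ok.sum() < 3:
        raise InsufficientVoicingError("too few plausible glottal periods")
    return F0Track(times=mid[ok], values=1.0 / periods[ok])


def f0_statistics(track: F0Track) -> dict[str, float]:
    """Five summary statistics plus the times of the F0 extrema.

    Ties on the extrema resolve to the first occurrence.
    """
    if track.values.size == 0:
        raise InsufficientVoicingError("empty F0 track")
    v, t = track.values, track.times
    i_min = int(np.argmin(v))
    i_max = int(np.argmax(v))
    return {
        "f0_mean": float(np.mean(v)),
        "f0_median": float(np.median(v)),
        "f0_std": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
        "f0_min": float(v[i_min]),
        "t0_f0_min": float(t[i_min]),
        "f0_max": float(v[i_max]),
        "t0_f0_max": float(t[i_max]),
    }


def compute_jitter(track: F0Track, max_gap: float | None = None) -> float:
    """Local (relative) jitter in percent.

    ``mean |T(i+1) - T(i)| / mean T * 100`` over consecutive period
    estimates ``T(i) = 1/F0(i)``; entries separated by more than
    ``max_gap`` seconds (default: 1.5x the median spacing) are not
    consecutive and do not contribute a difference.  Requires at least
    three consecutive period estimates.
    """
    t, v = track.times, track.values
    if v.size < 3:
        raise InsufficientVoicingError("need >= 3 period estimates for jitter")
    periods = 1.0 / v
    dt = np.diff(t)
    if max_gap is None:
        max_gap = 1.5 * float(np.median(dt)) if dt.size else np.inf
    consecutive = dt <= max_gap
    if consecutive.sum() < 2:
        raise InsufficientVoicingError("need >= 3 consecutive period estimates")
    diffs = np.abs(np.diff(periods))[consecutive]
    # mean period over the entries participating in at least one pair
    involved = np.zeros(v.size, bool)
    involved[:-1] |= consecutive
    involved[1:] |= consecutive
    return float(np.mean(diffs) / np.mean(periods[involved]) * 100.0)


# ---------------------------------------------------------------------------
# NNE
# ---------------------------------------------------------------------------

def compute_nne(
    rec: Recording,
    track: F0Track,
    cat: VoiceCategory,
    harmonic_bandwidth: float = 0.1,
    periods_per_frame: int = 20,
) -> float:
    """Normalized noise energy in dB (<= 0).

    Per voiced frame the spectrum is split by a comb at multiples of the
    frame F0: bins within ``harmonic_bandwidth * F0`` of a harmonic count
    as harmonic energy, the rest as noise, and
    ``NNE = 10 log10(noise / total)`` is averaged over frames.  The frame
    is pitch-synchronous (``periods_per_frame`` glottal periods, Hann
    window) so the window mainlobe stays inside the harmonic band.
    """
    if track.values.size == 0:
        raise InsufficientVoicingError("no voiced frames for NNE")
    x = rec.samples
    vals = []
    for t, f0 in zip(track.times, track.values):
        n_seg = int(round(periods_per_frame * rec.rate / f0))
        c = int(round(t * rec.rate))
        lo, hi = c - n_seg // 2, c - n_seg // 2 + n_seg
        if lo < 0 or hi > x.size:
            continue
        seg = x[lo:hi] - np.mean(x[lo:hi])
        win = np.hanning(n_seg)
        spec = np.abs(np.fft.rfft(seg * win)) ** 2
        freqs = np.fft.rfftfreq(n_seg, 1.0 / rec.rate)
        k = np.round(freqs / f0)
        harmonic = (k >= 1) & (np.abs(freqs - k * f0) <= harmonic_bandwidth * f0)
        total = spec.sum()
        if total <= 0:
            continue
        noise = spec[~harmonic].sum()
        vals.append(10.0 * np.log10(max(noise / total, 1e-12)))
    if not vals:
        raise InsufficientVoicingError("no usable NNE frames")
    return min(0.0, float(np.mean(vals)))


# ---------------------------------------------------------------------------
# formants
# ---------------------------------------------------------------------------

MAX_FORMANT_BANDWIDTH = 400.0  # Hz; wider resonances are spurious LPC roots
MIN_FORMANT_HZ = 90.0
PRE_EMPHASIS = 0.97


def _lpc(frame: np.ndarray, order: int) -> np.ndarray | None:
    """LPC coefficients via the autocorrelation (Levinson) method."""
    r = np.correlate(frame, frame, mode="full")[frame.size - 1 : frame.size + order]
    if r[0] <= 0:
        return None
    try:
        a = solve_toeplitz((r[:-1], r[:-1]), r[1:])
    except np.linalg.LinAlgError:
        return None
    return np.concatenate([[1.0], -a])


def estimate_formants(
    rec: Recording,
    mask: VoicedMask,
    cat: VoiceCategory,
    lpc_order: int | None = None,
):
    """Frame-wise F1-F3 by LPC root finding plus their summary statistics.

    The signal is resampled to twice the category formant ceiling,
    pre-emphasized, and per voiced frame a Hamming-windowed LPC polynomial
    is rooted; roots with bandwidth below 400 Hz and frequency inside
    (90 Hz, ceiling) are formant candidates, the lowest three being F1-F3.

    Returns ``(tracks, stats)`` where ``tracks`` maps ``"f1"|"f2"|"f3"``
    to per-frame arrays and ``stats`` holds the 15 statistics fields.
    """
    if mask.n_voiced == 0:
        raise InsufficientVoicingError("no voiced frames for formant analysis")
    target_fs = int(2 * cat.formant_ceiling)
    g = np.gcd(target_fs, rec.rate)
    x = signal.resample_poly(rec.samples, target_fs // g, rec.rate // g)
    x = np.append(x[0], x[1:] - PRE_EMPHASIS * x[:-1])
    if lpc_order is None:
        lpc_order = int(2 + 2 * cat.formant_ceiling / 1000)

    n_frame = int(round(mask.frame_len * target_fs))
    win = np.hamming(n_frame)
    f123 = []
    times = mask.frame_times[mask.frame_flags]
    kept_times = []
    for t in times:
        c = int(round(t * target_fs))
        lo = c - n_frame // 2
        if lo < 0 or lo + n_frame > x.size:
            continue
        frame = x[lo : lo + n_frame] * win
        a = _lpc(frame, lpc_order)
        if a is None:
            continue
        roots = np.roots(a)
        roots = roots[np.imag(roots) > 0]
        freqs = np.angle(roots) * target_fs / (2 * np.pi)
        bws = -target_fs / np.pi * np.log(np.abs(roots))
        ok = (
            (bws < MAX_FORMANT_BANDWIDTH)
            & (freqs > MIN_FORMANT_HZ)
            & (freqs < cat.formant_ceiling)
        )
        cand = np.sort(freqs[ok])
        if cand.size >= 3:
            f123.append(cand[:3])
            kept_times.append(t)
    if not f123:
        raise InsufficientVoicingError("no frame yielded three stable formants")
    if len(f123) < 0.5 * len(times):
        warnings.warn(
            f"only {len(f123)}/{len(times)} voiced frames yielded three stable "
            "formants; statistics cover available frames",
            stacklevel=2,
        )
    arr = np.asarray(f123)
    tracks = {
        "times": np.asarray(kept_times),
        "f1": arr[:, 0],
        "f2": arr[:, 1],
        "f3": arr[:, 2],
    }
    stats = {}
    for i, key in enumerate(("f1", "f2", "f3")):
        v = arr[:, i]
        stats[f"{key}_mean"] = float(np.mean(v))
        stats[f"{key}_median"] = float(np.median(v))
        stats[f"{key}_std"] = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        stats[f"{key}_min"] = float(np.min(v))
        stats[f"{key}_max"] = float(np.max(v))
    return tracks, stats


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def analyze_vowel(
    rec: Recording,
    cat: VoiceCategory,
    central_fraction: float = 0.5,
    frame_len: float = 0.04,
    hop: float = 0.01,
) -> AcousticProfile:
    """Full 24-parameter acoustic profile of one sustained-vowel recording.

    Analysis is restricted to the central (steady-state) segment.  Jitter
    is measured on a cycle-synchronous period track; all other F0
    statistics use the frame-wise track.
    """
    central = select_central_segment(rec, central_fraction)
    mask = detect_voiced(
        central, frame_len=frame_len, hop=hop, f0_range=cat.f0_range
    )
    track = estimate_f0_track(central, mask, cat)
    f0_stats = f0_statistics(track)
    cycle_track = estimate_period_track(central, track, cat)
    jitter = compute_jitter(cycle_track)
    nne = compute_nne(central, track, cat)
    _, formant_stats = estimate_formants(central, mask, cat)
    return _check_profile(
        AcousticProfile(jitter_pct=jitter, nne_db=nne, **f0_stats, **formant_stats)
    )


# ---------------------------------------------------------------------------
# parameter catalog
# ---------------------------------------------------------------------------

#: full acoustic-analysis catalog: 37 per-recording parameters.  ``selected``
#: marks the 24 fed (per vowel) into the classifier feature vector; the
#: remaining time-domain segmentation measures are available as extras and
#: are never part of the feature vector.
PARAMETER_CATALOG = (
    ("f0_mean", "Hz", True),
    ("f0_median", "Hz", True),
    ("f0_std", "Hz", True),
    ("f0_min", "Hz", True),
    ("t0_f0_min", "s", True),
    ("f0_max", "Hz", True),
    ("t0_f0_max", "s", True),
    ("jitter_pct", "%", True),
    ("nne_db", "dB", True),
    ("f1_mean", "Hz", True),
    ("f1_median", "Hz", True),
    ("f1_std", "Hz", True),
    ("f1_min", "Hz", True),
    ("f1_max", "Hz", True),
    ("f2_mean", "Hz", True),
    ("f2_median", "Hz", True),
    ("f2_std", "Hz", True),
    ("f2_min", "Hz", True),
    ("f2_max", "Hz", True),
    ("f3_mean", "Hz", True),
    ("f3_median", "Hz", True),
    ("f3_std", "Hz", True),
    ("f3_min", "Hz", True),
    ("f3_max", "Hz", True),
    ("signal_duration", "s", False),
    ("pct_voiced", "%", False),
    ("voiced_duration", "s", False),
    ("n_units", "", False),
    ("unit_duration_mean", "s", False),
    ("unit_duration_std", "s", False),
    ("unit_duration_min", "s", False),
    ("unit_duration_max", "s", False),
    ("n_pauses", "", False),
    ("pause_duration_mean", "s", False),
    ("pause_duration_std", "s", False),
    ("pause_duration_min", "s", False),
    ("pause_duration_max", "s", False),
)


def segmentation_stats(rec: Recording, mask: VoicedMask) -> dict[str, float]:
    """The 13 optional time-domain catalog parameters.

    Voiced units are maximal runs of voiced frames; pauses are the
    unvoiced runs between them.  Never part of the classifier features.
    """
    flags = mask.frame_flags.astype(int)
    edges = np.diff(np.concatenate([[0], flags, [0]]))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    unit_durs = (ends - starts) * mask.hop
    pause_durs = (
        (starts[1:] - ends[:-1]) * mask.hop if starts.size > 1 else np.empty(0)
    )

    def _s(v: np.ndarray, stat) -> float:
        return float(stat(v)) if v.size else 0.0

    return {
        "signal_duration": rec.duration,
        "pct_voiced": 100.0 * mask.voiced_fraction,
        "voiced_duration": float(unit_durs.sum()),
        "n_units": float(starts.size),
        "unit_duration_mean": _s(unit_durs, np.mean),
        "unit_duration_std": _s(unit_durs, lambda v: np.std(v, ddof=1) if v.size > 1 else 0.0),
        "unit_duration_min": _s(unit_durs, np.min),
        "unit_duration_max": _s(unit_durs, np.max),
        "n_pauses": float(pause_durs.size),
        "pause_duration_mean": _s(pause_durs, np.mean),
        "pause_duration_std": _s(pause_durs, lambda v: np.std(v, ddof=1) if v.size > 1 else 0.0),
        "pause_duration_min": _s(pause_durs, np.min),
        "pause_duration_max": _s(pause_durs, np.max),
    }
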