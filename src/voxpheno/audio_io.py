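"""Reading vowel recordings, steady-state segment selection and voicing.

Sustained-vowel analysis only uses the central, steady-state part of each
utterance; onsets and offsets carry transients that bias pitch and formant
statistics.  Denoising is deliberately not applied anywhere in the package:
background turbulence can itself be a pathological cue and filtering would
remove it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from voxpheno.errors import TooShortSegmentError, VoxPhenoError

logger = logging.getLogger(__name__)

#: vowels analyzed; the cardinal (corner) vowels are articulatorily stable
#: and robust to dialect, which is why analysis is restricted to them.
CARDINAL_VOWELS = ("a", "I", "u")

#: classes: four genetic syndromes plus healthy subjects
CLASS_LABELS = ("CS", "DS", "NS", "SMS", "HS")

MIN_RATE_HZ = 8000
MIN_SEGMENT_S = 0.5

MANIFEST_COLUMNS = (
    "subject_id",
    "session_id",
    "age_years",
    "sex",
    "label",
    "vowel",
    "path",
)


@dataclass(frozen=True)
class SubjectMeta:
    """Demographics and diagnosis of one subject."""

    subject_id: str
    age_years: float
    sex: str  # "female" | "male"
    label: str  # one of CLASS_LABELS

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValueError(f"age_years must be non-negative, got {self.age_years}")
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.label not in CLASS_LABELS:
            raise ValueError(f"label must be one of {CLASS_LABELS}, got {self.label!r}")


@dataclass(frozen=True)
class Recording:
    """A mono sustained-vowel recording with its provenance.

    ``samples`` are dimensionless amplitudes in [-1, 1]; ``rate`` is the
    sampling rate in Hz (at least 8 kHz).
    """

    samples: np.ndarray
    rate: int
    subject_id: str
    vowel: str
    session_id: str = "s1"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("Recording requires a single channel")
        if samples.size == 0:
            raise ValueError("Recording requires non-empty samples")
        if self.rate < MIN_RATE_HZ:
            raise ValueError(f"rate must be >= {MIN_RATE_HZ} Hz, got {self.rate}")
        if self.vowel not in CARDINAL_VOWELS:
            raise ValueError(f"vowel must be one of {CARDINAL_VOWELS}, got {self.vowel!r}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.samples.size / self.rate


@dataclass(frozen=True)
class VoicedMask:
    """Frame-level voiced/unvoiced decision aligned to analysis frames."""

    frame_flags: np.ndarray  # bool, one per frame
    frame_times: np.ndarray  # seconds, frame centers
    frame_len: float = 0.04
    hop: float = 0.01

    def __post_init__(self) -> None:
        flags = np.asarray(self.frame_flags, dtype=bool)
        times = np.asarray(self.frame_times, dtype=np.float64)
        if flags.shape != times.shape:
            raise ValueError("frame_flags and frame_times must have equal length")
        object.__setattr__(self, "frame_flags", flags)
        object.__setattr__(self, "frame_times", times)

    @property
    def n_voiced(self) -> int:
        return int(self.frame_flags.sum())

    @property
    def voiced_fraction(self) -> float:
        return float(self.frame_flags.mean()) if self.frame_flags.size else 0.0


def _normalize_pcm(data: np.ndarray) -> np.ndarray:
    """Scale integer PCM to [-1, 1]; float data is passed through."""
    if np.issubdtype(data.dtype, np.floating):
        return data.astype(np.float64)
    info = np.iinfo(data.dtype)
    if data.dtype == np.uint8:  # 8-bit WAV is unsigned
        return (data.astype(np.float64) - 128.0) / 128.0
    return data.astype(np.float64) / float(max(abs(info.min), info.max))


def load_recording(
    path: str | Path,
    meta: SubjectMeta,
    vowel: str,
    session_id: str = "s1",
) -> Recording:
    """Load a PCM WAV file as a :class:`Recording`.

    Stereo input is downmixed by channel mean (with a logged warning);
    integer PCM is rescaled to [-1, 1].

    Raises
    ------
    VoxPhenoError
        If the file cannot be read as RIFF WAV.
    ValueError
        If the audio is empty.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except (ValueError, OSError) as exc:
        raise VoxPhenoError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"empty audio in {path}")
    if data.ndim == 2:
        logger.warning("downmixing %d-channel file %s by channel mean", data.shape[1], path)
        data = _normalize_pcm(data).mean(axis=1)
    else:
        data = _normalize_pcm(data)
    return Recording(
        samples=data,
        rate=int(rate),
        subject_id=meta.subject_id,
        vowel=vowel,
        session_id=session_id,
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a recording manifest CSV and validate its schema."""
    df = pd.read_csv(path, dtype={"subject_id": str, "session_id": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise VoxPhenoError(f"manifest {path} is missing columns: {sorted(missing)}")
    bad = set(df["label"]) - set(CLASS_LABELS)
    if bad:
        raise VoxPhenoError(f"manifest {path} contains unknown labels: {sorted(bad)}")
    return df


def select_central_segment(rec: Recording, fraction: float = 0.5) -> Recording:
    """Return the temporally centered ``fraction`` of the recording.

    The central part of a sustained vowel approximates its steady state.
    The selected segment must be at least 0.5 s long.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = rec.samples.size
    n_keep = int(round(n * fraction))
    if n_keep / rec.rate < MIN_SEGMENT_S:
        raise TooShortSegmentError(
            f"central segment of {n_keep / rec.rate:.3f} s is shorter than "
            f"{MIN_SEGMENT_S} s (input {rec.duration:.3f} s, fraction {fraction})"
        )
    start = (n - n_keep) // 2
    return Recording(
        samples=rec.samples[start : start + n_keep],
        rate=rec.rate,
        subject_id=rec.subject_id,
        vowel=rec.vowel,
        session_id=rec.session_id,
    )


def frame_signal(x: np.ndarray, rate: int, frame_len: float, hop: float):
    """Slice ``x`` into overlapping frames.

    Returns ``(frames, times)`` where ``times`` are frame-center seconds.
    """
    n_frame = int(round(frame_len * rate))
    n_hop = int(round(hop * rate))
    if x.size < n_frame:
        return np.empty((0, n_frame)), np.empty(0)
    n_frames = 1 + (x.size - n_frame) // n_hop
    idx = np.arange(n_frame)[None, :] + n_hop * np.arange(n_frames)[:, None]
    frames = x[idx]
    times = (np.arange(n_frames) * n_hop + n_frame / 2) / rate
    return frames, times


def _autocorr_peak(frames: np.ndarray, lag_min: int, lag_max: int):
    """Normalized autocorrelation maximum per frame within a lag range.

    Returns ``(peak_value, peak_lag)`` arrays; computed via FFT for speed.
    """
    n_frame = frames.shape[1]
    frames = frames - frames.mean(axis=1, keepdims=True)
    nfft = int(2 ** np.ceil(np.log2(2 * n_frame)))
    spec = np.fft.rfft(frames, nfft, axis=1)
    acf = np.fft.irfft(spec * np.conj(spec), nfft, axis=1)[:, :n_frame]
    with np.errstate(invalid="ignore", divide="ignore"):
        acf = acf / acf[:, :1]
    acf = np.nan_to_num(acf)
    lag_max = min(lag_max, n_frame - 1)
    window = acf[:, lag_min : lag_max + 1]
    if window.shape[1] == 0:
        z = np.zeros(frames.shape[0])
        return z, np.full(frames.shape[0], lag_min)
    peak_rel = np.argmax(window, axis=1)
    peak_lag = peak_rel + lag_min
    peak_val = window[np.arange(window.shape[0]), peak_rel]
    return peak_val, peak_lag


def detect_voiced(
    rec: Recording,
    frame_len: float = 0.04,
    hop: float = 0.01,
    f0_range: tuple[float, float] = (60.0, 600.0),
    energy_rel_threshold: float = 0.01,
    periodicity_threshold: float = 0.45,
) -> VoicedMask:
    """Flag frames in which quasi-periodic vocal-fold vibration occurs.

    A frame is voiced iff its short-time energy exceeds an adaptive
    threshold (``energy_rel_threshold`` x the maximum frame energy) AND its
    normalized autocorrelation has a peak above ``periodicity_threshold``
    within the lag range implied by ``f0_range``.  Silence yields an
    all-false mask, never an error.
    """
    frames, times = frame_signal(rec.samples, rec.rate, frame_len, hop)
    if frames.shape[0] == 0:
        return VoicedMask(np.zeros(0, bool), np.zeros(0), frame_len, hop)
    energy = np.mean(frames**2, axis=1)
    e_max = energy.max()
    if e_max <= 0.0:
        flags = np.zeros(frames.shape[0], bool)
        return VoicedMask(flags, times, frame_len, hop)
    lag_min = max(2, int(np.floor(rec.rate / f0_range[1])))
    lag_max = int(np.ceil(rec.rate / f0_range[0]))
    peak_val, _ = _autocorr_peak(frames, lag_min, lag_max)
    flags = (energy > energy_rel_threshold * e_max) & (peak_val > periodicity_threshold)
    return VoicedMask(flags, times, frame_len, hop)
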