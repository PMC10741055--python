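"""F0, jitter, NNE and formant estimation against synthesis ground truth."""

import numpy as np
import pytest

from voxpheno.acoustics import (
    ADULT_FEMALE,
    ADULT_MALE,
    CHILD,
    PARAMETER_CATALOG,
    PROFILE_FIELDS,
    AcousticProfile,
    F0Track,
    analyze_vowel,
    category_for,
    compute_jitter,
    compute_nne,
    estimate_f0_track,
    estimate_formants,
    f0_statistics,
    segmentation_stats,
)
from voxpheno.audio_io import Recording, SubjectMeta, detect_voiced, select_central_segment
from voxpheno.errors import InsufficientVoicingError
from voxpheno.synth import VowelSpec, synthesize_vowel


def _sine(freq, duration=2.0, rate=16000):
    t = np.arange(int(duration * rate)) / rate
    return Recording(0.8 * np.sin(2 * np.pi * freq * t), rate, "s", "a")


class TestCategory:
    def test_mapping_by_age_and_sex(self):
        child = SubjectMeta("c", 8.0, "male", "HS")
        fa = SubjectMeta("f", 25.0, "female", "HS")
        ma = SubjectMeta("m", 25.0, "male", "HS")
        assert category_for(child) is CHILD
        assert category_for(fa) is ADULT_FEMALE
        assert category_for(ma) is ADULT_MALE


class TestF0Track:
    def test_pure_sinusoid_within_one_hz(self):
        rec = _sine(150.0)
        mask = detect_voiced(rec, f0_range=ADULT_MALE.f0_range)
        track = estimate_f0_track(rec, mask, ADULT_MALE)
        assert np.all(np.abs(track.values - 150.0) <= 1.0)

    def test_synthesized_vowel_mean_within_two_hz(self):
        spec = VowelSpec(
            f0=220.0, formants=(800.0, 1300.0, 2800.0), jitter_pct=0.0,
            snr_db=60.0, duration=2.0, rate=22050, seed=1,
        )
        rec = synthesize_vowel(spec)
        mask = detect_voiced(rec, f0_range=ADULT_FEMALE.f0_range)
        track = estimate_f0_track(rec, mask, ADULT_FEMALE)
        assert abs(np.mean(track.values) - 220.0) <= 2.0

    def test_silence_raises_insufficient_voicing(self):
        rec = Recording(np.zeros(16000), 16000, "s", "a")
        mask = detect_voiced(rec)
        with pytest.raises(InsufficientVoicingError):
            estimate_f0_track(rec, mask, ADULT_MALE)


class TestF0Statistics:
    def test_constant_track(self):
        track = F0Track(times=np.array([0.1, 0.2, 0.3]), values=np.full(3, 200.0))
        s = f0_statistics(track)
        assert s["f0_mean"] == s["f0_median"] == s["f0_min"] == s["f0_max"] == 200.0
        assert s["f0_std"] == 0.0
        assert s["t0_f0_min"] == 0.1  # first occurrence on ties

    def test_extrema_lookup(self):
        track = F0Track(np.array([0.1, 0.2, 0.3]), np.array([180.0, 190.0, 200.0]))
        s = f0_statistics(track)
        assert (s["f0_min"], s["t0_f0_min"]) == (180.0, 0.1)
        assert (s["f0_max"], s["t0_f0_max"]) == (200.0, 0.3)

    def test_matches_brute_force_on_random_track(self):
        rng = np.random.default_rng(42)
        values = rng.uniform(100, 300, size=50)
        times = np.sort(rng.uniform(0, 2, size=50))
        s = f0_statistics(F0Track(times, values))
        # independent brute-force recomputation
        assert s["f0_mean"] == pytest.approx(sum(values) / len(values))
        assert s["f0_median"] == pytest.approx(float(np.sort(values)[25 - 1 : 25 + 1].mean()))
        assert s["f0_std"] == pytest.approx(
            (sum((v - values.mean()) ** 2 for v in values) / 49) ** 0.5
        )
        assert s["f0_min"] == min(values) and s["f0_max"] == max(values)
        assert s["t0_f0_min"] == times[int(np.argmin(values))]


class TestJitter:
    def test_alternating_periods_hand_value(self):
        """Periods alternating 10.0/10.1 ms give 100 * 0.1 / 10.05 %."""
        periods = np.tile([0.0100, 0.0101], 10)
        times = np.cumsum(periods)
        track = F0Track(times, 1.0 / periods)
        assert compute_jitter(track) == pytest.approx(100 * 0.0001 / 0.01005, rel=1e-9)

    def test_too_few_periods_rejected(self):
        track = F0Track(np.array([0.0, 0.01]), np.array([100.0, 100.0]))
        with pytest.raises(InsufficientVoicingError):
            compute_jitter(track)

    def test_imposed_cycle_jitter_recovered(self):
        spec = VowelSpec(
            f0=200.0, formants=(800.0, 1300.0, 2800.0), jitter_pct=2.0,
            snr_db=35.0, duration=2.0, rate=22050, seed=8,
        )
        prof = analyze_vowel(synthesize_vowel(spec), ADULT_FEMALE)
        assert 1.0 <= prof.jitter_pct <= 3.0


class TestNNE:
    def _track(self, rec, cat):
        mask = detect_voiced(rec, f0_range=cat.f0_range)
        return estimate_f0_track(rec, mask, cat)

    def test_noiseless_vowel_is_low(self):
        spec = VowelSpec(
            f0=150.0, formants=(700.0, 1200.0, 2600.0), jitter_pct=0.0,
            snr_db=80.0, duration=2.0, rate=22050, seed=2,
        )
        rec = synthesize_vowel(spec)
        nne = compute_nne(rec, self._track(rec, ADULT_MALE), ADULT_MALE)
        assert nne <= -15.0

    def test_equal_power_noise_is_near_zero(self):
        spec = VowelSpec(
            f0=210.0, formants=(800.0, 1300.0, 2800.0), jitter_pct=0.0,
            snr_db=0.0, duration=2.0, rate=22050, seed=3,
        )
        rec = synthesize_vowel(spec)
        nne = compute_nne(rec, self._track(rec, ADULT_FEMALE), ADULT_FEMALE)
        assert -5.0 <= nne <= 0.0

    @pytest.mark.parametrize("snr_db", [40.0, 20.0, 5.0])
    def test_never_positive(self, snr_db):
        spec = VowelSpec(
            f0=180.0, formants=(700.0, 1200.0, 2600.0), snr_db=snr_db,
            duration=1.5, rate=16000, seed=4,
        )
        rec = synthesize_vowel(spec)
        assert compute_nne(rec, self._track(rec, ADULT_MALE), ADULT_MALE) <= 0.0


class TestFormants:
    def test_resonator_targets_recovered(self):
        spec = VowelSpec(
            f0=120.0, formants=(700.0, 1200.0, 2600.0), jitter_pct=0.5,
            snr_db=40.0, duration=2.0, rate=22050, seed=5,
        )
        rec = select_central_segment(synthesize_vowel(spec))
        mask = detect_voiced(rec, f0_range=ADULT_MALE.f0_range)
        _, stats = estimate_formants(rec, mask, ADULT_MALE)
        for i, target in enumerate((700.0, 1200.0, 2600.0), start=1):
            assert abs(stats[f"f{i}_mean"] - target) / target <= 0.05

    def test_ordering_invariant_for_front_vowel(self):
        spec = VowelSpec(
            f0=120.0, formants=(300.0, 2000.0, 2800.0), jitter_pct=0.5,
            snr_db=40.0, duration=2.0, rate=22050, seed=6,
        )
        rec = select_central_segment(synthesize_vowel(spec))
        mask = detect_voiced(rec, f0_range=ADULT_MALE.f0_range)
        _, stats = estimate_formants(rec, mask, ADULT_MALE)
        assert stats["f1_mean"] < stats["f2_mean"] < stats["f3_mean"]

    def test_statistics_match_brute_force_from_tracks(self):
        spec = VowelSpec(
            f0=150.0, formants=(600.0, 1100.0, 2400.0), jitter_pct=1.0,
            snr_db=35.0, duration=2.0, rate=16000, seed=7,
        )
        rec = select_central_segment(synthesize_vowel(spec))
        mask = detect_voiced(rec, f0_range=ADULT_MALE.f0_range)
        tracks, stats = estimate_formants(rec, mask, ADULT_MALE)
        for key in ("f1", "f2", "f3"):
            v = tracks[key]
            assert stats[f"{key}_mean"] == pytest.approx(v.sum() / v.size)
            assert stats[f"{key}_min"] == min(v) and stats[f"{key}_max"] == max(v)
            assert stats[f"{key}_median"] == pytest.approx(float(np.median(v)))
            assert stats[f"{key}_std"] == pytest.approx(float(np.std(v, ddof=1)))


class TestProfile:
    def test_profile_has_24_ordered_fields(self):
        assert len(PROFILE_FIELDS) == 24
        prof = AcousticProfile(**{name: 1.0 for name in PROFILE_FIELDS} | {"nne_db": -1.0})
        assert list(prof.as_dict()) == list(PROFILE_FIELDS)
        assert prof.as_array().size == 24

    def test_profile_invariants_on_synthetic_vowel(self, male_vowel_25db):
        _, rec = male_vowel_25db
        prof = analyze_vowel(rec, ADULT_MALE)
        d = prof.as_dict()
        assert d["f0_min"] <= d["f0_median"] <= d["f0_max"]
        for i in (1, 2, 3):
            assert d[f"f{i}_min"] <= d[f"f{i}_median"] <= d[f"f{i}_max"]
            assert d[f"f{i}_std"] >= 0
        assert d["nne_db"] <= 0

    def test_silence_propagates_insufficient_voicing(self):
        rec = Recording(np.zeros(32000), 16000, "s", "a")
        with pytest.raises(InsufficientVoicingError):
            analyze_vowel(rec, ADULT_MALE)


class TestCatalog:
    def test_catalog_has_37_parameters_24_selected(self):
        assert len(PARAMETER_CATALOG) == 37
        selected = [name for name, _, sel in PARAMETER_CATALOG if sel]
        assert len(selected) == 24
        assert tuple(selected) == PROFILE_FIELDS

    def test_segmentation_stats_cover_unselected_catalog(self):
        rec = _sine(150.0)
        mask = detect_voiced(rec, f0_range=ADULT_MALE.f0_range)
        extras = segmentation_stats(rec, mask)
        unselected = {name for name, _, sel in PARAMETER_CATALOG if not sel}
        assert set(extras) == unselected
        assert extras["signal_duration"] == pytest.approx(2.0)
        assert extras["pct_voiced"] > 90.0
        assert extras["n_units"] >= 1
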