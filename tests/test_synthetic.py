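"""Synthetic cohort generator: determinism, programmed effect directions,
spectral content, and phase-block consistency."""

import numpy as np
import pytest
from scipy import signal

from swaymetrics.cop_features import sample_entropy
from swaymetrics.montage import EEG_MONTAGE_64
from swaymetrics.session import PhaseLabel, ValidationError
from swaymetrics.synthetic import (
    SynthParams,
    assemble_collection,
    generate_cohort_session,
    generate_cop,
    generate_eeg,
    generate_emg,
    generate_phase_segments,
    null_params,
)


def _pergroup(h, p):
    return {"healthy": h, "pd": p}


class TestDeterminism:
    def test_same_seed_identical_samples(self):
        p = SynthParams()
        a = generate_cop(p, "healthy", 20.0, seed=42)
        b = generate_cop(p, "healthy", 20.0, seed=42)
        np.testing.assert_array_equal(a.values, b.values)
        e1 = generate_eeg(p, "pd", 10.0, seed=3)
        e2 = generate_eeg(p, "pd", 10.0, seed=3)
        np.testing.assert_array_equal(e1.values, e2.values)

    def test_collections_reproducible(self, tiny_schedule):
        p = SynthParams(n_healthy=2, n_pd=2, seed=11)
        c1 = assemble_collection(p, tiny_schedule)
        c2 = assemble_collection(p, tiny_schedule)
        for s1, s2 in zip(c1.sessions, c2.sessions):
            np.testing.assert_array_equal(s1.cop.values, s2.cop.values)
            np.testing.assert_array_equal(s1.eeg.values, s2.eeg.values)

    def test_subject_streams_independent_of_cohort_size(self, tiny_schedule):
        small = SynthParams(n_healthy=2, n_pd=2, seed=5)
        large = SynthParams(n_healthy=4, n_pd=3, seed=5)
        s_small = generate_cohort_session(small, "healthy", 1, tiny_schedule)
        s_large = generate_cohort_session(large, "healthy", 1, tiny_schedule)
        np.testing.assert_array_equal(s_small.cop.values, s_large.cop.values)

    def test_phase_generation_matches_full_session_slices(self, mini_schedule):
        p = SynthParams(seed=2)
        session = generate_cohort_session(p, "pd", 0, mini_schedule)
        segs = generate_phase_segments(p, "pd", 0, [PhaseLabel.PRE, PhaseLabel.POST],
                                       schedule=mini_schedule)
        for modality in ("cop", "emg", "eeg", "hr"):
            full = session.modality(modality)
            for phase in (PhaseLabel.PRE, PhaseLabel.POST):
                start, end = mini_schedule.window(phase)
                np.testing.assert_array_equal(
                    segs[modality][phase].values,
                    full.slice_seconds(start, end).values,
                )


class TestCoPGenerator:
    def test_sway_scale_orders_empirical_sd(self):
        p = SynthParams(cop_sway_scale=_pergroup(3.0, 2.0))
        wins = 0
        for seed in range(50):
            h = generate_cop(p, "healthy", 40.0, seed=seed).values
            d = generate_cop(p, "pd", 40.0, seed=seed + 1000).values
            wins += np.std(h) > np.std(d)
        assert wins > 25

    def test_complexity_raises_sample_entropy_at_equal_sd(self):
        hi = SynthParams(cop_ml_complexity=_pergroup(1.0, 1.0))
        lo = SynthParams(cop_ml_complexity=_pergroup(0.0, 0.0))
        wins = 0
        for seed in range(20):
            ml_hi = generate_cop(hi, "healthy", 40.0, seed=seed).channel("ML")
            ml_lo = generate_cop(lo, "healthy", 40.0, seed=seed).channel("ML")
            wins += sample_entropy(ml_hi) > sample_entropy(ml_lo)
        assert wins > 10

    def test_duration_too_short_rejected(self):
        with pytest.raises(ValidationError):
            generate_cop(SynthParams(), "healthy", 5.0, seed=0)


class TestEMGGenerator:
    def test_gain_scales_rms_linearly(self):
        p1 = SynthParams(emg_burst_gain=_pergroup({"R_TA": 1.0}, {}))
        p2 = SynthParams(emg_burst_gain=_pergroup({"R_TA": 2.0}, {}))
        a = generate_emg(p1, "healthy", 10.0, seed=4).channel("R_TA")
        b = generate_emg(p2, "healthy", 10.0, seed=4).channel("R_TA")
        ratio = np.sqrt(np.mean(b**2) / np.mean(a**2))
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_channels_are_zero_mean(self):
        ts = generate_emg(SynthParams(), "pd", 10.0, seed=8)
        for ch in ts.channel_labels:
            x = ts.channel(ch)
            assert abs(np.mean(x)) < 0.01 * np.sqrt(np.mean(x**2))

    def test_band_limited_20_450(self):
        ts = generate_emg(SynthParams(), "healthy", 20.0, seed=1)
        x = ts.channel("L_GL")
        f, p = signal.periodogram(x, fs=ts.rate)
        outside = p[(f < 10) | (f > 500)].sum()
        assert outside < 0.05 * p.sum()


class TestEEGGenerator:
    def test_montage_labels(self):
        ts = generate_eeg(SynthParams(), "healthy", 10.0, seed=0)
        assert ts.channel_labels == list(EEG_MONTAGE_64)
        for must in ("T7", "T8", "FC5", "FT7", "FT8", "C6", "P4", "PO6",
                     "AF3", "M1"):
            assert must in ts.channel_labels

    def test_alpha_factor_lowers_band_power(self):
        p = SynthParams(eeg_band_offset={("T7", "alpha"): _pergroup(1.0, 0.5)})
        wins = 0
        for seed in range(10):
            h = generate_eeg(p, "healthy", 10.0, seed=seed)
            d = generate_eeg(p, "pd", 10.0, seed=seed + 500)
            wins += _alpha_power(h, "T7") > _alpha_power(d, "T7")
        assert wins > 5

    def test_unknown_electrode_rejected(self):
        p = SynthParams(eeg_band_offset={("XX9", "alpha"): _pergroup(1.0, 0.5)})
        with pytest.raises(ValidationError, match="XX9"):
            generate_eeg(p, "healthy", 10.0, seed=0)

    def test_null_configuration_rejects_at_nominal_rate(self):
        """With no programmed offsets, per-electrode Mann-Whitney raw
        rejections should sit near the 5 % nominal level."""
        from swaymetrics.group_stats import mann_whitney

        rejections = 0
        total = 0
        p = null_params()
        for seed in range(3):
            pow_h = [_all_alpha(generate_eeg(p, "healthy", 10.0, seed=1000 * seed + i))
                     for i in range(8)]
            pow_d = [_all_alpha(generate_eeg(p, "pd", 10.0, seed=1000 * seed + 100 + i))
                     for i in range(8)]
            a, b = np.array(pow_h), np.array(pow_d)
            for ei in range(64):
                total += 1
                rejections += mann_whitney(a[:, ei], b[:, ei]) < 0.05
        # binomial 95% band around 0.05 for n=192 is roughly [0.02, 0.09]
        assert rejections / total < 0.12


class TestSessionAssembly:
    def test_collection_counts(self, tiny_schedule):
        p = SynthParams(n_healthy=29, n_pd=9, seed=3)
        coll = assemble_collection(p, tiny_schedule)
        groups = [s.group for s in coll.sessions]
        assert len(coll.sessions) == 38
        assert groups.count("healthy") == 29
        assert groups.count("pd") == 9

    def test_hr_trend_post_raises_post_mean(self, mini_schedule):
        p = SynthParams(hr_trend_post=_pergroup(0.0, 6.0),
                        hr_between_sd=_pergroup(0.0, 0.0))
        diffs = []
        for idx in range(6):
            segs = generate_phase_segments(p, "pd", idx,
                                           [PhaseLabel.PRE, PhaseLabel.POST],
                                           modalities=("hr",),
                                           schedule=mini_schedule)
            diffs.append(segs["hr"][PhaseLabel.POST].values.mean()
                         - segs["hr"][PhaseLabel.PRE].values.mean())
        assert np.mean(diffs) > 3.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            SynthParams(n_healthy=1).validate()
        with pytest.raises(ValidationError):
            SynthParams(cop_ml_complexity=_pergroup(0.5, 1.5)).validate()
        with pytest.raises(ValidationError):
            SynthParams(emg_burst_gain=_pergroup({"knee": 1.0}, {})).validate()


def _alpha_power(ts, electrode):
    x = ts.channel(electrode)
    f, p = signal.welch(x, fs=ts.rate, nperseg=int(2 * ts.rate))
    return p[(f >= 8) & (f <= 13)].sum()


def _all_alpha(ts):
    f, p = signal.welch(np.asarray(ts.values, dtype=float), fs=ts.rate,
                        nperseg=int(2 * ts.rate), axis=0)
    mask = (f >= 8) & (f <= 13)
    return p[mask].sum(axis=0)
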