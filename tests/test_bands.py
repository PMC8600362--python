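"""Band anchoring, band powers, center of gravity, and the 30 features."""

import numpy as np
import pytest

from restband import bands, simulate, spectral
from restband.bands import (
    BandDefinition,
    NoClearAlphaPeak,
    averaged_peak_power,
    band_absolute_power,
    band_relative_power,
    center_of_gravity,
    define_bands,
    detect_alpha_peak,
    extract_features,
)
from restband.spectral import PowerSpectrum

FREQS = np.arange(2.0, 47.5, 0.5)


def _spectrum(power, condition="closed"):
    return PowerSpectrum(FREQS, np.asarray(power, dtype=float), 1, condition)


def _flat(level=1.0):
    return _spectrum(np.full(FREQS.size, level))


def _one_over_f(offset=20.0, exponent=1.3):
    return _spectrum(offset * FREQS**-exponent)


def _with_alpha_bump(peak=10.0, amp=5.0, **kw):
    base = _one_over_f(**kw).power
    return _spectrum(base + amp * np.exp(-0.5 * ((FREQS - peak) / 0.8) ** 2))


class TestDefineBands:
    @pytest.mark.parametrize(
        "peak, alpha, theta",
        [
            (10.38, (7.38, 12.38), (4.38, 7.38)),
            (10.0, (7.0, 12.0), (4.0, 7.0)),
        ],
    )
    def test_three_below_two_above_rule(self, peak, alpha, theta):
        bd = define_bands(peak)
        assert (bd["alpha"].f_low, bd["alpha"].f_high) == pytest.approx(alpha)
        assert (bd["theta"].f_low, bd["theta"].f_high) == pytest.approx(theta)
        assert (bd["beta"].f_low, bd["beta"].f_high) == (14.0, 28.0)
        assert (bd["gamma"].f_low, bd["gamma"].f_high) == (30.0, 47.0)
        assert (bd["total"].f_low, bd["total"].f_high) == (2.0, 47.0)

    def test_band_edge_consistency_and_widths(self):
        for peak in np.arange(8.0, 13.0, 0.37):
            bd = define_bands(peak)
            assert bd["theta"].f_high == bd["alpha"].f_low
            assert bd["alpha"].f_high - bd["alpha"].f_low == pytest.approx(5.0)
            assert bd["theta"].f_high - bd["theta"].f_low == pytest.approx(3.0)

    def test_low_peak_clamps_theta_to_analysis_floor(self):
        with pytest.warns(UserWarning, match="clamping"):
            bd = define_bands(7.5)
        assert bd["theta"].f_low == 2.0


class TestBandPowers:
    def test_flat_spectrum_rectangle_area(self):
        assert band_absolute_power(_flat(2.0), BandDefinition("alpha", 7.0, 12.0)) == pytest.approx(10.0)

    def test_zero_spectrum(self):
        assert band_absolute_power(_spectrum(np.zeros(FREQS.size)), BandDefinition("x", 4, 8)) == 0.0

    def test_against_per_bin_oracle(self, rng):
        power = rng.random(FREQS.size) * 3
        ps = _spectrum(power)
        band = BandDefinition("b", 6.5, 13.5)
        # brute-force per-bin summation
        expect = sum(p * 0.5 for f, p in zip(FREQS, power) if 6.5 <= f < 13.5)
        assert band_absolute_power(ps, band) == pytest.approx(expect, rel=1e-12)

    def test_band_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            band_absolute_power(_flat(), BandDefinition("x", 0.5, 5.0))

    def test_relative_power_single_band_mass(self):
        power = np.zeros(FREQS.size)
        power[(FREQS >= 30) & (FREQS < 47)] = 4.0
        ps = _spectrum(power)
        assert band_relative_power(ps, BandDefinition("gamma", 30, 47)) == pytest.approx(1.0)
        assert band_relative_power(ps, BandDefinition("theta", 4, 7)) == 0.0

    def test_flat_spectrum_uniform_ratio(self):
        assert band_relative_power(_flat(), BandDefinition("beta", 14, 28)) == pytest.approx(14 / 45)

    def test_four_band_sum_at_most_one(self, rng):
        for _ in range(100):
            ps = _spectrum(rng.random(FREQS.size))
            bd = define_bands(float(rng.uniform(8.1, 12.9)))
            total = sum(
                band_relative_power(ps, bd[name]) for name in ("theta", "alpha", "beta", "gamma")
            )
            assert 0.0 <= total <= 1.0 + 1e-12


class TestCenterOfGravity:
    def test_hand_computed_three_bins(self):
        power = np.zeros(FREQS.size)
        for f, a in [(4.0, 1.0), (5.0, 3.0), (6.0, 1.0)]:
            power[np.argmin(np.abs(FREQS - f))] = a
        # (4*1 + 5*3 + 6*1) / 5 = 5.0
        assert center_of_gravity(_spectrum(power), BandDefinition("t", 3.5, 6.6)) == pytest.approx(5.0)

    def test_symmetric_spectrum_gives_band_center(self):
        band = BandDefinition("b", 14.0, 28.0)
        mask = (FREQS >= 14) & (FREQS < 28)
        power = np.zeros(FREQS.size)
        center = 20.75  # midpoint of the 14.0..27.5 bins
        power[mask] = np.exp(-0.5 * ((FREQS[mask] - center) / 2) ** 2)
        assert center_of_gravity(_spectrum(power), band) == pytest.approx(center)

    def test_point_mass(self):
        power = np.zeros(FREQS.size)
        power[np.argmin(np.abs(FREQS - 6.5))] = 2.0
        assert center_of_gravity(_spectrum(power), BandDefinition("t", 4, 7)) == 6.5

    def test_translation_covariance(self, rng):
        """Shifting band mass by delta shifts the output by delta."""
        band = BandDefinition("b", 14.0, 28.0)
        power = np.zeros(FREQS.size)
        sel = (FREQS >= 16) & (FREQS < 22)
        power[sel] = rng.random(sel.sum()) + 0.1
        base = center_of_gravity(_spectrum(power), band)
        shifted = np.zeros(FREQS.size)
        shifted[np.roll(sel, 6)] = power[sel]  # +3 Hz shift (6 bins)
        assert center_of_gravity(_spectrum(shifted), band) == pytest.approx(base + 3.0)

    def test_zero_band_power_is_an_error(self):
        with pytest.raises(ZeroDivisionError):
            center_of_gravity(_spectrum(np.zeros(FREQS.size)), BandDefinition("t", 4, 7))


class TestAveragedPeakPower:
    def test_on_bin_and_nearest_bin(self):
        ps = _spectrum(np.arange(FREQS.size, dtype=float))
        on_bin = averaged_peak_power(ps, 5.0)
        assert on_bin == ps.power[np.argmin(np.abs(FREQS - 5.0))]
        # 5.26 Hz: distance 0.26 to 5.0, 0.24 to 5.5 -> nearest is 5.5
        assert averaged_peak_power(ps, 5.26) == ps.power[np.argmin(np.abs(FREQS - 5.5))]

    def test_tie_resolves_to_lower_frequency(self):
        ps = _spectrum(np.arange(FREQS.size, dtype=float))
        assert averaged_peak_power(ps, 5.25) == ps.power[np.argmin(np.abs(FREQS - 5.0))]

    def test_flat_spectrum_value_independent_of_cog(self):
        assert averaged_peak_power(_flat(2.5), 9.87) == 2.5


class TestAlphaPeakDetection:
    def test_pure_one_over_f_has_no_peak(self):
        res = detect_alpha_peak(_one_over_f())
        assert not res.clear_peak and np.isnan(res.peak_freq)

    def test_strong_bump_detected_at_planted_frequency(self):
        res = detect_alpha_peak(_with_alpha_bump(10.0, amp=5.0))
        assert res.clear_peak
        assert res.peak_freq == pytest.approx(10.0, abs=0.5)
        assert res.prominence > 1.25

    def test_recovery_from_generated_signals(self, small_cohort_spec):
        """Over 20 seeds the periodogram peak of synthesized EEG is the IAPF."""
        spec = small_cohort_spec
        profile = simulate.sample_cohort(spec)[0]
        profile = simulate.SubjectProfile(
            subject_id="t", group="young", iapf={"closed": 10.0, "open": 9.8},
            band_amplitudes=profile.band_amplitudes, aperiodic_offset=profile.aperiodic_offset,
            aperiodic_exponent=profile.aperiodic_exponent, noise_sd=1.0, latent_factor=0.0,
        )
        detected = []
        for s in range(20):
            sig = simulate.synthesize_eeg(profile, "closed", spec, rng=s)
            ps = spectral.subject_spectrum(sig, spec.sfreq, condition="closed")
            detected.append(detect_alpha_peak(ps).peak_freq)
        assert np.median(detected) == pytest.approx(10.0, abs=0.5)

    def test_zero_alpha_amplitude_flags_no_clear_peak(self):
        # full-length recording: the prominence rule needs the study's
        # 180 averaged epochs to push averaging noise below the threshold
        spec = simulate.CohortSpec(
            n_young=1, n_older=0, n_channels=2, segment_len=60.0,
            n_segments_per_condition=3, seed=42,
        )
        base = simulate.sample_cohort(spec)[0]
        amps = dict(base.band_amplitudes)
        amps[("alpha", "closed")] = 0.0
        amps[("alpha", "open")] = 0.0
        profile = simulate.SubjectProfile(
            subject_id="flat", group="older", iapf=base.iapf, band_amplitudes=amps,
            aperiodic_offset=base.aperiodic_offset, aperiodic_exponent=base.aperiodic_exponent,
            noise_sd=1.0, latent_factor=0.0,
        )
        sig = simulate.synthesize_eeg(profile, "closed", spec, rng=0)
        ps = spectral.subject_spectrum(sig, spec.sfreq, condition="closed")
        assert not detect_alpha_peak(ps).clear_peak


class TestFeatureExtraction:
    def test_thirty_finite_values_and_compositional_equality(self, study_analysis):
        feats = study_analysis.features
        assert list(feats.columns[1:]) == list(bands.FEATURE_NAMES)
        assert feats[list(bands.FEATURE_NAMES)].notna().all().all()
        assert np.isfinite(feats[list(bands.FEATURE_NAMES)].to_numpy()).all()

    def test_componentwise_equality_with_individual_operations(self):
        spectra = {
            "closed": _with_alpha_bump(10.0, 5.0),
            "open": _with_alpha_bump(9.5, 3.0),
        }
        spectra["open"].condition = "open"
        feats = extract_features(spectra)
        peak = detect_alpha_peak(spectra["closed"])
        bd = define_bands(peak.peak_freq)
        assert feats["alpha_peak_freq_closed"] == peak.peak_freq
        assert feats["alpha_abs_closed"] == band_absolute_power(spectra["closed"], bd["alpha"])
        cog = center_of_gravity(spectra["closed"], bd["theta"])
        assert feats["theta_apf_closed"] == cog
        assert feats["theta_ap_power_closed"] == averaged_peak_power(spectra["closed"], cog)
        assert feats["beta_rel_open"] == band_relative_power(
            spectra["open"], define_bands(detect_alpha_peak(spectra["open"]).peak_freq)["beta"]
        )

    def test_missing_condition_and_peakless_subject(self):
        with pytest.raises(ValueError, match="missing"):
            extract_features({"closed": _with_alpha_bump()})
        with pytest.raises(NoClearAlphaPeak):
            extract_features({"closed": _one_over_f(), "open": _one_over_f()})

    def test_group_mean_effect_directions(self, study_analysis):
        """Older adults show lower theta absolute power and higher beta
        relative power in both eye conditions."""
        feats = study_analysis.features
        young = feats[feats["group"] == "young"]
        older = feats[feats["group"] == "older"]
        for cond in ("closed", "open"):
            assert older[f"theta_abs_{cond}"].mean() < young[f"theta_abs_{cond}"].mean()
            assert older[f"beta_rel_{cond}"].mean() > young[f"beta_rel_{cond}"].mean()
            assert older[f"alpha_peak_freq_{cond}"].mean() < young[f"alpha_peak_freq_{cond}"].mean()

    def test_alpha_closed_exceeds_open(self, study_analysis):
        feats = study_analysis.features
        assert (feats["alpha_abs_closed"] > feats["alpha_abs_open"]).mean() > 0.9

    def test_planted_peakless_subjects_are_the_excluded_ones(self, study_analysis):
        planted = {p.subject_id for p in study_analysis.profiles if p.peakless}
        flagged = {sid for sid, _ in study_analysis.excluded}
        assert planted <= flagged
        assert len(planted) == 3


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=100, derandomize=True)
@given(
    peak=st.floats(8.0, 12.9),
    powers=st.lists(st.floats(0.01, 100.0), min_size=91, max_size=91),
)
def test_band_invariants_hold_for_arbitrary_spectra(peak, powers):
    """For any positive spectrum and any anchoring peak: relative powers are
    proper fractions summing <= 1, and the center of gravity stays inside
    its band."""
    ps = _spectrum(np.asarray(powers))
    bd = define_bands(peak)
    rels = {n: band_relative_power(ps, bd[n]) for n in ("theta", "alpha", "beta", "gamma")}
    assert all(0.0 <= r <= 1.0 for r in rels.values())
    assert sum(rels.values()) <= 1.0 + 1e-9
    for name in ("theta", "beta"):
        cog = center_of_gravity(ps, bd[name])
        assert bd[name].f_low - 1e-9 <= cog <= bd[name].f_high + 1e-9


def test_parameter_recovery_correlation_over_cohort(study_analysis):
    """Detected alpha peaks track the generated IAPF (r > 0.95 over the cohort)."""
    prof = {p.subject_id: p for p in study_analysis.profiles}
    feats = study_analysis.features
    true_iapf = np.array([prof[s].iapf["closed"] for s in feats.index])
    detected = feats["alpha_peak_freq_closed"].to_numpy()
    assert np.corrcoef(true_iapf, detected)[0, 1] > 0.95
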