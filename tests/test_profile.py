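"""Profile statistics: cumulative curves, ΔS/ΔV, peaks, sub-peaks, ratios."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cffrag.io import FragmentSet, build_profile
from cffrag.profile import (
    RANGE_BOUNDS,
    SubpeakReport,
    cumulative,
    delta_s,
    delta_v,
    detect_subpeaks,
    feature_panel,
    maf_trend,
    peak,
    periodicity,
    range_fraction,
    ratio_at,
    reference_mean,
    stagger_offset,
)
from .conftest import profile_from_freqs


def random_profile(rng, support=(30, 440), assay="RAW"):
    lo, hi = support
    freqs = rng.random(hi - lo + 1) ** 3
    return profile_from_freqs(
        {l: f for l, f in zip(range(lo, hi + 1), freqs)}, support=support, assay=assay
    )


class TestCumulative:
    def test_two_point(self, two_length_profile):
        s = cumulative(two_length_profile)
        assert s.at(145) == pytest.approx(0.25)
        assert s.at(166) == pytest.approx(1.0)

    def test_uniform_midpoint(self, uniform_profile):
        assert cumulative(uniform_profile).at(149) == pytest.approx(0.50)

    def test_ends_at_one(self):
        rng = np.random.default_rng(0)
        s = cumulative(random_profile(rng))
        assert s.values[-1] == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(s.values) >= -1e-12).all()


class TestDeltaCurves:
    def test_identical_profiles_give_zero(self, two_length_profile):
        assert np.allclose(delta_s(two_length_profile, two_length_profile).values, 0)
        assert np.allclose(delta_v(two_length_profile, two_length_profile).values, 0)

    def test_disjoint_mass_step(self):
        a = profile_from_freqs({100: 1.0}, support=(100, 200))
        b = profile_from_freqs({200: 1.0}, support=(100, 200))
        ds = delta_s(a, b)
        assert ds.at(100) == pytest.approx(100.0)
        assert ds.at(199) == pytest.approx(100.0)
        assert ds.at(200) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        a = profile_from_freqs({100: 0.5, 200: 0.5}, support=(90, 210))
        b = profile_from_freqs({150: 1.0}, support=(90, 210))
        ds = delta_s(a, b)
        assert ds.at(120) == pytest.approx(50.0)
        assert ds.at(170) == pytest.approx(-50.0)
        assert ds.at(200) == pytest.approx(0.0)

    def test_delta_v_simple(self):
        a = profile_from_freqs({100: 1.0}, support=(90, 210))
        b = profile_from_freqs({100: 0.6, 200: 0.4}, support=(90, 210))
        dv = delta_v(a, b)
        assert dv.at(100) == pytest.approx(40.0)
        assert dv.at(200) == pytest.approx(-40.0)
        assert dv.values.sum() == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_supports_error(self):
        a = profile_from_freqs({100: 1.0}, support=(90, 110))
        b = profile_from_freqs({200: 1.0}, support=(190, 210))
        with pytest.raises(ValueError, match="disjoint"):
            delta_s(a, b)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_cumsum_of_delta_v_is_delta_s(self, seed):
        """ΔS is the running sum of ΔV, and both are antisymmetric."""
        rng = np.random.default_rng(seed)
        a, b = random_profile(rng), random_profile(rng)
        ds, dv = delta_s(a, b), delta_v(a, b)
        assert np.allclose(np.cumsum(dv.values), ds.values, atol=1e-9)
        assert abs(ds.values[-1]) < 1e-9
        assert np.allclose(delta_s(b, a).values, -ds.values, atol=1e-12)
        assert np.allclose(delta_v(b, a).values, -dv.values, atol=1e-12)


class TestRangeFraction:
    def test_uniform_half(self, uniform_profile):
        assert range_fraction(uniform_profile, 100, 149, 100, 199) == pytest.approx(50.0)

    def test_boundary_inclusion(self):
        p = profile_from_freqs({89: 0.5, 90: 0.5}, support=(30, 440))
        assert range_fraction(p, 90, 240, 30, 440) == pytest.approx(50.0)

    def test_three_ranges_partition(self):
        rng = np.random.default_rng(1)
        p = random_profile(rng)
        total = sum(range_fraction(p, lo, hi, 30, 440) for lo, hi in RANGE_BOUNDS)
        assert total == pytest.approx(100.0)

    def test_zero_denominator_error(self):
        p = profile_from_freqs({400: 1.0}, support=(30, 440))
        with pytest.raises(ZeroDivisionError):
            range_fraction(p, 30, 89, 30, 200)


class TestPeak:
    def test_position_and_height_percent(self):
        background = {l: 0.975 / 180 for l in range(81, 261)}
        background[166] = 0.025 + 0.975 / 180  # modal chromatosome length
        background[80] = 0.0
        p = profile_from_freqs(background, support=(80, 260))
        pos, height = peak(p, (80, 260))
        assert pos == 166
        assert height == pytest.approx(2.5 + 100 * 0.975 / 180, rel=1e-6)

    def test_tie_breaks_to_smallest(self, uniform_profile):
        assert peak(uniform_profile, (120, 180))[0] == 120

    def test_window_excluding_max(self, two_length_profile):
        assert peak(two_length_profile, (100, 150))[0] == 145


class TestSubpeaks:
    def comb_profile(self, positions, noise=0.0, seed=0, support=(40, 110)):
        rng = np.random.default_rng(seed)
        lo, hi = support
        base = np.full(hi - lo + 1, 0.01)
        if noise:
            base += rng.random(hi - lo + 1) * noise
        for p in positions:
            base[p - lo] += 0.05
        return profile_from_freqs(
            {l: f for l, f in zip(range(lo, hi + 1), base)}, support=support
        )

    def test_recovers_pure_comb(self):
        comb = [53, 63, 73, 83, 94]
        p = self.comb_profile(comb)
        rep = detect_subpeaks(p, (45, 100))
        assert rep.positions == comb

    def test_comb_with_noise_within_1bp(self):
        """A 10-bp comb at SNR >= 5 is recovered within ±1 bp (seeded)."""
        comb = [53, 63, 73, 83, 94]
        p = self.comb_profile(comb, noise=0.01, seed=42)
        rep = detect_subpeaks(p, (45, 100))
        assert len(rep.positions) == len(comb)
        assert all(min(abs(q - c) for c in comb) <= 1 for q in rep.positions)

    def test_flat_profile_empty(self):
        p = profile_from_freqs({l: 1.0 for l in range(40, 111)}, support=(40, 110))
        assert detect_subpeaks(p, (45, 100)).positions == []

    def test_adjacent_spikes_merge_to_higher(self):
        lo, hi = 40, 110
        base = {l: 0.01 for l in range(lo, hi + 1)}
        base[70] += 0.04
        base[71] += 0.06
        p = profile_from_freqs(base, support=(lo, hi))
        rep = detect_subpeaks(p, (45, 100))
        assert rep.positions == [71]

    def test_window_shorter_than_kernel_error(self, uniform_profile):
        with pytest.raises(ValueError, match="kernel"):
            detect_subpeaks(uniform_profile, (100, 103))


class TestPeriodicity:
    @pytest.mark.parametrize(
        "positions, expected",
        [([53, 63, 73, 83, 94], 10), ([10, 20, 30], 10), ([10, 12, 22, 32], 10)],
    )
    def test_median_spacing(self, positions, expected):
        rep = SubpeakReport(positions=positions, search_window=(0, 100))
        assert periodicity(rep) == expected

    def test_half_integer_rounds_down(self):
        rep = SubpeakReport(positions=[10, 20, 31], search_window=(0, 100))
        assert periodicity(rep) == 10  # median of {10, 11} = 10.5 -> 10

    def test_too_few_positions(self):
        rep = SubpeakReport(positions=[10, 20], search_window=(0, 100))
        with pytest.raises(ValueError):
            periodicity(rep)

    def test_translation_invariance(self):
        a = SubpeakReport(positions=[53, 63, 73, 83, 94], search_window=(0, 200))
        b = SubpeakReport(positions=[c + 17 for c in a.positions], search_window=(0, 200))
        assert periodicity(a) == periodicity(b)


class TestStaggerOffset:
    def test_constant_shift(self):
        a = SubpeakReport(positions=[94, 104, 114], search_window=(90, 120))
        b = SubpeakReport(positions=[91, 101, 111], search_window=(90, 120))
        assert stagger_offset(a, b) == 3

    def test_zero_for_identical(self):
        a = SubpeakReport(positions=[94, 104, 114], search_window=(90, 120))
        assert stagger_offset(a, a) == 0

    def test_mode_of_offsets(self):
        a = SubpeakReport(positions=[94, 104, 115], search_window=(90, 120))
        b = SubpeakReport(positions=[91, 101, 111], search_window=(90, 120))
        assert stagger_offset(a, b) == 3  # mode of {3, 3, 4}

    def test_translation_shifts_offset(self):
        a = SubpeakReport(positions=[94, 104, 114], search_window=(0, 300))
        b = SubpeakReport(positions=[99, 109, 119], search_window=(0, 300))
        assert stagger_offset(b, a) == 5

    def test_needs_two_positions(self):
        a = SubpeakReport(positions=[94], search_window=(90, 120))
        with pytest.raises(ValueError):
            stagger_offset(a, a)


class TestRatioAt:
    def test_healthy_like_ratio(self):
        p = profile_from_freqs({166: 0.031, 145: 0.010, 200: 0.959}, support=(30, 440))
        assert ratio_at(p) == pytest.approx(3.1)

    def test_equal_frequencies(self, uniform_profile):
        assert ratio_at(uniform_profile, 150, 160) == pytest.approx(1.0)

    def test_zero_numerator(self):
        p = profile_from_freqs({145: 0.5, 200: 0.5}, support=(30, 440))
        assert ratio_at(p) == 0.0

    def test_zero_denominator_error(self):
        p = profile_from_freqs({166: 1.0}, support=(30, 440))
        with pytest.raises(ZeroDivisionError):
            ratio_at(p)


class TestReferenceMean:
    def test_mean_of_identical_is_same(self, two_length_profile):
        m = reference_mean([two_length_profile, two_length_profile])
        assert np.allclose(m.freqs, two_length_profile.freqs)

    def test_mean_of_disjoint_masses(self):
        a = profile_from_freqs({100: 1.0}, support=(100, 100))
        b = profile_from_freqs({200: 1.0}, support=(200, 200))
        m = reference_mean([a, b])
        assert m.frequency(100) == pytest.approx(0.5)
        assert m.frequency(200) == pytest.approx(0.5)

    def test_mixed_assays_error(self):
        a = profile_from_freqs({100: 1.0}, assay="DSP")
        b = profile_from_freqs({100: 1.0}, assay="SSP")
        with pytest.raises(ValueError, match="assay"):
            reference_mean([a, b])


class TestFeaturePanel:
    def test_self_reference_gives_zero_deltas(self):
        rng = np.random.default_rng(3)
        p = random_profile(rng, assay="DSP")
        panel = feature_panel(p, reference=p)
        assert panel.delta_s_at_155 == pytest.approx(0.0, abs=1e-9)
        assert panel.delta_v_40_160 == pytest.approx(0.0, abs=1e-9)

    def test_range_pcts_sum_to_100(self):
        rng = np.random.default_rng(4)
        panel = feature_panel(random_profile(rng, assay="DSP"))
        assert sum(panel.range_pcts.values()) == pytest.approx(100.0, abs=0.01)

    def test_ssp_fallback_for_delta_v(self):
        rng = np.random.default_rng(5)
        dsp = random_profile(rng, assay="DSP")
        ssp = random_profile(rng, assay="SSP")
        panel = feature_panel(dsp, ssp=ssp)
        expected = delta_v(ssp, dsp).sum_over(40, 160)
        assert panel.delta_v_40_160 == pytest.approx(expected)


class TestMafTrend:
    def make_panels(self, values):
        rng = np.random.default_rng(6)
        panels = []
        for v in values:
            p = feature_panel(random_profile(rng, assay="DSP"))
            p.frac_short_pct = v
            p.ratio_166_145 = -v
            panels.append(p)
        return panels

    def test_monotone_features(self):
        mafs = [0.9, 3.2, 14.4, 23.3, 47.3]
        panels = self.make_panels([10, 11, 15, 20, 30])
        trend = maf_trend(panels, mafs)
        assert trend.correlations["frac_short_pct"] == pytest.approx(1.0)
        assert trend.correlations["ratio_166_145"] == pytest.approx(-1.0)

    def test_constant_feature_is_nan_not_zero(self):
        panels = self.make_panels([5, 5, 5])
        trend = maf_trend(panels, [1, 2, 3])
        assert math.isnan(trend.correlations["frac_short_pct"])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            maf_trend(self.make_panels([1, 2, 3]), [1, 2])
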