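"""Slice-distribution analysis: Mw, distribution fractions, monograph check."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycocal.chromatogram import AnalysisWindow, Chromatogram
from glycocal.mw_metrics import (
    MwResult,
    SliceDistribution,
    analyze_distribution,
    check_monograph,
    chromatogram_to_distribution,
    compute_distribution_fractions,
    compute_mn,
    compute_mw,
    round_to_50,
)


def brute_force_mw(ms, ns):
    """Independent elementwise evaluation of the defining ratio."""
    num = sum(n * m * m for m, n in zip(ms, ns))
    den = sum(n * m for m, n in zip(ms, ns))
    return num / den


class TestMwEquation:
    def test_monodisperse_identity(self):
        d = SliceDistribution(m=np.array([4370.0]), n=np.array([7.7]))
        assert compute_mw(d) == pytest.approx(4370.0)

    def test_two_slice_example(self):
        d = SliceDistribution(m=np.array([1000.0, 3000.0]), n=np.array([1.0, 1.0]))
        assert compute_mw(d) == pytest.approx(2500.0)
        assert compute_distribution_fractions(d) == pytest.approx((25.0, 75.0, 0.0))

    def test_matches_brute_force_on_random_distributions(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            k = rng.integers(1, 12)
            m = rng.uniform(200, 20000, k)
            n = rng.uniform(0, 1, k)
            n[rng.integers(0, k)] += 0.5  # ensure signal
            d = SliceDistribution(m=m, n=n)
            assert compute_mw(d) == pytest.approx(brute_force_mw(m, n), rel=1e-9)
            assert compute_mw(d) >= compute_mn(d) * (1 - 1e-12)

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=100, max_value=50000),
                st.floats(min_value=1e-6, max_value=10),
            ),
            min_size=1,
            max_size=20,
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_mw_at_least_mn_and_scale_invariant(self, slices):
        m = np.array([s[0] for s in slices])
        n = np.array([s[1] for s in slices])
        d = SliceDistribution(m=m, n=n)
        assert compute_mw(d) >= compute_mn(d) - 1e-9
        scaled = SliceDistribution(m=m, n=n * 137.0)
        assert compute_mw(scaled) == pytest.approx(compute_mw(d), rel=1e-12)

    def test_merging_equal_mass_slices_preserves_results(self):
        d = SliceDistribution(
            m=np.array([1000.0, 3000.0, 3000.0]), n=np.array([1.0, 0.4, 0.6])
        )
        merged = SliceDistribution(m=np.array([1000.0, 3000.0]), n=np.array([1.0, 1.0]))
        assert compute_mw(d) == pytest.approx(compute_mw(merged), rel=1e-12)
        assert compute_distribution_fractions(d) == pytest.approx(
            compute_distribution_fractions(merged), rel=1e-12
        )


class TestFractions:
    def test_all_below_2000(self):
        d = SliceDistribution(m=np.array([500.0, 1500.0]), n=np.array([1.0, 1.0]))
        assert compute_distribution_fractions(d) == pytest.approx((100.0, 0.0, 0.0))

    def test_fractions_sum_to_100(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            d = SliceDistribution(m=rng.uniform(300, 15000, 30), n=rng.uniform(0.01, 1, 30))
            assert sum(compute_distribution_fractions(d)) == pytest.approx(100.0, abs=1e-6)

    def test_boundary_masses_fall_in_middle_band(self):
        d = SliceDistribution(m=np.array([2000.0, 8000.0]), n=np.array([1.0, 1.0]))
        low, mid, high = compute_distribution_fractions(d)
        assert (low, mid, high) == pytest.approx((0.0, 100.0, 0.0))


class TestChromatogramConversion:
    def test_flat_signal_monotone_model(self, truth):
        model = truth.truth_model()
        t = np.arange(14.0, 16.0, 0.01)
        c = Chromatogram(t, np.ones_like(t), 232.0)
        d = chromatogram_to_distribution(c, model)
        assert np.all(np.diff(d.m) < 0)  # later slices are lighter
        assert np.allclose(d.n, 1.0)

    def test_mass_detector_on_mass_signal_equals_molar_on_molar(self, truth):
        model = truth.truth_model()
        t = np.arange(14.0, 16.0, 0.01)
        n_true = np.exp(-((t - 15.0) ** 2) / 0.1)
        mw = 10.0 ** np.atleast_1d(model.predict_log10_mw(t))
        molar = chromatogram_to_distribution(Chromatogram(t, n_true, 232.0), model)
        mass = chromatogram_to_distribution(
            Chromatogram(t, n_true * mw, 232.0), model, detector="mass"
        )
        assert compute_mw(mass) == pytest.approx(compute_mw(molar), rel=1e-12)

    def test_zero_signal_window_rejected(self, truth):
        model = truth.truth_model()
        t = np.arange(14.0, 16.0, 0.01)
        c = Chromatogram(t, np.zeros_like(t), 232.0)
        with pytest.raises(ValueError):
            chromatogram_to_distribution(c, model)

    def test_true_fractions_recovered_with_truth_calibration(self, truth):
        # exact component fractions vs slice analysis of the noiseless trace;
        # narrow peaks so band-boundary smearing is negligible
        from dataclasses import replace

        from glycocal.simulate import (
            effective_composition_offset,
            enoxaparin_mixture_spec,
            simulate_enoxaparin,
        )

        truth = replace(truth, peak_sigma=0.05)
        spec = enoxaparin_mixture_spec(group_offsets=truth.group_offsets)
        sim = simulate_enoxaparin(spec, truth, noiseless=True)
        model = truth.truth_model(offset=effective_composition_offset())
        d = chromatogram_to_distribution(
            sim.chromatogram, model, window=AnalysisWindow(12.5, 19.8)
        )
        got = compute_distribution_fractions(d)
        for g, t in zip(got, sim.true_fractions):
            assert g == pytest.approx(t, abs=1.0)


class TestMonograph:
    def make_result(self, mw=4500.0, fr=(16.0, 74.0, 10.0)):
        return MwResult(mw=mw, m2000=fr[0], m2000_8000=fr[1], m8000=fr[2])

    def test_reference_standard_bounds(self):
        ok = check_monograph(self.make_result(), rs_mw=4450.0)
        assert ok.criteria[0].passed  # 4450 within 4370 +/- 150
        bad = check_monograph(self.make_result(), rs_mw=3250.0)
        assert not bad.criteria[0].passed
        assert not bad.passed

    def test_sample_mw_closed_interval(self):
        assert check_monograph(self.make_result(mw=3800.0)).criteria[0].passed
        assert not check_monograph(self.make_result(mw=3799.9)).criteria[0].passed
        assert check_monograph(self.make_result(mw=5000.0)).criteria[0].passed

    def test_distribution_limits(self):
        r = self.make_result(fr=(11.0, 70.0, 19.0))
        chk = check_monograph(r)
        names_failed = [c.name for c in chk.criteria if not c.passed]
        assert any("M2000 " in n for n in names_failed)
        assert any("M8000" in n for n in names_failed)

    def test_rounding_convention(self):
        assert round_to_50(4374.0) == 4350.0
        assert round_to_50(4376.0) == 4400.0
        r = self.make_result(mw=4374.0)
        assert r.mw_rounded_50 == 4350.0
        assert analyze_distribution(
            SliceDistribution(m=np.array([4370.0]), n=np.array([1.0]))
        ).mw == pytest.approx(4370.0)
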