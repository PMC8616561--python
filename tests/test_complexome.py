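"""Profile smoothing, sigmoidal mass calibration, and peak reporting."""

import math

import numpy as np
import pandas as pd
import pytest

from ncx.complexome import (
    ProfileSmoother,
    SliceMassCalibrator,
    detect_peak,
    fit_calibration,
    mass_to_slice,
    oligomer_mass,
    slice_to_mass,
    smooth_profile,
)
from ncx.io import ProteinRecord
from ncx.masses import protein_average_mass
from ncx.simulate import _true_logmass


class TestSmoothing:
    def test_impulse_center_value(self):
        out = smooth_profile([0, 0, 1, 0, 0], window=5)
        assert out[2] == pytest.approx(0.2)

    def test_constant_profile_unchanged(self):
        out = smooth_profile([3.0] * 10, window=5)
        assert np.allclose(out, 3.0)

    def test_window_one_is_identity(self):
        v = [1.0, 5.0, 2.0]
        assert np.allclose(smooth_profile(v, window=1), v)

    def test_edges_truncate_and_preserve_length(self):
        out = smooth_profile([1, 0, 0, 0, 0], window=5)
        assert out.size == 5
        assert out[0] == pytest.approx(1 / 3)  # window truncated to 3 slices

    def test_contraction_bounds(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0, 100, 50)
        out = smooth_profile(v, window=7)
        assert out.max() <= v.max() + 1e-12
        assert out.min() >= v.min() - 1e-12

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_profile([1, 2, 3], window=4)
        with pytest.raises(ValueError):
            smooth_profile([1, 2, 3], window=5)

    def test_matrix_transformer(self):
        m = pd.DataFrame([[0, 0, 1, 0, 0], [2, 2, 2, 2, 2]],
                         index=["A", "B"], columns=[f"slice_{i:04d}" for i in range(1, 6)])
        out = ProfileSmoother(window=5).transform(m)
        assert out.loc["A"].iloc[2] == pytest.approx(0.2)
        assert np.allclose(out.loc["B"], 2.0)


CURVE = (3.8, 1.4, 80.0, 40.0)


def markers_on_curve(n=8, lo=2.2, hi=3.5):
    logm = np.linspace(hi, lo, n)
    slices = 80.0 + 40.0 * np.log((CURVE[0] - CURVE[1]) / (logm - CURVE[1]) - 1.0)
    return slices, 10.0 ** logm


class TestCalibration:
    def test_noiseless_parameter_recovery(self):
        slices, masses = markers_on_curve()
        model = fit_calibration(zip(slices, masses))
        for got, true in zip((model.a, model.d, model.s0, model.b), CURVE):
            assert got == pytest.approx(true, rel=1e-4)
        assert model.fit_residual_mad < 1e-8

    def test_fewer_than_four_markers_rejected(self):
        slices, masses = markers_on_curve(n=3)
        with pytest.raises(ValueError, match=">= 4"):
            fit_calibration(zip(slices, masses))

    def test_non_monotone_markers_named(self):
        with pytest.raises(ValueError, match="not strictly decreasing"):
            fit_calibration([(10, 3000.0), (20, 1000.0), (30, 2000.0), (40, 100.0)])

    def test_span_under_one_decade_rejected(self):
        with pytest.raises(ValueError, match="decade"):
            fit_calibration([(10, 1000.0), (20, 800.0), (30, 600.0), (40, 500.0)])

    def test_round_trip_markers_within_mad_band(self):
        """Under homoscedastic calibration noise, every marker's predicted
        mass agrees with its known mass within 3x the robust residual
        scale of the fit (log10 units)."""
        rng = np.random.default_rng(5)
        slices, masses = markers_on_curve(n=12)
        noisy = 10.0 ** (np.log10(masses) + rng.normal(0, 0.01, masses.size))
        model = fit_calibration(zip(slices, noisy))
        for s, mass in zip(slices, noisy):
            err = abs(math.log10(slice_to_mass(s, model)) - math.log10(mass))
            assert err <= max(3 * model.fit_residual_mad, 1e-6)

    def test_noisy_markers_predicted_within_ten_percent(self, bn_calibrated):
        bundle, truth, smoothed, calib = bn_calibrated
        for pid, mass in bundle.markers.itertuples(index=False):
            s = int(np.argmax(smoothed.loc[pid].to_numpy())) + 1
            pred = slice_to_mass(s, calib.model_)
            assert pred == pytest.approx(mass, rel=0.10)


@pytest.fixture(scope="module")
def model():
    slices, masses = markers_on_curve()
    return fit_calibration(zip(slices, masses))


class TestSliceMass:
    def test_midpoint_identity(self, model):
        mid = slice_to_mass(model.s0, model)
        assert math.log10(mid) == pytest.approx((model.a + model.d) / 2, abs=1e-9)

    def test_strictly_decreasing(self, model):
        lo, hi = model.valid_slice_range
        grid = np.linspace(lo, hi, 100)
        masses = np.array([slice_to_mass(s, model) for s in grid])
        assert np.all(np.diff(masses) < 0)

    def test_inverse_consistency(self, model):
        for mass in [200.0, 700.0, 1400.0, 2500.0]:
            s = mass_to_slice(mass, model)
            assert slice_to_mass(s, model) == pytest.approx(mass, rel=1e-6)

    def test_extrapolation_warns(self, model):
        with pytest.warns(UserWarning, match="extrapolating"):
            slice_to_mass(model.valid_slice_range[1] + 50, model)

    def test_mass_outside_asymptotes_rejected(self, model):
        with pytest.raises(ValueError):
            mass_to_slice(10.0 ** (model.a + 1), model)


class TestDetectPeak:
    def test_gaussian_peak_located(self, model):
        slices = np.arange(1, 121)
        v = np.exp(-0.5 * ((slices - 40) / 4) ** 2)
        rep = detect_peak(v, model, protein_id="X")
        assert rep.peak_slice == 40
        assert not rep.no_peak
        low, high = rep.mass_range_kda
        assert low < rep.apparent_mass_kda < high

    def test_all_zero_profile_flagged(self, model):
        rep = detect_peak(np.zeros(100), model)
        assert rep.no_peak and rep.peak_slice is None
        assert math.isnan(rep.apparent_mass_kda)

    def test_equal_maxima_ties_to_smaller_slice_with_warning(self, model):
        v = np.zeros(120)
        v[30] = v[70] = 5.0
        with pytest.warns(UserWarning, match="multiple equal maxima"):
            rep = detect_peak(v, model)
        assert rep.peak_slice == 31
        assert rep.multi_peak

    def test_half_maximum_range(self, model):
        v = np.zeros(120)
        v[49] = 2.5   # 50% of peak -> included
        v[50] = 5.0
        v[51] = 2.4   # below half maximum -> excluded
        rep = detect_peak(v, model)
        assert rep.peak_slice == 51
        assert rep.mass_range_kda[1] == pytest.approx(slice_to_mass(50, model))
        assert rep.mass_range_kda[0] == pytest.approx(slice_to_mass(51, model))

    def test_planted_complex_recovered_within_fifteen_percent(self, bn_calibrated):
        bundle, truth, smoothed, calib = bn_calibrated
        rep = detect_peak(smoothed.loc["BAIT_COMPLEX"], calib.model_)
        assert rep.apparent_mass_kda == pytest.approx(1400.0, rel=0.15)

    def test_end_to_end_recovery_over_seeds(self):
        """Median absolute relative error of the recovered complex mass
        over 50 seeded simulations stays below 10%."""
        from ncx.simulate import paper_like_complexome_config, simulate_complexome

        errors = []
        for seed in range(50):
            bundle, _ = simulate_complexome(paper_like_complexome_config(seed=seed))
            smoothed = ProfileSmoother(window=5).transform(bundle.matrix)
            slices = [int(np.argmax(smoothed.loc[p].to_numpy())) + 1
                      for p in bundle.markers["protein_id"]]
            calib = SliceMassCalibrator().fit(
                slices, bundle.markers["mass_kda"].to_numpy()
            )
            rep = detect_peak(smoothed.loc["BAIT_COMPLEX"], calib.model_)
            errors.append(abs(rep.apparent_mass_kda - 1400.0) / 1400.0)
        assert np.median(errors) < 0.10


class TestOligomerMass:
    REC = ProteinRecord("P1", "MKWVTFISLLLLFSSAYSRGV")

    def test_monomer_identity(self):
        assert oligomer_mass(self.REC, 1) == pytest.approx(
            protein_average_mass(self.REC.sequence)
        )

    def test_linearity(self):
        assert oligomer_mass(self.REC, 4) == pytest.approx(4 * oligomer_mass(self.REC, 1))

    def test_invalid_subunit_count(self):
        with pytest.raises(ValueError):
            oligomer_mass(self.REC, 0)
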