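"""m/z recalibration, LOESS warping, reference times, and PV assignment."""

import warnings

import numpy as np
import pandas as pd
import pytest

from ncx.align import (
    InsufficientAnchorsError,
    LoessWarp,
    MatchTolerances,
    align_study,
    apply_warp,
    assign_pvs,
    build_library,
    compute_reference_times,
    estimate_mz_offset,
    fit_warp,
    recalibrate_mz,
)
from ncx.io import RunMeta, RunTable, StudyBundle
from ncx.simulate import ApSimConfig, simulate_apms_study


def synthetic_run(n=100, offset_ppm=0.0, seed=0, run_id="R1"):
    rng = np.random.default_rng(seed)
    mz = rng.uniform(300, 1500, n)
    rt = np.sort(rng.uniform(0, 100, n))
    f = pd.DataFrame(
        {
            "protein_id": ["P1"] * n,
            "peptide_seq": [f"{'ACDEFGHILMNQSTVWY'[i % 17] * 6}K" + "AILK"[i % 4] * (i // 17 + 1)
                             for i in range(n)],
            "charge": [2] * n,
            "mz_theoretical": mz,
            "mz_observed": mz * (1 + offset_ppm * 1e-6),
            "rt": rt,
            "pv": rng.uniform(1e4, 1e6, n),
        }
    )
    return RunTable(RunMeta(run_id, "ab1", "target_ap", "CL-47"), f)


class TestMzOffset:
    def test_constant_shift_recovered_exactly(self):
        run = synthetic_run(offset_ppm=3.0)
        assert estimate_mz_offset(run) == pytest.approx(3.0, abs=1e-9)

    def test_symmetric_split_population_gives_zero(self):
        run = synthetic_run(n=100)
        f = run.features.copy()
        sign = np.where(np.arange(len(f)) % 2 == 0, 1.0, -1.0)
        f["mz_observed"] = f["mz_theoretical"] * (1 + sign * 2e-6)
        run = run.with_features(f)
        assert estimate_mz_offset(run) == pytest.approx(0.0, abs=1e-9)

    def test_too_few_matches_raises(self):
        run = synthetic_run(n=5)
        with pytest.raises(InsufficientAnchorsError):
            estimate_mz_offset(run)

    def test_simulated_offset_recovered_within_tolerance(self):
        cfg = ApSimConfig(
            n_background_proteins=60, n_antibodies_target=2, n_tuc_controls=2,
            include_ko_controls=False, mz_noise_ppm=0.5, seed=3,
        )
        bundle, truth = simulate_apms_study(cfg)
        for run in bundle.runs[:4]:
            est = estimate_mz_offset(run)
            assert est == pytest.approx(truth.run_mz_offset_ppm[run.meta.run_id], abs=0.3)

    def test_recalibration_inverts_offset(self):
        run = synthetic_run(offset_ppm=7.0)
        fixed = recalibrate_mz(run, 7.0)
        assert estimate_mz_offset(fixed) == pytest.approx(0.0, abs=1e-6)
        # identity at zero offset
        same = recalibrate_mz(run, 0.0)
        pd.testing.assert_frame_equal(same.features, run.features)


class TestReferenceTimes:
    def _runs(self, rts):
        runs = []
        for i, rt in enumerate(rts):
            f = pd.DataFrame(
                {
                    "protein_id": ["P1"],
                    "peptide_seq": ["PEPTIDEK"],
                    "charge": [2],
                    "mz_theoretical": [450.0],
                    "mz_observed": [450.0],
                    "rt": [rt],
                    "pv": [1e5],
                }
            )
            runs.append(RunTable(RunMeta(f"R{i}", "ab", "target_ap", "CL-47"), f))
        return runs

    def test_median_across_runs(self):
        ref = compute_reference_times(self._runs([10.0, 10.2, 10.4]))
        assert ref.loc[("PEPTIDEK", 2)] == pytest.approx(10.2)

    def test_invariant_to_run_order(self):
        runs = self._runs([12.0, 10.0, 11.0])
        ref1 = compute_reference_times(runs)
        ref2 = compute_reference_times(runs[::-1])
        pd.testing.assert_series_equal(ref1, ref2)

    def test_single_observation_is_own_rt(self):
        runs = self._runs([10.0, 10.4])
        extra = runs[0].features.copy()
        extra["peptide_seq"] = "ONLYONCEK"
        extra["rt"] = 42.0
        runs[0] = runs[0].with_features(pd.concat([runs[0].features, extra]))
        ref = compute_reference_times(runs)
        assert ref.loc[("ONLYONCEK", 2)] == pytest.approx(42.0)


class TestWarp:
    def test_identity_anchors_give_identity_warp(self):
        t = np.linspace(0, 100, 200)
        w = LoessWarp().fit(t, t)
        grid = np.linspace(0, 100, 50)
        assert np.max(np.abs(w.predict(grid) - grid)) < 0.01

    def test_constant_shift_recovered(self):
        t = np.linspace(0, 100, 300)
        w = LoessWarp().fit(t, t + 0.5)
        grid = np.linspace(20, 80, 50)
        assert np.max(np.abs(w.predict(grid) - (grid + 0.5))) < 0.02

    def test_monotone_after_isotonic_repair(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 100, 200))
        y = t + rng.normal(0, 3.0, 200)  # heavy noise can break raw LOESS
        w = LoessWarp(span=0.1).fit(t, y)
        assert np.all(np.diff(w.warped_times_) >= 0)
        grid = np.linspace(-5, 105, 300)
        assert np.all(np.diff(w.predict(grid)) >= -1e-12)

    def test_cubic_drift_recovered_with_outliers(self):
        """Monotone cubic drift (2 min amplitude), 500 anchors, 5% outliers:
        post-warp residual MAD < 0.1 min."""
        rng = np.random.default_rng(1)
        t = np.sort(rng.uniform(0, 100, 500))
        drift = 2.0 * np.sin(t / 100 * np.pi)  # smooth, bounded by 2 min
        observed = t + drift + rng.normal(0, 0.03, t.size)
        out = rng.random(t.size) < 0.05
        observed[out] += rng.uniform(-5, 5, out.sum())
        w = LoessWarp(span=0.3, iterations=2).fit(observed, t)
        resid = w.predict(observed[~out]) - t[~out]
        mad = np.median(np.abs(resid - np.median(resid)))
        assert mad < 0.1

    def test_degenerate_constant_rts_rejected(self):
        with pytest.raises(ValueError):
            LoessWarp().fit(np.ones(50), np.linspace(0, 1, 50))

    def test_fit_warp_needs_anchors(self):
        run = synthetic_run(n=10)
        ref = compute_reference_times([synthetic_run(n=10), synthetic_run(n=10, seed=1)])
        with pytest.raises(InsufficientAnchorsError):
            fit_warp(run, ref, min_anchors=30)


class TestAlignStudy:
    def test_single_run_unchanged_with_warning(self):
        bundle = StudyBundle(runs=[synthetic_run()])
        with pytest.warns(UserWarning, match="single-run"):
            aligned, diag = align_study(bundle)
        assert aligned.runs[0] is bundle.runs[0]
        assert len(diag) == 0

    def test_two_identical_runs_identity_warps(self):
        r1 = synthetic_run(seed=4, run_id="A")
        r2 = synthetic_run(seed=4, run_id="B")
        bundle = StudyBundle(runs=[r1, r2])
        aligned, diag = align_study(bundle, recalibrate=False, rounds=1)
        for orig, al in zip(bundle.runs, aligned.runs):
            assert np.max(np.abs(al.features["rt"] - orig.features["rt"])) < 1e-6

    def test_residual_mad_non_increasing_over_rounds(self, mini_result):
        res, _ = mini_result
        diag = res.align_diagnostics
        mad = diag[diag["round"] > 0].groupby("round")["residual_mad"].median()
        assert mad.iloc[-1] <= mad.iloc[0] + 1e-9

    def test_alignment_brings_runs_onto_common_time_base(self, mini_result):
        """After alignment, per-peptide RT spread across runs is small even
        though simulated drifts reach 2 min."""
        res, truth = mini_result
        rows = []
        for run in res.aligned.runs:
            g = run.features.groupby(["peptide_seq", "charge"])["rt"].median()
            rows.append(g)
        wide = pd.concat(rows, axis=1)
        spread = (wide.max(axis=1) - wide.min(axis=1)).dropna()
        shared = wide.notna().sum(axis=1) >= len(res.aligned.runs) // 2
        assert spread[shared].median() < 0.3


class TestAssignment:
    LIB = pd.DataFrame(
        {
            "peptide_seq": ["AAAAK", "CCCCK"],
            "charge": [2, 2],
            "mz_theoretical": [500.0, 500.0012],
            "ref_rt": [50.0, 50.0],
            "protein_id": ["P1", "P2"],
        }
    )

    def _run_with(self, mz, rt, pv=1e5):
        f = pd.DataFrame(
            {
                "protein_id": ["X"],
                "peptide_seq": ["UNKNOWNK"],
                "charge": [2],
                "mz_theoretical": [mz],
                "mz_observed": [mz],
                "rt": [rt],
                "pv": [pv],
            }
        )
        return RunTable(RunMeta("R", "ab", "target_ap", "CL-47"), f)

    def test_inside_window_assigned(self):
        run = self._run_with(500.0 * (1 + 2.9e-6), 50.5)
        assigned, n_un = assign_pvs(run, self.LIB.iloc[[0]])
        assert n_un == 0 and len(assigned) == 1
        assert assigned.features["peptide_seq"].iloc[0] == "AAAAK"

    def test_outside_ppm_window_unassigned(self):
        run = self._run_with(500.0 * (1 + 4e-6), 50.0)
        assigned, n_un = assign_pvs(run, self.LIB.iloc[[0]])
        assert n_un == 1 and len(assigned) == 0

    def test_outside_rt_window_unassigned(self):
        run = self._run_with(500.0, 51.5)
        assigned, n_un = assign_pvs(run, self.LIB.iloc[[0]])
        assert n_un == 1 and len(assigned) == 0

    def test_tie_breaks_ppm_then_rt_then_lexicographic(self):
        # closer in ppm to CCCCK (mz 500.0012) than AAAAK
        run = self._run_with(500.0012, 50.2)
        assigned, _ = assign_pvs(run, self.LIB)
        assert assigned.features["peptide_seq"].iloc[0] == "CCCCK"
        # exact ppm tie, then RT tie: lexicographically smaller peptide wins
        lib = self.LIB.copy()
        lib["mz_theoretical"] = 500.0
        lib["ref_rt"] = [50.0, 50.0]
        run = self._run_with(500.0, 50.0)
        assigned, _ = assign_pvs(run, lib)
        assert assigned.features["peptide_seq"].iloc[0] == "AAAAK"

    def test_pv_conservation_and_summing(self):
        f = pd.DataFrame(
            {
                "protein_id": ["X", "X", "X"],
                "peptide_seq": ["U1K", "U2K", "U3K"],
                "charge": [2, 2, 2],
                "mz_theoretical": [500.0, 500.0, 900.0],
                "mz_observed": [500.0, 500.0000005, 900.0],
                "rt": [50.0, 50.1, 10.0],
                "pv": [100.0, 200.0, 300.0],
            }
        )
        run = RunTable(RunMeta("R", "ab", "target_ap", "CL-47"), f)
        assigned, n_un = assign_pvs(run, self.LIB)
        assert n_un == 1  # the 900 Th feature has no library match
        assert assigned.features["pv"].sum() <= f["pv"].sum()
        assert assigned.features["pv"].iloc[0] == pytest.approx(300.0)  # summed

    def test_simulated_assignment_mostly_correct(self, mini_result):
        """>= 95% of features keep their true identity after m/z + RT
        matching at default tolerances."""
        res, truth = mini_result
        total, correct = 0, 0
        for orig, assigned in zip(res.aligned.runs, res.assigned.runs):
            true_map = orig.features.set_index(["peptide_seq", "charge"])["protein_id"]
            got = assigned.features.set_index(["peptide_seq", "charge"])["protein_id"]
            shared = got.index.intersection(true_map.index)
            correct += int((got.loc[shared] == true_map.loc[shared]).sum())
            total += len(got)
        assert total > 0
        assert correct / total >= 0.95


def test_tolerance_validation():
    with pytest.raises(ValueError):
        MatchTolerances(ppm_window=60.0, wide_ppm_window=50.0)
    with pytest.raises(ValueError):
        MatchTolerances(rt_window=-1.0)
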