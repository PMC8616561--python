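"""MS1 matching stage: m/z recalibration, LOESS retention-time alignment
against a dynamically computed reference, and tolerance-based peak-volume
assignment.

The stage mirrors standard label-free MS1 workflows: each run's observed
m/z values are first corrected by the median ppm offset of peptides matched
within a wide (50 ppm) window; elution times are then pairwise aligned to a
reference by robust local regression (reference times recomputed from median
peptide elution times over the aligned runs); finally peak volumes are
assigned to identified peptides within +/-1 min and 2-3 ppm.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.isotonic import IsotonicRegression
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess

from .io import RunTable, StudyBundle

logger = logging.getLogger("ncx")

__all__ = [
    "MatchTolerances",
    "WarpModel",
    "LoessWarp",
    "InsufficientAnchorsError",
    "estimate_mz_offset",
    "recalibrate_mz",
    "build_library",
    "compute_reference_times",
    "fit_warp",
    "apply_warp",
    "align_study",
    "assign_pvs",
]


class InsufficientAnchorsError(RuntimeError):
    """Too few matched peptides to estimate an offset or warp."""


@dataclass(frozen=True)
class MatchTolerances:
    """Matching windows for PV assignment and offset estimation.

    rt_window (min) and ppm_window follow the +/-1 min / 2-3 ppm assignment
    rule (3 ppm default); wide_ppm_window is the preliminary 50 ppm window
    used only for the m/z offset estimate.
    """

    rt_window: float = 1.0
    ppm_window: float = 3.0
    wide_ppm_window: float = 50.0

    def __post_init__(self) -> None:
        if min(self.rt_window, self.ppm_window, self.wide_ppm_window) <= 0:
            raise ValueError("all tolerance windows must be positive")
        if self.ppm_window > self.wide_ppm_window:
            raise ValueError("ppm_window must be <= wide_ppm_window")


def _ppm(observed: np.ndarray, theoretical: np.ndarray) -> np.ndarray:
    return (observed - theoretical) / theoretical * 1e6


def build_library(runs: list[RunTable]) -> pd.DataFrame:
    """Identified-peptide library across runs.

    One row per (peptide_seq, charge): theoretical m/z, the protein it maps
    to, and (after alignment) the reference RT. Peptides whose sequence maps
    to more than one protein are flagged non-specific.
    """
    frames = [r.features for r in runs if len(r.features)]
    if not frames:
        return pd.DataFrame(
            columns=["peptide_seq", "charge", "mz_theoretical", "protein_id", "specific"]
        )
    allf = pd.concat(frames, ignore_index=True)
    lib = (
        allf.groupby(["peptide_seq", "charge"], sort=True)
        .agg(
            mz_theoretical=("mz_theoretical", "median"),
            protein_id=("protein_id", "first"),
            n_proteins=("protein_id", "nunique"),
        )
        .reset_index()
    )
    lib["specific"] = lib["n_proteins"] == 1
    return lib.drop(columns="n_proteins")


def estimate_mz_offset(
    run: RunTable,
    library: pd.DataFrame | None = None,
    wide_ppm_window: float = 50.0,
    min_matches: int = 20,
) -> float:
    """Median ppm offset of a run's observed m/z against theoretical m/z.

    Matches features to library peptides by (peptide_seq, charge) within the
    wide ppm window and returns the median of
    (observed - theoretical) / theoretical * 1e6.
    """
    f = run.features
    if library is not None:
        key = pd.MultiIndex.from_frame(f[["peptide_seq", "charge"]])
        libkey = pd.MultiIndex.from_frame(library[["peptide_seq", "charge"]])
        theo = pd.Series(
            library["mz_theoretical"].values, index=libkey
        )
        theo = theo[~theo.index.duplicated()]
        matched_theo = key.map(theo)
        mask = ~pd.isna(matched_theo)
        obs = f["mz_observed"].values[mask]
        th = np.asarray(matched_theo[mask], dtype=float)
    else:
        obs = f["mz_observed"].values
        th = f["mz_theoretical"].values
    ppm = _ppm(obs, th)
    ppm = ppm[np.abs(ppm) <= wide_ppm_window]
    if ppm.size < min_matches:
        raise InsufficientAnchorsError(
            f"run {run.meta.run_id}: only {ppm.size} wide-window matches "
            f"(need >= {min_matches}) for m/z offset estimation"
        )
    return float(np.median(ppm))


def recalibrate_mz(run: RunTable, offset_ppm: float) -> RunTable:
    """Remove a constant ppm offset from a run's observed m/z values."""
    if not np.isfinite(offset_ppm):
        raise ValueError("offset_ppm must be finite")
    f = run.features.copy()
    f["mz_observed"] = f["mz_observed"] / (1.0 + offset_ppm * 1e-6)
    return run.with_features(f)


def compute_reference_times(runs: list[RunTable]) -> pd.Series:
    """Reference RT per (peptide_seq, charge): median over runs observed.

    Within a run a peptide's RT is first collapsed to its median, so a run
    contributes one vote per peptide.
    """
    if len(runs) < 2:
        raise ValueError("need >= 2 runs to compute reference times")
    per_run = []
    for r in runs:
        if len(r.features):
            per_run.append(
                r.features.groupby(["peptide_seq", "charge"], sort=True)["rt"].median()
            )
    if not per_run:
        warnings.warn("no features in any run; empty reference", stacklevel=2)
        return pd.Series(dtype=float)
    ref = pd.concat(per_run).groupby(level=[0, 1]).median()
    return ref


class LoessWarp(RegressorMixin, BaseEstimator):
    """Monotone RT warp: robust LOESS followed by isotonic repair.

    Fits a locally weighted regression of reference RT on run RT
    (tricube weights, ``iterations`` robustifying passes) and repairs the
    fitted curve to be non-decreasing with isotonic regression, preserving
    elution order. Prediction interpolates linearly between anchors and
    extends with unit slope beyond them.

    Attributes (after fit): ``anchor_times_``, ``warped_times_``,
    ``residual_mad_`` (minutes).
    """

    def __init__(self, span: float = 0.3, iterations: int = 2):
        self.span = span
        self.iterations = iterations

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.size != y.size or x.size < 2:
            raise ValueError("need >= 2 anchor pairs of equal length")
        if np.ptp(x) <= 0:
            raise ValueError("degenerate anchors: constant run RTs")
        order = np.argsort(x, kind="stable")
        x, y = x[order], y[order]
        fitted = _lowess(
            y, x, frac=self.span, it=self.iterations, return_sorted=False
        )
        if np.any(~np.isfinite(fitted)):  # pathological spans
            fitted = np.where(np.isfinite(fitted), fitted, y)
        iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
        fitted = iso.fit_transform(x, fitted)
        self.anchor_times_ = x
        self.warped_times_ = np.asarray(fitted, dtype=float)
        resid = y - self.warped_times_
        self.residual_mad_ = float(np.median(np.abs(resid - np.median(resid))))
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).ravel()
        xa, ya = self.anchor_times_, self.warped_times_
        out = np.interp(t, xa, ya)
        below = t < xa[0]
        above = t > xa[-1]
        out[below] = ya[0] + (t[below] - xa[0])
        out[above] = ya[-1] + (t[above] - xa[-1])
        return out


@dataclass
class WarpModel:
    """A fitted run -> reference RT warp with its anchor diagnostics."""

    warp: LoessWarp
    n_anchors: int
    residual_mad: float

    @property
    def anchor_times(self) -> np.ndarray:
        return self.warp.anchor_times_

    @property
    def warped_times(self) -> np.ndarray:
        return self.warp.warped_times_

    def __call__(self, t):
        return self.warp.predict(t)


def fit_warp(
    run: RunTable,
    reference: pd.Series,
    span: float = 0.3,
    iterations: int = 2,
    min_anchors: int = 30,
) -> WarpModel:
    """Fit the run's RT warp onto the reference time base."""
    if len(reference) == 0:
        raise InsufficientAnchorsError(f"run {run.meta.run_id}: empty reference")
    per_pep = run.features.groupby(["peptide_seq", "charge"], sort=True)["rt"].median()
    shared = per_pep.index.intersection(reference.index)
    if len(shared) < min_anchors:
        raise InsufficientAnchorsError(
            f"run {run.meta.run_id}: {len(shared)} anchors (need >= {min_anchors})"
        )
    x = per_pep.loc[shared].values
    y = reference.loc[shared].values
    warp = LoessWarp(span=span, iterations=iterations).fit(x, y)
    return WarpModel(warp=warp, n_anchors=len(shared), residual_mad=warp.residual_mad_)


def apply_warp(run: RunTable, warp: WarpModel | LoessWarp) -> RunTable:
    f = run.features.copy()
    predict = warp.predict if isinstance(warp, LoessWarp) else warp
    f["rt"] = np.maximum(np.asarray(predict(f["rt"].values), dtype=float), 0.0)
    return run.with_features(f)


def align_study(
    bundle: StudyBundle,
    tolerances: MatchTolerances | None = None,
    span: float = 0.3,
    iterations: int = 2,
    rounds: int = 2,
    min_anchors: int = 30,
    recalibrate: bool = True,
) -> tuple[StudyBundle, pd.DataFrame]:
    """Recalibrate m/z and align all runs onto a common time base.

    Performs ``rounds`` alternations of {compute reference times -> fit one
    LOESS warp per run -> apply}. Returns the aligned bundle and a
    diagnostics frame (run_id, round, n_anchors, residual_mad, offset_ppm).
    """
    tolerances = tolerances or MatchTolerances()
    if len(bundle.runs) < 2:
        warnings.warn("single-run bundle: nothing to align", stacklevel=2)
        return bundle, pd.DataFrame(
            columns=["run_id", "round", "n_anchors", "residual_mad", "offset_ppm"]
        )

    records = []
    runs = list(bundle.runs)
    if recalibrate:
        library = build_library(runs)
        new_runs = []
        for run in runs:
            offset = estimate_mz_offset(
                run, library, wide_ppm_window=tolerances.wide_ppm_window
            )
            new_runs.append(recalibrate_mz(run, offset))
            records.append(
                {"run_id": run.meta.run_id, "round": 0, "n_anchors": len(run),
                 "residual_mad": np.nan, "offset_ppm": offset}
            )
        runs = new_runs

    for rnd in range(1, rounds + 1):
        reference = compute_reference_times(runs)
        new_runs = []
        for run in runs:
            try:
                model = fit_warp(
                    run, reference, span=span, iterations=iterations,
                    min_anchors=min_anchors,
                )
            except InsufficientAnchorsError as err:
                raise InsufficientAnchorsError(
                    f"alignment round {rnd}: {err}"
                ) from err
            new_runs.append(apply_warp(run, model))
            records.append(
                {"run_id": run.meta.run_id, "round": rnd,
                 "n_anchors": model.n_anchors,
                 "residual_mad": model.residual_mad, "offset_ppm": 0.0}
            )
        runs = new_runs

    aligned = StudyBundle(
        runs=runs, proteins=bundle.proteins, ground_truth=bundle.ground_truth
    )
    return aligned, pd.DataFrame.from_records(records)


def assign_pvs(
    run: RunTable,
    library: pd.DataFrame,
    tolerances: MatchTolerances | None = None,
) -> tuple[RunTable, int]:
    """Assign a run's feature PVs to library peptides by m/z and RT.

    A feature is assigned to a library peptide iff |delta RT| <= rt_window
    and |delta ppm| <= ppm_window; each feature goes to at most one peptide
    (smallest |delta ppm|, ties by |delta RT|, then lexicographic peptide
    order). Matching features' PVs are summed per (peptide_seq, charge).
    The library must carry columns peptide_seq, charge, mz_theoretical,
    ref_rt, protein_id. Returns the assigned run plus the count of
    unassigned features.
    """
    tolerances = tolerances or MatchTolerances()
    need = {"peptide_seq", "charge", "mz_theoretical", "ref_rt", "protein_id"}
    if not need.issubset(library.columns):
        raise ValueError(f"library missing columns {sorted(need - set(library.columns))}")

    f = run.features
    if not len(f) or not len(library):
        empty = f.iloc[0:0]
        return run.with_features(empty), len(f)

    lib = library.sort_values("mz_theoretical", kind="stable").reset_index(drop=True)
    lib_mz = lib["mz_theoretical"].values
    lib_rt = lib["ref_rt"].values
    lib_pep = lib["peptide_seq"].values
    lib_charge = lib["charge"].values

    mz_obs = f["mz_observed"].values
    rt_obs = f["rt"].values
    half = lib_mz * (tolerances.ppm_window * 1e-6)
    lo = np.searchsorted(lib_mz + half, mz_obs, side="left")
    hi = np.searchsorted(lib_mz - half, mz_obs, side="right")

    assign_idx = np.full(len(f), -1, dtype=int)
    for i in range(len(f)):
        cand = np.arange(lo[i], hi[i])
        if cand.size == 0:
            continue
        d_rt = np.abs(rt_obs[i] - lib_rt[cand])
        cand = cand[d_rt <= tolerances.rt_window]
        if cand.size == 0:
            continue
        d_ppm = np.abs(_ppm(np.full(cand.size, mz_obs[i]), lib_mz[cand]))
        d_rt = np.abs(rt_obs[i] - lib_rt[cand])
        best = sorted(
            range(cand.size),
            key=lambda j: (round(d_ppm[j], 9), round(d_rt[j], 9),
                           lib_pep[cand[j]], lib_charge[cand[j]]),
        )[0]
        assign_idx[i] = cand[best]

    assigned = assign_idx >= 0
    n_unassigned = int((~assigned).sum())
    if not assigned.any():
        return run.with_features(f.iloc[0:0]), n_unassigned

    hits = pd.DataFrame(
        {
            "lib_idx": assign_idx[assigned],
            "pv": f["pv"].values[assigned],
            "mz_observed": f["mz_observed"].values[assigned],
        }
    )
    grouped = hits.groupby("lib_idx").agg(
        pv=("pv", "sum"), mz_observed=("mz_observed", "median")
    )
    out = lib.loc[grouped.index, ["protein_id", "peptide_seq", "charge",
                                  "mz_theoretical", "ref_rt"]].copy()
    out = out.rename(columns={"ref_rt": "rt"})
    out["mz_observed"] = grouped["mz_observed"].values
    out["pv"] = grouped["pv"].values
    out = out[["protein_id", "peptide_seq", "charge", "mz_theoretical",
               "mz_observed", "rt", "pv"]].reset_index(drop=True)
    return run.with_features(out), n_unassigned
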