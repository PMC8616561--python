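"""BN-gel complexome profiling: smoothing, marker-based slice-to-mass
calibration, peak detection, and oligomer-mass arithmetic.

Slice 1 is the gel top (largest mass); apparent log10 masses decrease
monotonically with slice number. Calibration fits a 4-parameter logistic
log10(mass) = d + (a - d) / (1 + exp((s - s0) / b)) through the observed
peak slices of marker complexes of known mass, after which any profile peak
can be reported as an apparent complex mass with a half-maximum mass range.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin

from .io import ProteinRecord
from .masses import protein_average_mass

logger = logging.getLogger("ncx")

__all__ = [
    "CalibrationModel",
    "PeakReport",
    "ProfileSmoother",
    "SliceMassCalibrator",
    "smooth_profile",
    "fit_calibration",
    "slice_to_mass",
    "mass_to_slice",
    "detect_peak",
    "oligomer_mass",
    "read_slice_matrix",
    "read_marker_table",
]


def _logistic(s, a, d, s0, b):
    return d + (a - d) / (1.0 + np.exp((s - s0) / b))


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted slice -> log10(mass kDa) logistic.

    a, d: top/bottom asymptotes of log10(mass); s0: inflection slice;
    b: slope scale (slices); fit_residual_mad: sigma-consistent robust
    residual scale (1.4826 x MAD) in log10 units; valid_slice_range:
    marker-supported slice interval.
    """

    a: float
    d: float
    s0: float
    b: float
    fit_residual_mad: float
    valid_slice_range: tuple[float, float]
    n_markers: int

    def log10_mass(self, s) -> np.ndarray:
        return _logistic(np.asarray(s, dtype=float), self.a, self.d, self.s0, self.b)


@dataclass
class PeakReport:
    """Apparent-mass report for one protein's slice profile."""

    protein_id: str
    peak_slice: int | None
    apparent_mass_kda: float
    mass_range_kda: tuple[float, float]  # (low, high) in kDa
    peak_pv: float
    no_peak: bool = False
    multi_peak: bool = False


def smooth_profile(values: np.ndarray | pd.Series, window: int = 5) -> np.ndarray:
    """Centered moving average with truncated windows at the edges.

    Window must be odd and no larger than the profile; length is preserved
    and non-negativity maintained. Window 1 is the identity.
    """
    v = np.asarray(values, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    if window > v.size:
        raise ValueError(f"window {window} exceeds profile length {v.size}")
    if window == 1:
        return v.copy()
    out = (
        pd.Series(v).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )
    return out


class ProfileSmoother(TransformerMixin, BaseEstimator):
    """Sliding-average transformer over a protein x slice matrix."""

    def __init__(self, window: int = 5):
        self.window = window

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(
                np.vstack([smooth_profile(row, self.window) for _, row in X.iterrows()]),
                index=X.index,
                columns=X.columns,
            )
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.vstack([smooth_profile(row, self.window) for row in X])


class SliceMassCalibrator(RegressorMixin, BaseEstimator):
    """Sigmoidal slice -> mass calibration fitted on marker complexes.

    ``fit(peak_slices, masses_kda)`` least-squares fits the 4-parameter
    logistic of log10(mass) versus slice; ``predict(slices)`` returns masses
    in kDa and ``inverse(mass)`` the implied (real-valued) slice.
    Requires >= 4 markers spanning >= 1 decade whose masses decrease with
    slice number.
    """

    def __init__(self, check_monotone: bool = True):
        self.check_monotone = check_monotone

    def fit(self, X, y):
        s = np.asarray(X, dtype=float).ravel()
        m = np.asarray(y, dtype=float).ravel()
        if s.size != m.size:
            raise ValueError("slices and masses must have equal length")
        if s.size < 4:
            raise ValueError(f"need >= 4 markers, got {s.size}")
        if np.any(m <= 0):
            raise ValueError("marker masses must be positive")
        logm = np.log10(m)
        if logm.max() - logm.min() < 1.0:
            raise ValueError("markers must span >= 1 decade of mass")
        order = np.argsort(s, kind="stable")
        s, m, logm = s[order], m[order], logm[order]
        if self.check_monotone:
            bad = np.where(np.diff(logm) >= 0)[0]
            if bad.size:
                pairs = [(float(s[i]), float(s[i + 1])) for i in bad]
                raise ValueError(
                    f"marker masses not strictly decreasing with slice at {pairs}"
                )

        span = s.max() - s.min()
        p0 = (logm.max() + 0.2, logm.min() - 0.2, float(np.median(s)), span / 4.0)
        bounds = (
            [logm.max() - 0.5, logm.min() - 3.0, s.min() - 2 * span, 1e-3],
            [logm.max() + 3.0, logm.min() + 0.5, s.max() + 2 * span, 10 * span],
        )
        try:
            popt, _ = curve_fit(
                _logistic, s, logm, p0=p0, bounds=bounds, maxfev=20000
            )
        except RuntimeError as err:
            raise RuntimeError(
                f"calibration fit failed to converge on {s.size} markers: {err}"
            ) from err
        a, d, s0, b = (float(v) for v in popt)
        resid = logm - _logistic(s, a, d, s0, b)
        # sigma-consistent robust residual scale (1.4826 x MAD)
        mad = float(1.4826 * np.median(np.abs(resid - np.median(resid))))
        model = CalibrationModel(
            a=a, d=d, s0=s0, b=b, fit_residual_mad=mad,
            valid_slice_range=(float(s.min()), float(s.max())), n_markers=int(s.size),
        )
        grid = np.linspace(model.valid_slice_range[0], model.valid_slice_range[1], 256)
        if np.any(np.diff(model.log10_mass(grid)) >= 0):
            raise RuntimeError("fitted calibration is not strictly decreasing")
        self.model_ = model
        return self

    def predict(self, X):
        return 10.0 ** self.model_.log10_mass(X)

    def inverse(self, mass_kda):
        return mass_to_slice(np.asarray(mass_kda, dtype=float), self.model_)


def fit_calibration(markers) -> CalibrationModel:
    """Fit the calibration from (peak_slice, known mass kDa) marker pairs."""
    arr = np.asarray(list(markers), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("markers must be (peak_slice, mass_kda) pairs")
    return SliceMassCalibrator().fit(arr[:, 0], arr[:, 1]).model_


def slice_to_mass(s, model: CalibrationModel):
    """Apparent mass in kDa at a (real-valued) slice index."""
    s_arr = np.asarray(s, dtype=float)
    lo, hi = model.valid_slice_range
    if np.any(s_arr < lo) or np.any(s_arr > hi):
        warnings.warn(
            f"slice outside calibrated range [{lo:.1f}, {hi:.1f}]; extrapolating",
            stacklevel=2,
        )
    out = 10.0 ** model.log10_mass(s_arr)
    return float(out) if np.isscalar(s) or out.ndim == 0 else out


def mass_to_slice(mass_kda, model: CalibrationModel):
    """Inverse calibration: the slice at which a mass would migrate."""
    y = np.log10(np.asarray(mass_kda, dtype=float))
    lo, hi = sorted((model.a, model.d))
    if np.any(y <= lo) or np.any(y >= hi):
        raise ValueError(
            f"mass outside calibration asymptotes (10^{lo:.2f}, 10^{hi:.2f}) kDa"
        )
    out = model.s0 + model.b * np.log((model.a - model.d) / (y - model.d) - 1.0)
    return float(out) if np.ndim(mass_kda) == 0 else out


def detect_peak(
    profile: np.ndarray | pd.Series,
    model: CalibrationModel,
    protein_id: str = "",
    half_max_fraction: float = 0.5,
) -> PeakReport:
    """Locate the profile maximum and convert it to an apparent mass.

    peak_slice is the argmax (ties -> smaller slice, i.e. larger mass; a
    multi-peak flag is set when several non-adjacent slices tie). The mass
    range spans the outermost slices at >= half the maximum, converted
    through the calibration; bounds are ordered (low, high) in kDa.
    An all-zero profile yields a flagged no-peak report.
    """
    if isinstance(profile, pd.Series):
        protein_id = protein_id or str(profile.name)
        v = profile.to_numpy(dtype=float)
    else:
        v = np.asarray(profile, dtype=float)
    if not np.any(v > 0):
        return PeakReport(
            protein_id, None, math.nan, (math.nan, math.nan), 0.0, no_peak=True
        )
    peak_idx = int(np.argmax(v))  # argmax returns the first (smallest) index on ties
    peak_pv = float(v[peak_idx])
    ties = np.where(v == peak_pv)[0]
    multi = bool(ties.size > 1 and np.any(np.diff(ties) > 1))
    if multi:
        warnings.warn(
            f"profile {protein_id or '<unnamed>'}: multiple equal maxima; "
            "reporting the smaller slice (larger mass)",
            stacklevel=2,
        )
    above = np.where(v >= half_max_fraction * peak_pv)[0]
    s_left, s_right = int(above.min()) + 1, int(above.max()) + 1  # 1-based slices
    peak_slice = peak_idx + 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        apparent = float(slice_to_mass(float(peak_slice), model))
        high = float(slice_to_mass(float(s_left), model))
        low = float(slice_to_mass(float(s_right), model))
    return PeakReport(
        protein_id=protein_id,
        peak_slice=peak_slice,
        apparent_mass_kda=apparent,
        mass_range_kda=(low, high),
        peak_pv=peak_pv,
        multi_peak=multi,
    )


def oligomer_mass(protein: ProteinRecord, n_subunits: int) -> float:
    """Mass (kDa, average) of an n-subunit homo-oligomer of the protein."""
    if n_subunits < 1:
        raise ValueError("n_subunits must be >= 1")
    return n_subunits * protein_average_mass(protein.sequence)


def read_slice_matrix(path: str | Path) -> pd.DataFrame:
    """Read a protein x slice TSV (rows proteins, columns slice_0001..N)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not all(c.startswith("slice_") for c in df.columns):
        raise ValueError("slice matrix columns must be named slice_0001..slice_N")
    return df.astype(float)


def read_marker_table(path: str | Path) -> pd.DataFrame:
    """Read a marker TSV with columns protein_id, mass_kda."""
    df = pd.read_csv(path, sep="\t")
    missing = {"protein_id", "mass_kda"} - set(df.columns)
    if missing:
        raise ValueError(f"marker table missing column(s) {sorted(missing)}")
    return df
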