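"""Specificity + consistency interactor calling.

A prey passes *specificity* in a given pull-down when its abundance there
exceeds the worst-case negative-control abundance by a configurable fold
(default 10x), or when it was never detected in any negative control at
all. A prey is *consistent* when it is specifically co-purified by at least
two different bait antibodies under the same solubilisation condition.
Consistent preys are the high-confidence partners. Each partner's abundance
relative to the bait is classified per detergent with the symbols
"=" (0.33-3.3x), "<" (0.033-0.33x), "<<" (0.0033-0.033x) and
"<<<" (< 0.0033x).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .quantify import RatioRecord, control_pseudo_floor

logger = logging.getLogger("ncx")

__all__ = [
    "CallConfig",
    "InteractorCall",
    "InteractorTable",
    "specificity_test",
    "consistency_test",
    "classify_relative_abundance",
    "call_interactors",
    "InteractorCaller",
]

ABUNDANCE_CLASSES = ("=", "<", "<<", "<<<")


@dataclass(frozen=True)
class CallConfig:
    """Thresholds of the decision procedure."""

    specificity_fold: float = 10.0
    min_antibodies: int = 2
    require_same_detergent: bool = True

    def __post_init__(self) -> None:
        if self.specificity_fold <= 1:
            raise ValueError("specificity_fold must be > 1")
        if self.min_antibodies < 2:
            raise ValueError("min_antibodies must be >= 2")


@dataclass
class InteractorCall:
    """Verdict for one protein."""

    protein_id: str
    specific_in: set[tuple[str, str]]  # (antibody, detergent)
    consistent: bool
    high_confidence: bool
    ratio_to_bait: dict[str, float] = field(default_factory=dict)  # per detergent
    abundance_class: dict[str, str] = field(default_factory=dict)  # per detergent
    is_bait: bool = False


@dataclass
class InteractorTable:
    """Sortable call table plus the protein x AP pass/fail matrix."""

    calls: pd.DataFrame
    matrix: pd.DataFrame  # values: 'pass' | 'fail' | 'nd'

    @property
    def high_confidence(self) -> set[str]:
        c = self.calls
        return set(c.loc[c["high_confidence"], "protein_id"])


def specificity_test(record: RatioRecord, config: CallConfig | None = None) -> bool:
    """Pass iff ratio >= specificity_fold, or the protein was quantified in
    the AP but never detected in any negative control."""
    config = config or CallConfig()
    if not np.isfinite(record.target_value) or record.target_value <= 0:
        return False
    if not record.control_detected:
        return True
    return record.ratio >= config.specificity_fold


def consistency_test(
    specific_in: set[tuple[str, str]], config: CallConfig | None = None
) -> bool:
    """True iff some detergent has >= min_antibodies distinct antibodies
    among the specificity-passing pull-downs (or overall, when
    ``require_same_detergent`` is off)."""
    config = config or CallConfig()
    if config.require_same_detergent:
        per_det: dict[str, set[str]] = {}
        for ab, det in specific_in:
            per_det.setdefault(det, set()).add(ab)
        return any(len(abs_) >= config.min_antibodies for abs_ in per_det.values())
    return len({ab for ab, _ in specific_in}) >= config.min_antibodies


def classify_relative_abundance(ratio_to_bait: float) -> str:
    """Map a prey/bait abundance ratio to its relative-abundance symbol.

    "=" for [0.33, 3.3]; "<" for [0.033, 0.33); "<<" for [0.0033, 0.033);
    "<<<" below 0.0033. Ratios above 3.3 (prey exceeding bait) also map to
    "=" with a warning — no class is defined above the reference.
    """
    if not (np.isfinite(ratio_to_bait) and ratio_to_bait > 0):
        raise ValueError("ratio_to_bait must be a positive finite number")
    if ratio_to_bait > 3.3:
        warnings.warn(
            f"ratio {ratio_to_bait:.3g} exceeds the bait; classified '='",
            stacklevel=2,
        )
        return "="
    if ratio_to_bait >= 0.33:
        return "="
    if ratio_to_bait >= 0.033:
        return "<"
    if ratio_to_bait >= 0.0033:
        return "<<"
    return "<<<"


def _ap_key(row) -> tuple[str, str]:
    return (row["antibody"], row["detergent"])


def call_interactors(
    quants: pd.DataFrame,
    bait_id: str,
    config: CallConfig | None = None,
) -> InteractorTable:
    """Apply the specificity and consistency criteria to a study
    quantification table (rows per (protein, run) with abundance_norm and
    run metadata, as produced by :func:`ncx.quantify.quantify_study`).

    The bait must be quantified in every target AP (hard error naming the
    run otherwise). The bait itself is kept in the table with ratio 1 and
    class "=" but is not counted as its own high-confidence partner.
    """
    config = config or CallConfig()
    q = quants[np.isfinite(quants["abundance_norm"].values)].copy()
    targets = q[q["sample_class"] == "target_ap"]
    controls = q[q["sample_class"] != "target_ap"]

    ap_runs = (
        targets[["run_id", "antibody", "detergent"]]
        .drop_duplicates()
        .sort_values("run_id", kind="stable")
    )
    if len(ap_runs["antibody"].unique()) < config.min_antibodies:
        logger.warning(
            "fewer than %d target antibodies in the study", config.min_antibodies
        )

    bait_by_run = targets[targets["protein_id"] == bait_id].set_index("run_id")
    for run_id in ap_runs["run_id"]:
        if run_id not in bait_by_run.index:
            raise ValueError(f"bait {bait_id!r} not quantified in target AP {run_id!r}")

    floor = control_pseudo_floor(controls)
    control_max = (
        controls.groupby("protein_id")["abundance_norm"].max()
        if len(controls)
        else pd.Series(dtype=float)
    )

    protein_ids = sorted(targets["protein_id"].unique())
    by_run = targets.set_index(["run_id", "protein_id"])["abundance_norm"]

    calls: list[InteractorCall] = []
    matrix = pd.DataFrame(
        "nd",
        index=protein_ids,
        columns=[f"{ab}|{det}" for ab, det in
                 ap_runs[["antibody", "detergent"]].itertuples(index=False)],
    )

    for pid in protein_ids:
        specific_in: set[tuple[str, str]] = set()
        for run_id, ab, det in ap_runs.itertuples(index=False):
            try:
                v = float(by_run.loc[(run_id, pid)])
            except KeyError:
                continue
            detected = pid in control_max.index
            cval = float(control_max.loc[pid]) if detected else floor
            ratio = v / cval if (isinstance(cval, float) and cval > 0) else np.inf
            rec = RatioRecord(pid, v, cval if cval == cval else np.nan, ratio, detected)
            ok = specificity_test(rec, config)
            matrix.loc[pid, f"{ab}|{det}"] = "pass" if ok else "fail"
            if ok:
                specific_in.add((ab, det))
        consistent = consistency_test(specific_in, config)
        is_bait = pid == bait_id

        ratio_to_bait: dict[str, float] = {}
        abundance_class: dict[str, str] = {}
        for det in sorted({d for _, d in specific_in}):
            ratios = []
            for run_id, ab, rdet in ap_runs.itertuples(index=False):
                if rdet != det or (ab, det) not in specific_in:
                    continue
                try:
                    v = float(by_run.loc[(run_id, pid)])
                    b = float(bait_by_run.loc[run_id, "abundance_norm"])
                except KeyError:
                    continue
                if b > 0:
                    ratios.append(v / b)
            if ratios:
                r = float(np.median(ratios))
                ratio_to_bait[det] = r
                with warnings.catch_warnings():
                    if is_bait:
                        warnings.simplefilter("ignore")
                    abundance_class[det] = classify_relative_abundance(r)

        calls.append(
            InteractorCall(
                protein_id=pid,
                specific_in=specific_in,
                consistent=consistent,
                high_confidence=consistent and not is_bait,
                ratio_to_bait=ratio_to_bait,
                abundance_class=abundance_class,
                is_bait=is_bait,
            )
        )

    detergents = sorted(targets["detergent"].unique())
    rows = []
    for c in calls:
        row = {
            "protein_id": c.protein_id,
            "is_bait": c.is_bait,
            "n_specific_aps": len(c.specific_in),
            "consistent": c.consistent,
            "high_confidence": c.high_confidence,
        }
        for det in detergents:
            row[f"ratio_to_bait_{det}"] = c.ratio_to_bait.get(det, np.nan)
            row[f"class_{det}"] = c.abundance_class.get(det, "")
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(
        ["high_confidence", "n_specific_aps", "protein_id"],
        ascending=[False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    return InteractorTable(calls=table, matrix=matrix)


class InteractorCaller(BaseEstimator):
    """Estimator-style wrapper over :func:`call_interactors`.

    Parameters are the decision thresholds; ``fit`` consumes a study
    quantification table and exposes ``table_``, ``matrix_`` and
    ``high_confidence_``.
    """

    def __init__(
        self,
        specificity_fold: float = 10.0,
        min_antibodies: int = 2,
        require_same_detergent: bool = True,
    ):
        self.specificity_fold = specificity_fold
        self.min_antibodies = min_antibodies
        self.require_same_detergent = require_same_detergent

    def fit(self, quants: pd.DataFrame, bait_id: str):
        config = CallConfig(
            specificity_fold=self.specificity_fold,
            min_antibodies=self.min_antibodies,
            require_same_detergent=self.require_same_detergent,
        )
        result = call_interactors(quants, bait_id=bait_id, config=config)
        self.table_ = result.calls
        self.matrix_ = result.matrix
        self.high_confidence_ = result.high_confidence
        return self
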