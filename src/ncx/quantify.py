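"""Protein-level label-free quantification.

Assigned peptide peak volumes (PVs) are summed per protein and run;
proteins identified by only one specific peptide are discarded. The
*abundance norm* — total PV divided by the number of MS-accessible tryptic
peptides of the protein — serves as a molar-abundance estimate comparable
across proteins of different size. AP-versus-control ratios compare the
median abundance norm over target pull-downs with the worst-case (maximum)
control, substituting a pseudo-floor when a protein was never detected in
any control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ProteinRecord, RunTable, StudyBundle
from .masses import DigestParams, tryptic_digest

logger = logging.getLogger("ncx")

__all__ = [
    "ProteinQuant",
    "RatioRecord",
    "protein_totals",
    "n_ms_accessible_peptides",
    "abundance_norm",
    "quantify_run",
    "quantify_study",
    "control_pseudo_floor",
    "ap_vs_control_ratio",
]


@dataclass(frozen=True)
class ProteinQuant:
    """Per-(protein, run) quantification summary."""

    protein_id: str
    run_id: str
    n_specific_peptides: int
    total_pv: float
    abundance_norm: float = math.nan  # NaN = undefined (no accessible peptides)

    @property
    def abundance_defined(self) -> bool:
        return math.isfinite(self.abundance_norm)


@dataclass(frozen=True)
class RatioRecord:
    """AP-versus-control abundance comparison for one protein."""

    protein_id: str
    target_value: float
    control_value: float
    ratio: float
    control_detected: bool


def protein_totals(
    run: RunTable,
    specific_peptides: set[str] | None = None,
    min_peptides: int = 2,
) -> pd.DataFrame:
    """Sum assigned peptide PVs per protein for one run.

    ``specific_peptides``, when given, restricts the sum to peptides unique
    to a single protein. Proteins with fewer than ``min_peptides`` distinct
    specific peptides are excluded (and logged), mirroring the rule that
    single-peptide identifications are not considered.
    Returns columns: protein_id, run_id, n_specific_peptides, total_pv.
    """
    f = run.features
    if specific_peptides is not None:
        f = f[f["peptide_seq"].isin(specific_peptides)]
    if not len(f):
        return pd.DataFrame(
            columns=["protein_id", "run_id", "n_specific_peptides", "total_pv"]
        )
    g = (
        f.groupby("protein_id", sort=True)
        .agg(n_specific_peptides=("peptide_seq", "nunique"), total_pv=("pv", "sum"))
        .reset_index()
    )
    dropped = g[g["n_specific_peptides"] < min_peptides]
    if len(dropped):
        logger.info(
            "run %s: excluded %d protein(s) with < %d specific peptides",
            run.meta.run_id, len(dropped), min_peptides,
        )
    g = g[g["n_specific_peptides"] >= min_peptides].reset_index(drop=True)
    g.insert(1, "run_id", run.meta.run_id)
    return g


def n_ms_accessible_peptides(
    protein: ProteinRecord, params: DigestParams | None = None
) -> int:
    """Number of distinct tryptic peptides of the protein inside the mass
    window at up to ``missed_cleavages`` missed cleavages — the abundance
    norm denominator (a declared stand-in for the upstream definition)."""
    return len(tryptic_digest(protein.sequence, params or DigestParams()))


def abundance_norm(quant: ProteinQuant, n_accessible: int) -> ProteinQuant:
    """Attach abundance_norm = total_pv / n_accessible to a quantification.

    A protein with zero accessible peptides gets NaN (undefined flag), not a
    division error.
    """
    if n_accessible < 0:
        raise ValueError("n_accessible must be >= 0")
    if n_accessible == 0:
        return ProteinQuant(
            quant.protein_id, quant.run_id, quant.n_specific_peptides,
            quant.total_pv, math.nan,
        )
    return ProteinQuant(
        quant.protein_id, quant.run_id, quant.n_specific_peptides,
        quant.total_pv, quant.total_pv / n_accessible,
    )


def quantify_run(
    run: RunTable,
    n_accessible: dict[str, int],
    specific_peptides: set[str] | None = None,
    min_peptides: int = 2,
) -> pd.DataFrame:
    """Protein totals plus abundance_norm for one run (NaN where the
    denominator is zero or unknown)."""
    g = protein_totals(run, specific_peptides=specific_peptides, min_peptides=min_peptides)
    denom = g["protein_id"].map(n_accessible)
    with np.errstate(divide="ignore", invalid="ignore"):
        g["abundance_norm"] = np.where(
            denom.fillna(0).values > 0, g["total_pv"].values / denom.values, np.nan
        )
    return g


def quantify_study(
    bundle: StudyBundle,
    digest_params: DigestParams | None = None,
    specific_peptides: set[str] | None = None,
    min_peptides: int = 2,
) -> pd.DataFrame:
    """Quantification table over all runs of a study.

    Returns one row per (protein, run) with run metadata columns
    (antibody, sample_class, detergent) joined in.
    """
    params = digest_params or DigestParams()
    n_acc = {
        p.protein_id: n_ms_accessible_peptides(p, params) for p in bundle.proteins
    }
    frames = []
    for run in bundle.runs:
        g = quantify_run(
            run, n_acc, specific_peptides=specific_peptides, min_peptides=min_peptides
        )
        g["antibody"] = run.meta.antibody
        g["sample_class"] = run.meta.sample_class
        g["detergent"] = run.meta.detergent
        frames.append(g)
    if not frames:
        return pd.DataFrame(
            columns=["protein_id", "run_id", "n_specific_peptides", "total_pv",
                     "abundance_norm", "antibody", "sample_class", "detergent"]
        )
    return pd.concat(frames, ignore_index=True)


def control_pseudo_floor(control_quants: pd.DataFrame) -> float:
    """Half the smallest positive abundance_norm seen in the control run set.

    Keeps 'not detected in any control' distinguishable while avoiding
    infinite ratios. NaN when controls are empty.
    """
    vals = control_quants["abundance_norm"].to_numpy(dtype=float, na_value=np.nan)
    vals = vals[np.isfinite(vals) & (vals > 0)]
    if vals.size == 0:
        return math.nan
    return float(vals.min() / 2.0)


def ap_vs_control_ratio(
    protein_id: str,
    target_quants: pd.DataFrame,
    control_quants: pd.DataFrame,
    floor: float | None = None,
) -> RatioRecord | None:
    """AP-versus-control abundance ratio for one protein.

    target_value: median abundance_norm over target APs quantifying the
    protein; control_value: maximum over all control runs (worst case);
    a protein absent from every control gets the pseudo-floor and
    ``control_detected=False``. Returns None (logged) when the protein was
    quantified in no target AP.
    """
    t = target_quants[target_quants["protein_id"] == protein_id]
    t = t[np.isfinite(t["abundance_norm"].to_numpy(dtype=float, na_value=np.nan))]
    if not len(t):
        logger.info("protein %s absent from all target APs: skipped", protein_id)
        return None
    target_value = float(t["abundance_norm"].median())
    c = control_quants[control_quants["protein_id"] == protein_id]
    c = c[np.isfinite(c["abundance_norm"].to_numpy(dtype=float, na_value=np.nan))]
    if len(c):
        control_value = float(c["abundance_norm"].max())
        detected = True
    else:
        control_value = control_pseudo_floor(control_quants) if floor is None else floor
        detected = False
    if not (isinstance(control_value, float) and control_value > 0):
        control_value = float("nan")
    ratio = target_value / control_value if control_value > 0 else math.inf
    return RatioRecord(protein_id, target_value, control_value, ratio, detected)
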