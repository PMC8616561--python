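"""End-to-end convenience drivers: align -> assign -> quantify -> call."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align import (
    MatchTolerances,
    align_study,
    assign_pvs,
    build_library,
    compute_reference_times,
)
from .interactors import CallConfig, InteractorTable, call_interactors
from .io import StudyBundle
from .masses import DigestParams
from .quantify import quantify_study

__all__ = ["ApmsResult", "assign_study", "run_apms_pipeline"]


@dataclass
class ApmsResult:
    """Outputs of the full AP-MS pipeline on one study."""

    aligned: StudyBundle
    assigned: StudyBundle
    library: pd.DataFrame
    quants: pd.DataFrame
    align_diagnostics: pd.DataFrame
    interactors: InteractorTable | None
    unassigned: dict[str, int]


def assign_study(
    bundle: StudyBundle, tolerances: MatchTolerances | None = None
) -> tuple[StudyBundle, pd.DataFrame, dict[str, int]]:
    """Build the identified-peptide library (with reference RTs) from an
    aligned bundle and re-assign every run's PVs against it."""
    tolerances = tolerances or MatchTolerances()
    library = build_library(bundle.runs)
    if len(bundle.runs) >= 2:
        ref = compute_reference_times(bundle.runs)
    else:
        ref = bundle.runs[0].features.groupby(["peptide_seq", "charge"])["rt"].median()
    library = library.merge(
        ref.rename("ref_rt"), left_on=["peptide_seq", "charge"], right_index=True,
        how="left",
    )
    assigned_runs = []
    unassigned: dict[str, int] = {}
    for run in bundle.runs:
        assigned, n_un = assign_pvs(run, library, tolerances)
        assigned_runs.append(assigned)
        unassigned[run.meta.run_id] = n_un
    assigned_bundle = StudyBundle(
        runs=assigned_runs, proteins=bundle.proteins, ground_truth=bundle.ground_truth
    )
    return assigned_bundle, library, unassigned


def run_apms_pipeline(
    bundle: StudyBundle,
    bait_id: str | None = None,
    tolerances: MatchTolerances | None = None,
    digest_params: DigestParams | None = None,
    call_config: CallConfig | None = None,
    span: float = 0.3,
    rounds: int = 2,
    min_peptides: int = 2,
) -> ApmsResult:
    """Full label-free pipeline: m/z recalibration + RT alignment, PV
    assignment, protein quantification, and (when ``bait_id`` is given)
    specificity/consistency interactor calling."""
    tolerances = tolerances or MatchTolerances()
    aligned, diagnostics = align_study(
        bundle, tolerances=tolerances, span=span, rounds=rounds
    )
    assigned, library, unassigned = assign_study(aligned, tolerances)
    specific = set(library.loc[library["specific"], "peptide_seq"])
    quants = quantify_study(
        assigned, digest_params=digest_params,
        specific_peptides=specific, min_peptides=min_peptides,
    )
    interactors = None
    if bait_id is not None:
        interactors = call_interactors(quants, bait_id=bait_id, config=call_config)
    return ApmsResult(
        aligned=aligned,
        assigned=assigned,
        library=library,
        quants=quants,
        align_diagnostics=diagnostics,
        interactors=interactors,
        unassigned=unassigned,
    )
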