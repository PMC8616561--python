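"""Domain types and text I/O for AP-MS feature tables and FASTA sequences.

A *feature table* is one MS run's identified MS1 peptide features (one row
per peptide feature: accession, sequence, charge, theoretical and observed
m/z, retention time in minutes, peak volume) preceded by ``#``-prefixed
``key=value`` metadata lines describing the run (antibody, sample class,
detergent). The format is a bespoke TSV: the upstream in-house software has
no published schema, so a documented plain-text stand-in is used.
"""

from __future__ import annotations

import io as _io
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .masses import is_valid_sequence

logger = logging.getLogger("ncx")

__all__ = [
    "FEATURE_COLUMNS",
    "SAMPLE_CLASSES",
    "DETERGENTS",
    "FeatureTableFormatError",
    "VocabularyError",
    "PeptideFeature",
    "RunMeta",
    "RunTable",
    "ProteinRecord",
    "StudyBundle",
    "read_feature_table",
    "write_feature_table",
    "read_fasta",
    "write_fasta",
]

SAMPLE_CLASSES = ("target_ap", "tuc_control", "ko_control")
DETERGENTS = ("CL-47", "CL-91")

FEATURE_COLUMNS = (
    "protein_id",
    "peptide_seq",
    "charge",
    "mz_theoretical",
    "mz_observed",
    "rt",
    "pv",
)
_FLOAT_COLS = ("mz_theoretical", "mz_observed", "rt", "pv")


class FeatureTableFormatError(ValueError):
    """Structural problem in a feature table (missing column, bad header)."""


class VocabularyError(ValueError):
    """Metadata value outside its closed vocabulary."""


@dataclass(frozen=True)
class PeptideFeature:
    """One identified MS1 peptide feature."""

    protein_id: str
    peptide_seq: str
    charge: int
    mz_theoretical: float
    mz_observed: float
    rt: float
    pv: float

    def __post_init__(self) -> None:
        if not is_valid_sequence(self.peptide_seq):
            raise ValueError(f"invalid peptide sequence {self.peptide_seq!r}")
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")
        if not (self.mz_theoretical > 0 and self.mz_observed > 0):
            raise ValueError("m/z values must be positive")
        if not (math.isfinite(self.pv) and self.pv >= 0):
            raise ValueError("pv must be finite and >= 0")
        if self.rt < 0:
            raise ValueError("rt must be >= 0 minutes")


@dataclass(frozen=True)
class RunMeta:
    """Metadata of one affinity-purification MS run."""

    run_id: str
    antibody: str
    sample_class: str
    detergent: str
    species_source: str = "synthetic"

    def __post_init__(self) -> None:
        if self.sample_class not in SAMPLE_CLASSES:
            raise VocabularyError(
                f"sample_class {self.sample_class!r} not in {SAMPLE_CLASSES}"
            )
        if self.detergent not in DETERGENTS:
            raise VocabularyError(f"detergent {self.detergent!r} not in {DETERGENTS}")


@dataclass
class RunTable:
    """One run: metadata plus a feature DataFrame with FEATURE_COLUMNS."""

    meta: RunMeta
    features: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in FEATURE_COLUMNS if c not in self.features.columns]
        if missing:
            raise FeatureTableFormatError(f"feature frame missing column(s) {missing}")
        self.features = self.features.loc[:, list(FEATURE_COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.features)

    def with_features(self, features: pd.DataFrame) -> "RunTable":
        return RunTable(meta=self.meta, features=features)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence entry (accession, sequence, free-text description)."""

    protein_id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not is_valid_sequence(self.sequence):
            raise ValueError(
                f"record {self.protein_id!r}: sequence contains non-amino-acid characters"
            )


@dataclass
class StudyBundle:
    """A multi-run AP-MS study: run tables plus the protein database."""

    runs: list[RunTable]
    proteins: list[ProteinRecord] = field(default_factory=list)
    ground_truth: object | None = None

    def __len__(self) -> int:
        return len(self.runs)

    @property
    def target_runs(self) -> list[RunTable]:
        return [r for r in self.runs if r.meta.sample_class == "target_ap"]

    @property
    def control_runs(self) -> list[RunTable]:
        return [r for r in self.runs if r.meta.sample_class != "target_ap"]

    def protein_map(self) -> dict[str, ProteinRecord]:
        return {p.protein_id: p for p in self.proteins}


def _fmt(x: float) -> str:
    """Full-precision float serialization that round-trips bit-stably."""
    return format(float(x), ".17g")


def write_feature_table(table: RunTable, path: str | Path) -> None:
    """Write a RunTable as tab-separated text with ``#`` metadata lines."""
    m = table.meta
    lines = [
        f"# run_id={m.run_id}",
        f"# antibody={m.antibody}",
        f"# sample_class={m.sample_class}",
        f"# detergent={m.detergent}",
        f"# species_source={m.species_source}",
        "\t".join(FEATURE_COLUMNS),
    ]
    for row in table.features.itertuples(index=False):
        lines.append(
            "\t".join(
                [
                    str(row.protein_id),
                    str(row.peptide_seq),
                    str(int(row.charge)),
                    _fmt(row.mz_theoretical),
                    _fmt(row.mz_observed),
                    _fmt(row.rt),
                    _fmt(row.pv),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_feature_table(path: str | Path) -> RunTable:
    """Read a feature table written by :func:`write_feature_table`.

    Malformed data rows (unparsable numbers, invalid sequences or charges)
    are rejected individually with row-indexed warnings; structural problems
    (missing columns, unknown metadata vocabulary) raise.
    """
    path = Path(path)
    meta_kv: dict[str, str] = {}
    header: list[str] | None = None
    data_lines: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta_kv[k.strip()] = v.strip()
            elif header is None:
                header = line.split("\t")
            else:
                data_lines.append(line)
    if header is None:
        raise FeatureTableFormatError(f"{path}: no header line found")
    missing = [c for c in FEATURE_COLUMNS if c not in header]
    if missing:
        raise FeatureTableFormatError(f"{path}: missing column(s) {missing}")
    for key in ("run_id", "antibody", "sample_class", "detergent"):
        if key not in meta_kv:
            raise FeatureTableFormatError(f"{path}: missing metadata line '# {key}='")
    meta = RunMeta(
        run_id=meta_kv["run_id"],
        antibody=meta_kv["antibody"],
        sample_class=meta_kv["sample_class"],
        detergent=meta_kv["detergent"],
        species_source=meta_kv.get("species_source", "unknown"),
    )

    if data_lines:
        raw = pd.read_csv(
            _io.StringIO("\n".join(["\t".join(header)] + data_lines)),
            sep="\t",
            dtype=str,
            keep_default_na=False,
        )
    else:
        raw = pd.DataFrame(columns=list(header), dtype=str)
    raw = raw.loc[:, [c for c in FEATURE_COLUMNS]]

    bad = pd.Series(False, index=raw.index)
    charge = pd.to_numeric(raw["charge"], errors="coerce")
    bad |= charge.isna() | (charge < 1) | (charge != charge.round())
    floats = {}
    for col in _FLOAT_COLS:
        vals = pd.to_numeric(raw[col], errors="coerce")
        floats[col] = vals
        bad |= ~np.isfinite(vals)
    floats["mz_theoretical"] = floats["mz_theoretical"]
    bad |= (floats["mz_theoretical"] <= 0) | (floats["mz_observed"] <= 0)
    bad |= (floats["rt"] < 0) | (floats["pv"] < 0)
    bad |= ~raw["peptide_seq"].map(is_valid_sequence)
    bad |= raw["protein_id"].str.len() == 0

    if bad.any():
        rows = [int(i) for i in raw.index[bad]]
        logger.warning(
            "%s: rejected %d malformed row(s) at data row index(es) %s",
            path.name,
            len(rows),
            rows[:20],
        )

    keep = raw.loc[~bad]
    features = pd.DataFrame(
        {
            "protein_id": keep["protein_id"].astype(str),
            "peptide_seq": keep["peptide_seq"].astype(str),
            "charge": charge.loc[keep.index].astype(int),
            "mz_theoretical": floats["mz_theoretical"].loc[keep.index].astype(float),
            "mz_observed": floats["mz_observed"].loc[keep.index].astype(float),
            "rt": floats["rt"].loc[keep.index].astype(float),
            "pv": floats["pv"].loc[keep.index].astype(float),
        }
    )
    return RunTable(meta=meta, features=features)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from FASTA; sequences are uppercased and a
    trailing ``*`` stop character is stripped. Non-amino-acid characters
    raise an error naming the offending record."""
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().rstrip("*")
        if not is_valid_sequence(seq):
            raise ValueError(
                f"FASTA record {rec.id!r}: sequence contains non-amino-acid characters"
            )
        records.append(
            ProteinRecord(protein_id=rec.id, sequence=seq, description=rec.description)
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write protein records as FASTA (60-column wrapped)."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.protein_id, description=r.description or "")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")
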