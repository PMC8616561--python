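"""Peptide/protein mass arithmetic and in-silico tryptic digestion.

Monoisotopic masses are used wherever ppm-scale m/z arithmetic matters
(MS1 feature matching); average masses are used for gel-scale reporting
(BN-PAGE apparent masses, oligomer masses), where the isotope envelope is
unresolved. Both are delegated to :mod:`pyteomics.mass`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from pyteomics import mass as _pmass
from pyteomics import parser as _pparser

__all__ = [
    "AMINO_ACIDS",
    "DigestParams",
    "PROTON_MASS",
    "WATER_MONOISOTOPIC",
    "is_valid_sequence",
    "peptide_monoisotopic_mass",
    "peptide_mz",
    "protein_average_mass",
    "tryptic_digest",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_SEQ_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")

#: Mass of a proton (Da), used for m/z computation.
PROTON_MASS = 1.00727646688
#: Monoisotopic mass of water (Da); one water per peptide bond chain.
WATER_MONOISOTOPIC = 18.0105646863

# Trypsin cleaves C-terminal to K/R unless the next residue is proline.
TRYPSIN_RULE = r"[KR](?=[^P])"


def is_valid_sequence(sequence: str) -> bool:
    """True iff *sequence* is a non-empty string over the 20-letter alphabet."""
    return bool(_SEQ_RE.match(sequence or ""))


def _check_sequence(sequence: str) -> None:
    if not isinstance(sequence, str) or not sequence:
        raise ValueError("empty or non-string amino-acid sequence")
    if not _SEQ_RE.match(sequence):
        bad = sorted(set(sequence) - set(AMINO_ACIDS))
        raise ValueError(f"invalid residue(s) {bad} in sequence {sequence[:30]!r}")


@dataclass(frozen=True)
class DigestParams:
    """Parameters of the in-silico tryptic digest.

    missed_cleavages : allowed internal missed cleavage sites (default 1,
        matching the database-search setting of the upstream identification).
    min_mass, max_mass : monoisotopic mass window (Da) of peptides considered
        MS-observable; 700-3500 Da is a typical MS1-accessible range.
    """

    missed_cleavages: int = 1
    min_mass: float = 700.0
    max_mass: float = 3500.0

    def __post_init__(self) -> None:
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        if not self.min_mass < self.max_mass:
            raise ValueError("min_mass must be < max_mass")


def peptide_monoisotopic_mass(peptide_seq: str) -> float:
    """Monoisotopic mass of a peptide in Da (residue masses plus one water)."""
    _check_sequence(peptide_seq)
    return float(_pmass.fast_mass(peptide_seq))


def peptide_mz(peptide_seq: str, charge: int) -> float:
    """Theoretical m/z (Th) of a peptide at the given positive charge state."""
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    return (peptide_monoisotopic_mass(peptide_seq) + charge * PROTON_MASS) / charge


def protein_average_mass(sequence: str) -> float:
    """Average (chemical) mass of a protein chain in kDa.

    Average masses match how gel migration and oligomer masses are reported;
    an empty sequence is an error rather than the mass of water.
    """
    _check_sequence(sequence)
    return float(_pmass.calculate_mass(sequence=sequence, average=True)) / 1000.0


def tryptic_digest(sequence: str, params: DigestParams | None = None) -> dict[str, int]:
    """Fully tryptic peptides of *sequence* with up to ``missed_cleavages``.

    Cleavage occurs after K or R except when followed by P. Returns a mapping
    peptide -> occurrence count, in order of first occurrence, restricted to
    peptides whose monoisotopic mass lies within ``[min_mass, max_mass]``.
    An empty sequence yields an empty mapping.
    """
    if not sequence:
        return {}
    _check_sequence(sequence)
    params = params or DigestParams()
    out: dict[str, int] = {}
    for _start, pep in _pparser.icleave(
        sequence, TRYPSIN_RULE, missed_cleavages=params.missed_cleavages, regex=True
    ):
        if not pep:
            continue
        m = peptide_monoisotopic_mass(pep)
        if params.min_mass <= m <= params.max_mass:
            out[pep] = out.get(pep, 0) + 1
    return out
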