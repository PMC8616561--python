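"""Reference sequences for closed-form mass checks.

The tetramer-mass reference line (four TRPM7 subunits, ~850 kDa) requires
the canonical mouse TRPM7 sequence (UniProtKB Q923J1). The sequence is not
bundled; :func:`mouse_trpm7_record` loads it from a user-supplied FASTA or
fetches it once from UniProt when the network is available.
"""

from __future__ import annotations

import os
import urllib.error
import urllib.request
from pathlib import Path

from .io import ProteinRecord, read_fasta

__all__ = ["MOUSE_TRPM7_ACCESSION", "fetch_uniprot_fasta", "mouse_trpm7_record"]

MOUSE_TRPM7_ACCESSION = "Q923J1"
_UNIPROT_URL = "https://rest.uniprot.org/uniprotkb/{acc}.fasta"


def fetch_uniprot_fasta(accession: str, path: str | Path, timeout: float = 30.0) -> Path:
    """Download one UniProtKB entry as FASTA to *path*."""
    url = _UNIPROT_URL.format(acc=accession)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        path.write_bytes(resp.read())
    return path


def mouse_trpm7_record(fasta_path: str | Path | None = None) -> ProteinRecord:
    """The canonical mouse TRPM7 sequence (UniProtKB Q923J1).

    Reads *fasta_path* (or $NCX_TRPM7_FASTA) if it exists; otherwise
    attempts a one-time UniProt download into that location (or a temporary
    file). Raises RuntimeError with guidance when neither is possible.
    """
    candidate = fasta_path or os.environ.get("NCX_TRPM7_FASTA")
    if candidate and Path(candidate).exists():
        records = read_fasta(candidate)
        if not records:
            raise RuntimeError(f"{candidate}: no FASTA records found")
        return records[0]
    target = Path(candidate) if candidate else Path("scratch") / "Q923J1.fasta"
    try:
        fetch_uniprot_fasta(MOUSE_TRPM7_ACCESSION, target)
    except (urllib.error.URLError, OSError) as err:
        raise RuntimeError(
            "canonical mouse TRPM7 sequence (UniProtKB Q923J1) is not available: "
            "no local FASTA was supplied and UniProt could not be reached "
            f"({err}). Download Q923J1.fasta and pass its path (or set "
            "NCX_TRPM7_FASTA) to run the tetramer-mass check."
        ) from err
    return read_fasta(target)[0]
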