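"""FASTA input/output, domain extraction, and protein mass.

Sequences are plain uppercase strings over the 20 standard residues; 'X' is
tolerated on input (it occurs rarely in UniProt entries) but is rejected by
any computation whose answer it would corrupt, such as molecular mass.
Coordinates are 1-based and inclusive throughout, matching UniProt numbering.
"""
from __future__ import annotations

import logging
import urllib.request
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import molecular_weight

from .errors import BoundaryError, SequenceValidationError

log = logging.getLogger(__name__)

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")
ACCEPTED_RESIDUES = STANDARD_RESIDUES | {"X"}


@dataclass(frozen=True)
class SequenceRecord:
    """A named protein sequence (uppercase, no gaps or whitespace)."""

    id: str
    description: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FBGDomain:
    """A domain-local sequence with provenance back to its parent protein.

    ``parent_start``/``parent_end`` are 1-based inclusive coordinates in the
    parent protein; they are ``None`` for domains that were built in silico
    rather than cut from a parent record.
    """

    id: str
    sequence: str
    parent_accession: str | None = None
    parent_start: int | None = None
    parent_end: int | None = None

    def __len__(self) -> int:
        return len(self.sequence)


def _validate_sequence(seq: str, record_id: str) -> str:
    seq = seq.upper().rstrip("*")
    if not seq:
        raise SequenceValidationError(f"record {record_id!r}: empty sequence")
    for pos, ch in enumerate(seq, start=1):
        if ch not in ACCEPTED_RESIDUES:
            raise SequenceValidationError(
                f"record {record_id!r}: invalid residue {ch!r} at position {pos}"
            )
    if "X" in seq:
        log.warning("record %r contains %d 'X' residue(s)", record_id, seq.count("X"))
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record protein FASTA file.

    Lowercase input is upcased and a trailing ``*`` terminator is stripped.
    Raises :class:`SequenceValidationError` on an empty file or on residues
    outside the accepted alphabet, naming the offending record and position.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(
                id=rec.id,
                description=rec.description,
                sequence=_validate_sequence(str(rec.seq), rec.id),
            )
        )
    if not records:
        raise SequenceValidationError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records to ``path`` in wrapped FASTA format (order preserved)."""
    seqrecords = []
    for r in records:
        description = r.description
        if description.startswith(r.id):
            description = description[len(r.id):].strip()
        seqrecords.append(SeqRecord(Seq(r.sequence), id=r.id, description=description))
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seqrecords)


def extract_domain(record: SequenceRecord, entry) -> FBGDomain:
    """Cut the FBG domain of a catalogue ``entry`` out of its parent record.

    The returned domain has length ``fbg_end - fbg_start + 1``. Boundaries
    beyond the record length raise :class:`BoundaryError`; this usually
    signals an accession or isoform mismatch between record and catalogue.
    """
    start, end = entry.fbg_start, entry.fbg_end
    if not (1 <= start < end):
        raise BoundaryError(f"{entry.name}: invalid boundaries {start}-{end}")
    if end > len(record.sequence):
        raise BoundaryError(
            f"{entry.name}: fbg_end {end} exceeds record {record.id!r} "
            f"length {len(record.sequence)} (accession/isoform mismatch?)"
        )
    return FBGDomain(
        id=f"{record.id}/FBG",
        sequence=record.sequence[start - 1:end],
        parent_accession=entry.accession,
        parent_start=start,
        parent_end=end,
    )


def compute_average_mass(domain: FBGDomain | str) -> float:
    """Average (isotope-weighted) mass of a peptide in kDa.

    Sum of average residue masses plus one water. Rounded only by callers;
    the Fig.-style report convention is one decimal in kDa. 'X' residues
    make the mass undefined and raise :class:`SequenceValidationError`.
    """
    seq = domain.sequence if isinstance(domain, FBGDomain) else domain
    if "X" in seq:
        raise SequenceValidationError("cannot compute mass: sequence contains 'X'")
    if not seq or set(seq) - STANDARD_RESIDUES:
        raise SequenceValidationError("mass requires a non-empty standard-residue sequence")
    return molecular_weight(seq, seq_type="protein") / 1000.0


UNIPROT_FASTA_URL = "https://rest.uniprot.org/uniprotkb/{accession}.fasta"


def fetch_uniprot_fasta(accessions: Sequence[str], out_path: str | Path,
                        url_template: str = UNIPROT_FASTA_URL) -> list[SequenceRecord]:
    """Fetch-and-freeze maintenance command: download canonical UniProt
    sequences and write them to a frozen FASTA file.

    This is never called by the test suite or by any analysis command; it is
    an explicitly-invoked, network-requiring maintenance step.
    """
    chunks = []
    for acc in accessions:
        with urllib.request.urlopen(url_template.format(accession=acc)) as fh:  # noqa: S310
            chunks.append(fh.read().decode())
    text = "".join(chunks)
    Path(out_path).write_text(text)
    return read_fasta(out_path)
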