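"""Packaged reference annotation and the 24-entry human FReP catalogue.

The reference is a synthetic tenascin-C FBG scaffold: a 228-residue sequence
honouring every published anchor of the real domain (the KTRYKLK loop-5
motif, the D157/I160/N162 loop-7 triad, the cationic RRKRA tail at 224-228
preceded by the printed NFRNLEG fragment, seven K/R in the ridge region, and
a 26.1 kDa average mass). It is a labelled reconstruction, not the UniProt
P24821 subsequence; see data/reference_annotation.json and docs/methods.md.

The catalogue mirrors, row for row, the published per-protein feature table
for the 24 human fibrinogen-related proteins: cationic-ridge count, loop-7
triad flag, cationic C-tail flag, and the ">=3 ridge charges => predicted
TLR4 activator" call.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .errors import ConfigError
from .seqio import read_fasta

Interval = tuple[int, int]

TENASCIN_FAMILY = "tenascin"
RIDGE_THRESHOLD = 3  # positive charges; the published classification boundary


@dataclass(frozen=True)
class ReferenceAnnotation:
    """Tenascin-C FBG reference sequence with loop/triad/tail anchors.

    All coordinates are domain-local, 1-based, inclusive.
    ``loop10_anchor`` is the first residue of the C-terminal tail region
    (RRKRA occupies 224-228 on the scaffold). ``ridge_slots`` are the
    canonical positions of the seven ridge positives on the scaffold; they
    parameterize the synthetic generators, not the scanner.
    """

    reference_id: str
    sequence: str
    loop5: Interval
    loop6: Interval
    loop7: Interval
    loop10_anchor: int
    triad_positions: tuple[int, int, int]
    triad_residues: tuple[str, str, str]
    ridge_motif: str
    ridge_slots: tuple[int, ...] = ()
    buffer_positions: tuple[int, ...] = ()

    @property
    def ridge_intervals(self) -> tuple[Interval, Interval, Interval]:
        return (self.loop5, self.loop6, self.loop7)

    def validate(self) -> None:
        n = len(self.sequence)
        ivs = [self.loop5, self.loop6, self.loop7]
        for a, b in ivs:
            if not (1 <= a <= b <= n):
                raise ConfigError(f"loop interval {a}-{b} outside [1, {n}]")
        if not (self.loop5[1] < self.loop6[0] and self.loop6[1] < self.loop7[0]):
            raise ConfigError("loops 5, 6, 7 must be ordered and non-overlapping")
        for p, r in zip(self.triad_positions, self.triad_residues):
            if self.sequence[p - 1] != r:
                raise ConfigError(f"triad residue mismatch at {p}: "
                                  f"{self.sequence[p - 1]} != {r}")
        if self.sequence.count(self.ridge_motif) != 1:
            raise ConfigError(f"ridge motif {self.ridge_motif} must occur exactly once")
        m = self.sequence.index(self.ridge_motif) + 1
        if not (self.loop5[0] <= m and m + len(self.ridge_motif) - 1 <= self.loop5[1]):
            raise ConfigError("ridge motif must lie within loop 5")
        if self.loop10_anchor <= self.loop7[1]:
            raise ConfigError("loop10 anchor must fall after loop 7")
        if self.loop10_anchor > n:
            raise ConfigError("loop10 anchor outside sequence")


@dataclass(frozen=True)
class FRePEntry:
    """One row of the 24-protein FReP catalogue (feature-table mirror)."""

    name: str
    family: str
    accession: str
    fbg_start: int
    fbg_end: int
    table1_ridge: int
    table1_triad: bool
    table1_ctail: bool
    table1_predicted: bool
    crystal_available: bool

    @property
    def domain_length(self) -> int:
        return self.fbg_end - self.fbg_start + 1

    def validate(self) -> None:
        if not self.fbg_start < self.fbg_end:
            raise ConfigError(f"{self.name}: fbg_start must precede fbg_end")
        if not 200 <= self.domain_length <= 260:
            raise ConfigError(f"{self.name}: implausible FBG length {self.domain_length}")
        if self.table1_ridge < 0:
            raise ConfigError(f"{self.name}: negative ridge count")
        if self.table1_predicted != (self.table1_ridge >= RIDGE_THRESHOLD):
            raise ConfigError(
                f"{self.name}: predicted flag inconsistent with ridge count "
                f"{self.table1_ridge} under the >= {RIDGE_THRESHOLD} rule"
            )


def _data_path(name: str):
    return resources.files("fbgscan").joinpath("data", name)


def load_reference() -> ReferenceAnnotation:
    """Load the packaged synthetic tenascin-C FBG reference annotation."""
    try:
        ann = json.loads(_data_path("reference_annotation.json").read_text())
        with resources.as_file(_data_path("reference_fbgc_synthetic.fasta")) as p:
            rec = read_fasta(p)[0]
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigError(f"packaged reference data unreadable: {exc}") from exc
    if rec.id != ann["reference_id"]:
        raise ConfigError("reference FASTA id does not match annotation")
    ref = ReferenceAnnotation(
        reference_id=ann["reference_id"],
        sequence=rec.sequence,
        loop5=tuple(ann["loop5"]),
        loop6=tuple(ann["loop6"]),
        loop7=tuple(ann["loop7"]),
        loop10_anchor=ann["loop10_anchor"],
        triad_positions=tuple(ann["triad_positions"]),
        triad_residues=tuple(ann["triad_residues"]),
        ridge_motif=ann["ridge_motif"],
        ridge_slots=tuple(ann["ridge_slots"]),
        buffer_positions=tuple(ann["buffer_positions"]),
    )
    ref.validate()
    return ref


_BOOL = {"yes": True, "no": False, "+": True, "-": False, "true": True, "false": False}


def load_catalog(path: str | Path | None = None) -> list[FRePEntry]:
    """Load the FReP catalogue (packaged 24-entry table by default).

    A user-supplied TSV with the same columns may be passed to rescan a
    custom protein set; the packaged catalogue must contain exactly 24
    entries and is validated for internal rule consistency either way.
    """
    if path is None:
        with resources.as_file(_data_path("frep_catalog.tsv")) as p:
            entries = _read_catalog_tsv(p)
        if len(entries) != 24:
            raise ConfigError(f"packaged catalogue has {len(entries)} entries, expected 24")
    else:
        entries = _read_catalog_tsv(Path(path))
    names = [e.name for e in entries]
    accs = [e.accession for e in entries]
    if len(set(names)) != len(names) or len(set(accs)) != len(accs):
        raise ConfigError("catalogue contains duplicate names or accessions")
    for e in entries:
        e.validate()
    return entries


def _read_catalog_tsv(path: Path) -> list[FRePEntry]:
    try:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
    except OSError as exc:
        raise ConfigError(f"cannot read catalogue {path}: {exc}") from exc
    if not rows:
        raise ConfigError(f"catalogue {path} is empty")
    entries = []
    for row in rows:
        try:
            entries.append(FRePEntry(
                name=row["name"],
                family=row["family"],
                accession=row["accession"],
                fbg_start=int(row["fbg_start"]),
                fbg_end=int(row["fbg_end"]),
                table1_ridge=int(row["table1_ridge"]),
                table1_triad=_BOOL[row["table1_triad"].lower()],
                table1_ctail=_BOOL[row["table1_ctail"].lower()],
                table1_predicted=_BOOL[row["table1_predicted"].lower()],
                crystal_available=_BOOL[row["crystal_available"].lower()],
            ))
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"malformed catalogue row {row!r}: {exc}") from exc
    return entries


def entry_by_name(entries: list[FRePEntry], name: str) -> FRePEntry:
    for e in entries:
        if e.name == name:
            return e
    raise KeyError(name)
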