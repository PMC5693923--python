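"""Epitope feature extraction and TLR4-agonist classification.

Three sequence features are read from each FBG domain after annotation
transfer from the tenascin-C reference:

* the cationic ridge — the count of K/R residues inside the mapped
  loop-5/6/7 intervals (histidine is not counted as positive);
* the loop-7 triad — D/I/N at the three mapped triad positions;
* the cationic C-tail — at least three K/R in the mapped loop-10 region.

A domain is called a predicted TLR4 activator when its ridge carries three
or more positive charges. The classifier is deliberately binary: it mirrors
the published per-protein feature table and makes no graded-activity claim.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil

import pandas as pd
from Bio.Align import substitution_matrices

from .align import AlignmentParams, MappedAnnotation, global_align, map_intervals, percent_identity
from .errors import BoundaryError, ScanError
from .reference import RIDGE_THRESHOLD, TENASCIN_FAMILY, FRePEntry, Interval, ReferenceAnnotation
from .seqio import FBGDomain, SequenceRecord, extract_domain

log = logging.getLogger(__name__)

CATIONIC = frozenset("KR")

TRIAD_MODES = ("exact", "conservative")


@dataclass(frozen=True)
class ScanConfig:
    """Tunable parameters of the scan, with published-rule defaults."""

    threshold: int = RIDGE_THRESHOLD          # ridge positives for an activator call
    triad_mode: str = "exact"                 # "exact" or "conservative"
    ctail_min_positives: int = 3              # K/R needed to call the C-tail cationic
    identity_floor: float = 15.0              # % identity below which a scan is refused
    identity_convention: str = "shorter"
    alignment: AlignmentParams = field(default_factory=AlignmentParams)


@dataclass(frozen=True)
class EpitopeProfile:
    """Extracted epitope features for one scanned domain."""

    domain_id: str
    ridge_count: int
    per_loop_counts: tuple[int, int, int]
    triad_present: bool
    ctail_present: bool
    ctail_positive_count: int
    predicted_activator: bool
    identity_to_reference: float


def count_cationic(seq: str, intervals: list[Interval]) -> list[int]:
    """K/R counts per 1-based inclusive interval of ``seq``."""
    counts = []
    for a, b in intervals:
        if not (1 <= a <= b <= len(seq)):
            raise BoundaryError(f"interval {a}-{b} outside sequence of length {len(seq)}")
        counts.append(sum(1 for ch in seq[a - 1:b] if ch in CATIONIC))
    return counts


def detect_triad(target: str, mapped_positions, reference_residues=("D", "I", "N"),
                 mode: str = "exact") -> bool:
    """Is the loop-7 triad present at the mapped target positions?

    ``exact`` requires the reference residues themselves; ``conservative``
    accepts any residue scoring positively against the reference residue
    under BLOSUM62. A position deleted in the target (``None``) always
    fails.
    """
    if mode not in TRIAD_MODES:
        raise ValueError(f"unknown triad mode {mode!r}")
    if any(p is None for p in mapped_positions):
        return False
    residues = [target[p - 1] for p in mapped_positions]
    if mode == "exact":
        return all(t == r for t, r in zip(residues, reference_residues))
    blosum = substitution_matrices.load("BLOSUM62")
    return all(blosum[t, r] > 0 for t, r in zip(residues, reference_residues))


def detect_ctail(target: str, loop10_region: Interval | None,
                 min_positives: int = 3) -> tuple[bool, int]:
    """(present, K/R count) for the mapped C-terminal loop-10 region."""
    if loop10_region is None:
        return (False, 0)
    count = count_cationic(target, [loop10_region])[0]
    return (count >= min_positives, count)


def classify(ridge_count: int, threshold: int = RIDGE_THRESHOLD) -> bool:
    """Predicted TLR4 activator iff the ridge carries >= threshold positives."""
    if ridge_count < 0:
        raise ValueError("ridge count cannot be negative")
    return ridge_count >= threshold


def scan_domain(domain: FBGDomain, annotation: ReferenceAnnotation,
                config: ScanConfig = ScanConfig()) -> EpitopeProfile:
    """Align, transfer annotation, extract the three features, classify."""
    aln = global_align(domain.sequence, annotation.sequence, config.alignment)
    identity = percent_identity(aln, config.identity_convention)
    if identity < config.identity_floor:
        raise ScanError(
            f"{domain.id}: {identity:.1f}% identity to the FBG reference is below "
            f"the {config.identity_floor:.0f}% floor; not an FBG domain?"
        )
    mapped = map_intervals(aln, annotation)
    per_loop = tuple(
        count_cationic(domain.sequence, [iv])[0] if iv is not None else 0
        for iv in (mapped.loop5, mapped.loop6, mapped.loop7)
    )
    ridge = sum(per_loop)
    triad = detect_triad(domain.sequence, mapped.triad_targets,
                         annotation.triad_residues, config.triad_mode)
    ctail_present, ctail_count = detect_ctail(domain.sequence, mapped.loop10_region,
                                              config.ctail_min_positives)
    return EpitopeProfile(
        domain_id=domain.id,
        ridge_count=ridge,
        per_loop_counts=per_loop,  # type: ignore[arg-type]
        triad_present=triad,
        ctail_present=ctail_present,
        ctail_positive_count=ctail_count,
        predicted_activator=classify(ridge, config.threshold),
        identity_to_reference=identity,
    )


def mapped_annotation(domain: FBGDomain, annotation: ReferenceAnnotation,
                      config: ScanConfig = ScanConfig()) -> MappedAnnotation:
    """Annotation transfer only (no feature extraction)."""
    aln = global_align(domain.sequence, annotation.sequence, config.alignment)
    return map_intervals(aln, annotation)


SCAN_COLUMNS = ["Protein", "Cationic ridge", "Loop 7", "Cationic C-terminal",
                "Predicted TLR4 activator"]


def scan_catalog(catalog: list[FRePEntry], sequences: dict[str, SequenceRecord],
                 annotation: ReferenceAnnotation,
                 config: ScanConfig = ScanConfig()) -> pd.DataFrame:
    """Scan every catalogue entry and compare against the packaged table.

    ``sequences`` maps entry name (or accession) to the full-length parent
    record. Entries without a sequence are skipped with a warning and appear
    in the report with a note. Columns mirror the published table layout,
    followed by concordance columns.
    """
    rows = []
    for entry in catalog:
        rec = sequences.get(entry.name) or sequences.get(entry.accession)
        base = {
            "Protein": entry.name,
            "family": entry.family,
            "accession": entry.accession,
            "table_ridge": entry.table1_ridge,
            "table_triad": entry.table1_triad,
            "table_ctail": entry.table1_ctail,
            "table_predicted": entry.table1_predicted,
        }
        if rec is None:
            log.warning("no sequence for catalogue entry %r; skipped", entry.name)
            rows.append(base | {"Cationic ridge": pd.NA, "Loop 7": pd.NA,
                                "Cationic C-terminal": pd.NA,
                                "Predicted TLR4 activator": pd.NA,
                                "note": "no sequence; skipped"})
            continue
        profile = scan_domain(extract_domain(rec, entry), annotation, config)
        rows.append(base | {
            "Cationic ridge": profile.ridge_count,
            "Loop 7": profile.triad_present,
            "Cationic C-terminal": profile.ctail_present,
            "Predicted TLR4 activator": profile.predicted_activator,
            "identity_pct": round(profile.identity_to_reference, 1),
            "concordant_ridge": profile.ridge_count == entry.table1_ridge,
            "concordant_prediction": profile.predicted_activator == entry.table1_predicted,
            "note": "",
        })
    return pd.DataFrame(rows)


def summarize_scan(report: pd.DataFrame) -> dict:
    """Summary counts of a catalogue scan report."""
    scanned = report[report["note"] == ""] if "note" in report else report
    is_ten = scanned["family"] == TENASCIN_FAMILY
    pred = scanned["Predicted TLR4 activator"].astype(bool)
    return {
        "n_scanned": int(len(scanned)),
        "n_skipped": int(len(report) - len(scanned)),
        "activators_tenascin": int((pred & is_ten).sum()),
        "activators_other": int((pred & ~is_ten).sum()),
        "prediction_concordance": int(scanned.get(
            "concordant_prediction", pd.Series(dtype=bool)).sum()),
    }


@dataclass(frozen=True)
class PeptideWindow:
    """One tile of the overlapping-peptide reconstruction of a domain."""

    index: int           # 1-based ordinal
    start: int
    end: int
    sequence: str
    ridge_overlap_count: int   # K/R of the reference ridge motif inside the window
    predicted_active: bool     # >= 3 mapped ridge positives inside the window


def tile_peptides(domain: FBGDomain, annotation: ReferenceAnnotation,
                  length: int = 30, stride: int = 25,
                  config: ScanConfig = ScanConfig()) -> list[PeptideWindow]:
    """Cut a domain into overlapping windows, flagging those carrying the ridge.

    Windows advance by ``stride`` and the last window is right-aligned to the
    C-terminus so the whole domain is covered. This reconstructs the
    published peptide-tiling strategy (nine ~30-mers over the 228-residue
    reference); the published peptide sequences themselves are not available,
    so the tiling is a reconstruction, and reports label it as such.
    """
    n = len(domain.sequence)
    if length > n:
        raise BoundaryError(f"window length {length} exceeds domain length {n}")
    if stride < 1:
        raise ValueError("stride must be positive")

    mapped = mapped_annotation(domain, annotation, config)
    ridge_positions = {
        p for iv in mapped.ridge_intervals
        for p in range(iv[0], iv[1] + 1) if domain.sequence[p - 1] in CATIONIC
    }
    motif_start = annotation.sequence.index(annotation.ridge_motif) + 1
    aln = global_align(domain.sequence, annotation.sequence, config.alignment)
    motif_positions = {
        t for i, ch in enumerate(annotation.ridge_motif)
        if ch in CATIONIC and (t := aln.column_map.get(motif_start + i)) is not None
    }

    n_windows = max(1, ceil((n - length) / stride) + 1)
    windows = []
    for i in range(n_windows):
        start = 1 + i * stride
        if start + length - 1 > n:
            start = n - length + 1   # right-align the final window
        end = start + length - 1
        span = set(range(start, end + 1))
        windows.append(PeptideWindow(
            index=i + 1, start=start, end=end,
            sequence=domain.sequence[start - 1:end],
            ridge_overlap_count=len(motif_positions & span),
            predicted_active=len(ridge_positions & span) >= RIDGE_THRESHOLD,
        ))
        if end == n:
            break
    return windows
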