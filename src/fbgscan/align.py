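"""Global pairwise alignment and alignment-mediated annotation transfer.

A target FBG domain is aligned to the reference scaffold with global
Needleman-Wunsch (BLOSUM62, affine gaps, open 10 / extend 0.5, where a gap
of length g costs open + (g-1)*extend). Reference loop intervals and triad
positions are then transferred onto the target through the alignment column
map. The dynamic programming itself is delegated to Biopython's
PairwiseAligner; this module owns the column bookkeeping, identity
conventions, and interval transfer semantics.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import AlignmentError
from .reference import Interval, ReferenceAnnotation

GAP = "-"

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5

IDENTITY_CONVENTIONS = ("shorter", "aligned_columns", "alignment_length")


@dataclass(frozen=True)
class AlignmentParams:
    matrix: str = DEFAULT_MATRIX
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped global alignment of target vs reference.

    ``column_map`` sends each reference position (1-based) to the target
    position aligned with it, or ``None`` where the reference residue is
    aligned to a gap.
    """

    target: str
    reference: str
    target_aligned: str
    reference_aligned: str
    score: float
    identities: int
    aligned_columns: int
    column_map: dict[int, int | None]

    def validate(self) -> None:
        if len(self.target_aligned) != len(self.reference_aligned):
            raise AlignmentError("aligned rows differ in length")
        if self.target_aligned.replace(GAP, "") != self.target:
            raise AlignmentError("target row does not recover target sequence")
        if self.reference_aligned.replace(GAP, "") != self.reference:
            raise AlignmentError("reference row does not recover reference sequence")
        for t, r in zip(self.target_aligned, self.reference_aligned):
            if t == GAP and r == GAP:
                raise AlignmentError("column with gaps in both rows")
        if self.identities > self.aligned_columns:
            raise AlignmentError("identities exceed aligned columns")


@lru_cache(maxsize=8)
def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # Biopython convention: the first gap residue scores open_gap_score and
    # each further residue extend_gap_score, i.e. cost open + (g-1)*extend.
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(target: str, reference: str,
                 params: AlignmentParams = AlignmentParams()) -> PairwiseAlignment:
    """Optimal global alignment of ``target`` against ``reference``.

    Deterministic: of the co-optimal tracebacks, the aligner's first
    reported alignment is always returned.
    """
    if not target or not reference:
        raise AlignmentError("cannot align an empty sequence")
    aligner = _make_aligner(params.matrix, params.gap_open, params.gap_extend)
    aln = aligner.align(target, reference)[0]
    target_aligned, reference_aligned = str(aln[0]), str(aln[1])

    identities = aligned = 0
    column_map: dict[int, int | None] = {}
    tpos = rpos = 0
    for t, r in zip(target_aligned, reference_aligned):
        if t != GAP:
            tpos += 1
        if r != GAP:
            rpos += 1
            column_map[rpos] = tpos if t != GAP else None
        if t != GAP and r != GAP:
            aligned += 1
            if t == r:
                identities += 1
    result = PairwiseAlignment(
        target=target, reference=reference,
        target_aligned=target_aligned, reference_aligned=reference_aligned,
        score=float(aln.score), identities=identities,
        aligned_columns=aligned, column_map=column_map,
    )
    result.validate()
    return result


def percent_identity(aln: PairwiseAlignment, convention: str = "shorter") -> float:
    """Percent identity under a stated denominator convention.

    ``shorter``: identities / length of the shorter input sequence (default
    reporting convention); ``aligned_columns``: identities / columns where
    both rows carry a residue; ``alignment_length``: identities / total
    alignment columns.
    """
    if convention == "shorter":
        denom = min(len(aln.target), len(aln.reference))
    elif convention == "aligned_columns":
        denom = aln.aligned_columns
    elif convention == "alignment_length":
        denom = len(aln.target_aligned)
    else:
        raise ValueError(f"unknown identity convention {convention!r}; "
                         f"choose from {IDENTITY_CONVENTIONS}")
    if denom == 0:
        raise AlignmentError("cannot compute identity on an empty alignment")
    return 100.0 * aln.identities / denom


@dataclass(frozen=True)
class MappedAnnotation:
    """Reference annotation transferred onto a target domain.

    Intervals are the smallest target intervals covering all non-gap
    columns of the corresponding reference interval (``None`` if the whole
    interval is deleted in the target). ``triad_targets`` holds one target
    position per triad site, ``None`` where the site is aligned to a gap.
    ``loop10_region`` covers every target residue at or after the column of
    the reference loop-10 anchor, including any target overhang past the
    reference C-terminus; it is ``None`` for truncated tails.
    """

    loop5: Interval | None
    loop6: Interval | None
    loop7: Interval | None
    triad_targets: tuple[int | None, int | None, int | None]
    loop10_region: Interval | None

    @property
    def ridge_intervals(self) -> tuple[Interval, ...]:
        return tuple(iv for iv in (self.loop5, self.loop6, self.loop7) if iv is not None)


def _map_interval(column_map: dict[int, int | None], iv: Interval) -> Interval | None:
    hits = [column_map[p] for p in range(iv[0], iv[1] + 1) if column_map.get(p) is not None]
    if not hits:
        return None
    return (min(hits), max(hits))


def map_intervals(aln: PairwiseAlignment, annotation: ReferenceAnnotation) -> MappedAnnotation:
    """Transfer the reference loops, triad, and tail onto the target."""
    if aln.reference != annotation.sequence:
        raise AlignmentError("alignment reference row does not match the annotation sequence")
    cm = aln.column_map
    triad = tuple(cm.get(p) for p in annotation.triad_positions)

    # The tail region starts at the column of the loop-10 anchor and runs to
    # the end of the target, so a target tail longer than the reference's
    # (an "extended" loop 10) is included, and a truncated tail maps to None.
    anchor_targets = [cm[p] for p in range(annotation.loop10_anchor, len(aln.reference) + 1)
                      if cm.get(p) is not None]
    n_target = len(aln.target)
    if anchor_targets:
        loop10 = (min(anchor_targets), n_target)
    else:
        # anchor region fully deleted; check for a pure overhang past the
        # reference C-terminus (target residues aligned beyond it)
        last_ref_target = max((t for t in cm.values() if t is not None), default=0)
        loop10 = (last_ref_target + 1, n_target) if last_ref_target < n_target else None

    return MappedAnnotation(
        loop5=_map_interval(cm, annotation.loop5),
        loop6=_map_interval(cm, annotation.loop6),
        loop7=_map_interval(cm, annotation.loop7),
        triad_targets=triad,  # type: ignore[arg-type]
        loop10_region=loop10,
    )


def alignment_to_fasta(aln: PairwiseAlignment, target_id: str = "target",
                       reference_id: str = "reference") -> str:
    """Two-row gapped FASTA dump of an alignment, for inspection."""
    return (f">{target_id}\n{aln.target_aligned}\n"
            f">{reference_id}\n{aln.reference_aligned}\n")
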