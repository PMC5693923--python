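"""Alignment, identity conventions, and annotation transfer.

The affine-gap score oracle used here enumerates every gapped global
alignment recursively; it shares no code with the aligner under test.
"""
import dataclasses

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings
from hypothesis import strategies as st

from fbgscan import (AlignmentError, PairwiseAlignment, global_align,
                     map_intervals, percent_identity)

BLOSUM = substitution_matrices.load("BLOSUM62")
OPEN, EXT = 10.0, 0.5

SHORT = st.text(alphabet="KTRY", min_size=1, max_size=7)


def brute_force_score(a: str, b: str) -> float:
    """Exhaustive max over all global alignments; gap run costs open+(g-1)*ext."""
    def rec(i, j, last):
        if i == len(a) and j == len(b):
            return 0.0
        best = float("-inf")
        if i < len(a) and j < len(b):
            best = max(best, BLOSUM[a[i], b[j]] + rec(i + 1, j + 1, "M"))
        if i < len(a):
            best = max(best, -(EXT if last == "U" else OPEN) + rec(i + 1, j, "U"))
        if j < len(b):
            best = max(best, -(EXT if last == "L" else OPEN) + rec(i, j + 1, "L"))
        return best
    return rec(0, 0, "M")


class TestGlobalAlign:
    def test_self_alignment_is_gapless(self):
        aln = global_align("KTRYKLK", "KTRYKLK")
        assert aln.identities == 7
        assert "-" not in aln.target_aligned + aln.reference_aligned

    def test_suffix_deletion_uses_terminal_gaps(self):
        aln = global_align("KTRYKLK", "KTRYK")
        assert aln.identities == 5
        assert aln.reference_aligned.count("-") == 2

    def test_empty_sequence_rejected(self):
        with pytest.raises(AlignmentError):
            global_align("", "KTRYK")

    @settings(max_examples=40, deadline=None)
    @given(a=SHORT, b=SHORT)
    def test_score_matches_exhaustive_enumeration(self, a, b):
        assert global_align(a, b).score == pytest.approx(brute_force_score(a, b))

    @settings(max_examples=25, deadline=None)
    @given(a=SHORT, b=SHORT)
    def test_score_symmetry(self, a, b):
        assert global_align(a, b).score == pytest.approx(global_align(b, a).score)

    @settings(max_examples=25, deadline=None)
    @given(a=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=40),
           b=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=40))
    def test_gap_removal_recovers_inputs(self, a, b):
        aln = global_align(a, b)
        assert aln.target_aligned.replace("-", "") == a
        assert aln.reference_aligned.replace("-", "") == b
        aln.validate()


class TestPercentIdentity:
    def test_identical_sequences(self):
        assert percent_identity(global_align("KTRYKLK", "KTRYKLK")) == 100.0

    def test_half_identical(self):
        assert percent_identity(global_align("AAAA", "AATT")) == 50.0

    def test_convention_denominators_differ(self):
        aln = global_align("KTRYKLK", "KTRYK")
        assert percent_identity(aln, "shorter") == 100.0
        assert percent_identity(aln, "alignment_length") == pytest.approx(5 / 7 * 100)

    def test_unknown_convention(self):
        with pytest.raises(ValueError):
            percent_identity(global_align("AA", "AA"), "bogus")


def _manual_alignment(target_aligned: str, reference_aligned: str) -> PairwiseAlignment:
    """Build a PairwiseAlignment from explicit gapped rows (column-walk)."""
    target = target_aligned.replace("-", "")
    reference = reference_aligned.replace("-", "")
    cm, tpos, rpos, ident, cols = {}, 0, 0, 0, 0
    for t, r in zip(target_aligned, reference_aligned):
        if t != "-":
            tpos += 1
        if r != "-":
            rpos += 1
            cm[rpos] = tpos if t != "-" else None
        if t != "-" and r != "-":
            cols += 1
            ident += t == r
    return PairwiseAlignment(target=target, reference=reference,
                             target_aligned=target_aligned,
                             reference_aligned=reference_aligned, score=0.0,
                             identities=ident, aligned_columns=cols, column_map=cm)


def _toy_annotation(annotation, sequence, loop5, loop6, loop7, anchor, triad):
    return dataclasses.replace(
        annotation, sequence=sequence, loop5=loop5, loop6=loop6, loop7=loop7,
        loop10_anchor=anchor, triad_positions=triad,
        triad_residues=tuple(sequence[p - 1] for p in triad))


class TestMapIntervals:
    def test_identity_alignment_maps_to_self(self, annotation):
        aln = global_align(annotation.sequence, annotation.sequence)
        m = map_intervals(aln, annotation)
        assert (m.loop5, m.loop6, m.loop7) == \
            (annotation.loop5, annotation.loop6, annotation.loop7)
        assert m.triad_targets == annotation.triad_positions
        assert m.loop10_region == (annotation.loop10_anchor, len(annotation.sequence))

    def test_gapped_interval_shrinks_and_flags_absent(self, annotation):
        toy = _toy_annotation(annotation, "KTRYKLK", (1, 7), (1, 1), (2, 2),
                              3, (1, 2, 3))
        toy = dataclasses.replace(toy, loop6=(1, 1), loop7=(2, 2), loop10_anchor=7,
                                  ridge_motif="KTRYKLK")
        aln = _manual_alignment("KTR--LK", "KTRYKLK")
        m = map_intervals(aln, toy)
        assert m.loop5 == (1, 5)
        assert sum(1 for t in [aln.column_map[p] for p in range(1, 8)]
                   if t is None) == 2

    def test_reference_mismatch_rejected(self, annotation):
        aln = global_align("KTRYKLK", "KTRYK")
        with pytest.raises(AlignmentError):
            map_intervals(aln, annotation)

    def test_loop10_includes_target_overhang(self, annotation):
        target = annotation.sequence + "GGGGG"
        aln = global_align(target, annotation.sequence)
        m = map_intervals(aln, annotation)
        assert m.loop10_region == (annotation.loop10_anchor, len(target))

    def test_truncated_tail_maps_to_none(self, annotation):
        target = annotation.sequence[:annotation.loop10_anchor - 1]
        aln = global_align(target, annotation.sequence)
        m = map_intervals(aln, annotation)
        assert m.loop10_region is None

    @settings(max_examples=30, deadline=None)
    @given(data=st.data())
    def test_random_pairs_agree_with_column_walk(self, annotation, data):
        """Mapped intervals equal a position-by-position column walk."""
        ref = data.draw(st.text(alphabet="KTRYAG", min_size=8, max_size=16))
        tgt = data.draw(st.text(alphabet="KTRYAG", min_size=4, max_size=16))
        lo = data.draw(st.integers(1, len(ref) - 2))
        hi = data.draw(st.integers(lo, len(ref) - 2))
        toy = _toy_annotation(annotation, ref, (lo, hi),
                              (len(ref) - 1, len(ref) - 1), (len(ref), len(ref)),
                              len(ref), (lo, lo + 1, lo + 2))
        toy = dataclasses.replace(toy, ridge_motif=ref[lo - 1:hi])
        aln = global_align(tgt, ref)
        m = map_intervals(aln, toy)
        hits = [aln.column_map[p] for p in range(lo, hi + 1)
                if aln.column_map[p] is not None]
        assert m.loop5 == ((min(hits), max(hits)) if hits else None)
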