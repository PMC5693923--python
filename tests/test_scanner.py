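import numpy as np
import pytest

from fbgscan import (BoundaryError, FBGDomain, ScanConfig, ScanError, classify,
                     count_cationic, detect_ctail, detect_triad, entry_by_name,
                     scan_catalog, scan_domain, summarize_scan, tile_peptides)
from fbgscan.simulate import SyntheticParams, generate_domain


class TestCountCationic:
    @pytest.mark.parametrize("seq,expected", [
        ("KTRYKLK", 4),   # the loop-5 ridge motif carries four positives
        ("KAKYR", 3),     # the engineered chimera motif carries three
        ("TTTTT", 0),
    ])
    def test_known_motifs(self, seq, expected):
        assert count_cationic(seq, [(1, len(seq))]) == [expected]

    def test_histidine_not_counted(self):
        assert count_cationic("HHHH", [(1, 4)]) == [0]

    def test_out_of_bounds_interval(self):
        with pytest.raises(BoundaryError):
            count_cationic("KTRYK", [(2, 9)])


class TestDetectTriad:
    def test_wild_type_exact(self):
        assert detect_triad("ADXIXNA", (2, 4, 6), ("D", "I", "N"), "exact")

    def test_inactive_residues_fail_both_modes(self):
        # P/L/S, the inactive-domain residues: L and S score positively
        # against I and N but D/P does not, so both modes reject
        assert not detect_triad("APXLXSA", (2, 4, 6), ("D", "I", "N"), "exact")
        assert not detect_triad("APXLXSA", (2, 4, 6), ("D", "I", "N"), "conservative")

    def test_conservative_accepts_positive_blosum_partners(self):
        # E/V/S all score > 0 against D/I/N
        assert not detect_triad("AEXVXSA", (2, 4, 6), ("D", "I", "N"), "exact")
        assert detect_triad("AEXVXSA", (2, 4, 6), ("D", "I", "N"), "conservative")

    def test_gap_absent_position_fails(self):
        assert not detect_triad("ADXIXNA", (2, None, 6), ("D", "I", "N"), "exact")

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            detect_triad("ADIN", (1, 2, 3), mode="liberal")


class TestDetectCtail:
    def test_cationic_tail(self):
        assert detect_ctail("RRKRA", (1, 5)) == (True, 4)

    def test_truncated_tail(self):
        assert detect_ctail("WHATEVER", None) == (False, 0)

    def test_neutral_tail(self):
        assert detect_ctail("AAAAA", (1, 5)) == (False, 0)


class TestClassify:
    @pytest.mark.parametrize("ridge,expected", [(0, False), (2, False),
                                                (3, True), (7, True)])
    def test_threshold_boundary(self, ridge, expected):
        assert classify(ridge) is expected

    def test_monotone_in_ridge_count(self):
        calls = [classify(k) for k in range(8)]
        assert calls == sorted(calls)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify(-1)


class TestScanDomain:
    def test_reference_scans_to_catalogued_profile(self, reference_domain,
                                                   annotation, catalog):
        profile = scan_domain(reference_domain, annotation)
        tnc = entry_by_name(catalog, "Tenascin-C")
        assert profile.ridge_count == tnc.table1_ridge == 7
        assert profile.ridge_count == sum(profile.per_loop_counts)
        assert profile.triad_present and profile.ctail_present
        assert profile.predicted_activator

    def test_unrelated_sequence_rejected(self, annotation):
        junk = FBGDomain(id="junk", sequence="GPGPGP" * 38)
        with pytest.raises(ScanError, match="not an FBG domain"):
            scan_domain(junk, annotation)

    def test_adding_ridge_lysine_never_decreases_count(self, annotation):
        base = generate_domain(SyntheticParams(ridge_positives=3,
                                               background_mutation_rate=0.0),
                               seed=5, annotation=annotation)
        prof = scan_domain(base.domain, annotation)
        seq = list(base.domain.sequence)
        for pos in range(annotation.loop5[0], annotation.loop5[1] + 1):
            mutated = seq.copy()
            mutated[pos - 1] = "K"
            prof2 = scan_domain(FBGDomain(id="m", sequence="".join(mutated)),
                                annotation)
            assert prof2.ridge_count >= prof.ridge_count

    def test_neutralizing_ridge_charge_never_increases_count(self, annotation,
                                                             reference_domain):
        prof = scan_domain(reference_domain, annotation)
        for pos in annotation.ridge_slots:
            seq = list(annotation.sequence)
            seq[pos - 1] = "A"
            prof2 = scan_domain(FBGDomain(id="m", sequence="".join(seq)), annotation)
            assert prof2.ridge_count == prof.ridge_count - 1

    def test_profile_invariant_to_unannotated_positions(self, annotation):
        """Randomizing residues outside the mapped regions changes only
        the alignment-identity metadata, not the extracted features."""
        base = generate_domain(SyntheticParams(ridge_positives=4,
                                               background_mutation_rate=0.0),
                               seed=9, annotation=annotation)
        p1 = scan_domain(base.domain, annotation)
        noisy = generate_domain(SyntheticParams(ridge_positives=4,
                                                background_mutation_rate=0.3,
                                                conservative_only=False),
                                seed=9, annotation=annotation)
        p2 = scan_domain(noisy.domain, annotation)
        assert (p1.ridge_count, p1.triad_present, p1.ctail_present,
                p1.predicted_activator) == \
            (p2.ridge_count, p2.triad_present, p2.ctail_present,
             p2.predicted_activator)
        assert p2.identity_to_reference < p1.identity_to_reference


class TestScanCatalog:
    def test_empty_sequence_set_skips_everything(self, catalog, annotation):
        report = scan_catalog(catalog, {}, annotation)
        assert len(report) == 24
        assert (report["note"] == "no sequence; skipped").all()
        assert summarize_scan(report)["n_skipped"] == 24

    def test_full_standin_scan_concordant(self, catalog, standin_records,
                                          annotation):
        report = scan_catalog(catalog, standin_records, annotation)
        assert report["concordant_ridge"].all()
        assert report["concordant_prediction"].all()
        summary = summarize_scan(report)
        assert summary["activators_tenascin"] == 3
        assert summary["activators_other"] == 10


class TestTilePeptides:
    def test_reference_yields_nine_windows(self, reference_domain, annotation):
        windows = tile_peptides(reference_domain, annotation)
        assert len(windows) == 9
        assert windows[0].start == 1
        assert windows[-1].end == len(reference_domain.sequence)

    def test_windows_tile_in_order_with_overlap(self, reference_domain, annotation):
        windows = tile_peptides(reference_domain, annotation)
        for prev, cur in zip(windows, windows[1:]):
            assert cur.start > prev.start
            assert cur.start <= prev.end + 1  # covering, with overlap

    def test_only_the_two_ridge_windows_are_active(self, reference_domain,
                                                   annotation):
        windows = tile_peptides(reference_domain, annotation)
        active = [w.index for w in windows if w.predicted_active]
        assert len(active) == 2
        assert active[1] == active[0] + 1  # consecutive, as for the real peptides

    def test_window_longer_than_domain_errors(self, annotation):
        short = FBGDomain(id="s", sequence=annotation.sequence[:20])
        with pytest.raises(BoundaryError):
            tile_peptides(short, annotation, length=30)
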