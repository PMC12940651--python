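"""Profile construction, PSSM scanning, E-value calibration, architecture calls."""

import math

import numpy as np
import pytest

import famscan as fs
from famscan.domain_scan import (
    CalibrationError,
    DomainHit,
    ProfileError,
    hydropathy_flag,
    window_scores,
)
from famscan.profiles import AA_ORDER, MADS_CONSENSUS, robinson_background


def uniform_bg():
    return np.full(20, 0.05)


class TestBuildProfile:
    def test_identical_sequences_zero_pseudocount(self):
        prof = fs.build_profile(["ACDE"] * 4, pseudocount=0.0, background=uniform_bg())
        bg = 0.05
        for j, letter in enumerate("ACDE"):
            assert prof.weights[j, AA_ORDER.index(letter)] == pytest.approx(
                math.log2(1 / bg)
            )

    def test_two_sequence_toy_alignment(self):
        prof = fs.build_profile(["AC", "AD"], pseudocount=0.0, background=uniform_bg())
        assert prof.weights[0, AA_ORDER.index("A")] == pytest.approx(
            math.log2(1 / 0.05), abs=1e-6
        )  # 4.32 bits
        # position 2: C and D each at frequency 0.5
        assert prof.weights[1, AA_ORDER.index("C")] == pytest.approx(math.log2(10))

    def test_all_gap_column_dropped(self):
        prof = fs.build_profile(["A-C", "A-C", "A-D"], pseudocount=0.5)
        assert prof.length == 2

    @pytest.mark.parametrize("aln", [[], ["ACDE"], ["AC", "ACD"]])
    def test_invalid_alignments_rejected(self, aln):
        with pytest.raises(ProfileError):
            fs.build_profile(aln)

    def test_mostly_gapped_alignment_rejected(self):
        with pytest.raises(ProfileError, match="50%"):
            fs.build_profile(["A---", "A---", "C---"])


class TestScan:
    def test_planted_consensus_found_at_position(self, profiles):
        prof = profiles["MADS"]
        rng = np.random.default_rng(5)
        bg = robinson_background()
        for p in (0, 13, 40):
            prot = (
                "".join(rng.choice(list(AA_ORDER), p, p=bg))
                + prof.consensus
                + "".join(rng.choice(list(AA_ORDER), 25, p=bg))
            )
            hits = fs.scan_sequence(prof, prot, evalue=1e-3)
            assert hits and hits[0].start == p and hits[0].end == p + prof.length

    def test_consensus_protein_scores_column_maxima_sum(self, profiles):
        prof = profiles["MADS"]
        hits = fs.scan_sequence(prof, prof.consensus, evalue=1e-3)
        assert len(hits) == 1
        assert hits[0].score == pytest.approx(prof.max_score)
        assert (hits[0].start, hits[0].end) == (0, prof.length)

    def test_short_protein_returns_empty(self, profiles):
        assert fs.scan_sequence(profiles["MADS"], "ACDEFG") == []

    def test_illegal_character_rejected(self, profiles):
        with pytest.raises(ProfileError, match="illegal"):
            fs.scan_sequence(profiles["MADS"], "B" * 100)

    def test_x_scored_zero(self, profiles):
        prof = profiles["K1"]
        base = window_scores(prof, prof.consensus)[0]
        with_x = "X" + prof.consensus[1:]
        assert window_scores(prof, with_x)[0] == pytest.approx(
            base - prof.weights[0].max()
        )

    def test_window_scores_match_bruteforce(self, profiles):
        """Vectorized scores equal an exhaustive per-window sum on proteins <=200 aa."""
        prof = profiles["K2"]
        rng = np.random.default_rng(7)
        bg = robinson_background()
        for _ in range(5):
            prot = "".join(rng.choice(list(AA_ORDER), int(rng.integers(40, 200)), p=bg))
            fast = window_scores(prof, prot)
            for i in range(len(prot) - prof.length + 1):
                brute = sum(
                    prof.weights[j, AA_ORDER.index(prot[i + j])]
                    for j in range(prof.length)
                )
                assert fast[i] == pytest.approx(brute)

    def test_translation_invariance(self, profiles):
        prof = profiles["MADS"]
        rng = np.random.default_rng(11)
        bg = robinson_background()
        core = prof.consensus + "".join(rng.choice(list(AA_ORDER), 30, p=bg))
        base = fs.scan_sequence(prof, core, evalue=1e-3)
        k = 17
        shifted = "".join(rng.choice(list(AA_ORDER), k, p=bg)) + core
        moved = fs.scan_sequence(prof, shifted, evalue=1e-3)
        assert [h.start + k for h in base] == [h.start for h in moved]

    def test_threshold_monotonicity(self, profiles):
        prof = profiles["MADS"]
        rng = np.random.default_rng(13)
        bg = robinson_background()
        prot = (
            prof.consensus
            + "".join(rng.choice(list(AA_ORDER), 60, p=bg))
            + prof.consensus
        )
        counts = [
            len(fs.scan_sequence(prof, prot, evalue=e)) for e in (1.0, 1e-1, 1e-3, 1e-6)
        ]
        assert counts == sorted(counts, reverse=True)


class TestCalibration:
    def test_deterministic_given_seed(self):
        prof1 = fs.build_profile(fs.domain_scan.seed_alignment("K1"), name="K1")
        prof2 = fs.build_profile(fs.domain_scan.seed_alignment("K1"), name="K1")
        a = fs.calibrate_evalue(prof1, n_shuffles=150, length=120, seed=99)
        b = fs.calibrate_evalue(prof2, n_shuffles=150, length=120, seed=99)
        assert a == b

    def test_evalue_closed_form_at_mu(self, profiles):
        prof = profiles["MADS"]
        assert prof.evalue(prof.gumbel_mu, database_size=1) == pytest.approx(
            1 - math.exp(-1), rel=1e-6
        )

    def test_threshold_inverts_evalue(self, profiles):
        prof = profiles["MADS"]
        s = prof.score_threshold(1e-3, database_size=500)
        assert prof.evalue(s, database_size=500) == pytest.approx(1e-3, rel=1e-6)

    def test_degenerate_distribution_raises(self):
        flat = fs.ProfileMatrix(
            name="flat", weights=np.zeros((5, 20)), background=np.full(20, 0.05)
        )
        with pytest.raises(CalibrationError):
            fs.calibrate_evalue(flat, n_shuffles=150, length=50, seed=1)

    def test_too_few_shuffles_rejected(self, profiles):
        with pytest.raises(ProfileError):
            fs.calibrate_evalue(profiles["K3"], n_shuffles=10, length=100, seed=1)


def hit(profile, start, pid="p1", score=50.0):
    length = {"MADS": 57, "K1": 29, "K2": 29, "K3": 29}[profile]
    return DomainHit(pid, profile, start, start + length, score, 1e-9)


class TestArchitecture:
    def test_full_mikc_structure_is_type_ii(self):
        hits = [hit("MADS", 10), hit("K1", 80), hit("K2", 115), hit("K3", 150)]
        call = fs.call_architecture(hits, exon_count=6)
        assert call.type_call == "TypeII"
        assert call.k_segments_found == 3
        assert not call.reannotation_flag

    def test_mads_only_single_exon_is_type_i(self):
        call = fs.call_architecture([hit("MADS", 5)], exon_count=1)
        assert call.type_call == "TypeI" and not call.reannotation_flag

    def test_single_k_segment_flags_short_k_domain(self):
        call = fs.call_architecture([hit("MADS", 5), hit("K3", 90)], exon_count=6)
        assert call.type_call == "unclassified"
        assert call.reannotation_flag and "K domain too short" in call.reason

    def test_multi_exon_without_k_flags_reannotation(self):
        call = fs.call_architecture([hit("MADS", 5)], exon_count=7)
        assert call.reannotation_flag and call.type_call == "unclassified"

    def test_no_mads_is_unclassified_not_error(self):
        call = fs.call_architecture([hit("K1", 5)], exon_count=1)
        assert call.type_call == "unclassified" and call.reason == "no MADS domain"

    def test_k_segments_upstream_of_mads_do_not_count(self):
        hits = [hit("K1", 0), hit("K2", 30), hit("MADS", 70)]
        call = fs.call_architecture(hits, exon_count=1)
        assert call.type_call == "TypeI"

    def test_mixed_protein_ids_rejected(self):
        with pytest.raises(ProfileError):
            fs.call_architecture([hit("MADS", 0, "a"), hit("K1", 60, "b")], 6)


def test_hydropathy_flag_detects_hydrophobic_stretch():
    assert hydropathy_flag("M" + "I" * 25 + "DDDDEEEE" * 5)
    assert not hydropathy_flag("DEKR" * 20)
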