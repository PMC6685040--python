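"""Sequence toolkit: alignment, scoring, numbering, motifs, topology."""

import numpy as np
import pytest

from conftest import best_alignment_score_bruteforce
from mc4rkit.sequences import (AnchorNotFoundError, PairwiseAlignment,
                               SequenceRecord, TopologyAnnotation,
                               align_pair, assign_bw_numbers,
                               assign_topology, detect_motifs,
                               find_anchors_by_motif, load_anchors,
                               load_boundaries, load_pocket,
                               percent_identity, percent_similarity,
                               pocket_conservation_check)


def rec(s, ident="seq"):
    return SequenceRecord(id=ident, residues=s)


class TestAlignPair:
    def test_identity_alignment_has_all_match_columns(self):
        aln = align_pair(rec("ACD"), rec("ACD"))
        assert aln.columns == [(1, 1), (2, 2), (3, 3)]
        assert percent_identity(aln) == 100.0

    def test_single_gap_placed_at_mismatched_middle_position(self):
        aln = align_pair(rec("ACD"), rec("AD"))
        assert aln.columns == [(1, 1), (2, None), (3, 2)]

    def test_score_matches_exhaustive_enumeration_on_short_sequences(self):
        rng = np.random.default_rng(11)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(25):
            a = "".join(rng.choice(aas, rng.integers(1, 6)))
            b = "".join(rng.choice(aas, rng.integers(1, 6)))
            aln = align_pair(rec(a), rec(b))
            assert aln.score == pytest.approx(
                best_alignment_score_bruteforce(a, b))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            SequenceRecord(id="x", residues="")

    def test_unknown_matrix_rejected(self):
        with pytest.raises(ValueError, match="matrix"):
            align_pair(rec("ACD"), rec("ACD"), matrix="NOSUCH62")


class TestPercentIdentitySimilarity:
    def test_planted_mismatch_fraction_recovered(self):
        rng = np.random.default_rng(5)
        a = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 100))
        b = list(a)
        mutated = rng.choice(100, size=30, replace=False)
        for i in mutated:
            b[i] = "W" if a[i] != "W" else "Y"
        aln = PairwiseAlignment(a=rec(a, "a"), b=rec("".join(b), "b"),
                                columns=[(i + 1, i + 1) for i in range(100)])
        assert percent_identity(aln) == pytest.approx(70.0)

    def test_conservative_substitution_counts_as_similar_only(self):
        # D↔E scores +2 in BLOSUM62 (similar); D↔K scores -1 (not)
        aln_de = PairwiseAlignment(a=rec("D"), b=rec("E"), columns=[(1, 1)])
        aln_dk = PairwiseAlignment(a=rec("D"), b=rec("K"), columns=[(1, 1)])
        assert percent_similarity(aln_de) == 100.0
        assert percent_identity(aln_de) == 0.0
        assert percent_similarity(aln_dk) == 0.0

    def test_similarity_never_below_identity(self):
        rng = np.random.default_rng(7)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(20):
            a = "".join(rng.choice(aas, 40))
            b = "".join(rng.choice(aas, 40))
            aln = align_pair(rec(a, "a"), rec(b, "b"))
            assert percent_similarity(aln) >= percent_identity(aln)

    def test_gap_only_restriction_errors(self):
        aln = PairwiseAlignment(a=rec("A"), b=rec("C"),
                                columns=[(1, None), (None, 1)])
        with pytest.raises(ValueError):
            percent_identity(aln)


class TestTopology:
    def test_default_hmc4r_loop_sizes(self, hmc4r, topology):
        assert topology.size("ICL1") == 8
        assert topology.size("ICL2") == 13
        assert topology.size("ECL2") == 4

    def test_regions_partition_the_sequence(self, hmc4r, topology):
        total = sum(topology.size(label)
                    for label, _, _ in topology.regions)
        assert total == len(hmc4r)
        labels = [topology.label_of(n) for n in hmc4r.numbers]
        assert len(labels) == len(hmc4r)  # every residue labeled once

    def test_non_contiguous_boundaries_rejected(self, hmc4r):
        bad = [("Ntt", 1, 39), ("TMH1", 41, 332)]  # residue 40 unlabeled
        with pytest.raises(ValueError, match="contiguous"):
            assign_topology(hmc4r, bad)

    def test_incomplete_coverage_rejected(self, hmc4r):
        short = load_boundaries()[:-1]
        with pytest.raises(ValueError):
            assign_topology(hmc4r, short)


class TestBWNumbering:
    def test_hmc4r_landmark_positions(self, bw):
        assert bw.bw(90) == "2.50"
        assert bw.bw(298) == "7.49"
        assert bw.position_of("3.50") == 147

    def test_anchor_maps_to_h50_and_offsets_are_contiguous(self, bw,
                                                           topology):
        for helix, anchor in load_anchors().items():
            assert bw.bw(anchor) == f"{helix}.50"
            start, end = topology.span(f"TMH{helix}")
            numbers = [int(bw.bw(n).split(".")[1])
                       for n in range(start, end + 1)]
            assert numbers == list(range(numbers[0], numbers[0]
                                         + end - start + 1))

    def test_motif_search_recovers_shipped_anchors(self, hmc4r, topology):
        found = find_anchors_by_motif(hmc4r, topology)
        expected = load_anchors()
        # helix 5 has no motif (no P5.50 in melanocortin receptors)
        assert found == {h: p for h, p in expected.items() if h != 5}

    def test_missing_anchor_reports_the_helix(self, topology):
        polya = SequenceRecord(id="polyA", residues="A" * 332)
        with pytest.raises(AnchorNotFoundError) as err:
            find_anchors_by_motif(polya, topology)
        assert err.value.helix in range(1, 8)

    def test_planted_anchor_numbered_h50(self, hmc4r):
        topo = TopologyAnnotation([("TMH1", 1, 21)])
        seq = SequenceRecord(id="t", residues="A" * 21)
        ann = assign_bw_numbers(seq, {1: 11}, topo)
        assert ann.bw(11) == "1.50"
        assert ann.bw(1) == "1.40"
        assert ann.bw(21) == "1.60"


class TestMotifs:
    def test_hmc4r_carries_dpxxy_not_npxxy(self, hmc4r, topology):
        report = detect_motifs(hmc4r, topology, load_anchors())
        assert report["tm7_class"] == "DPxxY"
        assert report["tm7_motif"].start == 298

    def test_hmc4r_n_terminal_motif_and_regular_tmh5(self, hmc4r, topology):
        report = detect_motifs(hmc4r, topology, load_anchors())
        assert (report["n_terminal_motif"].start,
                report["n_terminal_motif"].end) == (14, 19)
        assert report["position_5_50"] == "M"
        assert "regular" in report["tmh5_geometry"]

    def test_rhodopsin_like_npxxy_detected(self):
        report = detect_motifs(rec("AAANPVIYAAA"))
        assert report["tm7_class"] == "NPxxY"

    def test_absent_motifs_reported_as_absent(self):
        report = detect_motifs(rec("AAAAAAAA"))
        assert report["tm7_class"] == "absent"
        assert report["n_terminal_motif"] is None


class TestPocketConservation:
    def test_surrogate_set_conserves_agonist_pocket(self, surrogates):
        seqs, _ = surrogates
        table = pocket_conservation_check(
            [seqs["hMC4R"], seqs["zfMC4R"], seqs["zfMC2R"]],
            load_pocket("msh_binding"))
        assert [row["status"] for row in table] == ["identical"] * 6

    def test_single_sequence_is_trivially_identical(self, hmc4r):
        table = pocket_conservation_check([hmc4r], [100, 126])
        assert all(row["status"] == "identical" for row in table)

    def test_planted_divergent_and_similar_columns(self):
        a = rec("AAADAAAKAA", "a")
        b = rec("AAAEAAAWAA", "b")  # D→E similar; K→W divergent
        table = pocket_conservation_check([a, b], [4, 8])
        assert table[0]["status"] == "similar"
        assert table[1]["status"] == "divergent"

    def test_position_outside_reference_errors(self, hmc4r):
        with pytest.raises(KeyError):
            pocket_conservation_check([hmc4r, hmc4r], [999])
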