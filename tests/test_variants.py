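"""Variant curation, summary arithmetic, and structural classification."""

import pytest

from mc4rkit import synth
from mc4rkit.sequences import load_pocket
from mc4rkit.variants import (classify_structural_context, curate,
                              parse_variant, region_report, summarize)


class TestParsing:
    @pytest.mark.parametrize("text,kind", [
        ("D90N", "substitution"), ("Y35X", "stop"), ("Y35*", "stop"),
        ("ΔI125", "deletion"), ("I125del", "deletion"),
        ("D37V/I102T", "double"),
    ])
    def test_grammar_kinds(self, text, kind):
        assert parse_variant(text)["kind"] == kind

    def test_substitution_fields(self):
        parsed = parse_variant("D90N")
        assert (parsed["wt"], parsed["position"], parsed["mut"]) \
            == ("D", 90, "N")

    @pytest.mark.parametrize("text", ["", "90N", "D90", "D-90-N", "foo"])
    def test_unparseable_strings_rejected(self, text):
        with pytest.raises(ValueError):
            parse_variant(text)


class TestCuration:
    def test_stops_deletions_doubles_filtered(self):
        rows = [{"variant": v} for v in
                ["D90N", "S58C", "P78L", "G98R", "I317T",    # 5 keepers
                 "Y35X", "W258X", "ΔI125", "D37V/I102T"]]
        records, rejected = curate(rows)
        assert len(records) == 5
        assert len(rejected) == 4
        reasons = [reason for _, reason in rejected]
        assert sum("stop" in r for r in reasons) == 2
        assert sum("deletion" in r for r in reasons) == 1
        assert sum("double" in r for r in reasons) == 1

    def test_conflicting_reports_merge_to_contradictory(self):
        rows = [{"variant": "D90N", "camp": "=", "source": "a"},
                {"variant": "D90N", "binding": "down", "source": "b"}]
        records, _ = curate(rows)
        assert len(records) == 1
        assert records[0].functional_class == "contradictory"
        assert records[0].sources == ["a", "b"]

    def test_same_class_duplicates_merge_without_conflict(self):
        rows = [{"variant": "D90N", "camp": "down", "source": "a"},
                {"variant": "D90N", "expression": "down", "source": "b"}]
        records, _ = curate(rows)
        assert len(records) == 1
        assert records[0].functional_class == "decreased"

    def test_wild_type_mismatch_rejected_against_reference(self, hmc4r):
        records, rejected = curate([{"variant": "A90N"}], sequence=hmc4r)
        assert records == []
        assert "mismatch" in rejected[0][1]

    def test_basal_only_evidence_is_increased_basal(self):
        records, _ = curate([{"variant": "H158R", "basal": "up"}])
        assert records[0].functional_class == "increased_basal"
        assert records[0].basal_increased


class TestSummaryArithmetic:
    def test_empty_input_gives_zero_summary(self):
        s = summarize([])
        assert (s.n_variants, s.n_positions, s.n_no_data, s.n_like_wt,
                s.n_decreased, s.n_contradictory) == (0,) * 6

    def test_overlap_identity_on_many_random_tables(self, hmc4r):
        rng_counts = []
        import numpy as np
        rng = np.random.default_rng(0)
        for seed in range(1000):
            n = int(rng.integers(5, 40))
            contr = int(rng.integers(0, n // 3 + 1))
            nd = int(rng.integers(0, n - contr + 1))
            rest = n - contr - nd
            lw_only = int(rng.integers(0, rest + 1))
            dec_only = rest - lw_only
            counts = (nd, lw_only + contr, dec_only + contr, contr)
            n_pos = int(rng.integers((n + 18) // 19, n + 1))
            rows, manifest = synth.make_variant_table(
                n, n_pos, counts, seed=seed, sequence=hmc4r)
            records, rejected = curate(rows, sequence=hmc4r)
            assert rejected == []
            s = summarize(records)
            assert s.overlap_identity_holds
            planted = manifest["counts"]
            assert (s.n_no_data, s.n_like_wt, s.n_decreased,
                    s.n_contradictory) == (planted["no_data"],
                                           planted["like_wt"],
                                           planted["decreased"],
                                           planted["contradictory"])
            assert s.n_variants == n and s.n_positions == n_pos
            rng_counts.append(n)
        assert len(rng_counts) == 1000


@pytest.fixture(scope="module")
def curated(hmc4r, topology):
    rows, manifest = synth.make_sm1_like_table(seed=0)
    records, rejected = curate(rows, sequence=hmc4r)
    return records, rejected, manifest, summarize(records, topology)


class TestSm1Table:
    def test_headline_counts(self, curated):
        _, _, _, s = curated
        assert s.n_variants == 165
        assert s.n_positions == 129
        assert (s.n_no_data, s.n_like_wt, s.n_decreased,
                s.n_contradictory) == (24, 71, 92, 22)
        assert s.overlap_identity_holds

    def test_excluded_rows_rejected(self, curated):
        _, rejected, manifest, _ = curated
        assert len(rejected) == manifest["n_excluded_rows"]

    def test_loop_and_nterminal_region_tallies(self, curated):
        _, _, _, s = curated
        assert s.per_region["Ntt"]["n_variants"] == 21
        assert s.per_region["Ntt"]["n_positions"] == 14
        assert s.per_region["ICL1"]["n_positions"] == 5
        assert s.per_region["ICL1"]["region_size"] == 8
        assert s.per_region["ICL2"]["n_positions"] == 6
        assert s.per_region["ICL2"]["region_size"] == 13
        assert s.per_region["ICL3"]["n_variants"] == 7
        assert s.per_region["ICL3"]["n_positions"] == 6

    def test_position_counts_sum_over_regions(self, curated):
        _, _, _, s = curated
        assert sum(r["n_positions"] for r in s.per_region.values()) \
            == s.n_positions

    def test_named_variants_keep_their_reported_classes(self, curated):
        records, _, manifest, _ = curated
        by_name = {r.name: r for r in records}
        for name in manifest["named_decreased"]:
            assert by_name[name].functional_class == "decreased", name
        cam = by_name[manifest["named_cam"]]
        assert cam.functional_class == "like_wt"
        assert cam.basal_increased


@pytest.fixture(scope="module")
def annotations(topology, bw):
    return load_pocket("variant_sensitive"), topology, bw


class TestStructuralContext:
    @pytest.mark.parametrize("variant,expected", [
        ("D126Y", "ligand_binding"),     # pocket residue
        ("D90N", "TM_microdomain"),      # 2.50 sodium-site aspartate
        ("H76R", "gprotein_interface"),  # ICL1
        ("G32S", "ligand_binding"),      # N-terminal but in the pocket set
        ("S30F", "other"),               # plain N-terminal tail
    ])
    def test_classification_precedence(self, annotations, hmc4r,
                                       variant, expected):
        pocket, topology, bw = annotations
        records, _ = curate([{"variant": variant}], sequence=hmc4r)
        ctx = classify_structural_context(records[0], pocket, [],
                                          topology, bw)
        assert ctx.label == expected

    def test_classification_total_on_full_table(self, annotations, hmc4r):
        pocket, topology, bw = annotations
        rows, _ = synth.make_sm1_like_table(seed=0)
        records, _ = curate(rows, sequence=hmc4r)
        labels = {classify_structural_context(r, pocket, [], topology,
                                              bw).label for r in records}
        assert labels <= {"ligand_binding", "gprotein_interface",
                          "TM_microdomain", "other"}

    def test_region_report_single_variant(self, hmc4r, topology):
        records, _ = curate([{"variant": "D90N"}], sequence=hmc4r)
        rows = region_report(records, topology)
        assert rows == [{"region": "TMH2", "region_size": 26,
                         "n_variants": 1, "n_positions": 1,
                         "no_data": 1, "like_wt": 0, "decreased": 0,
                         "increased_basal": 0, "contradictory": 0}]
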