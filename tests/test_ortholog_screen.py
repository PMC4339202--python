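import math
from itertools import combinations

import pandas as pd
import pytest

from lossmark import (
    ConfigError,
    category_enrichment,
    classify_residual_hit,
    collapse_paralogs,
    evalue_bins,
    merge_screens,
    pfam_complement_screen,
    run_screen,
    stage1_dikarya_filter,
    stage2_choano_filter,
    stage3_holozoa_filter,
    stage4_animal_comparison,
)
from lossmark.io_core import BlastHitTable
from lossmark.ortholog_screen import adjust_bh

from conftest import make_matrix

INF = math.inf


class TestStages:
    def test_stage1_keeps_dikarya_only_genes(self, small_matrix, panel):
        kept = stage1_dikarya_filter(small_matrix, panel)
        assert "lostA" in kept and "retained" not in kept

    def test_stage1_accepts_lineage_specific_duplication(self, panel):
        m = make_matrix(
            panel,
            {"dup": {t: 1e-80 for t in panel.dikarya}},
            flags={"dup": {"P_graminis": "one2many"}},
        )
        assert stage1_dikarya_filter(m, panel) == {"dup"}

    def test_stage1_missing_flag_names_gene_and_taxon(self, panel):
        m = make_matrix(panel, {"g": {}})
        m.ortho_flags.loc["g", "S_pombe"] = None
        with pytest.raises(ConfigError, match="'g'.*'S_pombe'"):
            stage1_dikarya_filter(m, panel)

    @pytest.mark.parametrize(
        "evalue,kept",
        [(1e-35, True), (1e-30, False), (INF, False)],  # threshold strict: "lower than"
    )
    def test_stage2_strict_threshold(self, panel, evalue, kept):
        m = make_matrix(panel, {"g": {panel.choano_primary: evalue}})
        assert (stage2_choano_filter({"g"}, m, panel) == {"g"}) is kept

    @pytest.mark.parametrize(
        "rosetta,capsaspora,kept",
        [(1e-12, 1e-40, True), (1e-12, INF, False), (1e-9, 1e-40, False)],
    )
    def test_stage3_requires_both_holozoans(self, panel, rosetta, capsaspora, kept):
        m = make_matrix(
            panel, {"g": {"S_rosetta": rosetta, "C_owczarzaki": capsaspora}}
        )
        assert (stage3_holozoa_filter({"g"}, m, panel) == {"g"}) is kept

    @pytest.mark.parametrize(
        "animal,holo,kept",
        [(1e-50, 1e-40, False), (1e-20, 1e-40, True), (INF, 1e-40, True)],
    )
    def test_stage4_best_animal_vs_best_holozoan(self, panel, animal, holo, kept):
        m = make_matrix(
            panel,
            {"g": {panel.choano_primary: holo,
                   "S_rosetta": 1e-12, "C_owczarzaki": 1e-12,
                   "T_adhaerens": animal}},
        )
        assert (stage4_animal_comparison({"g"}, m, panel) == {"g"}) is kept

    def test_stage4_worst_mode_drops_more(self, panel):
        # animal between the best and worst holozoan E-values:
        # kept under 'best' (does not beat 1e-60), dropped under 'worst'
        m = make_matrix(
            panel,
            {"g": {panel.choano_primary: 1e-60,
                   "S_rosetta": 1e-12, "C_owczarzaki": 1e-12,
                   "T_adhaerens": 1e-30}},
        )
        assert stage4_animal_comparison({"g"}, m, panel, mode="best") == {"g"}
        assert stage4_animal_comparison({"g"}, m, panel, mode="worst") == set()

    def test_stage_outputs_are_nested(self, small_matrix, panel):
        result = run_screen(small_matrix, panel)
        s = result.stage_sets
        assert s[1] >= s[2] >= s[3] >= s[4]
        assert result.final == {"lostA"}


class TestCollapseParalogs:
    def test_27_genes_with_3_pairs_give_24_functions(self):
        genes = [f"G{i}" for i in range(21)] + ["TRR1", "TRR2", "LYS20", "LYS21", "SCT1", "GPT2"]
        groups = [{"TRR1", "TRR2"}, {"LYS20", "LYS21"}, {"SCT1", "GPT2"}]
        functions = collapse_paralogs(genes, groups)
        assert len(functions) == 24
        assert "TRR1/TRR2" in functions

    def test_no_groups_is_identity(self):
        assert collapse_paralogs({"a", "b"}, []) == ["a", "b"]

    def test_partial_group_emits_survivor_only(self):
        assert collapse_paralogs({"A"}, [{"A", "B"}]) == ["A"]

    def test_gene_in_two_groups_is_error(self):
        with pytest.raises(ConfigError, match="two paralog groups"):
            collapse_paralogs({"A"}, [{"A", "B"}, {"A", "C"}])

    def test_idempotent_and_bounded(self):
        genes = {"a", "b", "c", "d"}
        groups = [{"a", "b"}]
        once = collapse_paralogs(genes, groups)
        assert len(once) <= len(genes)
        assert collapse_paralogs(set(once) - {"a/b"} | {"a", "b"}, groups) == once


class TestClassifyResidualHit:
    def test_non_opisthokont_taxon_means_contaminant(self):
        assert (
            classify_residual_hit("HSP104", 1e-30, "gamma_proteobacteria", None)
            == "contaminant_or_hgt"
        )

    def test_reciprocal_family_mismatch_means_non_ortholog(self):
        assert classify_residual_hit("LYS4", 1e-25, None, "ACO1") == "non_ortholog"

    def test_no_animal_hit(self):
        assert classify_residual_hit("TRP5", None, None, None) == "no_hit"

    def test_contradictory_inputs_rejected(self):
        with pytest.raises(ConfigError):
            classify_residual_hit("g", None, "gamma_proteobacteria", None)

    def test_weak_match_with_opisthokont_origin_is_possible_ortholog(self):
        assert classify_residual_hit("HIS2", 1e-22, "C_owczarzaki", "HIS2") == "possible_ortholog"


class TestPfamComplement:
    @staticmethod
    def _hits(evalue):
        frame = pd.DataFrame(
            [{"query_id": "repPURB", "subject_id": "mb1", "subject_taxon": "M_brevicollis",
              "evalue": evalue, "bitscore": 400.0, "aln_len": 400}]
        )
        return BlastHitTable(frame)

    def _table(self, animal_present=False):
        return pd.DataFrame(
            {
                "D_discoideum": [True],
                "M_brevicollis": [True],
                "H_sapiens": [animal_present],
                "S_cerevisiae": [False],
            },
            index=["PF08238"],
        )

    def test_domain_reported_when_absent_in_animals(self):
        out = pfam_complement_screen(
            self._table(), self._hits(2e-129),
            present_taxa=["D_discoideum", "M_brevicollis"],
            absent_taxa=["H_sapiens", "S_cerevisiae"],
            domain_queries={"PF08238": "repPURB"},
            hit_taxa=["M_brevicollis"],
        )
        assert out == ["PF08238"]

    def test_domain_present_in_an_animal_is_excluded(self):
        out = pfam_complement_screen(
            self._table(animal_present=True), self._hits(2e-129),
            present_taxa=["D_discoideum", "M_brevicollis"],
            absent_taxa=["H_sapiens"],
            domain_queries={"PF08238": "repPURB"},
            hit_taxa=["M_brevicollis"],
        )
        assert out == []

    def test_domain_without_representative_is_skipped(self):
        out = pfam_complement_screen(
            self._table(), self._hits(2e-129),
            present_taxa=["D_discoideum"], absent_taxa=["H_sapiens"],
            domain_queries={}, hit_taxa=["M_brevicollis"],
        )
        assert out == []

    def test_weak_hit_fails_threshold(self):
        out = pfam_complement_screen(
            self._table(), self._hits(1e-20),
            present_taxa=["D_discoideum"], absent_taxa=["H_sapiens"],
            domain_queries={"PF08238": "repPURB"}, hit_taxa=["M_brevicollis"],
        )
        assert out == []

    def test_merge_24_functions_with_6_gene_list_sharing_5_gives_25(self):
        functions = [f"F{i}" for i in range(19)] + [
            "TRR1/TRR2", "HSP104", "HSP78", "GDH2", "PAN6",
        ]
        assert len(functions) == 24
        alternates = ["GDH2", "HSP104", "HSP78", "PAN6", "PURB", "TRR1"]
        merged = merge_screens(functions, alternates)
        assert len(merged) == 25
        assert "PURB" in merged


class TestEvalueBins:
    def test_binning(self):
        m = pd.DataFrame({"t": [1e-150, 1e-100, 1e-50, 1e-5, INF]},
                         index=list("abcde"))
        out = evalue_bins(m)
        assert list(out["t"]) == [0, 0, 1, 4, "absent"]

    def test_boundary_falls_in_stronger_bin(self):
        m = pd.DataFrame({"t": [1e-30]}, index=["a"])
        assert evalue_bins(m)["t"].iloc[0] == 1

    def test_non_monotone_breakpoints_rejected(self):
        with pytest.raises(ConfigError):
            evalue_bins(pd.DataFrame({"t": [1e-5]}), breakpoints=[1e-10, 1e-50])


def brute_force_tail(background, category, selected_size, observed):
    """Exact P(overlap >= observed) by enumerating all draws."""
    draws = list(combinations(sorted(background), selected_size))
    hits = sum(1 for d in draws if len(set(d) & category) >= observed)
    return hits / len(draws)


class TestEnrichment:
    def test_known_exact_value(self):
        # background 20, category 5, all 4 selected in category: p = 5/4845
        background = [f"g{i}" for i in range(20)]
        category = background[:5]
        selected = background[:4]
        overlap, p = category_enrichment(selected, background, category)
        assert overlap == 4
        assert p == pytest.approx(5 / 4845, rel=1e-12)

    def test_zero_overlap_has_large_p(self):
        background = [f"g{i}" for i in range(20)]
        overlap, p = category_enrichment(background[10:12], background, background[:2])
        assert overlap == 0 and p >= 0.5

    @pytest.mark.parametrize("n_bg", [4, 6, 8, 10, 12])
    def test_matches_brute_force_enumeration(self, n_bg):
        background = set(f"g{i}" for i in range(n_bg))
        category = set(list(sorted(background))[: n_bg // 2])
        for sel_size in (1, n_bg // 3 + 1, n_bg // 2):
            selected = set(list(sorted(background))[-sel_size:])
            overlap, p = category_enrichment(selected, background, category)
            expected = brute_force_tail(background, category, sel_size, overlap)
            assert p == pytest.approx(expected, rel=1e-9)

    def test_selected_equals_category(self):
        background = set(f"g{i}" for i in range(10))
        category = set(list(sorted(background))[:3])
        overlap, p = category_enrichment(category, background, category)
        assert overlap == 3
        assert p == pytest.approx(brute_force_tail(background, category, 3, 3), rel=1e-9)

    def test_empty_background_rejected(self):
        with pytest.raises(ConfigError):
            category_enrichment([], [], [])


def test_bh_adjustment_monotone_and_bounded():
    raw = [0.001, 0.01, 0.02, 0.8]
    adj = adjust_bh(raw)
    assert all(a >= r for a, r in zip(adj, raw))
    assert all(0 < a <= 1 for a in adj)
    assert adj[0] == pytest.approx(0.004)
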