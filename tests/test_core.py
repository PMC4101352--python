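"""Candidate→target mapping, replicated/novel classification and ratios."""

import numpy as np
import pytest

from drugrepo import (
    Phenotype,
    build_phenotype_report,
    classify_target,
    enumerate_novel_drugs,
    indication_matches,
    load_known_therapeutics,
    load_synonyms,
    map_candidates_to_targets,
    novelty_ratio,
    stratify_status,
    targetability_index,
)
from drugrepo.core import (
    competition_ranks,
    phenotype_candidate_union,
    read_candidates,
    round_half_up,
    shared_synonyms,
)
from tests.conftest import make_unified

SYN = load_synonyms()


class TestIndicationMatching:
    @pytest.mark.parametrize(
        "indication,code,expected",
        [
            ("Diabetes mellitus", "T1D", True),  # unqualified diabetes counts for T1D
            ("Diabetes mellitus", "T2D", True),  # ... and for T2D
            ("Type 2 diabetes mellitus", "T2D", True),
            ("Peptic ulcer disease", "T2D", False),
            ("pulmonary hypertension", "HT", True),  # whole-word substring
            ("hypertensionx", "HT", False),  # no partial-word match
            ("Crohn's disease", "CD", True),
            ("", "CD", False),
        ],
    )
    def test_whole_word_case_insensitive(self, indication, code, expected):
        assert indication_matches(indication, SYN[code].synonyms) is expected

    def test_diabetes_synonym_is_shared_between_types(self):
        shared = shared_synonyms(SYN)
        assert set(shared["diabetes mellitus"]) == {"T1D", "T2D"}


class TestRatios:
    @pytest.mark.parametrize(
        "tt,cand,expected",
        [(84, 291, 0.29), (102, 264, 0.39), (0, 100, 0.00), (97, 358, 0.27)],
    )
    def test_targetability_index(self, tt, cand, expected):
        assert targetability_index(tt, cand).rounded == expected

    @pytest.mark.parametrize(
        "novel,tt,expected", [(135, 135, 1.00), (77, 84, 0.92), (0, 5, 0.00)]
    )
    def test_novelty_ratio(self, novel, tt, expected):
        assert novelty_ratio(novel, tt).rounded == expected

    def test_undefined_denominators_fail_hard(self):
        with pytest.raises(ValueError):
            targetability_index(1, 0)
        with pytest.raises(ValueError):
            novelty_ratio(0, 0)
        with pytest.raises(ValueError):
            targetability_index(5, 4)

    def test_half_up_rounding(self):
        assert round_half_up(0.385) == 0.39
        assert round_half_up(0.125) == 0.13
        assert round_half_up(0.124) == 0.12


class TestMapping:
    def test_intersection(self, mini_unified):
        got = map_candidates_to_targets({"PPARG", "CHRM1", "NOTATARGET"}, mini_unified)
        assert got == {"PPARG", "CHRM1"}

    def test_disjoint_and_empty(self, mini_unified):
        assert map_candidates_to_targets({"X1", "X2"}, mini_unified) == set()
        assert map_candidates_to_targets(set(), mini_unified) == set()


class TestClassifyTarget:
    def test_replicated_via_unqualified_diabetes(self, mini_unified):
        verdict, calls = classify_target("PPARG", SYN["T1D"], mini_unified)
        assert verdict == "replicated"
        assert calls[0].drug_key == "rosiglitazone"

    def test_novel_when_indications_elsewhere(self, mini_unified):
        verdict, _ = classify_target("CHRM1", SYN["T2D"], mini_unified)
        assert verdict == "novel"

    def test_novel_when_no_indications(self, mini_unified):
        verdict, _ = classify_target("GHR", SYN["T2D"], mini_unified)
        assert verdict == "novel"

    def test_untargetable_gene_fails(self, mini_unified):
        with pytest.raises(ValueError):
            classify_target("NOTATARGET", SYN["T2D"], mini_unified)

    def test_adding_matching_indication_only_flips_to_replicated(self):
        base = [("d1", "G1", "A", {"psoriasis"}, "approved")]
        assert classify_target("G1", SYN["HT"], make_unified(base))[0] == "novel"
        more = base + [("d2", "G1", "A", {"hypertension"}, "approved")]
        assert classify_target("G1", SYN["HT"], make_unified(more))[0] == "replicated"
        # and an extra non-matching indication cannot flip it back
        even_more = more + [("d3", "G1", "A", {"asthma"}, "approved")]
        assert classify_target("G1", SYN["HT"], make_unified(even_more))[0] == "replicated"


class TestNovelDrugs:
    def test_drug_treating_phenotype_via_other_gene_excluded(self):
        unified = make_unified(
            [
                ("cureall", "NOVEL1", "A", set(), "approved"),
                ("cureall", "KNOWN1", "A", {"hypertension"}, "approved"),
                ("repo1", "NOVEL1", "A", {"asthma"}, "approved"),
                ("repo2", "NOVEL1", "A", set(), "clinical"),
            ]
        )
        drugs, calls = enumerate_novel_drugs({"NOVEL1"}, SYN["HT"], unified)
        assert drugs == {"repo1", "repo2"}
        assert all(c.verdict == "novel" for c in calls)

    def test_no_novel_targets_gives_empty(self, mini_unified):
        assert enumerate_novel_drugs(set(), SYN["T2D"], mini_unified)[0] == set()

    def test_output_never_indicated_for_phenotype(self, small_study):
        _, _, bundle = small_study
        from drugrepo.core import indicated_drugs

        for rep in bundle.reports:
            ph = SYN[rep.phenotype]
            indicated = indicated_drugs(ph, bundle.unified)
            assert not (bundle.novel_drugs[rep.phenotype] & indicated)

    def test_matches_bruteforce_enumeration(self, small_study):
        _, _, bundle = small_study
        unified = bundle.unified
        for rep in bundle.reports:
            ph = SYN[rep.phenotype]
            # oracle: scan every association directly
            expected = set()
            for a in unified.associations:
                if a.gene in rep.novel_targets:
                    expected.add(a.drug_key)
            for a in unified.associations:
                if any(indication_matches(i, ph.synonyms) for i in a.indications):
                    expected.discard(a.drug_key)
            assert bundle.novel_drugs[rep.phenotype] == expected


class TestStatusStratification:
    def test_target_counts_in_both_classes(self):
        unified = make_unified(
            [
                ("appr", "G1", "A", set(), "approved"),
                ("clin", "G1", "A", set(), "clinical"),
                ("unk", "G2", "A", set(), "unknown"),
            ]
        )
        counts = stratify_status({"G1", "G2"}, set(), unified)
        assert (counts.AT, counts.CT) == (1, 1)
        # unknown-status drugs put G2 in neither stratum
        assert counts.AT + counts.CT == 2

    def test_novel_variants_exclude_replicated(self):
        unified = make_unified(
            [("a", "G1", "A", {"hypertension"}, "approved"), ("b", "G2", "A", set(), "approved")]
        )
        counts = stratify_status({"G1", "G2"}, {"G1"}, unified)
        assert (counts.AT, counts.NAT) == (2, 1)


class TestPhenotypeReport:
    def test_identities_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            genes = [f"G{i}" for i in range(30)]
            rows = []
            for i in range(40):
                g = genes[rng.integers(0, 30)]
                ind = {"hypertension"} if rng.random() < 0.15 else {"asthma"}
                status = ["approved", "clinical", "unknown"][rng.integers(0, 3)]
                rows.append((f"d{rng.integers(0, 25)}", g, "A", ind, status))
            unified = make_unified(rows)
            candidates = {g for g in genes if rng.random() < 0.5} | {"X1", "X2"}
            rep = build_phenotype_report(SYN["HT"], candidates, unified)
            assert rep.TT == rep.RTT + rep.NTT
            assert rep.TT == len(candidates & unified.targets)
            # brute-force the replicated set
            expected_rep = set()
            for g in candidates & unified.targets:
                for a in unified.associations:
                    if a.gene == g and any(
                        indication_matches(i, SYN["HT"].synonyms) for i in a.indications
                    ):
                        expected_rep.add(g)
            assert set(rep.replicated_targets) == expected_rep
            if rep.TT:
                assert rep.NV.raw == rep.NTT / rep.TT

    def test_zero_targetable_flags_nv_undefined(self):
        unified = make_unified([("d", "G1", "A", set(), "approved")])
        rep = build_phenotype_report(SYN["HT"], {"X1", "X2"}, unified)
        assert rep.TT == 0 and rep.TI.rounded == 0.0 and rep.NV is None


def test_competition_ranks_share_and_skip():
    assert competition_ranks([0.39, 0.38, 0.27, 0.27, 0.35]) == [1, 2, 4, 4, 3]


def test_candidates_tsv_roundtrip(small_study):
    out, truth, _ = small_study
    sets = read_candidates(out / "candidates.tsv")
    union = phenotype_candidate_union(sets, "T2D")
    assert union == set(truth.phenotypes["T2D"].candidates)
    for cs in sets:
        assert cs.genes <= cs.search_space_genes


def test_known_therapeutics_reference_shape():
    df = load_known_therapeutics()
    assert list(df.columns) == ["phenotype", "gene", "drug_name", "status", "action", "source"]
    assert len(df) == 25
    assert df["gene"].nunique() < len(df)  # AGTR1 appears for two phenotypes
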