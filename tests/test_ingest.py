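"""Source parsing, gene/drug normalization, merging and overlap statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from drugrepo import (
    filter_human,
    load_alias_map,
    merge_sources,
    normalize_gene_symbol,
    overlap_stats,
    parse_source,
)
from drugrepo.ingest import (
    DIALECT_COLUMNS,
    VennCounts,
    classify_status,
    most_advanced_status,
    read_unified_table,
    write_unified_table,
)
from tests.conftest import make_unified

ALIAS = {"CD297": "ART1", "P35354": "PTGS2"}


class TestGeneNormalization:
    @pytest.mark.parametrize(
        "token,expected",
        [("pparg ", "PPARG"), ("CD297", "ART1"), ("ART1", "ART1"), (" tnf\t", "TNF")],
    )
    def test_trim_case_alias(self, token, expected):
        assert normalize_gene_symbol(token, ALIAS) == expected

    @pytest.mark.parametrize("bad", ["", "   ", "\t"])
    def test_empty_token_rejected(self, bad):
        with pytest.raises(ValueError):
            normalize_gene_symbol(bad, ALIAS)

    @given(st.text(alphabet=st.characters(categories=["Lu", "Ll", "Nd"]), min_size=1, max_size=12))
    def test_idempotent(self, token):
        once = normalize_gene_symbol(token, ALIAS)
        assert normalize_gene_symbol(once, ALIAS) == once

    def test_alias_chains_rejected(self, write_tsv):
        path = write_tsv(
            "aliases.tsv",
            [("A", "B"), ("B", "C")],
            ["input_token", "canonical_symbol"],
        )
        with pytest.raises(ValueError, match="chained"):
            load_alias_map(path)


class TestStatusClassification:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Approved", "approved"),
            ("Launched", "approved"),
            ("Phase III", "clinical"),
            ("Phase IIa", "clinical"),
            ("Preclinical", "preclinical"),
            ("Discontinued in phase I", "discontinued"),
            ("", "unknown"),
            ("Unknown", "unknown"),
        ],
    )
    def test_vocabulary(self, text, expected):
        assert classify_status(text) == expected

    def test_precedence_keeps_most_advanced(self):
        assert most_advanced_status("clinical", "approved") == "approved"
        assert most_advanced_status("discontinued", "preclinical") == "preclinical"
        assert most_advanced_status("unknown", "discontinued") == "discontinued"


def _drugbank_rows(rows):
    return [
        dict(
            zip(
                DIALECT_COLUMNS["drugbank_like"],
                (rid, name, brands, gene, species, "inhibitor", ind, status),
            )
        )
        for rid, name, brands, gene, species, ind, status in rows
    ]


class TestParseSource:
    def test_wellformed_drugbank(self, write_tsv):
        path = write_tsv(
            "db.tsv",
            _drugbank_rows(
                [
                    ("DB1", "Metformin", "", "PRKAA1", "Human", "diabetes", "Approved"),
                    ("DB2", "Aspirin", "Acuprin|Ecotrin", "PTGS1", "Human", "pain", "Approved"),
                    ("DB3", "Aspirin", "", "PTGS2", "Human", "pain", "Approved"),
                ]
            ),
            DIALECT_COLUMNS["drugbank_like"],
        )
        ps = parse_source(path, "drugbank_like", ALIAS, source_id="db")
        assert len(ps.associations) == 3
        assert ps.report.clean and ps.report.n_rows == 3
        # one drug hits two genes on two rows -> 2 associations, 1 record
        assert len(ps.drugs) == 2
        assert "ecotrin" not in ps.drugs  # brands are synonyms, not records
        assert "Ecotrin" in ps.drugs["aspirin"].names

    def test_nonhuman_flagged_then_filtered(self, write_tsv):
        path = write_tsv(
            "db.tsv",
            _drugbank_rows(
                [
                    ("DB1", "DrugA", "", "GENE1", "Human", "", "Approved"),
                    ("DB2", "DrugB", "", "GENE2", "Bacterial", "", "Approved"),
                ]
            ),
            DIALECT_COLUMNS["drugbank_like"],
        )
        ps = parse_source(path, "drugbank_like", source_id="db")
        species = {a.gene: a.species for a in ps.associations}
        assert species == {"GENE1": "human", "GENE2": "nonhuman"}
        kept = filter_human(ps.associations)
        assert [a.gene for a in kept] == ["GENE1"]

    def test_pharmgkb_multi_gene_row(self, write_tsv):
        path = write_tsv(
            "pk.tsv",
            [{"drug_name": "Warfarin", "associated_genes": "VKORC1|CYP2C9", "description": "anticoagulation"}],
            DIALECT_COLUMNS["pharmgkb_like"],
        )
        ps = parse_source(path, "pharmgkb_like", source_id="pk")
        assert {a.gene for a in ps.associations} == {"VKORC1", "CYP2C9"}
        assert len(ps.drugs) == 1

    def test_ttd_accession_resolution_and_quarantine(self, write_tsv):
        path = write_tsv(
            "ttd.tsv",
            [
                {"drug_name": "Celecoxib", "target_uniprot_or_symbol": "P35354",
                 "disease": "arthritis", "status": "Approved", "action": "inhibitor"},
                {"drug_name": "Mystery", "target_uniprot_or_symbol": "Q99999",
                 "disease": "none", "status": "Approved", "action": "inhibitor"},
            ],
            DIALECT_COLUMNS["ttd_like"],
        )
        ps = parse_source(path, "ttd_like", ALIAS, source_id="ttd")
        assert [a.gene for a in ps.associations] == ["PTGS2"]
        assert ps.report.n_rejected == 1
        assert "Q99999" in ps.report.rejected_rows[0][1]

    def test_missing_column_names_the_column(self, write_tsv):
        path = write_tsv("bad.tsv", [{"drug_name": "X"}], ["drug_name"])
        with pytest.raises(ValueError, match="associated_genes"):
            parse_source(path, "pharmgkb_like")

    def test_duplicate_rows_merged_and_counted(self, write_tsv):
        row = ("DB1", "DrugA", "", "GENE1", "Human", "ulcer", "Approved")
        path = write_tsv(
            "db.tsv", _drugbank_rows([row, row]), DIALECT_COLUMNS["drugbank_like"]
        )
        ps = parse_source(path, "drugbank_like", source_id="db")
        assert len(ps.associations) == 1
        assert ps.report.n_duplicates == 1


class TestMerge:
    def _parsed(self, write_tsv, name, rows, source):
        path = write_tsv(name, _drugbank_rows(rows), DIALECT_COLUMNS["drugbank_like"])
        return parse_source(path, "drugbank_like", source_id=source)

    def test_shared_pair_unions_sources(self, write_tsv):
        a = self._parsed(write_tsv, "a.tsv", [("1", "DrugA", "", "G1", "Human", "", "Approved")], "src_a")
        b = self._parsed(write_tsv, "b.tsv", [("2", "DrugA", "", "G1", "Human", "", "Phase II")], "src_b")
        unified = merge_sources([a, b])
        assert unified.targets == {"G1"}
        assert unified.drugs["druga"].sources == {"src_a", "src_b"}
        # status conflict resolved to the most advanced
        assert unified.drugs["druga"].status == "approved"

    def test_self_merge_idempotent(self, small_study):
        _, _, bundle = small_study
        u = bundle.unified
        again = merge_sources([(u.associations, u.drugs)])
        assert again.associations == u.associations
        assert {k: r.status for k, r in again.drugs.items()} == {
            k: r.status for k, r in u.drugs.items()
        }

    def test_order_invariant(self, write_tsv):
        parts = [
            self._parsed(write_tsv, f"{s}.tsv", [("1", f"Drug{s}", "", f"G{i}", "Human", "", "Approved")], s)
            for i, s in enumerate(["x", "y", "z"])
        ]
        tables = [merge_sources(list(p)) for p in itertools.permutations(parts)]
        for t in tables[1:]:
            assert t.associations == tables[0].associations


class TestOverlapStats:
    def test_three_set_worked_example(self):
        unified = make_unified(
            [("d1", "G1", "A", set(), "unknown"), ("d1", "G2", "A", set(), "unknown"),
             ("d2", "G2", "B", set(), "unknown"), ("d2", "G3", "B", set(), "unknown"),
             ("d3", "G2", "C", set(), "unknown")]
        )
        rep = overlap_stats(unified, genome_size=100)
        t = rep.targets
        assert t.union == 3
        assert t.triple_shared == 1
        assert t.pairwise_shared[("A", "B")] == 1
        assert t.pairwise_exclusive[("A", "B")] == 0
        assert t.unique_per_source == {"A": 1, "B": 1, "C": 0}

    def test_single_source(self):
        unified = make_unified([("d1", "G1", "A", set(), "unknown"), ("d1", "G2", "A", set(), "unknown")])
        rep = overlap_stats(unified, genome_size=10)
        assert rep.targets.union == 2
        assert rep.targets.unique_per_source == {"A": 2}

    def test_genome_smaller_than_union_rejected(self):
        unified = make_unified([("d1", "G1", "A", set(), "unknown"), ("d1", "G2", "A", set(), "unknown")])
        with pytest.raises(ValueError, match="coverage"):
            overlap_stats(unified, genome_size=1)

    def test_matches_bruteforce_region_enumeration(self):
        # random 3-set instances vs exhaustive per-gene region labelling
        rng = np.random.default_rng(42)
        for _ in range(25):
            genes = [f"G{i}" for i in range(rng.integers(5, 60))]
            sets = {
                s: {g for g in genes if rng.random() < p}
                for s, p in (("A", 0.5), ("B", 0.4), ("C", 0.3))
            }
            for s in sets:
                if not sets[s]:
                    sets[s] = {genes[0]}
            vc = VennCounts.from_sets(sets)
            regions = {}
            for g in genes:
                key = frozenset(s for s in sets if g in sets[s])
                if key:
                    regions[key] = regions.get(key, 0) + 1
            assert vc.union == sum(regions.values())
            assert vc.triple_shared == regions.get(frozenset("ABC"), 0)
            for a, b in (("A", "B"), ("A", "C"), ("B", "C")):
                raw = sum(n for k, n in regions.items() if a in k and b in k)
                assert vc.pairwise_shared[(a, b)] == raw
            for s in "ABC":
                assert vc.unique_per_source[s] == regions.get(frozenset(s), 0)


def test_unified_table_roundtrip_is_fixed_point(small_study, tmp_path):
    _, _, bundle = small_study
    p1 = tmp_path / "u1.tsv"
    write_unified_table(bundle.unified, p1)
    back = read_unified_table(p1)
    assert back.associations == bundle.unified.associations
    p2 = tmp_path / "u2.tsv"
    write_unified_table(back, p2)
    assert p1.read_bytes() == p2.read_bytes()
    assert back.drugs.keys() == bundle.unified.drugs.keys()
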