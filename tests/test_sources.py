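"""Parsing of the five source formats and the seed list."""

import pytest

from cpn.model import FormatError, SeedList
from cpn import sources as src


def write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text, encoding="utf-8")
    return path


class TestPharmGKBRelationships:
    def test_example_fixture_parses_with_pmid_splitting(self, worked_example):
        rel, _ = worked_example
        result = src.read_pharmgkb_relationships(rel)
        assert len(result.rows) == 4
        assert result.rows[0].pmids == ("18798002",)
        assert result.rows[0].entity1_name == "Urinary bladder neoplasms"
        assert result.rows[0].entity2_type == "variant"
        # multi-valued PMIDs cell splits on ';'
        assert result.rows[2].pmids == ("18496682", "19581389")
        result.stats.check()

    def test_header_only_file_yields_empty_list(self, tmp_path):
        path = write(tmp_path, "r.tsv",
                     "Entity1_id\tEntity1_name\tEntity1_type\tEntity2_id\t"
                     "Entity2_name\tEntity2_type\tPMIDs\n")
        assert src.read_pharmgkb_relationships(path).rows == []

    def test_missing_column_names_the_column(self, tmp_path):
        path = write(tmp_path, "r.tsv", "Entity1_id\tEntity1_name\n")
        with pytest.raises(FormatError, match="Entity1_type"):
            src.read_pharmgkb_relationships(path)

    def test_rows_with_missing_names_are_dropped_and_counted(self, tmp_path):
        path = write(tmp_path, "r.tsv",
                     "Entity1_id\tEntity1_name\tEntity1_type\tEntity2_id\t"
                     "Entity2_name\tEntity2_type\tPMIDs\n"
                     "PA1\tDrugA\tDrug\tPA2\t\tGene\t123\n"
                     "PA1\tDrugA\tDrug\tPA3\tGENE1\tGene\t123\n")
        result = src.read_pharmgkb_relationships(path)
        assert len(result.rows) == 1
        assert result.stats.dropped["missing_name"] == 1
        assert result.stats.rows_in == result.stats.rows_kept + result.stats.rows_dropped


class TestGwasCatalog:
    HEADER = "Disease/Trait\tReported Gene(s)\tSNPs\n"

    def seeds(self):
        return SeedList.from_terms(["bladder cancer"])

    def test_pair_enumeration_two_genes_one_snp(self, tmp_path):
        path = write(tmp_path, "g.tsv",
                     self.HEADER + "bladder cancer\tGENE1, GENE2\trs1\n")
        rows = src.read_gwas_catalog(path, self.seeds()).rows
        # 2 disease-gene + 1 disease-snp + 2 gene-snp
        assert len(rows) == 5
        kinds = sorted((r.entity1_type, r.entity2_type) for r in rows)
        assert kinds == [("disease", "gene"), ("disease", "gene"),
                         ("disease", "variant"), ("gene", "variant"),
                         ("gene", "variant")]

    def test_non_seed_trait_is_filtered(self, tmp_path):
        path = write(tmp_path, "g.tsv",
                     self.HEADER + "hypertension\tGENE1\trs1\n")
        result = src.read_gwas_catalog(path, self.seeds())
        assert result.rows == []
        assert result.stats.dropped["trait_not_seed"] == 1

    def test_seed_match_ignores_case_and_whitespace(self, tmp_path):
        path = write(tmp_path, "g.tsv",
                     self.HEADER + "Bladder  CANCER \tGENE1\t\n")
        assert len(src.read_gwas_catalog(path, self.seeds()).rows) == 1

    def test_empty_gene_cell_yields_disease_snp_only(self, tmp_path):
        path = write(tmp_path, "g.tsv",
                     self.HEADER + "bladder cancer\tNR\trs5\n")
        rows = src.read_gwas_catalog(path, self.seeds()).rows
        assert len(rows) == 1
        assert (rows[0].entity1_type, rows[0].entity2_type) == ("disease", "variant")

    def test_malformed_snp_is_skipped(self, tmp_path):
        path = write(tmp_path, "g.tsv",
                     self.HEADER + "bladder cancer\tGENE1\tchr7:123; rs9\n")
        rows = src.read_gwas_catalog(path, self.seeds()).rows
        snps = [r for r in rows if r.entity2_type == "variant"
                and r.entity1_type == "disease"]
        assert [r.entity2_name for r in snps] == ["rs9"]


class TestFdaBiomarkers:
    HEADER = "Drug\tTherapeutic areas\tHUGO Symbol\n"

    def test_multi_gene_cell_splits_into_pairs(self, tmp_path):
        path = write(tmp_path, "f.tsv", self.HEADER + "DrugD\tOncology\tG1; G2\n")
        rows = src.read_fda_biomarkers(path).rows
        assert [(r.entity1_name, r.entity2_name) for r in rows] == \
            [("DrugD", "G1"), ("DrugD", "G2")]
        assert all(r.source == "fda" for r in rows)

    def test_non_oncology_rows_are_filtered(self, tmp_path):
        path = write(tmp_path, "f.tsv", self.HEADER
                     + "DrugP\tPsychiatry\tG1\n"
                     + "DrugO\tOncology (solid tumours)\tG1\n")
        result = src.read_fda_biomarkers(path)
        assert [r.entity1_name for r in result.rows] == ["DrugO"]
        assert result.stats.dropped["not_oncology"] == 1

    def test_pairs_can_exceed_drug_count(self, tmp_path):
        # multi-gene rows yield more pairs than drugs
        path = write(tmp_path, "f.tsv", self.HEADER
                     + "D1\tOncology\tG1; G2; G3\nD2\tOncology\tG4\n")
        rows = src.read_fda_biomarkers(path).rows
        assert len(rows) == 4
        assert len({r.entity1_name for r in rows}) == 2


class TestPredications:
    HEADER = "subject\tpredicate\tobject\tpmid\n"

    def test_duplicates_collapse_and_blank_predicate_skipped(self, tmp_path):
        path = write(tmp_path, "p.tsv", self.HEADER
                     + "GENE1\tASSOCIATED_WITH\tDiseaseX\t123\n"
                     + "GENE1\tASSOCIATED_WITH\tDiseaseX\t123\n"
                     + "GENE1\t\tDiseaseX\t124\n")
        result = src.read_predications(path)
        assert len(result.rows) == 1
        assert result.rows[0].predicate == "ASSOCIATED_WITH"
        assert result.stats.dropped == {"duplicate": 1, "blank_predicate": 1}

    def test_distinct_pmids_for_one_triple_kept_separately(self, tmp_path):
        body = "".join(f"A\tAFFECTS\tB\t{p}\n" for p in ("11", "12", "13"))
        path = write(tmp_path, "p.tsv", self.HEADER + body)
        assert len(src.read_predications(path).rows) == 3


class TestSeedList:
    def test_case_insensitive_dedup_preserves_order(self, tmp_path):
        path = write(tmp_path, "s.txt",
                     "bladder cancer\nBreast cancer\nBLADDER CANCER\n# note\n")
        seeds = src.read_seed_list(path)
        assert seeds.terms == ("bladder cancer", "Breast cancer")


class TestRoundTrip:
    def test_dump_then_load_reproduces_row_multiset(self, worked_example, tmp_path):
        rel, _ = worked_example
        rows = src.read_pharmgkb_relationships(rel).rows
        dump = tmp_path / "dump.tsv"
        src.dump_parsed(rows, dump)
        again = src.load_parsed(dump)
        assert sorted(map(repr, rows)) == sorted(map(repr, again))

    def test_round_trip_covers_all_sources(self, tmp_path):
        from conftest import make_row

        rows = [make_row("A drug", "drug", "G1", "gene", pmids=("1", "2")),
                make_row("trait", "disease", "rs1", "variant", source="gwas"),
                make_row("D", "drug", "G2", "gene", source="fda")]
        dump = tmp_path / "dump.tsv"
        src.dump_parsed(rows, dump)
        assert src.load_parsed(dump) == rows
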