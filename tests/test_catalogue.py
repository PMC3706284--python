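"""Embedded catalogue, references and fixture-table integrity."""

import pytest

from deafscreen.calling import Locus, VariantNameError
from deafscreen.catalogue import annotate_variant, canonical_name, load_catalogue


class TestLoad:
    def test_unpacks_into_three_components(self, cat):
        annotations, refs, tables = cat
        assert len(annotations) == 45
        assert len(refs.gjb2_cds) == 678
        assert tables.n_cases == 658 and tables.n_controls == 462

    def test_nine_pathogenic_gjb2_entries(self, cat):
        assert len(cat.pathogenic_names(Locus.GJB2)) == 9

    def test_thirty_mtdna_panel_rows(self, cat):
        assert len(cat.tables.table4_mt) == 30

    def test_references_cover_every_catalogued_position(self, cat):
        for ann in cat.annotations:
            seq, off = cat.references.sequence_for(ann.locus)
            assert off < ann.call.position <= off + len(seq), ann.name
            if ann.call.ref_allele:
                start = ann.call.position - off - 1
                assert (
                    seq[start : start + len(ann.call.ref_allele)] == ann.call.ref_allele
                ), ann.name

    def test_load_is_cached_singleton(self, cat):
        assert load_catalogue() is cat


class TestGenotypeStrata:
    def test_pathogenic_strata_partition(self, cat):
        """70 monoallelic + 94 biallelic (79 hom + 15 compound het) cases."""
        path = cat.pathogenic_names(Locus.GJB2)
        strata = cat.tables.table2_genotypes
        n_path = lambda s: sum(
            any(v in path for v in allele) for allele in (s.allele1, s.allele2)
        )
        mono = sum(s.case_count for s in strata if n_path(s) == 1)
        hom = sum(
            s.case_count for s in strata if n_path(s) == 2 and s.allele1 == s.allele2
        )
        chet = sum(
            s.case_count for s in strata if n_path(s) == 2 and s.allele1 != s.allele2
        )
        assert (mono, hom, chet) == (70, 79, 15)

    def test_derived_case_carriers_match_carrier_table_for_pathogenic(self, cat):
        t1 = cat.tables.table1_counts.set_index("name")
        derived = cat.tables.derived_carriers("case")
        for name in cat.pathogenic_names(Locus.GJB2):
            assert derived.get(name, 0) == t1.loc[name, "case_carriers"], name

    def test_derived_control_carriers_match_for_all_variants(self, cat):
        t1 = cat.tables.table1_counts.set_index("name")
        derived = cat.tables.derived_carriers("control")
        for name in t1.index:
            assert derived.get(name, 0) == t1.loc[name, "control_carriers"], name

    def test_case_strata_for_c235delC_sum_to_carrier_count(self, cat):
        """The genotype rows containing c.235delC sum to its carrier count."""
        total = sum(
            s.case_count
            for s in cat.tables.table2_genotypes
            if "c.235delC" in s.carried
        )
        assert total == 102

    def test_phenotype_strata_partition_the_case_cohort(self, cat):
        t3 = cat.tables.table3_phenotypes
        assert t3["count"].sum() == 658
        assert (
            t3["moderate"] + t3["severe"] + t3["profound"] == t3["count"]
        ).all()
        onset_total = (
            t3["onset_postlingual"] + t3["onset_prelingual"] + t3["onset_unknown"]
        )
        assert (onset_total == t3["count"]).all()


class TestAnnotate:
    @pytest.mark.parametrize(
        "name, locus, category",
        [
            ("c.235delC", Locus.GJB2, "pathogenic"),
            ("c.79G > A", Locus.GJB2, "polymorphism"),
            ("m.1222A>G", Locus.MT12S, "novel"),
            ("m.709G>A", Locus.MT12S, "unknown"),
        ],
    )
    def test_catalogued_lookup(self, cat, name, locus, category):
        ann = annotate_variant(name, locus, cat)
        assert ann.category == category

    def test_m1222_not_previously_reported(self, cat):
        assert not annotate_variant("m.1222A>G", Locus.MT12S, cat).previously_reported

    def test_uncatalogued_name_is_novel(self, cat):
        ann = annotate_variant("c.123G>T", Locus.GJB2, cat)
        assert ann.category == "novel"
        assert not ann.previously_reported

    def test_malformed_name_raises(self, cat):
        with pytest.raises(VariantNameError):
            annotate_variant("c.999X>Y", Locus.GJB2, cat)

    def test_canonical_name_strips_spaces(self):
        assert canonical_name("c.101 T > C") == "c.101T>C"


class TestPrintedFrequencies:
    def test_every_fixture_frequency_recomputes_from_counts(self, cat):
        from deafscreen.stats import carrier_frequency

        t1 = cat.tables.table1_counts
        for _, r in t1.iterrows():
            assert carrier_frequency(r["case_carriers"], 658) == r["case_freq"]
            assert carrier_frequency(r["control_carriers"], 462) == r["control_freq"]
        t4 = cat.tables.table4_mt
        for _, r in t4.iterrows():
            assert carrier_frequency(r["case_count"], 658) == r["case_freq"]
            assert carrier_frequency(r["control_count"], 462) == r["control_freq"]
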