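"""Synthetic cohort and ortholog-alignment generation."""

import pytest

from deafscreen.calling import Locus, ReferenceMismatchError, VariantCall, VariantKind
from deafscreen.catalogue import GenotypeStratum
from deafscreen.cohort import (
    CohortSpec,
    CohortSpecError,
    MsaSpec,
    generate_cohort,
    generate_msa,
    plant_variant,
)
from deafscreen.io import write_fasta


def small_spec(strata, seed=0, n_cases=10, n_controls=5, mt=None):
    return CohortSpec(
        n_cases=n_cases,
        n_controls=n_controls,
        genotype_strata=strata,
        mt_variant_counts=mt or {},
        seed=seed,
    )


class TestPlantVariant:
    def test_substitution_and_ref_check(self):
        call = VariantCall(Locus.GJB2, VariantKind.SUBSTITUTION, 3, "G", "T")
        assert plant_variant("ACGTA", call) == "ACTTA"
        with pytest.raises(ReferenceMismatchError):
            plant_variant("ACTTA", call)

    def test_insertion_follows_anchor_base(self):
        call = VariantCall(Locus.GJB2, VariantKind.INSERTION, 2, "", "GG")
        assert plant_variant("ACGT", call) == "ACGGGT"

    def test_planting_nothing_is_identity(self):
        from deafscreen.cohort import apply_variants

        assert apply_variants("ACGT", []) == "ACGT"


class TestGenerateCohort:
    def test_single_subject_compound_het_differs_at_planted_sites(self, cat):
        spec = small_spec(
            [GenotypeStratum(("c.235delC",), ("c.299delAT",), 1, 0)],
            n_cases=1,
            n_controls=0,
        )
        res = generate_cohort(spec, cat.references, cat)
        ref = cat.references.gjb2_cds
        a1 = next(
            r.sequence
            for r in res.records
            if r.locus is Locus.GJB2 and r.allele_index == 1
        )
        a2 = next(
            r.sequence
            for r in res.records
            if r.locus is Locus.GJB2 and r.allele_index == 2
        )
        # allele 1: single-base deletion at c.235; allele 2: two-base deletion at c.299
        assert a1 == ref[:234] + ref[235:]
        assert a2 == ref[:298] + ref[300:]

    def test_all_zero_spec_gives_wildtype_cohort(self, cat):
        res = generate_cohort(small_spec([]), cat.references, cat)
        ref_by_locus = {
            Locus.GJB2: cat.references.gjb2_cds,
            Locus.GJB2_EX1: cat.references.promoter_exon1,
            Locus.MT12S: cat.references.mt12s,
        }
        assert all(r.sequence == ref_by_locus[r.locus] for r in res.records)

    def test_stratum_counts_exceeding_group_size_rejected(self):
        with pytest.raises(CohortSpecError):
            small_spec([GenotypeStratum(("c.235delC",), (), 11, 0)], n_cases=10)

    def test_mt_carrier_counts_exact_and_disjoint(self, cat):
        spec = small_spec(
            [GenotypeStratum(("c.235delC",), ("c.235delC",), 3, 0)],
            n_cases=20,
            mt={"m.1555A>G": (5, 0), "m.1494C>T": (2, 0), "m.750A>G": (18, 3)},
        )
        res = generate_cohort(spec, cat.references, cat)
        carriers = {
            name: {s for s, names in res.truth_mt.items() if name in names}
            for name in spec.mt_variant_counts
        }
        assert len(carriers["m.1555A>G"]) == 5
        assert len(carriers["m.1494C>T"]) == 2
        assert not carriers["m.1555A>G"] & carriers["m.1494C>T"]
        assert not carriers["m.1555A>G"] & res.gjb2_pathogenic_carriers
        assert not carriers["m.1494C>T"] & res.gjb2_pathogenic_carriers

    def test_same_seed_byte_identical_fasta(self, cat, tmp_path):
        spec = CohortSpec.from_fixtures(cat, seed=7)
        out = []
        for tag in ("a", "b"):
            res = generate_cohort(spec, cat.references, cat)
            p = tmp_path / f"{tag}.fasta"
            write_fasta(res.records[:50], p)
            out.append(p.read_bytes())
        assert out[0] == out[1]

    def test_case_audiograms_match_stratum_severity(self, cat):
        from deafscreen.genotypes import classify_severity, pta_average

        spec = CohortSpec.from_fixtures(cat, seed=3)
        res = generate_cohort(spec, cat.references, cat)
        bands = {}
        for s in res.subjects:
            if s.group != "case":
                continue
            key = res.truth_gjb2[s.id]
            bands.setdefault(key, []).append(
                classify_severity(pta_average(s.audiogram)).band
            )
        # the 52 c.235delC homozygotes: 1 moderate, 11 severe, 40 profound
        got = bands[(("c.235delC",), ("c.235delC",))]
        assert sorted(got) == ["moderate"] + ["profound"] * 40 + ["severe"] * 11


class TestGenerateMsa:
    def test_fully_conserved_profile(self):
        human = "ACGTACGT"
        msa = generate_msa(MsaSpec(tuple([22] * 8), seed=0), human)
        assert len(msa) == 22
        for col in range(8):
            assert all(str(rec.seq[col]) == human[col] for rec in msa)

    def test_profile_match_counts_exact(self):
        human = "ACGTACGTAC"
        profile = (22, 20, 1, 11, 22, 5, 18, 22, 2, 13)
        msa = generate_msa(MsaSpec(profile, seed=4), human)
        for col, want in enumerate(profile):
            got = sum(str(rec.seq[col]) == human[col] for rec in msa)
            assert got == want

    def test_profile_of_one_means_reference_only(self):
        human = "AAAA"
        msa = generate_msa(MsaSpec((1, 1, 1, 1), seed=0), human)
        for col in range(4):
            assert sum(str(rec.seq[col]) == "A" for rec in msa) == 1

    def test_profile_length_mismatch_rejected(self):
        with pytest.raises(CohortSpecError):
            generate_msa(MsaSpec((22, 22), seed=0), "ACGT")

    def test_profile_out_of_range_rejected(self):
        with pytest.raises(CohortSpecError):
            MsaSpec((0, 22), seed=0)
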