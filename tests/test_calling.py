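"""Alignment, variant extraction, left-normalization and legacy naming."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deafscreen.calling import (
    AlignmentParams,
    Locus,
    VariantCall,
    VariantKind,
    VariantNameError,
    call_sequence,
    extract_variants,
    global_align,
    name_variant,
    normalize_variant,
    parse_variant_name,
)

P = AlignmentParams()


def brute_force_score(q: str, r: str, p: AlignmentParams = P) -> float:
    """Exhaustive recursion over all global alignments (tiny inputs only)."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def f(i: int, j: int) -> float:
        if i == 0:
            return p.gap * j
        if j == 0:
            return p.gap * i
        s = p.match if q[i - 1] == r[j - 1] else p.mismatch
        return max(f(i - 1, j - 1) + s, f(i - 1, j) + p.gap, f(i, j - 1) + p.gap)

    return f(len(q), len(r))


class TestGlobalAlign:
    def test_identical_sequences_align_gapless(self):
        a = global_align("ACGTACGT", "ACGTACGT")
        assert "-" not in a.aligned_query + a.aligned_ref
        assert a.score == 8 * P.match

    def test_single_base_deletion_gives_one_gap_column(self):
        ref = "ACGTACGT"
        a = global_align(ref[:3] + ref[4:], ref)
        assert a.aligned_query.count("-") == 1
        assert a.aligned_ref.count("-") == 0

    def test_score_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            q = "".join(rng.choice(list("ACGT"), rng.integers(1, 8)))
            r = "".join(rng.choice(list("ACGT"), rng.integers(1, 8)))
            a = global_align(q, r)
            assert a.score == brute_force_score(q, r)
            # gapped strings must recover the inputs
            assert a.aligned_query.replace("-", "") == q
            assert a.aligned_ref.replace("-", "") == r

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")


class TestExtractVariants:
    def test_adjacent_mismatches_merge_into_mnv(self):
        ref = "A" * 10 + "TC" + "A" * 10
        query = ref[:10] + "AA" + ref[12:]
        calls = extract_variants(global_align(query, ref), Locus.GJB2)
        assert [(c.kind, c.position, c.ref_allele, c.alt_allele) for c in calls] == [
            (VariantKind.MNV_SUBSTITUTION, 11, "TC", "AA")
        ]

    def test_long_deletion_is_one_call(self, refs):
        ref = refs.gjb2_cds
        query = ref[:175] + ref[191:]  # remove c.176..c.191
        calls = call_sequence(query, ref, Locus.GJB2)
        assert [c.name for c in calls] == ["c.176del16"]

    def test_wildtype_yields_no_calls(self, refs):
        assert call_sequence(refs.gjb2_cds, refs.gjb2_cds, Locus.GJB2) == []

    def test_n_in_query_excluded_with_warning(self):
        ref = "ACGTACGTACGT"
        query = ref[:5] + "N" + ref[6:]
        with pytest.warns(UserWarning, match="ambiguous"):
            calls = extract_variants(global_align(query, ref), Locus.GJB2)
        assert calls == []

    def test_coordinate_offset_applied(self):
        ref = "ACGTACGTAA"
        query = "ACGTCCGTAA"
        calls = extract_variants(global_align(query, ref), Locus.MT12S, 600)
        assert calls[0].position == 605
        assert calls[0].name == "m.605A>C"


class TestNormalize:
    def test_deletion_left_shifts_through_homopolymer(self):
        ref = "GACCCGT"
        # deleting the third C (position 5) is the same edit as deleting
        # the first C (position 3)
        call = VariantCall(Locus.GJB2, VariantKind.DELETION, 5, "C", "")
        norm = normalize_variant(call, ref)
        assert norm.position == 3
        # left-shift oracle: both edits produce the same string
        assert ref[:4] + ref[5:] == ref[:2] + ref[3:]

    def test_insertion_left_shifts_in_homopolymer(self):
        ref = "GATTTACGT"
        call = VariantCall(Locus.GJB2, VariantKind.INSERTION, 5, "", "T")
        norm = normalize_variant(call, ref)
        assert norm.position == 2
        assert norm.alt_allele == "T"

    def test_substitution_unchanged_and_idempotent(self):
        ref = "ACGTACGT"
        call = VariantCall(Locus.GJB2, VariantKind.SUBSTITUTION, 3, "G", "T")
        once = normalize_variant(call, ref)
        assert once == call
        assert normalize_variant(once, ref) == once

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=6, max_size=20), st.data())
    def test_normalized_edit_reapplies_to_same_sequence(self, ref, data):
        """Left-shifting never changes the edited sequence (oracle check)."""
        pos = data.draw(st.integers(min_value=2, max_value=len(ref)))
        call = VariantCall(Locus.GJB2, VariantKind.DELETION, pos, ref[pos - 1], "")
        norm = normalize_variant(call, ref)
        edited_orig = ref[: call.position - 1] + ref[call.position :]
        edited_norm = ref[: norm.position - 1] + ref[norm.position :]
        assert edited_orig == edited_norm
        assert normalize_variant(norm, ref) == norm


class TestNaming:
    @pytest.mark.parametrize(
        "call, expected",
        [
            (VariantCall(Locus.GJB2, VariantKind.DELETION, 235, "C", ""), "c.235delC"),
            (VariantCall(Locus.GJB2, VariantKind.DELETION, 299, "AT", ""), "c.299delAT"),
            (VariantCall(Locus.GJB2, VariantKind.DELETION, 176, "A" * 16, ""), "c.176del16"),
            (VariantCall(Locus.GJB2, VariantKind.INSERTION, 504, "", "AAGG"), "c.504insAAGG"),
            (VariantCall(Locus.GJB2, VariantKind.INSERTION, 605, "", "A" * 46), "c.605ins46"),
            (VariantCall(Locus.GJB2, VariantKind.MNV_SUBSTITUTION, 608, "TC", "AA"), "c.608TC>AA"),
            (VariantCall(Locus.MT12S, VariantKind.SUBSTITUTION, 1555, "A", "G"), "m.1555A>G"),
        ],
    )
    def test_legacy_names(self, call, expected):
        assert name_variant(call) == expected

    @pytest.mark.parametrize(
        "name, kind, pos",
        [
            ("c.235delC", "deletion", 235),
            ("c.176del16", "deletion", 176),
            ("c.605ins46", "insertion", 605),
            ("m.961delT+insC", "delins", 961),
            ("c.101 T > C", "substitution", 101),
            ("c.608TC>AA", "mnv_substitution", 608),
        ],
    )
    def test_parse_legacy_forms(self, name, kind, pos):
        parsed = parse_variant_name(name.replace(" ", ""))
        assert parsed["kind"] == kind
        assert parsed["position"] == pos

    def test_malformed_name_raises(self):
        with pytest.raises(VariantNameError):
            parse_variant_name("c.999X>Y")


class TestRoundTrip:
    def test_every_catalogued_variant_round_trips(self, cat):
        """plant -> align -> extract -> normalize -> name recovers each
        catalogue entry (the historic m.961delT+insC spelling maps to its
        equivalent canonical edit)."""
        from deafscreen.cohort import plant_variant

        for ann in cat.annotations:
            ref, off = cat.references.sequence_for(ann.locus)
            query = plant_variant(ref, ann.call, off)
            calls = call_sequence(query, ref, ann.locus, off)
            want = ann.equivalent_to or ann.name
            assert [c.name for c in calls] == [want], ann.name

    def test_two_variant_allele_round_trips(self, cat):
        from deafscreen.cohort import apply_variants

        ref, off = cat.references.sequence_for(Locus.GJB2)
        calls_in = [cat.get(n, Locus.GJB2).call for n in ("c.235delC", "c.299delAT")]
        query = apply_variants(ref, calls_in, off)
        got = sorted(c.name for c in call_sequence(query, ref, Locus.GJB2, off))
        assert got == ["c.235delC", "c.299delAT"]
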