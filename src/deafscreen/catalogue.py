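"""Embedded variant-annotation catalogue, reference sequences and cohort
fixture tables.

The catalogue covers the 15 GJB2 coding-region variants and the 30
mitochondrial 12S rRNA variants screened by the pipeline, with their
category (pathogenic / polymorphism / unknown / novel), protein-domain
and amino-acid annotation, and in-silico scores where reported. The
fixture tables hold the study's carrier counts (cases N=658, controls
N=462), genotype strata, genotype-phenotype composition and the mtDNA
variant panel with conservation indices.

Reference sequences are synthetic stand-ins of the correct lengths with
the catalogued wild-type base planted at every catalogued position, so
the whole pipeline is self-contained and runs offline.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import pandas as pd

from .calling import Locus, VariantCall, VariantKind, parse_variant_name
from .stats import carrier_frequency

__all__ = [
    "VariantAnnotation",
    "ReferenceSet",
    "GenotypeStratum",
    "FixtureTables",
    "Catalogue",
    "CatalogueIntegrityError",
    "load_catalogue",
    "annotate_variant",
    "canonical_name",
]

N_CASES = 658
N_CONTROLS = 462

_KIND = {k.value: k for k in VariantKind}


class CatalogueIntegrityError(RuntimeError):
    """Embedded catalogue data failed an internal consistency check."""


def canonical_name(name: str) -> str:
    """Normalize spacing of a legacy name (``c.101 T > C`` -> ``c.101T>C``)."""
    s = name.replace(" ", "")
    if not s.startswith(("c.", "m.")):
        raise ValueError(f"legacy name must start with c. or m.: {name!r}")
    return s


@dataclass(frozen=True)
class VariantAnnotation:
    """Catalogue entry for one named variant at one locus."""

    name: str
    locus: Locus
    category: str  # pathogenic | polymorphism | unknown | novel
    domain_label: str = ""
    previously_reported: bool = False
    polyphen_score: float | None = None
    sift_score: float | None = None
    aa_change: str = ""
    call: VariantCall | None = None
    equivalent_to: str = ""  # another catalogue name denoting the same edit

    @property
    def is_pathogenic(self) -> bool:
        return self.category == "pathogenic"


@dataclass(frozen=True)
class ReferenceSet:
    """Locus reference sequences with their coordinate offsets.

    String index ``i`` (0-based) of a sequence corresponds to locus
    coordinate ``offset + i + 1``; the GJB2 coding sequence starts at
    c.1 (offset 0) and the 12S region covers m.601 onwards (offset 600).
    """

    gjb2_cds: str
    promoter_exon1: str
    mt12s: str
    mt12s_offset: int

    def sequence_for(self, locus: Locus) -> tuple[str, int]:
        if locus is Locus.GJB2:
            return self.gjb2_cds, 0
        if locus is Locus.GJB2_EX1:
            return self.promoter_exon1, 0
        return self.mt12s, self.mt12s_offset

    def base_at(self, locus: Locus, position: int) -> str:
        seq, off = self.sequence_for(locus)
        return seq[position - off - 1]


@dataclass(frozen=True)
class GenotypeStratum:
    """One genotype row: variant names on each allele plus group counts."""

    allele1: tuple[str, ...]
    allele2: tuple[str, ...]
    case_count: int
    control_count: int

    @property
    def carried(self) -> tuple[str, ...]:
        return self.allele1 + self.allele2


@dataclass(frozen=True)
class FixtureTables:
    """Machine-readable counterparts of the study's four result tables."""

    table1_counts: pd.DataFrame
    table2_genotypes: list[GenotypeStratum]
    table3_phenotypes: pd.DataFrame
    table4_mt: pd.DataFrame
    n_cases: int = N_CASES
    n_controls: int = N_CONTROLS

    def derived_carriers(self, group: str = "case") -> dict[str, int]:
        """Per-variant carrier counts implied by the genotype strata
        (a subject counts once per variant, regardless of zygosity)."""
        col = "case_count" if group == "case" else "control_count"
        out: dict[str, int] = {}
        for s in self.table2_genotypes:
            n = getattr(s, col)
            for name in set(s.carried):
                out[name] = out.get(name, 0) + n
        return out


@dataclass(frozen=True)
class Catalogue:
    """The full embedded catalogue: annotations, references and fixtures."""

    annotations: list[VariantAnnotation]
    references: ReferenceSet
    tables: FixtureTables
    _by_key: dict[tuple[Locus, str], VariantAnnotation] = field(repr=False, default=None)

    def __iter__(self):
        # allow  annotations, refs, tables = load_catalogue()
        return iter((self.annotations, self.references, self.tables))

    def get(self, name: str, locus: Locus) -> VariantAnnotation | None:
        return self._by_key.get((locus, canonical_name(name)))

    def pathogenic_names(self, locus: Locus) -> set[str]:
        return {
            a.name for a in self.annotations if a.locus is locus and a.is_pathogenic
        }


def _read_tsv(fname: str) -> pd.DataFrame:
    text = resources.files("deafscreen.data").joinpath(fname).read_text()
    return pd.read_csv(_stdio.StringIO(text), sep="\t", comment="#", dtype=str)


def _read_fasta_resource(fname: str) -> tuple[str, str]:
    text = resources.files("deafscreen.data").joinpath(fname).read_text()
    lines = text.strip().splitlines()
    return lines[0][1:], "".join(lines[1:])


def _alleles(name: str) -> tuple[str, ...]:
    if name == "-" or not name:
        return ()
    return tuple(canonical_name(p) for p in name.split("+"))


def _check(cond: bool, table: str, msg: str) -> None:
    if not cond:
        raise CatalogueIntegrityError(f"{table}: {msg}")


@lru_cache(maxsize=1)
def load_catalogue() -> Catalogue:
    """Load and integrity-check the embedded catalogue.

    Raises CatalogueIntegrityError naming the failing table if any
    embedded resource is internally inconsistent.
    """
    gjb2_hdr, gjb2 = _read_fasta_resource("gjb2_cds.fasta")
    ex1_hdr, ex1 = _read_fasta_resource("gjb2_promoter_exon1.fasta")
    mt_hdr, mt = _read_fasta_resource("mt12s.fasta")
    mt_offset = int(mt_hdr.rsplit("offset=", 1)[1])
    refs = ReferenceSet(gjb2, ex1, mt, mt_offset)
    for seq, label in ((gjb2, "gjb2_cds"), (ex1, "promoter_exon1"), (mt, "mt12s")):
        _check(set(seq) <= set("ACGT"), "references", f"{label} has non-ACGT characters")

    vdf = _read_tsv("variants.tsv").fillna("")
    annotations: list[VariantAnnotation] = []
    for _, r in vdf.iterrows():
        locus = Locus(r["locus"])
        kind = _KIND[r["kind"]]
        pos = int(r["position"])
        ref_allele, alt_allele = r["ref_allele"], r["alt_allele"]
        seq, off = refs.sequence_for(locus)
        _check(
            off < pos <= off + len(seq),
            "variants",
            f"{r['name']}: position {pos} outside {locus.value} reference",
        )
        if ref_allele:
            got = seq[pos - off - 1 : pos - off - 1 + len(ref_allele)]
            _check(
                got == ref_allele,
                "variants",
                f"{r['name']}: reference has {got}, catalogue says {ref_allele}",
            )
        call = VariantCall(locus, kind, pos, ref_allele, alt_allele)
        annotations.append(
            VariantAnnotation(
                name=canonical_name(r["name"]),
                locus=locus,
                category=r["category"],
                domain_label=r["domain_label"],
                previously_reported=r["previously_reported"] == "yes",
                polyphen_score=float(r["polyphen_score"]) if r["polyphen_score"] else None,
                sift_score=float(r["sift_score"]) if r["sift_score"] else None,
                aa_change=r["aa_change"],
                call=call,
                equivalent_to=r["equivalent_to"],
            )
        )
    by_key = {(a.locus, a.name): a for a in annotations}
    _check(
        len(by_key) == len(annotations), "variants", "duplicate variant name at a locus"
    )

    t1 = _read_tsv("table1_gjb2.tsv")
    for c in ("case_carriers", "control_carriers"):
        t1[c] = t1[c].astype(int)
    for c in ("case_freq", "control_freq"):
        t1[c] = t1[c].astype(float)
    t1["name"] = t1["name"].map(canonical_name)

    t2rows = _read_tsv("table2_genotypes.tsv")
    strata = [
        GenotypeStratum(
            _alleles(r["allele1"]),
            _alleles(r["allele2"]),
            int(r["case_count"]),
            int(r["control_count"]),
        )
        for _, r in t2rows.iterrows()
    ]

    t3 = _read_tsv("table3_phenotypes.tsv")
    for c in t3.columns[2:]:
        t3[c] = t3[c].astype(int)

    t4 = _read_tsv("table4_mt.tsv")
    for c in ("case_count", "control_count", "ci_matches", "ci_total"):
        t4[c] = t4[c].astype(int)
    for c in ("case_freq", "control_freq"):
        t4[c] = t4[c].astype(float)
    t4["name"] = t4["name"].map(canonical_name)

    tables = FixtureTables(t1, strata, t3, t4)
    cat = Catalogue(annotations, refs, tables, by_key)
    _integrity(cat)
    return cat


def _integrity(cat: Catalogue) -> None:
    t1, t4 = cat.tables.table1_counts, cat.tables.table4_mt
    path_gjb2 = cat.pathogenic_names(Locus.GJB2)
    _check(
        len(path_gjb2) == 9,
        "variants",
        f"expected 9 pathogenic GJB2 entries, found {len(path_gjb2)}",
    )
    _check(len(t4) == 30, "table4_mt", f"expected 30 rows, found {len(t4)}")
    _check(
        set(t1["name"]) == {a.name for a in cat.annotations if a.locus is Locus.GJB2},
        "table1_gjb2",
        "variant names disagree with the catalogue",
    )
    _check(
        set(t4["name"]) == {a.name for a in cat.annotations if a.locus is Locus.MT12S},
        "table4_mt",
        "variant names disagree with the catalogue",
    )

    # printed frequencies must be recomputable from the counts
    for tab, label, n_case, n_ctrl, ccol, kcol in (
        (t1, "table1_gjb2", N_CASES, N_CONTROLS, "case_carriers", "control_carriers"),
        (t4, "table4_mt", N_CASES, N_CONTROLS, "case_count", "control_count"),
    ):
        for _, r in tab.iterrows():
            _check(
                carrier_frequency(r[ccol], n_case) == r["case_freq"],
                label,
                f"{r['name']}: case frequency mismatch",
            )
            _check(
                carrier_frequency(r[kcol], n_ctrl) == r["control_freq"],
                label,
                f"{r['name']}: control frequency mismatch",
            )

    # genotype strata: pathogenic stratification of the case group
    strata = cat.tables.table2_genotypes
    def n_path(s: GenotypeStratum) -> int:
        a1 = any(v in path_gjb2 for v in s.allele1)
        a2 = any(v in path_gjb2 for v in s.allele2)
        return a1 + a2
    mono = sum(s.case_count for s in strata if n_path(s) == 1)
    hom = sum(
        s.case_count
        for s in strata
        if n_path(s) == 2 and s.allele1 == s.allele2
    )
    chet = sum(
        s.case_count
        for s in strata
        if n_path(s) == 2 and s.allele1 != s.allele2
    )
    _check(mono == 70, "table2_genotypes", f"monoallelic case sum {mono} != 70")
    _check(hom == 79, "table2_genotypes", f"homozygous case sum {hom} != 79")
    _check(chet == 15, "table2_genotypes", f"compound-het case sum {chet} != 15")
    _check(
        mono + hom + chet == 164,
        "table2_genotypes",
        "pathogenic case strata do not sum to 164",
    )

    # derived carrier counts match the carrier table for pathogenic variants
    t1_case = dict(zip(t1["name"], t1["case_carriers"]))
    t1_ctrl = dict(zip(t1["name"], t1["control_carriers"]))
    for group, printed in (("case", t1_case), ("control", t1_ctrl)):
        derived = cat.tables.derived_carriers(group)
        for name in path_gjb2:
            _check(
                derived.get(name, 0) == printed[name],
                "table2_genotypes",
                f"{name}: derived {group} carriers {derived.get(name, 0)} "
                f"!= table1 {printed[name]}",
            )

    total_cases = sum(s.case_count for s in strata)
    _check(
        total_cases <= N_CASES,
        "table2_genotypes",
        f"case strata sum {total_cases} exceeds cohort size",
    )


def annotate_variant(
    name: str, locus: Locus, catalogue: Catalogue | None = None
) -> VariantAnnotation:
    """Look up a legacy variant name; unseen names get a novel annotation.

    Malformed names raise VariantNameError.
    """
    cname = canonical_name(name)
    parsed = parse_variant_name(cname)  # validates syntax
    want_prefix = locus.prefix
    if parsed["prefix"] != want_prefix:
        raise ValueError(f"name {name!r} has prefix {parsed['prefix']}, locus wants {want_prefix}")
    cat = catalogue or load_catalogue()
    hit = cat.get(cname, locus)
    if hit is not None:
        return hit
    call = None
    if "ref" in parsed or "alt" in parsed:
        kind = _KIND.get(parsed["kind"])
        if kind is not None:
            call = VariantCall(
                locus, kind, parsed["position"], parsed.get("ref", ""), parsed.get("alt", "")
            )
    return VariantAnnotation(
        name=cname,
        locus=locus,
        category="novel",
        previously_reported=False,
        call=call,
    )
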