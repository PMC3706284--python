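"""End-to-end screening pipeline over a (synthetic or supplied) cohort.

Runs the full analysis the package implements: variant calling of every
subject sequence against the locus references, genotype classification,
carrier-frequency tables for both loci, the GJB2 summary figures, the
genotype-phenotype cross-tabulation, conservation-index computation
from an ortholog alignment, mtDNA variant triage, and the
secondary-structure comparison for the novel 12S variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import stats
from .calling import AlignmentParams, Locus, VariantCall, call_sequence
from .catalogue import Catalogue, load_catalogue
from .cohort import CohortResult, CohortSpec, MsaSpec, generate_cohort, generate_msa, plant_variant
from .conservation import (
    CIRecord,
    TriageResult,
    conservation_index,
    map_msa_columns,
    summarize_ci_bins,
    triage_mt_variant,
)
from .genotypes import (
    GenotypeRecord,
    SeverityBand,
    classify_severity,
    crosstab_genotype_phenotype,
    genotype_from_calls,
    pta_average,
)
from .io import SequenceRecord
from .rna import StructureDelta, fold_rna, structure_delta

__all__ = ["ScreenResult", "run_screen", "call_cohort"]

#: half-window (nt) of 12S sequence folded around a variant position
FOLD_WINDOW = 60


@dataclass
class ScreenResult:
    """Everything the pipeline computes for one cohort."""

    catalogue: Catalogue
    cohort: CohortResult
    genotypes: dict[str, GenotypeRecord]  # subject -> GJB2 genotype
    severities: dict[str, SeverityBand]
    gjb2_table: stats.CohortTable
    mt_table: stats.CohortTable
    gjb2_summary: stats.Gjb2Summary
    crosstab: pd.DataFrame
    mt_carrier_sets: dict[str, dict[str, set[str]]]  # group -> name -> ids
    ci_records: list[CIRecord]
    ci_bins: tuple[int, int, int]
    triage: list[TriageResult]
    rna_delta: StructureDelta
    exon1_calls: list[VariantCall]
    combined_carrier_freq: float

    @property
    def putative_new(self) -> list[str]:
        return [
            t.name for t in self.triage if t.tclass == "putative_deafness_associated"
        ]


def call_cohort(
    records: list[SequenceRecord],
    catalogue: Catalogue,
    params: AlignmentParams | None = None,
) -> dict[str, dict[Locus, dict[int | str, list[VariantCall]]]]:
    """Call variants for every record, caching identical sequences."""
    cache: dict[tuple[Locus, str], list[VariantCall]] = {}
    out: dict[str, dict[Locus, dict[int | str, list[VariantCall]]]] = {}
    for rec in records:
        key = (rec.locus, rec.sequence)
        if key not in cache:
            ref, off = catalogue.references.sequence_for(rec.locus)
            cache[key] = call_sequence(rec.sequence, ref, rec.locus, off, params)
        out.setdefault(rec.subject_id, {}).setdefault(rec.locus, {})[
            rec.allele_index
        ] = cache[key]
    return out


def _mt_profile(catalogue: Catalogue) -> tuple[int, ...]:
    """Per-column conservation targets: the catalogued matches at variant
    positions, full conservation elsewhere."""
    mt, off = catalogue.references.sequence_for(Locus.MT12S)
    t4 = catalogue.tables.table4_mt
    profile = [22] * len(mt)
    for _, r in t4.iterrows():
        ann = catalogue.get(r["name"], Locus.MT12S)
        profile[ann.call.position - off - 1] = int(r["ci_matches"])
    return tuple(profile)


def run_screen(seed: int = 0, catalogue: Catalogue | None = None) -> ScreenResult:
    """Generate the fixture cohort and run the complete analysis on it."""
    cat = catalogue or load_catalogue()
    spec = CohortSpec.from_fixtures(cat, seed=seed)
    cohort = generate_cohort(spec, cat.references, cat)
    calls = call_cohort(cohort.records, cat)

    genotypes: dict[str, GenotypeRecord] = {}
    severities: dict[str, SeverityBand] = {}
    onsets: dict[str, str] = {}
    exon1_calls: list[VariantCall] = []
    gjb2_sets: dict[str, dict[str, set[str]]] = {"case": {}, "control": {}}
    mt_sets: dict[str, dict[str, set[str]]] = {"case": {}, "control": {}}
    for subj in cohort.subjects:
        per_locus = calls[subj.id]
        genotypes[subj.id] = genotype_from_calls(
            subj.id, per_locus.get(Locus.GJB2, {}), cat
        )
        severities[subj.id] = classify_severity(pta_average(subj.audiogram))
        onsets[subj.id] = subj.onset
        exon1_calls += [
            c for allele in per_locus.get(Locus.GJB2_EX1, {}).values() for c in allele
        ]
        for name in set(genotypes[subj.id].carried):
            gjb2_sets[subj.group].setdefault(name, set()).add(subj.id)
        for c in per_locus.get(Locus.MT12S, {}).get("mito", []):
            mt_sets[subj.group].setdefault(c.name, set()).add(subj.id)

    t1_order = list(cat.tables.table1_counts["name"])
    gjb2_table = stats.tally_carriers(
        gjb2_sets, spec.n_cases, spec.n_controls, variant_order=t1_order
    )
    mt_order = [
        n
        for n in cat.tables.table4_mt["name"]
        if n in mt_sets["case"] or n in mt_sets["control"]
    ]
    mt_table = stats.tally_carriers(
        mt_sets, spec.n_cases, spec.n_controls, variant_order=mt_order
    )

    case_genotypes = [genotypes[sid] for sid in cohort.case_ids]
    gjb2_summary = stats.summarize_gjb2(case_genotypes, n_cases=spec.n_cases)
    crosstab = crosstab_genotype_phenotype(case_genotypes, severities, onsets)

    combined = stats.combined_deafness_frequency(
        {
            g.subject_id
            for g in case_genotypes
            if g.gclass.value in ("biallelic_homozygous", "biallelic_compound_het", "monoallelic")
        },
        mt_sets["case"],
        ["m.1555A>G", "m.1494C>T"],
        spec.n_cases,
    )

    # conservation: synthetic ortholog alignment honouring the catalogued
    # per-position conservation, then CI and triage for the variant panel
    mt_ref, mt_off = cat.references.sequence_for(Locus.MT12S)
    msa = generate_msa(MsaSpec(_mt_profile(cat), n_species=22, seed=seed + 1), mt_ref)
    cmap = map_msa_columns(msa, "human", mt_off)
    ci_records: list[CIRecord] = []
    triage: list[TriageResult] = []
    for _, r in cat.tables.table4_mt.iterrows():
        ann = cat.get(r["name"], Locus.MT12S)
        rec = conservation_index(
            msa, ann.call.position, ann.call.ref_allele or mt_ref[ann.call.position - mt_off - 1],
            column_map=cmap,
        )
        ci_records.append(rec)
        triage.append(
            triage_mt_variant(
                r["name"], int(r["case_count"]), int(r["control_count"]),
                rec.ci_percent, cat,
            )
        )
    ci_bins = summarize_ci_bins(ci_records)

    # structural consequence of the novel m.1222A>G variant on a local
    # 12S window (coarse maximum-pairing model)
    v1222 = cat.get("m.1222A>G", Locus.MT12S).call
    i = v1222.position - mt_off - 1
    lo, hi = max(0, i - FOLD_WINDOW), min(len(mt_ref), i + FOLD_WINDOW + 1)
    wt_win = mt_ref[lo:hi]
    mut_win = plant_variant(wt_win, VariantCall(
        Locus.MT12S, v1222.kind, i - lo + 1, v1222.ref_allele, v1222.alt_allele
    ))
    rna_delta = structure_delta(
        fold_rna(wt_win), fold_rna(mut_win), variant_position=i - lo + 1
    )

    return ScreenResult(
        catalogue=cat,
        cohort=cohort,
        genotypes=genotypes,
        severities=severities,
        gjb2_table=gjb2_table,
        mt_table=mt_table,
        gjb2_summary=gjb2_summary,
        crosstab=crosstab,
        mt_carrier_sets=mt_sets,
        ci_records=ci_records,
        ci_bins=ci_bins,
        triage=triage,
        rna_delta=rna_delta,
        exon1_calls=exon1_calls,
        combined_carrier_freq=combined,
    )
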