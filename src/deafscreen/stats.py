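"""Cohort-level carrier counts, frequencies and summary aggregates.

Carrier frequency counts *subjects*: a subject carrying a variant on one
or both alleles (or homoplasmically in mtDNA) contributes once.
Percentages are rounded half-up, 2 decimal places, matching how carrier
tables in the deafness-screening literature are printed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = [
    "round_half_up",
    "carrier_frequency",
    "CohortTable",
    "tally_carriers",
    "Gjb2Summary",
    "summarize_gjb2",
    "aggregate_variants",
    "combined_deafness_frequency",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (half-up), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def carrier_frequency(count: int, n: int, ndigits: int = 2) -> float:
    """Percent of a group of size ``n`` carrying a variant, half-up rounded."""
    if n <= 0:
        raise ValueError(f"group size must be positive, got {n}")
    if not 0 <= count <= n:
        raise ValueError(f"carrier count {count} outside [0, {n}]")
    q = Decimal(1).scaleb(-ndigits)
    return float((Decimal(count) * 100 / Decimal(n)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CohortTable:
    """Per-variant carrier counts and percent frequencies in both groups."""

    rows: pd.DataFrame  # name, case_carriers, case_freq, control_carriers, control_freq
    n_cases: int
    n_controls: int

    def row(self, name: str) -> pd.Series:
        hit = self.rows[self.rows["name"] == name]
        if hit.empty:
            raise KeyError(f"variant {name!r} not in cohort table")
        return hit.iloc[0]


def tally_carriers(
    carrier_sets: dict[str, dict[str, set[str]]],
    n_cases: int,
    n_controls: int,
    variant_order: list[str] | None = None,
) -> CohortTable:
    """Build a cohort table from per-variant carrier-subject sets.

    ``carrier_sets`` maps group ("case"/"control") to variant name to the
    set of subject ids carrying it; a subject counts once per variant
    regardless of zygosity.
    """
    names = variant_order or sorted(
        set(carrier_sets.get("case", {})) | set(carrier_sets.get("control", {}))
    )
    rows = []
    for name in names:
        ca = len(carrier_sets.get("case", {}).get(name, ()))
        co = len(carrier_sets.get("control", {}).get(name, ()))
        rows.append(
            {
                "name": name,
                "case_carriers": ca,
                "case_freq": carrier_frequency(ca, n_cases),
                "control_carriers": co,
                "control_freq": carrier_frequency(co, n_controls),
            }
        )
    cols = ["name", "case_carriers", "case_freq", "control_carriers", "control_freq"]
    return CohortTable(pd.DataFrame(rows, columns=cols), n_cases, n_controls)


@dataclass(frozen=True)
class Gjb2Summary:
    """Headline GJB2 figures for the case group."""

    n_biallelic: int
    n_homozygous: int
    n_compound_het: int
    n_monoallelic: int
    n_pathogenic_carriers: int
    pathogenic_carrier_freq: float
    n_cases: int

    def __post_init__(self) -> None:
        assert self.n_biallelic == self.n_homozygous + self.n_compound_het
        assert self.n_pathogenic_carriers == self.n_biallelic + self.n_monoallelic


def summarize_gjb2(genotypes, n_cases: int | None = None) -> Gjb2Summary:
    """Summarize assigned genotype classes for the case group.

    ``genotypes`` is an iterable of GenotypeRecord (genotypes module);
    only the genotype-class field is consulted.
    """
    from .genotypes import GenotypeClass

    gclasses = [g.gclass for g in genotypes]
    n = n_cases if n_cases is not None else len(gclasses)
    hom = sum(g is GenotypeClass.BIALLELIC_HOMOZYGOUS for g in gclasses)
    chet = sum(g is GenotypeClass.BIALLELIC_COMPOUND_HET for g in gclasses)
    mono = sum(g is GenotypeClass.MONOALLELIC for g in gclasses)
    carriers = hom + chet + mono
    return Gjb2Summary(
        n_biallelic=hom + chet,
        n_homozygous=hom,
        n_compound_het=chet,
        n_monoallelic=mono,
        n_pathogenic_carriers=carriers,
        pathogenic_carrier_freq=carrier_frequency(carriers, n) if n else 0.0,
        n_cases=n,
    )


def aggregate_variants(table: CohortTable, names: list[str]) -> tuple[int, float]:
    """Sum of per-variant case carrier counts over ``names``, with frequency.

    This sums table rows, so a subject carrying two of the listed
    variants is counted twice; compare with a subject-level union when
    the distinction matters.
    """
    total = 0
    for name in names:
        total += int(table.row(name)["case_carriers"])
    return total, carrier_frequency(total, table.n_cases)


def combined_deafness_frequency(
    gjb2_carriers: set[str],
    mt_carrier_sets: dict[str, set[str]],
    mt_pathogenic_names: list[str],
    n_cases: int,
) -> float:
    """Percent of cases carrying a deafness-causing mutation in either gene.

    Union semantics at the subject level: the set of GJB2
    pathogenic-genotype carriers is merged with the carriers of each of
    the listed mtDNA mutations.
    """
    union = set(gjb2_carriers)
    for name in mt_pathogenic_names:
        union |= mt_carrier_sets.get(name, set())
    return carrier_frequency(len(union), n_cases)
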