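"""Per-subject GJB2 genotype classes and audiometric severity banding.

A subject's genotype class is determined by how many of the two nuclear
alleles carry a *pathogenic* catalogue variant: two identical ones make
a biallelic homozygote, two different ones a compound heterozygote, one
a monoallelic carrier. Polymorphisms and variants of unknown
significance never count toward the pathogenic allele number; subjects
carrying only those form their own stratum.

Hearing severity is banded from the pure-tone average (PTA) over 0.5,
1, 2 and 4 kHz in the better ear: 26-40 dB mild, 41-60 moderate,
61-80 severe, above 80 profound. Non-integer averages are classified
on the real line, so 40.5 dB already counts as moderate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .calling import Locus
from .catalogue import Catalogue

__all__ = [
    "GenotypeClass",
    "GenotypeRecord",
    "SeverityBand",
    "pta_average",
    "classify_severity",
    "assign_genotype",
    "genotype_from_calls",
    "crosstab_genotype_phenotype",
]


class GenotypeClass(str, Enum):
    BIALLELIC_HOMOZYGOUS = "biallelic_homozygous"
    BIALLELIC_COMPOUND_HET = "biallelic_compound_het"
    MONOALLELIC = "monoallelic"
    POLYMORPHISM_OR_UNKNOWN_ONLY = "polymorphism_or_unknown_only"
    NONE = "none"


@dataclass(frozen=True)
class GenotypeRecord:
    subject_id: str
    allele1: tuple[str, ...]
    allele2: tuple[str, ...]
    gclass: GenotypeClass

    @property
    def carried(self) -> tuple[str, ...]:
        return self.allele1 + self.allele2

    @property
    def genotype_label(self) -> str:
        """Printable genotype, e.g. ``c.235delC/c.299delAT`` or ``c.79G>A``."""
        a1 = "+".join(self.allele1) or "-"
        a2 = "+".join(self.allele2) or "-"
        if not self.allele1 and not self.allele2:
            return "-"
        if not self.allele2:
            return a1
        return f"{a1}/{a2}"


@dataclass(frozen=True)
class SeverityBand:
    band: str  # normal | mild | moderate | severe | profound
    pta: float


def pta_average(thresholds) -> float:
    """Arithmetic mean of the four speech-frequency thresholds."""
    t = list(thresholds)
    if len(t) != 4 or any(x is None for x in t):
        raise ValueError("PTA needs all four thresholds (0.5/1/2/4 kHz)")
    return sum(float(x) for x in t) / 4.0


def classify_severity(pta: float) -> SeverityBand:
    """Band a PTA value; boundaries are inclusive at the top of each band."""
    if pta < 0:
        raise ValueError(f"PTA must be non-negative, got {pta}")
    if pta < 26:
        band = "normal"
    elif pta <= 40:
        band = "mild"
    elif pta <= 60:
        band = "moderate"
    elif pta <= 80:
        band = "severe"
    else:
        band = "profound"
    return SeverityBand(band, pta)


def assign_genotype(
    subject_id: str,
    allele1: tuple[str, ...] | list[str],
    allele2: tuple[str, ...] | list[str],
    catalogue: Catalogue,
    locus: Locus = Locus.GJB2,
) -> GenotypeRecord:
    """Assign the genotype class from the variant names on each allele."""
    a1, a2 = tuple(allele1), tuple(allele2)
    pathogenic = catalogue.pathogenic_names(locus)

    def path_on(allele: tuple[str, ...]) -> frozenset:
        return frozenset(v for v in allele if v in pathogenic)

    p1, p2 = path_on(a1), path_on(a2)
    n_path = bool(p1) + bool(p2)
    if n_path == 2:
        gclass = (
            GenotypeClass.BIALLELIC_HOMOZYGOUS
            if p1 == p2
            else GenotypeClass.BIALLELIC_COMPOUND_HET
        )
    elif n_path == 1:
        gclass = GenotypeClass.MONOALLELIC
    elif a1 or a2:
        gclass = GenotypeClass.POLYMORPHISM_OR_UNKNOWN_ONLY
    else:
        gclass = GenotypeClass.NONE
    return GenotypeRecord(subject_id, a1, a2, gclass)


def genotype_from_calls(
    subject_id: str,
    allele_calls: dict[int, list],
    catalogue: Catalogue,
) -> GenotypeRecord:
    """Assemble a genotype from per-allele variant calls (1 and 2)."""
    extra = set(allele_calls) - {1, 2}
    if extra:
        raise ValueError(
            f"{subject_id}: more than two allele sequences for a nuclear locus"
        )
    a1 = tuple(c.name for c in allele_calls.get(1, []))
    a2 = tuple(c.name for c in allele_calls.get(2, []))
    return assign_genotype(subject_id, a1, a2, catalogue)


def crosstab_genotype_phenotype(
    genotypes: list[GenotypeRecord],
    severities: dict[str, SeverityBand],
    onsets: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Genotype x severity (x onset) counts over the case cohort.

    Returns one row per genotype label with subject counts per severity
    band and onset class; rows partition the input subjects.
    """
    onsets = onsets or {}
    counts: dict[str, Counter] = {}
    order: list[str] = []
    for g in genotypes:
        label = g.genotype_label
        if label not in counts:
            counts[label] = Counter()
            order.append(label)
        band = severities[g.subject_id].band
        counts[label]["n"] += 1
        counts[label][band] += 1
        counts[label][f"onset_{onsets.get(g.subject_id, 'unknown')}"] += 1
    cols = [
        "genotype", "n", "normal", "mild", "moderate", "severe", "profound",
        "onset_postlingual", "onset_prelingual", "onset_unknown",
    ]
    rows = [
        {"genotype": label, **{c: counts[label].get(c, 0) for c in cols[1:]}}
        for label in order
    ]
    return pd.DataFrame(rows, columns=cols)
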