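"""Synthetic study-cohort generation.

Builds self-contained pipeline inputs that emulate the screened study
population: a case group (default 658 subjects, moderate-to-profound
nonsyndromic hearing loss) and a control group (default 462, normal
hearing), with GJB2 allele sequences and homoplasmic mtDNA 12S
sequences carrying planted variants according to a genotype-count
specification, audiograms sampled to match the per-genotype severity
composition, and multi-species ortholog alignments with an exactly
configured per-column conservation profile.

Everything is deterministic under a fixed seed; the same seed produces
byte-identical FASTA output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calling import Locus, ReferenceMismatchError, VariantCall, VariantKind
from .catalogue import Catalogue, GenotypeStratum, ReferenceSet
from .io import SequenceRecord

__all__ = [
    "CohortSpecError",
    "Subject",
    "CohortSpec",
    "MsaSpec",
    "CohortResult",
    "plant_variant",
    "apply_variants",
    "generate_cohort",
    "generate_msa",
]

#: severity band -> integer PTA range (dB) used when sampling audiograms
_BAND_PTA = {
    "normal": (5, 20),
    "mild": (26, 40),
    "moderate": (41, 60),
    "severe": (61, 80),
    "profound": (81, 110),
}

#: mtDNA variants whose carrier sets must not overlap, either because the
#: variants occupy the same or adjacent positions (one merged call would
#: result) or because the study arithmetic treats the carrier groups as
#: disjoint (GJB2 pathogenic genotypes vs the two main mtDNA mutations)
_DISJOINT_GROUPS = (
    ("__GJB2_PATHOGENIC__", "m.1555A>G", "m.1494C>T"),
    ("m.961insC", "m.961delT+insC", "m.961T>C"),
    ("m.1040T>C", "m.1041A>G"),
)


class CohortSpecError(ValueError):
    """A cohort specification that cannot be satisfied."""


@dataclass(frozen=True)
class Subject:
    """One study participant with audiological metadata."""

    id: str
    group: str  # case | control
    sex: str
    age: int
    audiogram: tuple[float, float, float, float]  # dB at 0.5/1/2/4 kHz, better ear
    onset: str  # prelingual | postlingual | unknown
    aminoglycoside_exposure: bool

    def __post_init__(self) -> None:
        if not all(0 <= t <= 120 for t in self.audiogram):
            raise ValueError(f"{self.id}: audiogram thresholds outside 0-120 dB")


@dataclass(frozen=True)
class CohortSpec:
    """Counts-level description of the cohort to generate.

    ``genotype_strata`` follows the genotype fixture table;
    ``mt_variant_counts`` maps mtDNA variant name to (case, control)
    carrier counts; ``phenotypes`` optionally maps a stratum key
    (allele1 tuple, allele2 tuple) to severity and onset counts
    (moderate, severe, profound, post, pre, unknown).
    """

    n_cases: int
    n_controls: int
    genotype_strata: list[GenotypeStratum]
    mt_variant_counts: dict[str, tuple[int, int]]
    seed: int = 0
    phenotypes: dict[tuple, tuple[int, int, int, int, int, int]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        ncase = sum(s.case_count for s in self.genotype_strata)
        nctrl = sum(s.control_count for s in self.genotype_strata)
        if ncase > self.n_cases:
            raise CohortSpecError(
                f"case stratum counts sum to {ncase} > group size {self.n_cases}"
            )
        if nctrl > self.n_controls:
            raise CohortSpecError(
                f"control stratum counts sum to {nctrl} > group size {self.n_controls}"
            )
        for name, (ca, co) in self.mt_variant_counts.items():
            if ca > self.n_cases or co > self.n_controls:
                raise CohortSpecError(f"{name}: mtDNA carrier count exceeds group size")

    @classmethod
    def from_fixtures(cls, catalogue: Catalogue, seed: int = 0) -> "CohortSpec":
        """The study conditions: genotype and mtDNA counts of the fixtures."""
        t = catalogue.tables
        mt = {
            r["name"]: (int(r["case_count"]), int(r["control_count"]))
            for _, r in t.table4_mt.iterrows()
        }
        phen = {}
        for _, r in t.table3_phenotypes.iterrows():
            key = (_split(r["allele1"]), _split(r["allele2"]))
            phen[key] = (
                r["moderate"], r["severe"], r["profound"],
                r["onset_postlingual"], r["onset_prelingual"], r["onset_unknown"],
            )
        return cls(
            n_cases=t.n_cases,
            n_controls=t.n_controls,
            genotype_strata=list(t.table2_genotypes),
            mt_variant_counts=mt,
            seed=seed,
            phenotypes=phen,
        )


def _split(cell: str) -> tuple[str, ...]:
    return () if cell in ("-", "") else tuple(cell.split("+"))


@dataclass(frozen=True)
class MsaSpec:
    """Target shape of a synthetic ortholog alignment.

    ``conservation_profile[i]`` is the number of species (reference
    included, so at least 1) whose base at column ``i`` must equal the
    reference base.
    """

    conservation_profile: tuple[int, ...]
    n_species: int = 22
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 1 <= m <= self.n_species for m in self.conservation_profile):
            raise CohortSpecError(
                f"conservation profile values must lie in [1, {self.n_species}]"
            )


@dataclass
class CohortResult:
    """Generated subjects, their sequences, and the planting ground truth."""

    subjects: list[Subject]
    records: list[SequenceRecord]
    truth_gjb2: dict[str, tuple[tuple[str, ...], tuple[str, ...]]]
    truth_mt: dict[str, tuple[str, ...]]
    gjb2_pathogenic_carriers: set[str]

    @property
    def case_ids(self) -> list[str]:
        return [s.id for s in self.subjects if s.group == "case"]

    @property
    def control_ids(self) -> list[str]:
        return [s.id for s in self.subjects if s.group == "control"]


def plant_variant(
    reference: str, variant: VariantCall, coordinate_offset: int = 0
) -> str:
    """Apply one edit to a reference string (locus coordinates).

    Raises ReferenceMismatchError if the variant's stated reference
    allele disagrees with the sequence.
    """
    i = variant.position - coordinate_offset - 1
    if not 0 <= i < len(reference):
        raise ReferenceMismatchError(
            f"{variant.name}: position outside reference of length {len(reference)}"
        )
    if variant.kind is VariantKind.INSERTION:
        return reference[: i + 1] + variant.alt_allele + reference[i + 1 :]
    found = reference[i : i + len(variant.ref_allele)]
    if found != variant.ref_allele:
        raise ReferenceMismatchError(
            f"{variant.name}: reference has {found!r}, call expects "
            f"{variant.ref_allele!r}"
        )
    return reference[:i] + variant.alt_allele + reference[i + len(variant.ref_allele) :]


def apply_variants(
    reference: str, calls: list[VariantCall], coordinate_offset: int = 0
) -> str:
    """Apply several edits; applied right-to-left so positions stay valid."""
    seq = reference
    for call in sorted(calls, key=lambda c: c.position, reverse=True):
        seq = plant_variant(seq, call, coordinate_offset)
    return seq


def _sample_audiogram(rng: np.random.Generator, band: str) -> tuple[int, ...]:
    """Four integer thresholds whose mean is an integer PTA inside the band."""
    lo, hi = _BAND_PTA[band]
    b = int(rng.integers(lo, hi + 1))
    d = int(rng.integers(0, 6))
    e = int(rng.integers(0, 6))
    return (b + d, b - d, b + e, b - e)


def _severity_onset_queue(
    spec: CohortSpec, stratum_key: tuple, n: int, group: str
) -> list[tuple[str, str]]:
    """Per-subject (severity band, onset) labels for one stratum."""
    if group == "control":
        return [("normal", "unknown")] * n
    phen = spec.phenotypes.get(stratum_key)
    if phen is None:
        return [("profound", "prelingual")] * n
    mod, sev, prof, post, pre, unk = phen
    bands = ["moderate"] * mod + ["severe"] * sev + ["profound"] * prof
    onsets = ["postlingual"] * post + ["prelingual"] * pre + ["unknown"] * unk
    bands += ["profound"] * (n - len(bands))
    onsets += ["unknown"] * (n - len(onsets))
    return list(zip(bands[:n], onsets[:n]))


def generate_cohort(
    spec: CohortSpec, refs: ReferenceSet, catalogue: Catalogue
) -> CohortResult:
    """Generate subjects and sequences matching the specification exactly.

    Every genotype stratum receives exactly its specified number of
    subjects, mtDNA carrier counts are exact, and the carrier sets
    listed in the module-level disjointness groups never overlap.
    """
    rng = np.random.default_rng(spec.seed)
    gjb2_ref, gjb2_off = refs.sequence_for(Locus.GJB2)
    ex1_ref, _ = refs.sequence_for(Locus.GJB2_EX1)
    mt_ref, mt_off = refs.sequence_for(Locus.MT12S)
    path_names = catalogue.pathogenic_names(Locus.GJB2)

    def resolve(name: str) -> VariantCall:
        ann = catalogue.get(name, Locus.GJB2) or catalogue.get(name, Locus.MT12S)
        if ann is None or ann.call is None:
            raise CohortSpecError(f"variant {name!r} not in catalogue")
        return ann.call

    subjects: list[Subject] = []
    truth_gjb2: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {}
    truth_mt: dict[str, list[str]] = {}
    gjb2_path_carriers: set[str] = set()
    group_ids: dict[str, list[str]] = {"case": [], "control": []}

    for group, n_group, prefix in (
        ("case", spec.n_cases, "C"),
        ("control", spec.n_controls, "N"),
    ):
        count_attr = "case_count" if group == "case" else "control_count"
        assignments: list[tuple[tuple[str, ...], tuple[str, ...]]] = []
        labels: list[tuple[str, str]] = []
        for s in spec.genotype_strata:
            n = getattr(s, count_attr)
            assignments += [(s.allele1, s.allele2)] * n
            labels += _severity_onset_queue(spec, (s.allele1, s.allele2), n, group)
        n_rest = n_group - len(assignments)
        assignments += [((), ())] * n_rest
        labels += _severity_onset_queue(spec, ((), ()), n_rest, group)

        age_lo, age_hi = (2, 45) if group == "case" else (8, 34)
        for k, ((a1, a2), (band, onset)) in enumerate(zip(assignments, labels), 1):
            sid = f"{prefix}{k:04d}"
            subjects.append(
                Subject(
                    id=sid,
                    group=group,
                    sex=str(rng.choice(["F", "M"])),
                    age=int(rng.integers(age_lo, age_hi + 1)),
                    audiogram=_sample_audiogram(rng, band),
                    onset=onset,
                    aminoglycoside_exposure=False,
                )
            )
            truth_gjb2[sid] = (a1, a2)
            truth_mt[sid] = []
            group_ids[group].append(sid)
            if any(v in path_names for v in a1 + a2):
                gjb2_path_carriers.add(sid)

    # mtDNA carrier assignment with disjointness constraints
    blocked: dict[str, set[str]] = {}
    for grp in _DISJOINT_GROUPS:
        for name in grp:
            blocked.setdefault(name, set())
    mt_order = list(spec.mt_variant_counts)
    for group in ("case", "control"):
        idx = 0 if group == "case" else 1
        used_in_group: dict[tuple[str, ...], set[str]] = {
            grp: set() for grp in _DISJOINT_GROUPS
        }
        if group == "case":
            for grp in _DISJOINT_GROUPS:
                if "__GJB2_PATHOGENIC__" in grp:
                    used_in_group[grp] |= gjb2_path_carriers
        for name in mt_order:
            n = spec.mt_variant_counts[name][idx]
            if n == 0:
                continue
            excluded: set[str] = set()
            for grp in _DISJOINT_GROUPS:
                if name in grp:
                    excluded |= used_in_group[grp]
            eligible = [sid for sid in group_ids[group] if sid not in excluded]
            if len(eligible) < n:
                raise CohortSpecError(
                    f"{name}: cannot place {n} {group} carriers disjointly"
                )
            chosen = rng.choice(len(eligible), size=n, replace=False)
            carriers = [eligible[i] for i in sorted(chosen)]
            for sid in carriers:
                truth_mt[sid].append(name)
            for grp in _DISJOINT_GROUPS:
                if name in grp:
                    used_in_group[grp] |= set(carriers)

    # aminoglycoside exposure: three of the four m.1494C>T carriers had a
    # documented exposure history; background exposure is rare
    m1494 = sorted(sid for sid, names in truth_mt.items() if "m.1494C>T" in names)
    exposed = set(m1494[:3])
    background = rng.random(len(subjects)) < 0.02
    subjects = [
        Subject(
            s.id, s.group, s.sex, s.age, s.audiogram, s.onset,
            s.id in exposed or bool(background[i]),
        )
        for i, s in enumerate(subjects)
    ]

    # sequence synthesis
    records: list[SequenceRecord] = []
    for s in subjects:
        a1, a2 = truth_gjb2[s.id]
        for allele_index, names in ((1, a1), (2, a2)):
            seq = apply_variants(gjb2_ref, [resolve(n) for n in names], gjb2_off)
            records.append(SequenceRecord(s.id, Locus.GJB2, allele_index, seq))
        records.append(SequenceRecord(s.id, Locus.GJB2_EX1, 1, ex1_ref))
        mt_calls = [resolve(n) for n in truth_mt[s.id]]
        records.append(
            SequenceRecord(s.id, Locus.MT12S, "mito", apply_variants(mt_ref, mt_calls, mt_off))
        )

    return CohortResult(
        subjects=subjects,
        records=records,
        truth_gjb2=truth_gjb2,
        truth_mt={k: tuple(v) for k, v in truth_mt.items()},
        gjb2_pathogenic_carriers=gjb2_path_carriers,
    )


def generate_msa(spec: MsaSpec, human_row: str) -> MultipleSeqAlignment:
    """Synthesize an ortholog alignment with an exact conservation profile.

    The human reference row is kept verbatim; at each column exactly
    ``profile - 1`` of the other species carry the human base and the
    rest a uniformly drawn alternative base. No gaps are generated.
    """
    if len(spec.conservation_profile) != len(human_row):
        raise CohortSpecError(
            f"profile length {len(spec.conservation_profile)} != sequence "
            f"length {len(human_row)}"
        )
    rng = np.random.default_rng(spec.seed)
    n_other = spec.n_species - 1
    length = len(human_row)
    bases = np.array(list("ACGT"))
    grid = np.empty((n_other, length), dtype="<U1")
    human = np.array(list(human_row))
    for j in range(length):
        want = spec.conservation_profile[j] - 1  # human always matches
        matchers = rng.choice(n_other, size=want, replace=False)
        col = np.empty(n_other, dtype="<U1")
        mask = np.zeros(n_other, dtype=bool)
        mask[matchers] = True
        col[mask] = human[j]
        alts = bases[bases != human[j]]
        col[~mask] = alts[rng.integers(0, 3, size=int((~mask).sum()))]
        grid[:, j] = col
    rows = [SeqRecord(Seq(human_row), id="human", description="")]
    rows += [
        SeqRecord(Seq("".join(grid[i])), id=f"primate_{i + 1:02d}", description="")
        for i in range(n_other)
    ]
    return MultipleSeqAlignment(rows)
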