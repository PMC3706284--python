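"""Readers and writers for the formats the pipeline touches.

Sequences travel as FASTA with structured record ids
(``subject|locus|allele``); variant calls are written either as a
legacy-name TSV or as minimal VCF 4.2 (1-based positions, left-anchored
indels against the locus reference). Pipeline configuration is a flat
YAML file.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calling import Locus, VariantCall, VariantKind
from .catalogue import ReferenceSet, VariantAnnotation

__all__ = [
    "SequenceRecord",
    "PipelineConfig",
    "read_fasta",
    "write_fasta",
    "write_variant_table",
    "read_variant_table",
    "load_config",
    "FastaFormatError",
]

logger = logging.getLogger("deafscreen")

_ALLELE_TOKENS = {"1": 1, "2": 2, "mito": "mito"}


class FastaFormatError(ValueError):
    """Malformed FASTA input (bad header layout or alphabet)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One subject sequence at one locus.

    ``allele_index`` is 1 or 2 for the nuclear locus and ``"mito"`` for
    the (homoplasmic) mitochondrial sequence.
    """

    subject_id: str
    locus: Locus
    allele_index: int | str
    sequence: str

    def __post_init__(self) -> None:
        if not set(self.sequence) <= set("ACGTN"):
            raise FastaFormatError(
                f"{self.id}: sequence contains characters outside ACGTN"
            )
        is_mito = self.allele_index == "mito"
        if is_mito != (self.locus is Locus.MT12S):
            raise ValueError(
                f"{self.id}: allele_index 'mito' is required exactly for MT12S"
            )

    @property
    def id(self) -> str:
        return f"{self.subject_id}|{self.locus.value}|{self.allele_index}"


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read subject sequences; ids must be ``subject|locus|allele``.

    Lowercase sequence is uppercased with a warning. An empty file
    yields an empty list.
    """
    records: list[SequenceRecord] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        parts = rec.id.split("|")
        if len(parts) != 3 or parts[1] not in Locus.__members__:
            raise FastaFormatError(
                f"{path}: record {i + 1} ({rec.id!r}): header must be "
                "'subject|locus|allele'"
            )
        allele = _ALLELE_TOKENS.get(parts[2])
        if allele is None:
            raise FastaFormatError(
                f"{path}: record {i + 1} ({rec.id!r}): allele must be 1, 2 or mito"
            )
        seq = str(rec.seq)
        if seq != seq.upper():
            warnings.warn(f"{rec.id}: lowercase sequence uppercased", stacklevel=2)
            seq = seq.upper()
        records.append(SequenceRecord(parts[0], Locus(parts[1]), allele, seq))
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def _vcf_fields(call: VariantCall, refs: ReferenceSet) -> tuple[str, int, str, str]:
    """Map a call to (CHROM, POS, REF, ALT) with left-anchored indels."""
    seq, off = refs.sequence_for(call.locus)

    def base(pos: int) -> str:
        idx = pos - off - 1
        if not 0 <= idx < len(seq):
            raise ValueError(f"{call.name}: position {pos} unmappable on {call.locus.value}")
        return seq[idx]

    if call.kind in (VariantKind.SUBSTITUTION, VariantKind.MNV_SUBSTITUTION):
        return call.locus.value, call.position, call.ref_allele, call.alt_allele
    if call.kind is VariantKind.DELETION:
        anchor = call.position - 1
        a = base(anchor)
        return call.locus.value, anchor, a + call.ref_allele, a
    # insertion: anchor base is the base the insertion follows
    a = base(call.position)
    return call.locus.value, call.position, a, a + call.alt_allele


_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=LEGACY,Number=1,Type=String,Description="Legacy variant name">\n'
    '##INFO=<ID=CATEGORY,Number=1,Type=String,Description="Catalogue category">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def write_variant_table(
    calls: list[VariantCall],
    annotations: dict[str, VariantAnnotation],
    path: str | Path,
    dialect: str = "tsv",
    refs: ReferenceSet | None = None,
) -> None:
    """Write calls as a legacy-name TSV or a minimal VCF 4.2.

    The VCF dialect needs the reference set to anchor indels; legacy
    names are preserved in the LEGACY info key because names such as
    ``c.605ins46`` are not valid HGVS and remain the primary identifier.
    """
    path = Path(path)
    if dialect == "tsv":
        lines = ["name\tlocus\tkind\tposition\tref_allele\talt_allele\tcategory"]
        for c in calls:
            ann = annotations.get(c.name)
            lines.append(
                f"{c.name}\t{c.locus.value}\t{c.kind.value}\t{c.position}\t"
                f"{c.ref_allele}\t{c.alt_allele}\t{ann.category if ann else 'novel'}"
            )
        path.write_text("\n".join(lines) + "\n")
        return
    if dialect != "vcf":
        raise ValueError(f"unknown dialect {dialect!r}")
    if refs is None:
        raise ValueError("VCF output requires the reference set for indel anchoring")
    out = [_VCF_HEADER.rstrip("\n")]
    for c in calls:
        chrom, pos, ref_a, alt_a = _vcf_fields(c, refs)
        ann = annotations.get(c.name)
        info = f"LEGACY={c.name};CATEGORY={ann.category if ann else 'novel'}"
        out.append(f"{chrom}\t{pos}\t.\t{ref_a}\t{alt_a}\t.\tPASS\t{info}")
    path.write_text("\n".join(out) + "\n")


def read_variant_table(path: str | Path, dialect: str = "tsv") -> list[VariantCall]:
    """Read calls back from either dialect, recovering normalized identity."""
    path = Path(path)
    calls: list[VariantCall] = []
    if dialect == "tsv":
        lines = path.read_text().strip().splitlines()
        for line in lines[1:]:
            name, locus, kind, pos, ref_a, alt_a, _cat = (line + "\t").split("\t")[:7]
            calls.append(
                VariantCall(Locus(locus), VariantKind(kind), int(pos), ref_a, alt_a)
            )
        return calls
    if dialect != "vcf":
        raise ValueError(f"unknown dialect {dialect!r}")
    for line in path.read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, pos, _id, ref_a, alt_a, *_ = line.split("\t")
        locus, pos = Locus(chrom), int(pos)
        if len(ref_a) == len(alt_a):
            kind = (
                VariantKind.SUBSTITUTION if len(ref_a) == 1 else VariantKind.MNV_SUBSTITUTION
            )
            calls.append(VariantCall(locus, kind, pos, ref_a, alt_a))
        elif len(ref_a) > len(alt_a) and ref_a.startswith(alt_a) and len(alt_a) == 1:
            calls.append(
                VariantCall(locus, VariantKind.DELETION, pos + 1, ref_a[1:], "")
            )
        elif len(alt_a) > len(ref_a) and alt_a.startswith(ref_a) and len(ref_a) == 1:
            calls.append(
                VariantCall(locus, VariantKind.INSERTION, pos, "", alt_a[1:])
            )
        else:
            raise ValueError(f"unsupported VCF allele pair {ref_a}>{alt_a} at {chrom}:{pos}")
    return calls


@dataclass
class PipelineConfig:
    """Flat pipeline configuration with the study-condition defaults."""

    seed: int = 0
    n_cases: int = 658
    n_controls: int = 462
    match: int = 1
    mismatch: int = -1
    gap: int = -2
    ci_high_threshold: float = 78.0
    ci_low_threshold: float = 50.0
    freq_ndigits: int = 2
    ci_ndigits: int = 1
    output_dir: str = "."
    input_fasta: str = ""
    subjects_tsv: str = ""
    verbose: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ci_low_threshold < self.ci_high_threshold:
            raise ValueError("CI bin thresholds must be strictly ordered")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a flat-key YAML config; unknown keys land in ``extra``."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {k: v for k, v in data.items() if k in PipelineConfig.__dataclass_fields__}
    extra = {k: v for k, v in data.items() if k not in PipelineConfig.__dataclass_fields__}
    return PipelineConfig(**known, extra=extra) if "extra" not in known else PipelineConfig(**known)
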