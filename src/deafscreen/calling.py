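"""Variant identification from Sanger-style consensus sequences.

A subject sequence is globally aligned to the locus reference
(Needleman-Wunsch, linear gap penalty), differences are extracted as
substitutions / multi-nucleotide substitutions / insertions / deletions,
indels are shifted to their left-most equivalent position, and each call
is named in the legacy style used throughout the deafness literature
(``c.235delC``, ``c.608TC>AA``, ``m.1555A>G``).

Legacy names predate strict HGVS normalization: deletions of one or two
bases spell the bases (``delC``, ``delAT``) while longer ones give the
length (``del16``); insertions spell up to four bases (``insAAGG``) and
give the length beyond that (``ins46``).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Locus",
    "VariantKind",
    "Alignment",
    "VariantCall",
    "AlignmentParams",
    "global_align",
    "extract_variants",
    "normalize_variant",
    "name_variant",
    "parse_variant_name",
    "call_sequence",
    "VariantNameError",
    "ReferenceMismatchError",
]


class Locus(str, Enum):
    """Screened loci: the GJB2 coding exon, the GJB2 exon-1/basal-promoter
    amplicon, and the mitochondrial 12S rRNA region."""

    GJB2 = "GJB2"
    GJB2_EX1 = "GJB2_EX1"
    MT12S = "MT12S"

    @property
    def prefix(self) -> str:
        """Coordinate prefix of legacy names at this locus."""
        return "m." if self is Locus.MT12S else "c."


class VariantKind(str, Enum):
    SUBSTITUTION = "substitution"
    MNV_SUBSTITUTION = "mnv_substitution"
    DELETION = "deletion"
    INSERTION = "insertion"


class VariantNameError(ValueError):
    """A legacy variant name that cannot be parsed."""


class ReferenceMismatchError(ValueError):
    """A call whose stated reference allele disagrees with the reference."""


@dataclass(frozen=True)
class AlignmentParams:
    """Linear-gap scoring. Defaults suit short, high-identity Sanger reads."""

    match: int = 1
    mismatch: int = -1
    gap: int = -2


@dataclass(frozen=True)
class Alignment:
    """A global pairwise alignment; equal-length gapped strings."""

    aligned_query: str
    aligned_ref: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_ref):
            raise ValueError("aligned strings must have equal length")


@dataclass(frozen=True, order=True)
class VariantCall:
    """A sequence change at a locus in 1-based locus coordinates.

    ``position`` is the first affected base for substitutions and
    deletions, and the anchor base (the base the new material follows)
    for insertions. Exactly one of ``ref_allele`` / ``alt_allele`` is
    empty for indels; both are non-empty and equal-length for
    (multi-)nucleotide substitutions.
    """

    locus: Locus = field(compare=False)
    kind: VariantKind = field(compare=False)
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"position must be >= 0, got {self.position}")
        if self.kind is VariantKind.DELETION:
            if not self.ref_allele or self.alt_allele:
                raise ValueError("deletion needs ref_allele only")
        elif self.kind is VariantKind.INSERTION:
            if self.ref_allele or not self.alt_allele:
                raise ValueError("insertion needs alt_allele only")
        else:
            if len(self.ref_allele) != len(self.alt_allele) or not self.ref_allele:
                raise ValueError("substitution alleles must be equal-length and non-empty")
            want = (
                VariantKind.SUBSTITUTION
                if len(self.ref_allele) == 1
                else VariantKind.MNV_SUBSTITUTION
            )
            if self.kind is not want:
                raise ValueError(f"kind {self.kind} inconsistent with allele length")

    @property
    def name(self) -> str:
        return name_variant(self)

    @property
    def end(self) -> int:
        """1-based position of the last reference base involved."""
        return self.position + max(len(self.ref_allele) - 1, 0)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def global_align(query: str, ref: str, params: AlignmentParams | None = None) -> Alignment:
    """Optimal global alignment under linear gap penalties.

    The dynamic program fills the score matrix row-wise with the
    horizontal (gap-in-query) dependency resolved by a running-maximum
    scan, which is exact for linear gaps. Traceback is deterministic
    with tie-break order diagonal > up (gap in reference) > left
    (gap in query).
    """
    if not query or not ref:
        raise ValueError("global_align requires non-empty sequences")
    p = params or AlignmentParams()
    q, r = _encode(query), _encode(ref)
    n, m = len(q), len(r)
    gap = p.gap
    H = np.empty((n + 1, m + 1), dtype=np.float64)
    H[0, :] = gap * np.arange(m + 1)
    H[1:, 0] = gap * np.arange(1, n + 1)
    jg = gap * np.arange(m + 1)
    for i in range(1, n + 1):
        sub = np.where(r == q[i - 1], p.match, p.mismatch)
        cand = np.empty(m + 1)
        cand[0] = H[i, 0]
        np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] + gap, out=cand[1:])
        # H[i,j] = max_{k<=j} cand[k] + (j-k)*gap, via a prefix max scan
        H[i, :] = np.maximum.accumulate(cand - jg) + jg

    # Traceback. Base tie-break order is diagonal > up (gap in reference) >
    # left (gap in query); while walking through a gap run the run is
    # extended first, so an indel stays one contiguous run instead of being
    # split across equal-score placements (linear gap penalties score a
    # split run identically to a contiguous one).
    aq: list[str] = []
    ar: list[str] = []
    i, j = n, m
    prev = "diag"
    while i > 0 or j > 0:
        can_diag = i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + (
            p.match if q[i - 1] == r[j - 1] else p.mismatch
        )
        can_up = i > 0 and H[i, j] == H[i - 1, j] + gap
        can_left = j > 0 and H[i, j] == H[i, j - 1] + gap
        if prev == "up":
            order = ("up", "diag", "left")
        elif prev == "left":
            order = ("left", "diag", "up")
        else:
            order = ("diag", "up", "left")
        feasible = {"diag": can_diag, "up": can_up, "left": can_left}
        move = next(mv for mv in order if feasible[mv])
        if move == "diag":
            aq.append(query[i - 1])
            ar.append(ref[j - 1])
            i -= 1
            j -= 1
        elif move == "up":
            aq.append(query[i - 1])
            ar.append("-")
            i -= 1
        else:
            aq.append("-")
            ar.append(ref[j - 1])
            j -= 1
        prev = move
    return Alignment("".join(reversed(aq)), "".join(reversed(ar)), float(H[n, m]))


def extract_variants(
    alignment: Alignment, locus: Locus, coordinate_offset: int = 0
) -> list[VariantCall]:
    """Turn alignment columns into variant calls.

    Maximal runs of gap columns become one insertion or deletion;
    maximal runs of adjacent mismatch columns become one substitution
    (length 1) or mnv_substitution (length >= 2). Positions are reported
    in locus coordinates: ``coordinate_offset`` plus the 1-based
    reference index. Columns where the query has ``N`` are ambiguous
    and excluded with a warning.
    """
    calls: list[VariantCall] = []
    ref_pos = 0  # 1-based index of the last reference base consumed
    run_kind: str | None = None
    run_ref: list[str] = []
    run_alt: list[str] = []
    run_start = 0  # locus coordinate of the run (first base / anchor)
    run_ambiguous = False

    def flush() -> None:
        nonlocal run_kind, run_ref, run_alt, run_ambiguous
        if run_kind is None:
            return
        if run_ambiguous:
            warnings.warn(
                f"ambiguous call (N in query) near {locus.prefix}{run_start} excluded",
                stacklevel=2,
            )
        elif run_kind == "mismatch":
            ref_a, alt_a = "".join(run_ref), "".join(run_alt)
            kind = (
                VariantKind.SUBSTITUTION
                if len(ref_a) == 1
                else VariantKind.MNV_SUBSTITUTION
            )
            calls.append(VariantCall(locus, kind, run_start, ref_a, alt_a))
        elif run_kind == "del":
            calls.append(
                VariantCall(locus, VariantKind.DELETION, run_start, "".join(run_ref), "")
            )
        else:  # ins
            calls.append(
                VariantCall(locus, VariantKind.INSERTION, run_start, "", "".join(run_alt))
            )
        run_kind = None
        run_ref, run_alt = [], []
        run_ambiguous = False

    for qc, rc in zip(alignment.aligned_query, alignment.aligned_ref):
        if rc != "-":
            ref_pos += 1
        if qc == rc and qc != "-":
            flush()
            continue
        if rc == "-" and qc == "-":  # degenerate all-gap column
            flush()
            continue
        if rc != "-" and qc != "-":
            kind = "mismatch"
            start = coordinate_offset + ref_pos
        elif qc == "-":
            kind = "del"
            start = coordinate_offset + ref_pos
        else:
            kind = "ins"
            start = coordinate_offset + ref_pos  # anchor: base before the gap
        if run_kind != kind:
            flush()
            run_kind = kind
            run_start = start
        if rc != "-":
            run_ref.append(rc)
        if qc != "-":
            run_alt.append(qc)
        if qc == "N":
            run_ambiguous = True
    flush()
    return calls


def normalize_variant(call: VariantCall, ref: str, coordinate_offset: int = 0) -> VariantCall:
    """Shift an indel to its left-most equivalent placement; idempotent.

    Substitutions are returned unchanged. ``ref`` is the reference
    string whose 1-based index ``i`` corresponds to locus coordinate
    ``coordinate_offset + i``.
    """

    def base(pos: int) -> str:
        return ref[pos - coordinate_offset - 1]

    if call.kind is VariantKind.DELETION:
        pos, seg = call.position, call.ref_allele
        L = len(seg)
        lo = coordinate_offset + 1
        while pos > lo and base(pos - 1) == base(pos + L - 1):
            pos -= 1
            seg = base(pos) + seg[:-1]
        if seg != call.ref_allele or pos != call.position:
            return VariantCall(call.locus, call.kind, pos, seg, "")
        return call
    if call.kind is VariantKind.INSERTION:
        pos, seg = call.position, call.alt_allele
        lo = coordinate_offset + 1
        while pos >= lo and seg[-1] == base(pos):
            seg = base(pos) + seg[:-1]
            pos -= 1
        if pos != call.position:
            return VariantCall(call.locus, call.kind, pos, "", seg)
        return call
    return call


#: naming policy: spell deleted bases up to this length, else give the length
_DEL_SPELL_MAX = 2
#: naming policy: spell inserted bases up to this length, else give the length
_INS_SPELL_MAX = 4


def name_variant(call: VariantCall) -> str:
    """Render a call as a legacy-style name (``c.235delC``, ``m.1555A>G``)."""
    pre = call.locus.prefix
    if call.kind in (VariantKind.SUBSTITUTION, VariantKind.MNV_SUBSTITUTION):
        return f"{pre}{call.position}{call.ref_allele}>{call.alt_allele}"
    if call.kind is VariantKind.DELETION:
        body = (
            call.ref_allele
            if len(call.ref_allele) <= _DEL_SPELL_MAX
            else str(len(call.ref_allele))
        )
        return f"{pre}{call.position}del{body}"
    body = (
        call.alt_allele
        if len(call.alt_allele) <= _INS_SPELL_MAX
        else str(len(call.alt_allele))
    )
    return f"{pre}{call.position}ins{body}"


_NAME_RE = re.compile(
    r"""^(?P<prefix>[cm])\.\s*(?P<pos>\d+)\s*
        (?:
            (?P<ref>[ACGT]+)\s*>\s*(?P<alt>[ACGT]+)
          | del\s*(?P<delpart>[ACGT]+|\d+)(?:\s*\+\s*ins\s*(?P<delins>[ACGT]+))?
          | ins\s*(?P<inspart>[ACGT]+|\d+)
        )$""",
    re.VERBOSE,
)


def parse_variant_name(name: str) -> dict:
    """Parse a legacy variant name into its components.

    Returns a dict with keys ``prefix``, ``position``, ``kind`` and,
    depending on the form, ``ref``/``alt`` (spelled alleles) or
    ``length`` (numeric del/ins forms, whose bases must be resolved
    against a reference or catalogue). The historic combined form
    ``m.961delT+insC`` parses as kind ``delins`` with both alleles.
    """
    m = _NAME_RE.match(name.replace(" ", ""))
    if m is None:
        raise VariantNameError(f"unparseable legacy variant name: {name!r}")
    out: dict = {"prefix": m.group("prefix") + ".", "position": int(m.group("pos"))}
    if m.group("ref"):
        if len(m.group("ref")) != len(m.group("alt")):
            raise VariantNameError(f"unequal substitution alleles in {name!r}")
        out["kind"] = "substitution" if len(m.group("ref")) == 1 else "mnv_substitution"
        out["ref"] = m.group("ref")
        out["alt"] = m.group("alt")
    elif m.group("delpart") is not None:
        part = m.group("delpart")
        if m.group("delins"):
            out["kind"] = "delins"
            if part.isdigit():
                raise VariantNameError(f"delins requires spelled bases: {name!r}")
            out["ref"] = part
            out["alt"] = m.group("delins")
        else:
            out["kind"] = "deletion"
            if part.isdigit():
                out["length"] = int(part)
            else:
                out["ref"] = part
    else:
        part = m.group("inspart")
        out["kind"] = "insertion"
        if part.isdigit():
            out["length"] = int(part)
        else:
            out["alt"] = part
    return out


def call_sequence(
    query: str,
    ref: str,
    locus: Locus,
    coordinate_offset: int = 0,
    params: AlignmentParams | None = None,
) -> list[VariantCall]:
    """Align, extract and left-normalize all variants in one step."""
    if query == ref:
        return []
    aln = global_align(query, ref, params)
    return [
        normalize_variant(c, ref, coordinate_offset)
        for c in extract_variants(aln, locus, coordinate_offset)
    ]
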