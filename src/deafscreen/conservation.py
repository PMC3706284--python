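"""Multi-species conservation index and mtDNA variant triage.

The conservation index (CI) of a position is the number of species in
an ortholog alignment — the human reference included — whose base at
that position equals the human wild-type base, expressed as a percent
of the species compared (half-up rounded to 1 decimal place). CI values
are binned as high (> 78%), mid (50-78%, both ends inclusive) and low
(< 50%).

Triage of a mitochondrial variant applies, in priority order:
(1) catalogued literature-confirmed deafness mutations keep their
pathogenic label; (2) presence in the control group marks a
polymorphism regardless of conservation; (3) absence from controls at
high CI marks a putative deafness-associated variant; (4) anything else
stays unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .calling import Locus
from .catalogue import Catalogue

__all__ = [
    "CIRecord",
    "TriageResult",
    "CI_HIGH_THRESHOLD",
    "CI_LOW_THRESHOLD",
    "map_msa_columns",
    "conservation_index",
    "summarize_ci_bins",
    "triage_mt_variant",
]

CI_HIGH_THRESHOLD = 78.0
CI_LOW_THRESHOLD = 50.0


@dataclass(frozen=True)
class CIRecord:
    """Conservation of one m. position."""

    position: int
    wildtype_base: str
    matches: int
    total_species: int
    ci_percent: float
    bin: str  # high | mid | low

    def __post_init__(self) -> None:
        if not 1 <= self.matches <= self.total_species:
            raise ValueError("matches must lie in [1, total_species]")

    @property
    def label(self) -> str:
        """Printed form, e.g. ``20/22(90.9%)``."""
        pct = f"{self.ci_percent:g}"
        return f"{self.matches}/{self.total_species}({pct}%)"


@dataclass(frozen=True)
class TriageResult:
    name: str
    tclass: str  # known_pathogenic | putative_deafness_associated | polymorphism | unclassified
    rule_fired: str


def _ci_percent(matches: int, total: int, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float((Decimal(matches) * 100 / Decimal(total)).quantize(q, ROUND_HALF_UP))


def _bin(ci: float, high: float = CI_HIGH_THRESHOLD, low: float = CI_LOW_THRESHOLD) -> str:
    if ci > high:
        return "high"
    if ci >= low:
        return "mid"
    return "low"


def map_msa_columns(
    msa, reference_row_id: str, coordinate_offset: int = 0
) -> dict[int, int]:
    """Map locus positions to alignment columns via the reference row.

    Every non-gap base of the reference row maps to exactly one column;
    columns where the reference has a gap carry no position.
    """
    ref_row = None
    for rec in msa:
        if rec.id == reference_row_id:
            ref_row = str(rec.seq)
            break
    if ref_row is None:
        raise KeyError(f"reference row {reference_row_id!r} not in alignment")
    mapping: dict[int, int] = {}
    pos = coordinate_offset
    for col, base in enumerate(ref_row):
        if base != "-":
            pos += 1
            mapping[pos] = col
    return mapping


def conservation_index(
    msa,
    position: int,
    wildtype_base: str,
    reference_row_id: str = "human",
    coordinate_offset: int = 0,
    column_map: dict[int, int] | None = None,
    high_threshold: float = CI_HIGH_THRESHOLD,
    low_threshold: float = CI_LOW_THRESHOLD,
) -> CIRecord:
    """CI of one position: rows matching the wild-type base, gaps count as
    non-matches, the reference row contributes its own match."""
    cmap = column_map or map_msa_columns(msa, reference_row_id, coordinate_offset)
    if position not in cmap:
        raise KeyError(f"position {position} not mapped in the alignment")
    col = cmap[position]
    total = len(msa)
    matches = sum(1 for rec in msa if str(rec.seq[col]).upper() == wildtype_base)
    ci = _ci_percent(matches, total)
    return CIRecord(position, wildtype_base, matches, total, ci, _bin(ci, high_threshold, low_threshold))


def summarize_ci_bins(records: list[CIRecord]) -> tuple[int, int, int]:
    """(n_high, n_mid, n_low) — a partition of the records."""
    n_high = sum(r.bin == "high" for r in records)
    n_mid = sum(r.bin == "mid" for r in records)
    return n_high, n_mid, len(records) - n_high - n_mid


def triage_mt_variant(
    name: str,
    case_count: int,
    control_count: int,
    ci_percent: float,
    catalogue: Catalogue,
    high_threshold: float = CI_HIGH_THRESHOLD,
) -> TriageResult:
    """Classify a 12S variant; exactly one rule fires, in priority order."""
    if case_count < 0 or control_count < 0:
        raise ValueError("carrier counts must be non-negative")
    ann = catalogue.get(name, Locus.MT12S)
    if ann is not None and ann.is_pathogenic:
        return TriageResult(name, "known_pathogenic", "catalogued_deafness_mutation")
    if control_count > 0:
        return TriageResult(name, "polymorphism", "present_in_controls")
    if ci_percent > high_threshold:
        return TriageResult(
            name, "putative_deafness_associated", "absent_in_controls_high_ci"
        )
    return TriageResult(name, "unclassified", "no_rule_matched")
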