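"""Coarse RNA secondary-structure prediction and comparison.

Structures are predicted by base-pair maximization (Nussinov-style
dynamic programming) over Watson-Crick and G·U wobble pairs with a
minimum hairpin-loop size, and compared by base-pair distance — the
size of the symmetric difference of the two pair sets. This is a
deliberately coarse model: it maximizes pairing count, not free
energy, and is used to ask whether a variant perturbs the predicted
pairing around its position, not to reproduce any particular published
fold.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "RnaStructure",
    "StructureDelta",
    "fold_rna",
    "structure_delta",
    "bp_distance",
]

_CAN_PAIR = {
    ("A", "U"), ("U", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "U"), ("U", "G"),
}

MIN_LOOP = 3


@dataclass(frozen=True)
class RnaStructure:
    """A pseudoknot-free secondary structure.

    ``pairs`` hold 1-based (i, j) with i < j; ``dot_bracket`` is the
    usual parenthesis notation.
    """

    sequence: str  # RNA alphabet (U, not T)
    pairs: frozenset[tuple[int, int]]
    dot_bracket: str

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def partner(self, position: int) -> int | None:
        for i, j in self.pairs:
            if i == position:
                return j
            if j == position:
                return i
        return None


@dataclass(frozen=True)
class StructureDelta:
    """How a variant changed the predicted structure."""

    bp_distance: int
    altered: bool
    local_window_report: list[tuple[int, int | None, int | None]]
    # (position, wild-type partner, variant partner) near the variant

    def __post_init__(self) -> None:
        assert self.altered == (self.bp_distance > 0)


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in _CAN_PAIR


def fold_rna(sequence: str, min_loop: int = MIN_LOOP) -> RnaStructure:
    """Maximum-pairing fold with deterministic traceback.

    T is auto-transcribed to U. Ties are broken by preferring to leave
    the 5' base unpaired, then by the smallest pairing partner.
    """
    seq = sequence.upper().replace("T", "U")
    if not seq:
        raise ValueError("cannot fold an empty sequence")
    if not set(seq) <= set("ACGU"):
        raise ValueError("sequence must be over A/C/G/U (or T)")
    n = len(seq)
    M = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = M[i + 1][j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if _can_pair(seq[i], seq[k]):
                    inner = M[i + 1][k - 1] if k - 1 > i + 1 else 0
                    right = M[k + 1][j] if k + 1 <= j else 0
                    best = max(best, 1 + inner + right)
            M[i][j] = best

    pairs: set[tuple[int, int]] = set()
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        if M[i][j] == M[i + 1][j]:  # prefer leaving i unpaired
            stack.append((i + 1, j))
            continue
        for k in range(i + min_loop + 1, j + 1):  # then smallest partner
            if _can_pair(seq[i], seq[k]):
                inner = M[i + 1][k - 1] if k - 1 > i + 1 else 0
                right = M[k + 1][j] if k + 1 <= j else 0
                if M[i][j] == 1 + inner + right:
                    pairs.add((i + 1, k + 1))
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    break

    db = ["."] * n
    for i, j in pairs:
        db[i - 1] = "("
        db[j - 1] = ")"
    return RnaStructure(seq, frozenset(pairs), "".join(db))


def bp_distance(a: RnaStructure, b: RnaStructure) -> int:
    """Symmetric difference of the pair sets; zero iff identical."""
    return len(a.pairs ^ b.pairs)


def structure_delta(
    wt: RnaStructure,
    mut: RnaStructure,
    variant_position: int,
    window: int = 15,
    indel: bool = False,
) -> StructureDelta:
    """Quantify the structural change a variant induces.

    The window report lists positions within ``window`` of the variant
    whose pairing partner changed. Sequences of unequal length are only
    accepted when ``indel`` is set, in which case positions 3' of the
    variant are compared naively (no coordinate projection).
    """
    if len(wt.sequence) != len(mut.sequence) and not indel:
        raise ValueError("sequence lengths differ but no indel variant was declared")
    d = bp_distance(wt, mut)
    lo, hi = variant_position - window, variant_position + window
    report: list[tuple[int, int | None, int | None]] = []
    for pos in range(max(1, lo), min(max(len(wt.sequence), len(mut.sequence)), hi) + 1):
        pw, pm = wt.partner(pos), mut.partner(pos)
        if pw != pm:
            report.append((pos, pw, pm))
    return StructureDelta(d, d > 0, report)
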