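"""The AW-box motif pattern CNTNG(N)7CG and basic sequence utilities.

The canonical AW box is a 14-mer with five conserved slots — C at position 1,
T at 3, G at 5 and CG at 13–14 — and nine variable slots N1..N9 occupying
positions 2, 4 and 6–12 (1-based).  WRI1-class transcription factors also
bind a non-canonical form carrying one extra internal base, which this module
models as a single tolerated insertion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "MOTIF_LENGTH",
    "FIXED_SLOTS",
    "N_SLOTS",
    "MotifPattern",
    "AW_BOX",
    "AW_BOX_INSERTION",
    "reverse_complement",
    "matches_canonical",
    "insertion_offsets",
    "n_bases",
    "iupac_code",
]

MOTIF_LENGTH = 14

# 0-based slot -> conserved base
FIXED_SLOTS: dict[int, str] = {0: "C", 2: "T", 4: "G", 12: "C", 13: "G"}

# 0-based slots of N1..N9, in order
N_SLOTS: tuple[int, ...] = (1, 3, 5, 6, 7, 8, 9, 10, 11)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T", frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("GT"): "K", frozenset("AC"): "M", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


@dataclass(frozen=True)
class MotifPattern:
    """AW-box pattern: fixed slots plus N slots, with 0 or 1 tolerated insertions."""

    max_insertions: int = 0
    fixed_slots: dict[int, str] = field(default_factory=lambda: dict(FIXED_SLOTS))

    def __post_init__(self) -> None:
        if self.max_insertions not in (0, 1):
            raise ValueError("max_insertions must be 0 or 1")

    @property
    def length(self) -> int:
        return MOTIF_LENGTH

    @property
    def n_slots(self) -> tuple[int, ...]:
        return N_SLOTS


AW_BOX = MotifPattern(max_insertions=0)
AW_BOX_INSERTION = MotifPattern(max_insertions=1)


def reverse_complement(seq: str) -> str:
    """Reverse complement over the ACGTN alphabet (involution)."""
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def matches_canonical(window: str, pattern: MotifPattern = AW_BOX) -> bool:
    """True if a 14-mer matches the fixed slots; N slots accept ACGT only.

    Windows containing the ambiguity character 'N' never match.
    """
    if len(window) != MOTIF_LENGTH:
        return False
    if "N" in window:
        return False
    return all(window[i] == b for i, b in pattern.fixed_slots.items())


def insertion_offsets(window: str, pattern: MotifPattern = AW_BOX) -> list[int]:
    """1-based positions whose deletion turns a 15-mer into a canonical match.

    Only internal insertions are considered: deleting the first or last base
    would re-anchor the conserved 5' C or 3' CG and is not allowed.
    """
    if len(window) != MOTIF_LENGTH + 1 or "N" in window:
        return []
    out = []
    for i in range(1, MOTIF_LENGTH):  # 0-based deletion index, internal only
        if matches_canonical(window[:i] + window[i + 1:], pattern):
            out.append(i + 1)
    return out


def n_bases(seq: str, insertion_offset: int | None = None) -> dict[int, str]:
    """Bases at N1..N9 (keys 1..9) of a canonical 14-mer.

    For a 15-mer insertion variant, ``insertion_offset`` (1-based) names the
    extra base, which is removed before reading the slots.
    """
    if len(seq) == MOTIF_LENGTH + 1:
        if insertion_offset is None:
            offs = insertion_offsets(seq)
            if not offs:
                raise ValueError(f"{seq!r} is not an AW-box insertion variant")
            insertion_offset = offs[0]
        seq = seq[: insertion_offset - 1] + seq[insertion_offset:]
    if not matches_canonical(seq):
        raise ValueError(f"{seq!r} does not match the canonical AW-box pattern")
    return {k + 1: seq[slot] for k, slot in enumerate(N_SLOTS)}


def iupac_code(bases) -> str:
    """Minimal IUPAC degeneracy code covering a non-empty set of bases."""
    key = frozenset(bases)
    if not key or not key <= set("ACGT"):
        raise ValueError(f"cannot encode base set {sorted(bases)!r}")
    return _IUPAC[key]
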