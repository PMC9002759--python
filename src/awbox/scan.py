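"""Strand-aware scanning of promoter sequences for AW boxes.

Hits are reported on the coding-strand footprint with both promoter-local
(0-based, half-open) and TIS-relative (signed, inclusive, no zero)
coordinates.  Minus-strand hits carry the matched sequence as read 5'->3' on
the minus strand, while their coordinates describe the occupied span on the
coding strand, matching the convention of published motif tables.
"""

from __future__ import annotations

from dataclasses import dataclass

from .coords import index_to_tis, span_length
from .pattern import (
    AW_BOX,
    AW_BOX_INSERTION,
    MOTIF_LENGTH,
    MotifPattern,
    insertion_offsets,
    matches_canonical,
    reverse_complement,
)

__all__ = ["PromoterSequence", "MotifHit", "scan_canonical",
           "scan_with_insertion", "dedupe_hits", "distance_gate",
           "hits_to_records"]


@dataclass(frozen=True)
class PromoterSequence:
    """One upstream region on the coding strand with its TIS annotation.

    ``tis_index`` is the promoter-local 0-based index of the first base of
    the ATG; ``tis_index == len(seq)`` means the ATG lies just beyond the
    sequenced region.  ``utr5_start`` is the TIS-relative (negative)
    coordinate where the 5'-UTR begins, when known.
    """

    gene_id: str
    seq: str
    tis_index: int
    utr5_start: int | None = None

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        object.__setattr__(self, "seq", seq)
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.gene_id}: invalid characters {sorted(bad)}")
        if not 0 <= self.tis_index <= len(seq):
            raise ValueError(
                f"{self.gene_id}: tis_index {self.tis_index} outside sequence "
                f"of length {len(seq)}")
        if self.utr5_start is not None and self.utr5_start >= 0:
            raise ValueError(f"{self.gene_id}: utr5_start must be negative")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class MotifHit:
    """A scanner match with local and TIS-relative coordinates."""

    gene_id: str
    local_start: int
    local_end: int  # half-open
    tis_start: int
    tis_end: int    # inclusive
    strand: str
    variant: str    # "canonical" | "insertion"
    matched_seq: str
    insertion_offset: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        expected = MOTIF_LENGTH + (1 if self.variant == "insertion" else 0)
        if self.local_end - self.local_start != expected:
            raise ValueError("hit span length inconsistent with variant")
        if span_length(self.tis_start, self.tis_end) != expected:
            raise ValueError("TIS span inconsistent with variant")


def _tis_span(promoter: PromoterSequence, start: int, end: int) -> tuple[int, int]:
    return (index_to_tis(start, promoter.tis_index),
            index_to_tis(end - 1, promoter.tis_index))


def _sorted(hits: list[MotifHit]) -> list[MotifHit]:
    return sorted(hits, key=lambda h: (h.local_start, h.strand, h.variant))


def scan_canonical(promoter: PromoterSequence,
                   pattern: MotifPattern = AW_BOX,
                   strands: str = "both") -> list[MotifHit]:
    """All canonical 14-mer AW-box matches on the requested strands.

    The minus strand is scanned by testing the reverse complement of each
    coding-strand window; sequence 'N' characters never match.
    """
    if strands not in ("both", "plus", "minus"):
        raise ValueError(f"invalid strands {strands!r}")
    if pattern.max_insertions != 0:
        raise ValueError("scan_canonical requires a canonical pattern")
    seq = promoter.seq
    hits: list[MotifHit] = []
    for start in range(len(seq) - MOTIF_LENGTH + 1):
        window = seq[start: start + MOTIF_LENGTH]
        end = start + MOTIF_LENGTH
        if strands in ("both", "plus") and matches_canonical(window, pattern):
            ts, te = _tis_span(promoter, start, end)
            hits.append(MotifHit(promoter.gene_id, start, end, ts, te, "+",
                                 "canonical", window))
        if strands in ("both", "minus"):
            rc = reverse_complement(window)
            if matches_canonical(rc, pattern):
                ts, te = _tis_span(promoter, start, end)
                hits.append(MotifHit(promoter.gene_id, start, end, ts, te, "-",
                                     "canonical", rc))
    return _sorted(hits)


def scan_with_insertion(promoter: PromoterSequence,
                        pattern: MotifPattern = AW_BOX_INSERTION,
                        strands: str = "both") -> list[MotifHit]:
    """Canonical hits plus 15-mers matching after one internal deletion.

    When several deletion positions within one window yield a match (runs of
    identical bases), the 5'-most offset on the matched strand is reported,
    giving deterministic output.  With ``max_insertions == 0`` the result
    equals :func:`scan_canonical`.
    """
    canonical_pattern = MotifPattern(max_insertions=0,
                                     fixed_slots=dict(pattern.fixed_slots))
    hits = scan_canonical(promoter, canonical_pattern, strands)
    if pattern.max_insertions == 0:
        return hits
    seq = promoter.seq
    for start in range(len(seq) - MOTIF_LENGTH):
        window = seq[start: start + MOTIF_LENGTH + 1]
        end = start + MOTIF_LENGTH + 1
        if strands in ("both", "plus"):
            offs = insertion_offsets(window, canonical_pattern)
            if offs:
                ts, te = _tis_span(promoter, start, end)
                hits.append(MotifHit(promoter.gene_id, start, end, ts, te, "+",
                                     "insertion", window, offs[0]))
        if strands in ("both", "minus"):
            rc = reverse_complement(window)
            offs = insertion_offsets(rc, canonical_pattern)
            if offs:
                ts, te = _tis_span(promoter, start, end)
                hits.append(MotifHit(promoter.gene_id, start, end, ts, te, "-",
                                     "insertion", rc, offs[0]))
    return _sorted(hits)


def dedupe_hits(hits: list[MotifHit]) -> list[MotifHit]:
    """Collapse hits with identical (gene, span, variant), keeping '+' first."""
    seen: dict[tuple, MotifHit] = {}
    for h in _sorted(hits):
        key = (h.gene_id, h.local_start, h.local_end, h.variant)
        seen.setdefault(key, h)
    return _sorted(list(seen.values()))


def distance_gate(hit: MotifHit, promoter: PromoterSequence,
                  max_distance: int = 500,
                  require_utr5: bool = False) -> tuple[bool, str]:
    """Positional plausibility gate for a hit.

    Passes iff |tis_start| <= max_distance (inclusive bound) and, when
    required and the promoter is annotated, the hit lies within the 5'-UTR.
    Returns (passed, reason); the reason names the failed condition.
    """
    if hit.gene_id != promoter.gene_id:
        raise ValueError("hit does not belong to this promoter")
    if abs(hit.tis_start) > max_distance:
        return False, (f"distance {abs(hit.tis_start)} bp from TIS exceeds "
                       f"max_distance {max_distance}")
    if require_utr5 and promoter.utr5_start is not None:
        in_utr = promoter.utr5_start <= hit.tis_start and hit.tis_end <= -1
        if not in_utr:
            return False, (f"span {hit.tis_start}/{hit.tis_end} outside the "
                           f"5'-UTR ({promoter.utr5_start}..-1)")
    return True, "within distance gate"


def hits_to_records(hits: list[MotifHit]) -> list[dict]:
    """Plain-dict rows (TSV-ready) for a list of hits."""
    return [
        {
            "gene_id": h.gene_id,
            "tis_start": h.tis_start,
            "tis_end": h.tis_end,
            "strand": h.strand,
            "variant": h.variant,
            "matched_seq": h.matched_seq,
            "local_start": h.local_start,
            "local_end": h.local_end,
            "insertion_offset": "" if h.insertion_offset is None else h.insertion_offset,
        }
        for h in hits
    ]
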