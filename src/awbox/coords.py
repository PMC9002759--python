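"""Signed, no-zero coordinate system anchored on the translation initiation site.

Positions upstream of the ATG are negative (−1 is the base immediately 5' of
the A of the ATG) and positions from the ATG onward are positive (+1 is the A
of the ATG).  There is no position 0, which is the convention under which the
promoter-fragment arithmetic used throughout this package is exact: a fragment
spanning −272..+51 is 323 bp long and a 14-bp motif starting at −110 ends at
−97.
"""

from __future__ import annotations

__all__ = [
    "TISCoordinate",
    "validate_coordinate",
    "index_to_tis",
    "tis_to_index",
    "span_length",
    "span_end",
]

TISCoordinate = int


def validate_coordinate(value: int) -> int:
    """Return ``value`` unchanged if it is a legal TIS-relative coordinate."""
    if not isinstance(value, (int,)) or isinstance(value, bool):
        raise TypeError(f"TIS coordinate must be an integer, got {value!r}")
    if value == 0:
        raise ValueError("TIS coordinates have no position 0 (-1 abuts +1)")
    return int(value)


def index_to_tis(i: int, tis_index: int) -> TISCoordinate:
    """Convert a promoter-local 0-based index to a TIS-relative coordinate.

    ``tis_index`` is the 0-based index of the first base of the ATG.  The base
    at ``tis_index`` maps to +1 and the base immediately upstream maps to −1.
    """
    if i < 0:
        raise ValueError(f"index {i} out of range (negative)")
    if i < tis_index:
        return i - tis_index
    return i - tis_index + 1


def tis_to_index(coord: TISCoordinate, tis_index: int) -> int:
    """Inverse of :func:`index_to_tis`."""
    validate_coordinate(coord)
    if coord < 0:
        return tis_index + coord
    return tis_index + coord - 1


def span_length(start: TISCoordinate, end: TISCoordinate) -> int:
    """Number of bases in the inclusive span ``start..end``.

    Spans crossing the TIS contain no position 0, so (−1, +1) has length 2.
    """
    validate_coordinate(start)
    validate_coordinate(end)
    if start > end:
        raise ValueError(f"span start {start} greater than end {end}")
    if (start > 0) == (end > 0):
        return end - start + 1
    # sign-crossing: upstream part has -start bases, downstream part end bases
    return -start + end


def span_end(start: TISCoordinate, length: int) -> TISCoordinate:
    """End coordinate of an inclusive span of ``length`` bases from ``start``."""
    validate_coordinate(start)
    if length < 1:
        raise ValueError(f"span length must be >= 1, got {length}")
    end = start + length - 1
    if start < 0 and end >= 0:
        end += 1  # skip the non-existent position 0
    return end
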