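"""Coordinate conventions and small interval/sequence helpers.

All genomic coordinates in this package are 1-based inclusive on the
forward strand, matching GFF3 and the packaged annotation table. The only
place 0-based half-open coordinates appear is BED export.
"""

from __future__ import annotations

Interval = tuple[int, int]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


def length(iv: Interval) -> int:
    return iv[1] - iv[0] + 1


def overlaps(a: Interval, b: Interval) -> bool:
    """True iff the two closed intervals share at least one position."""
    return a[0] <= b[1] and b[0] <= a[1]


def contains(outer: Interval, inner: Interval) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1]


def reciprocal_overlap(a: Interval, b: Interval) -> float:
    """min(overlap/|a|, overlap/|b|); 0 if disjoint."""
    ov = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if ov <= 0:
        return 0.0
    return min(ov / length(a), ov / length(b))


def to_bed(iv: Interval) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return iv[0] - 1, iv[1]


def from_bed(start: int, end: int) -> Interval:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


def local_to_genomic(p: int, offset: int, region_length: int, inverted: bool) -> int:
    """Map a 1-based position in an extracted region to a genomic position.

    For a same-orientation region the map is ``offset + p - 1``; for an
    inverted (reverse-complemented) region position p counts from the
    region's right genomic edge: ``offset + region_length - p``.
    """
    if inverted:
        return offset + region_length - p
    return offset + p - 1


def genomic_to_local(g: int, offset: int, region_length: int, inverted: bool) -> int:
    if inverted:
        return offset + region_length - g
    return g - offset + 1


def local_interval_to_genomic(
    iv: Interval, offset: int, region_length: int, inverted: bool
) -> Interval:
    a = local_to_genomic(iv[0], offset, region_length, inverted)
    b = local_to_genomic(iv[1], offset, region_length, inverted)
    return (min(a, b), max(a, b))
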