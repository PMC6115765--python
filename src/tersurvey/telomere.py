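"""Telomeric repeat inference and template-region localization.

Telomeric repeat units are defined only up to rotation and strand; units
are therefore stored as the lexicographically smallest rotation of the
G-richer strand. The template region of the telomerase RNA is the reverse
complement of the G-strand repeat, located by matching a doubled copy of
the repeat unit (which contains every rotation as a substring) against both
strands of a candidate sequence. A matched template typically repeats a few
of its first nucleotides at its end — the signature used to verify hits and
to extend them over the 3'-terminal repetition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil

from .intervals import Interval, revcomp
from .io import Genome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TelomereRepeat:
    unit: str  # canonical rotation of the G-rich-strand repeat
    source: str = "chromosome_ends"  # chromosome_ends | catalog | literature

    def __post_init__(self):
        if not 2 <= len(self.unit) <= 30:
            raise ValueError("repeat unit length must be in [2, 30]")
        if "G" not in self.unit:
            raise ValueError("stored strand of the unit must contain a G")


@dataclass(frozen=True)
class TemplateHit:
    interval: Interval  # forward-strand, 1-based inclusive, incl. extension
    strand: str  # pos: template on forward strand; neg: on reverse
    matched_length: int  # length of the core repeat match
    end_repeat_length: int  # prefix length repeated at the template's end

    def __post_init__(self):
        if self.end_repeat_length < 0:
            raise ValueError("end_repeat_length must be >= 0")


def canonical_rotation(unit: str) -> str:
    """Lexicographically smallest rotation; idempotent."""
    if not unit:
        raise ValueError("empty unit")
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def canonical_unit(unit: str) -> str | None:
    """Canonical rotation of the G-richer strand (ties lexicographic);
    None if neither strand contains a G."""
    fwd = canonical_rotation(unit)
    rev = canonical_rotation(revcomp(unit))
    gf, gr = fwd.count("G"), rev.count("G")
    if gf == gr == 0:
        return None
    if gf != gr:
        return fwd if gf > gr else rev
    return min(fwd, rev)


def doubled_query(repeat: TelomereRepeat) -> str:
    """Two concatenated copies of the unit: contains every rotation."""
    return repeat.unit * 2


def _is_primitive(unit: str) -> bool:
    k = len(unit)
    for d in range(1, k):
        if k % d == 0 and unit == unit[:d] * (k // d):
            return False
    return True


def _tandem_runs(s: str, max_unit: int = 30):
    """Maximal tandem runs in s: yields (primitive unit, total_length, copies)."""
    n = len(s)
    for k in range(1, max_unit + 1):
        i = 0
        while i + k < n:
            if s[i] == s[i + k] and s[i] != "N":
                j = i
                while j + k < n and s[j] == s[j + k] and s[j] != "N":
                    j += 1
                total = (j - i) + k
                copies = total // k
                unit = s[i : i + k]
                if copies >= 2 and "N" not in unit and _is_primitive(unit):
                    yield unit, total, copies
                i = j + 1
            else:
                i += 1


def infer_repeat_unit(
    genome: Genome, terminal_window: int = 500, min_copies: int = 4
) -> TelomereRepeat | None:
    """Infer the telomeric repeat from contig termini.

    Returns the unit whose tandem arrays cover the largest total length over
    all termini, requiring at least ``min_copies`` consecutive copies in at
    least one terminus; None when no terminus is telomere-capped (the common
    case for assemblies that stop short of the telomeres).
    """
    if terminal_window < 60:
        raise ValueError("terminal_window must be >= 60")
    coverage: dict[str, int] = {}
    qualified: set[str] = set()
    for seq in genome.contigs.values():
        w = min(terminal_window, len(seq))
        termini = [seq[:w]]
        if len(seq) > w:
            termini.append(seq[-w:])
        for term in termini:
            for unit, total, copies in _tandem_runs(term):
                if len(unit) < 2:
                    continue
                cu = canonical_unit(unit)
                if cu is None:
                    continue
                coverage[cu] = coverage.get(cu, 0) + total
                if copies >= min_copies:
                    qualified.add(cu)
    if not qualified:
        return None
    best = max(qualified, key=lambda u: (coverage[u], -len(u), u))
    return TelomereRepeat(unit=best, source="chromosome_ends")


def _periodic_windows(unit_pat: str, text: str, min_len: int, max_mismatch: int):
    """Maximal windows of text matching the periodic extension of unit_pat.

    For each of the k phase alignments, a two-pointer sweep finds maximal
    windows containing at most ``max_mismatch`` mismatches (N always
    mismatches), trimmed so windows start and end on a match. Yields
    (start, end, length, matches) 0-based half-open tuples with
    length >= min_len, best window per phase.
    """
    k = len(unit_pat)
    n = len(text)
    out = []
    for phase in range(k):
        is_match = [
            text[i] == unit_pat[(i + phase) % k] and text[i] != "N"
            for i in range(n)
        ]
        best = None
        left = 0
        mm = 0
        for right in range(n):
            if not is_match[right]:
                mm += 1
            while mm > max_mismatch:
                if not is_match[left]:
                    mm -= 1
                left += 1
            # trim so each window edge sits on 3 consecutive matches; this
            # keeps the mismatch budget from bridging into chance matches
            # just outside the genuine periodic region
            a, b = left, right
            while a <= b - 2 and not (
                is_match[a] and is_match[a + 1] and is_match[a + 2]
            ):
                a += 1
            while b >= a + 2 and not (
                is_match[b] and is_match[b - 1] and is_match[b - 2]
            ):
                b -= 1
            if b - a < 2:
                continue
            L = b - a + 1
            if L >= min_len and (best is None or L > best[2]):
                matches = sum(is_match[a : b + 1])
                best = (a, b + 1, L, matches)
        if best is not None:
            out.append(best)
    return out


def _longest_prefix_suffix(s: str, min_overlap: int) -> int:
    for ell in range(len(s) - 1, min_overlap - 1, -1):
        if s[:ell] == s[-ell:]:
            return ell
    return 0


def verify_template_ends(template_seq: str, min_overlap: int = 3):
    """(True, L) iff a prefix of length L >= min_overlap equals a suffix;
    L is the longest such proper overlap."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if len(template_seq) < 2 * min_overlap:
        return False, 0
    ell = _longest_prefix_suffix(template_seq, min_overlap)
    return (ell > 0), ell


def find_template(
    candidate_seq: str,
    repeat: TelomereRepeat,
    min_match: int | None = None,
) -> list[TemplateHit]:
    """Locate template-region matches of the doubled repeat query on both
    strands of a candidate sequence.

    Matching is ungapped, tolerating one mismatch per 9 nt of ``min_match``
    (default 1.5 unit lengths). Each core match is extended across the
    template's 3'-terminal repetition of its first nucleotides when present
    (transcript orientation); hits are ranked by total matched span — the
    end repetition is the verification signature that separates genuine
    templates from chance repeat-phase matches of the same core length.
    """
    if not candidate_seq:
        return []
    k = len(repeat.unit)
    if min_match is None:
        min_match = ceil(1.5 * k)
    if min_match < k:
        raise ValueError("min_match must be >= unit length")
    max_mismatch = max(1, min_match // 9)
    # pattern on the transcript strand: rc of the G-strand repeat
    unit_pat = revcomp(repeat.unit)
    n = len(candidate_seq)
    raw = []
    for strand, text in (("pos", candidate_seq), ("neg", revcomp(candidate_seq))):
        for t0, t1, L, matches in _periodic_windows(
            unit_pat, text, min_match, max_mismatch
        ):
            # 3'-end repetition: a few nt from the template's start repeated
            # just past its end (transcript orientation = rightward in text).
            # The window may over-extend a little leftward into chance phase
            # matches; allow the repeated prefix to start up to 2 nt into
            # the window and trim the reported start accordingly.
            core = text[t0:t1]
            ext = 0
            shift = 0
            for j in range(0, min(3, len(core) - min_match + 1)):
                for ell in range(min(k, n - t1), 2, -1):
                    if text[t1 : t1 + ell] == core[j : j + ell]:
                        ext = ell
                        shift = j
                        break
                if ext:
                    break
            t0 += shift
            L -= shift
            matches -= shift
            s_t, e_t = t0, t1 + ext
            if strand == "neg":
                s_f, e_f = n - e_t, n - s_t
            else:
                s_f, e_f = s_t, e_t
            raw.append(
                (
                    matches,
                    TemplateHit(
                        interval=(s_f + 1, e_f),
                        strand=strand,
                        matched_length=L,
                        end_repeat_length=ext,
                    ),
                )
            )
    # verified hits (end repetition present) first, then matched bases plus
    # repetition length, then exact matches (chance windows almost always
    # spend the mismatch budget), ties leftmost
    raw.sort(
        key=lambda mh: (
            0 if mh[1].end_repeat_length else 1,
            -(mh[0] + mh[1].end_repeat_length),
            -mh[0],
            mh[1].interval[0],
        )
    )
    raw = [h for _, h in raw]
    kept: list[TemplateHit] = []
    for h in raw:
        if any(
            not (h.interval[1] < kh.interval[0] or kh.interval[1] < h.interval[0])
            for kh in kept
        ):
            continue
        kept.append(h)
    return kept
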