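"""Microsatellite detection and the single-SSR candidate filter.

Perfect repeats of primitive 1-6 nt units are mined with the classic
per-unit-length minimum-repeat thresholds; adjacent runs are joined into
compound (c) or imperfect-compound (c*) hits; sequences carrying exactly
one qualifying repeat with both flanks long enough pass on to clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

from .dna import canonical_rotation, is_primitive
from .seqio import Read

if TYPE_CHECKING:  # pragma: no cover
    from .config import PipelineConfig

#: Conventional minimum repeat counts by unit length (mono through hexa).
DEFAULT_MIN_REPEATS = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

PERFECT_TYPES = frozenset({"p1", "p2", "p3", "p4", "p5", "p6"})
SSR_TYPES = PERFECT_TYPES | {"c", "c*"}


@dataclass(frozen=True)
class SSRHit:
    """A detected repeat run.

    unit: primitive motif as first observed (phase not canonicalised);
    for compound hits the constituent units joined by '-'.
    repeats: run repeat count; for compound hits the maximum over
    constituents (used by the minimum-repetition filter).
    start/end: 0-based half-open span on the source sequence; for p-types
    end - start == unit_len * repeats.
    type: p1..p6, c (adjacent runs) or c* (runs separated by a short gap).
    """

    unit: str
    unit_len: int
    repeats: int
    start: int
    end: int
    type: str
    left_flank_len: int
    right_flank_len: int
    parts: tuple["SSRHit", ...] = ()

    @property
    def label(self) -> str:
        """Motif cell text, e.g. ``(AC)8`` or ``(AC)6-(AG)6``."""
        if self.parts:
            return "-".join(p.label for p in self.parts)
        return f"({self.unit}){self.repeats}"

    @property
    def motif_key(self) -> tuple[str, ...]:
        """Phase-independent motif identity used for consistency checks."""
        if self.parts:
            return tuple(canonical_rotation(p.unit) for p in self.parts)
        return (canonical_rotation(self.unit),)


def find_perfect_ssrs(
    seq: str, min_repeats: dict[int, int] | None = None
) -> list[SSRHit]:
    """All maximal perfect repeat runs meeting the per-unit thresholds.

    A run of period u starting at i is maximal at base resolution: it
    cannot be extended by one base on either side.  Runs whose unit is a
    repetition of a shorter unit are skipped (they are reported under the
    shorter, primitive unit), so each maximal run appears exactly once,
    phased at its leftmost start.  N breaks runs and never occurs inside
    a reported unit.  Hits are returned left to right.
    """
    if min_repeats is None:
        min_repeats = DEFAULT_MIN_REPEATS
    seq = seq.upper()
    n = len(seq)
    hits: list[SSRHit] = []
    for u in range(1, 7):
        thr = min_repeats.get(u)
        if thr is None:
            continue
        j = u
        while j < n:
            if seq[j] == seq[j - u] and seq[j] != "N":
                s = j
                while j < n and seq[j] == seq[j - u] and seq[j] != "N":
                    j += 1
                i = s - u
                t = (j - s) + u  # base length of the periodic run
                k = t // u
                unit = seq[i : i + u]
                if k >= thr and "N" not in unit and is_primitive(unit):
                    hits.append(
                        SSRHit(
                            unit=unit,
                            unit_len=u,
                            repeats=k,
                            start=i,
                            end=i + u * k,
                            type=f"p{u}",
                            left_flank_len=i,
                            right_flank_len=n - (i + u * k),
                        )
                    )
            else:
                j += 1
    hits.sort(key=lambda h: (h.start, h.unit_len))
    return hits


def join_compound(hits: list[SSRHit], max_gap: int = 100) -> list[SSRHit]:
    """Join neighbouring runs into compound hits.

    Consecutive hits (sorted by start) whose gap is <= 0 (adjacent or
    overlapping phases) merge into type ``c``; a gap of 1..max_gap makes
    the merged hit type ``c*``.  Hits farther apart stay separate.  The
    merged span covers all constituents plus gaps; the total sequence
    length is preserved in the flank fields.
    """
    if not hits:
        return []
    hits = sorted(hits, key=lambda h: (h.start, h.end))
    seq_len = hits[0].end + hits[0].right_flank_len
    out: list[SSRHit] = []
    chain: list[SSRHit] = [hits[0]]
    imperfect = False

    def flush() -> None:
        nonlocal imperfect
        if len(chain) == 1:
            out.append(chain[0])
        else:
            parts = tuple(chain)
            start = chain[0].start
            end = chain[-1].end
            out.append(
                SSRHit(
                    unit="-".join(p.unit for p in chain),
                    unit_len=min(p.unit_len for p in chain),
                    repeats=max(p.repeats for p in chain),
                    start=start,
                    end=end,
                    type="c*" if imperfect else "c",
                    left_flank_len=start,
                    right_flank_len=seq_len - end,
                    parts=parts,
                )
            )
        imperfect = False

    for h in hits[1:]:
        gap = h.start - chain[-1].end
        if gap <= max_gap:
            if gap >= 1:
                imperfect = True
            chain.append(h)
        else:
            flush()
            chain = [h]
    flush()
    return out


@dataclass
class FilterDecision:
    """Outcome of the single-SSR candidate filter for one sequence."""

    read: Read
    hit: SSRHit | None
    reason: str | None  # None when passed; 'no_ssr' or 'multi_ssr' otherwise

    @property
    def passed(self) -> bool:
        return self.reason is None


def filter_candidates(
    seq: Read, hits: list[SSRHit], cfg: "PipelineConfig"
) -> FilterDecision:
    """Keep sequences with exactly one qualifying repeat.

    A hit is discarded outright when its type is excluded or its repeat
    count is below the minimum motif repetition.  A surviving hit
    qualifies iff both flanking regions are at least the minimum flank
    length.  Exactly one qualifying hit -> pass; zero -> 'no_ssr';
    more than one independent qualifying hit -> 'multi_ssr'.
    """
    qualifying = []
    for h in hits:
        if h.type in cfg.excluded_ssr_types:
            continue
        if h.repeats < cfg.min_motif_repetition:
            continue
        if h.left_flank_len >= cfg.min_flank_len and h.right_flank_len >= cfg.min_flank_len:
            qualifying.append(h)
    if not qualifying:
        return FilterDecision(read=seq, hit=None, reason="no_ssr")
    if len(qualifying) > 1:
        return FilterDecision(read=seq, hit=None, reason="multi_ssr")
    return FilterDecision(read=seq, hit=qualifying[0], reason=None)
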