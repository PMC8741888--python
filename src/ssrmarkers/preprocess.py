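"""Read preprocessing: adapter removal, quality trimming, pair merging,
and the restriction-site authenticity filter.

These are self-contained equivalents of the usual trimming/merging tools
(sliding-window quality trim, mismatch-tolerant 3' adapter clipping,
overlap-consensus pair merging), with their conventional defaults, so the
whole pipeline is reproducible without external binaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dna import revcomp
from .seqio import Read


@dataclass
class TrimParams:
    """Quality/adapter trimming parameters.

    window / min_mean_q: a 5'→3' sliding window of `window` bases cuts the
    read at the first window whose mean Phred quality drops below
    `min_mean_q` (the classic sliding-window scheme, defaults 4 / Q15).
    min_len: reads shorter than this after trimming are dropped (36).
    adapter_max_error_rate: highest allowed mismatch fraction when locating
    a 3' adapter (0.10).
    adapter_min_overlap: shortest adapter prefix considered at the read's
    3' end; 1 so that even a single read-through base is clipped.
    """

    window: int = 4
    min_mean_q: float = 15.0
    min_len: int = 36
    adapter_max_error_rate: float = 0.10
    adapter_min_overlap: int = 1

    def __post_init__(self) -> None:
        if self.window < 1 or self.min_len < 1:
            raise ValueError("window and min_len must be >= 1")


@dataclass
class MergeParams:
    """Overlap-merging parameters: minimum overlap length (10 bp) and the
    highest accepted mismatch density within the overlap (0.25)."""

    min_overlap: int = 10
    max_mismatch_density: float = 0.25

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0.0 <= self.max_mismatch_density <= 1.0:
            raise ValueError("max_mismatch_density must be in [0, 1]")


def _locate_adapter(bases: str, adapter: str, params: TrimParams) -> int | None:
    """Best 3' occurrence of `adapter` in `bases`, or None.

    Semi-global: the adapter may run off the read's 3' end.  For every
    start offset the compared prefix of the adapter is scored by Hamming
    mismatches; offsets whose error rate exceeds the allowed maximum are
    rejected.  Among qualifying offsets the one maximising
    (matched bases − errors) wins, ties going to the leftmost (longest
    removal); this prefers a genuine full-length adapter hit over a
    spurious short suffix match.
    """
    n, la = len(bases), len(adapter)
    best_off = None
    best_score = -1
    for i in range(0, n - params.adapter_min_overlap + 1):
        compared = min(la, n - i)
        errors = sum(
            1 for a, b in zip(bases[i : i + compared], adapter[:compared]) if a != b
        )
        if errors > params.adapter_max_error_rate * compared:
            continue
        score = compared - errors
        if score > best_score:
            best_score = score
            best_off = i
    return best_off


def trim_read(
    read: Read, adapters: list[str], params: TrimParams
) -> Read | None:
    """Clip 3' adapters, quality-trim, drop short reads.

    Returns the trimmed read or None when it is dropped (a normal,
    counted outcome).  The output is always a prefix of the input bases.
    """
    if read.quals is None:
        raise ValueError(f"read {read.id!r} has no qualities")
    bases, quals = read.bases, read.quals

    for adapter in adapters:
        if not adapter:
            continue
        off = _locate_adapter(bases, adapter.upper(), params)
        if off is not None:
            bases, quals = bases[:off], quals[:off]
    if not bases:
        return None

    w = params.window
    cut = len(bases)
    for i in range(0, len(bases) - w + 1):
        if sum(quals[i : i + w]) / w < params.min_mean_q:
            cut = i
            break
    bases, quals = bases[:cut], quals[:cut]

    if len(bases) < params.min_len:
        return None
    return Read(id=read.id, bases=bases, quals=quals)


def merge_pair(r1: Read, r2: Read, params: MergeParams) -> Read | None:
    """Merge a read pair by 3' overlap; None when no acceptable overlap.

    r2 is reverse-complemented (qualities reversed) and slid against the
    3' end of r1.  Every overlap length L >= min_overlap is scored by its
    mismatch density m/L; the density-minimising candidate (ties broken
    toward the longer overlap, which is the deterministic choice when the
    overlap sits inside a repeat) is accepted if the density does not
    exceed the configured maximum.  Consensus: at agreements the base is
    shared and the quality is the max of the two; at disagreements the
    higher-quality base wins with quality = the difference.

    Feeding the same read as both mates reproduces that read unchanged,
    which is what makes single-end mode (same file twice) work.
    """
    if r1.quals is None or r2.quals is None:
        raise ValueError("merge_pair requires quality values")
    rc = revcomp(r2.bases)
    rcq = r2.quals[::-1]

    a = np.frombuffer(r1.bases.encode(), dtype=np.uint8)
    b = np.frombuffer(rc.encode(), dtype=np.uint8)
    n1, n2 = len(a), len(b)

    best: tuple[float, int] | None = None  # (density, L)
    max_l = min(n1, n2)
    for L in range(params.min_overlap, max_l + 1):
        m = int((a[n1 - L :] != b[:L]).sum())
        d = m / L
        if best is None or d < best[0] or (d == best[0] and L > best[1]):
            best = (d, L)
    if best is None or best[0] > params.max_mismatch_density:
        return None

    L = best[1]
    off = n1 - L
    bases = list(r1.bases[:off])
    quals = list(r1.quals[:off])
    for j in range(L):
        x, qx = r1.bases[off + j], r1.quals[off + j]
        y, qy = rc[j], rcq[j]
        if x == y:
            bases.append(x)
            quals.append(max(qx, qy))
        elif qx >= qy:
            bases.append(x)
            quals.append(qx - qy)
        else:
            bases.append(y)
            quals.append(qy - qx)
    bases.extend(rc[L:])
    quals.extend(rcq[L:])
    return Read(id=r1.id, bases="".join(bases), quals=quals)


def filter_restriction(seq: Read | str, pattern: str, anchor: str = "either") -> bool:
    """True iff the residual restriction pattern occurs at the anchored
    position.  An empty pattern disables the filter (always True).

    anchor: 'start' (prefix), 'end' (suffix), 'either' (prefix or
    suffix), 'anywhere' (substring).
    """
    bases = seq.bases if isinstance(seq, Read) else seq
    if not pattern:
        return True
    pattern = pattern.upper()
    if anchor == "start":
        return bases.startswith(pattern)
    if anchor == "end":
        return bases.endswith(pattern)
    if anchor == "either":
        return bases.startswith(pattern) or bases.endswith(pattern)
    if anchor == "anywhere":
        return pattern in bases
    raise ValueError(f"unknown restriction anchor {anchor!r}")
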