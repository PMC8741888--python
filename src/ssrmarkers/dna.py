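"""Small DNA string utilities shared across the pipeline."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G/C bases; 0.0 for the empty string."""
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer(seq: str) -> int:
    """Length of the longest single-base run in `seq`."""
    best = run = 0
    prev = ""
    for b in seq:
        run = run + 1 if b == prev else 1
        prev = b
        best = max(best, run)
    return best


def is_primitive(unit: str) -> bool:
    """True if `unit` is not itself a repetition of a shorter unit.

    A string of length n is periodic with period p < n dividing n iff
    rotating it by p leaves it unchanged; equivalently, unit occurs in
    (unit + unit) at an offset other than 0 and n.
    """
    if not unit:
        return False
    doubled = (unit + unit).find(unit, 1)
    return doubled == len(unit)


def canonical_rotation(unit: str) -> str:
    """Lexicographically smallest rotation; phase-independent motif key."""
    return min(unit[i:] + unit[:i] for i in range(len(unit)))
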